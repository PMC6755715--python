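"""scikit-learn style estimator wrapping the compile/annotate pipeline.

``EntityRecognizer`` is fit on a vocabulary (the lexicon terms, optionally
with term→URI links) and then annotates free text.  It follows the sklearn
estimator contract — constructor stores hyper-parameters verbatim,
``fit`` learns the four-part index into trailing-underscore attributes,
``get_params``/``set_params``/``clone`` work — so it composes with sklearn
model-selection utilities even though its "X" at fit time is a term list and
at transform time a list of documents.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .lexicon import (
    LinksTable,
    RawLexicon,
    compile_lexicon,
    load_compiled,
    save_compiled,
)
from .normalization import NormalizationConfig
from .recognizer import Annotation, recognize

__all__ = ["EntityRecognizer"]


class EntityRecognizer(TransformerMixin, BaseEstimator):
    """Dictionary-lookup named-entity recognizer and linker.

    Parameters
    ----------
    min_entity_length : int, default=3
        Minimum character length of words used for matching and of reported
        spans.
    stopwords : iterable of str, optional
        Stop-word list; ``None`` selects the packaged default.
    entity_type : str, optional
        Value for the entity-type column of the output; defaults to *name*.
    name : str, default="lexicon"
        Lexicon identifier, used for the on-disk file layout.

    Attributes
    ----------
    lexicon_ : CompiledLexicon
        The fitted four-part index.
    links_ : LinksTable or None
        The fitted term→URI table, when links were supplied.
    n_terms_ : int
        Number of distinct normalized terms in the index.

    Examples
    --------
    >>> est = EntityRecognizer(name="compounds").fit(["ATP", "nicotinic acid"])
    >>> [a.span() for a in est.annotate("ATP binds nicotinic acid")]
    [(0, 3, 'atp'), (10, 24, 'nicotinic acid')]
    """

    def __init__(
        self,
        *,
        min_entity_length: int = 3,
        stopwords: Iterable[str] | None = None,
        entity_type: str | None = None,
        name: str = "lexicon",
    ) -> None:
        self.min_entity_length = min_entity_length
        self.stopwords = stopwords
        self.entity_type = entity_type
        self.name = name

    def _config(self) -> NormalizationConfig:
        stopwords = (
            None if self.stopwords is None else frozenset(self.stopwords)
        )
        return NormalizationConfig(
            min_entity_length=self.min_entity_length, stopwords=stopwords
        )

    def fit(
        self,
        X: RawLexicon | Iterable[str],
        y: None = None,
        *,
        links: LinksTable | Iterable[tuple[str, str]] | None = None,
    ) -> "EntityRecognizer":
        """Compile the lexicon given as *X* (term list or ``RawLexicon``).

        *y* is ignored (sklearn API compatibility).  *links* may be a
        ``LinksTable`` or raw (term, uri) pairs.
        """
        if isinstance(X, RawLexicon):
            raw = X
        else:
            terms = list(X)
            for term in terms:
                if not isinstance(term, str):
                    raise TypeError(
                        f"lexicon terms must be strings, got {type(term).__name__}"
                    )
            raw = RawLexicon(self.name, terms)
        self.lexicon_ = compile_lexicon(raw)
        if links is None or isinstance(links, LinksTable):
            self.links_ = links
        else:
            self.links_ = LinksTable(links)
        self.n_terms_ = self.lexicon_.n_terms
        return self

    def annotate(self, text: str) -> list[Annotation]:
        """Annotate a single document, returning sorted annotations."""
        check_is_fitted(self, "lexicon_")
        if not isinstance(text, str):
            raise TypeError("annotate expects a single text string")
        return recognize(
            text,
            self.lexicon_,
            self.links_,
            self._config(),
            entity_type=self.entity_type,
        )

    def transform(self, X: Sequence[str]) -> list[list[Annotation]]:
        """Annotate each document in *X* (an iterable of strings)."""
        if isinstance(X, str):
            raise TypeError(
                "transform expects an iterable of documents; "
                "use annotate() for a single text"
            )
        return [self.annotate(doc) for doc in X]

    def predict(self, X: Sequence[str]) -> list[list[Annotation]]:
        """Alias of :meth:`transform`."""
        return self.transform(X)

    def save(self, directory: str | Path) -> list[Path]:
        """Persist the fitted index (and links) in the four-file layout."""
        check_is_fitted(self, "lexicon_")
        return save_compiled(self.lexicon_, self.links_, directory)

    @classmethod
    def load(
        cls, name: str, directory: str | Path, **params
    ) -> "EntityRecognizer":
        """Rebuild a fitted recognizer from files written by :meth:`save`."""
        est = cls(name=name, **params)
        est.lexicon_, est.links_ = load_compiled(name, directory)
        est.n_terms_ = est.lexicon_.n_terms
        return est
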