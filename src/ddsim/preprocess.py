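"""Text preprocessing and bag-of-n-grams vectorization of drug documents.

The pipeline is deliberately plain: clean out digits and punctuation,
lowercase, tokenize on whitespace, drop stopwords, expand into unigrams,
bigrams and trigrams, and weight the resulting terms.  Stemming,
lemmatization and medical-concept normalization are out of scope.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus_io import DrugDocument
from .exceptions import FormatError

__all__ = [
    "clean_text",
    "normalize",
    "tokenize",
    "remove_stopwords",
    "generate_ngrams",
    "load_stopwords",
    "build_doc_term_matrix",
    "to_term_set",
    "DocTermMatrix",
    "WEIGHTINGS",
]

WEIGHTINGS = ("count", "binary", "relfreq", "tfidf")


@lru_cache(maxsize=None)
def _is_stripped(ch: str) -> bool:
    # digits and other numerals (Nd, No) and every punctuation class (P*)
    cat = unicodedata.category(ch)
    return cat in ("Nd", "No") or cat.startswith("P")


def clean_text(raw: str) -> str:
    """Replace digits, numerals and punctuation with spaces and tidy whitespace."""
    cleaned = "".join(" " if _is_stripped(c) else c for c in raw)
    return " ".join(cleaned.split())


def normalize(text: str) -> str:
    """Lowercase the text (idempotent)."""
    return text.lower()


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization; cleaning has already reduced text to words."""
    return text.split()


def remove_stopwords(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Order-preserving removal of stoplist members."""
    stop = set(stoplist)
    return [t for t in tokens if t not in stop]


def generate_ngrams(tokens: Sequence[str], max_n: int = 3) -> list[str]:
    """All contiguous n-grams for n = 1..max_n, ordered by (n, position).

    A k-token sequence yields sum over n of (k - n + 1) terms; n-gram
    tokens are joined with single spaces.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    k = len(tokens)
    out: list[str] = []
    for n in range(1, min(max_n, k) + 1):
        for i in range(k - n + 1):
            out.append(" ".join(tokens[i : i + n]))
    return out


def load_stopwords(path=None) -> frozenset[str]:
    """Load a stopword list (one word per line); default is the packaged
    standard English list."""
    if path is None:
        text = (
            resources.files("ddsim.data").joinpath("stopwords_en.txt").read_text("utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass
class DocTermMatrix:
    """Per-drug weighted n-gram vectors over a shared vocabulary.

    ``matrix`` is a sparse ``n_docs x n_terms`` array; ``vocabulary`` is
    lexicographically ordered.  ``empty_labels`` flags documents whose
    processed token list was empty (their rows are zero vectors; cosine and
    Jaccard refuse them downstream).
    """

    doc_labels: list[str]
    vocabulary: list[str]
    matrix: sp.csr_matrix
    weighting: str
    empty_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.doc_labels), len(self.vocabulary)):
            raise FormatError("doc-term matrix shape mismatch")
        if self.weighting not in WEIGHTINGS:
            raise FormatError(f"unknown weighting {self.weighting!r}")

    def vector(self, label: str) -> np.ndarray:
        i = self.doc_labels.index(label)
        return np.asarray(self.matrix.getrow(i).todense()).ravel()

    def term_set(self, label: str) -> frozenset[str]:
        i = self.doc_labels.index(label)
        row = self.matrix.getrow(i)
        return frozenset(self.vocabulary[j] for j in row.indices[row.data > 0])


def to_term_set(vector: np.ndarray, vocabulary: Sequence[str]) -> frozenset[str]:
    """The support of a weight vector, as a set of terms."""
    vector = np.asarray(vector)
    return frozenset(v for v, w in zip(vocabulary, vector) if w > 0)


def preprocess_document(
    text: str, stoplist: Iterable[str], max_n: int = 3
) -> list[str]:
    """Full chain from raw text to n-gram terms.

    Stage order is clean, lowercase, tokenize, stopword removal, n-grams;
    n-grams may therefore bridge the gap left by a removed stopword.
    """
    tokens = remove_stopwords(tokenize(normalize(clean_text(text))), stoplist)
    return generate_ngrams(tokens, max_n=max_n)


def build_doc_term_matrix(
    documents: Sequence[DrugDocument],
    weighting: str = "count",
    stoplist: Iterable[str] | None = None,
    max_n: int = 3,
) -> DocTermMatrix:
    """Vectorize drug documents into a weighted bag-of-n-grams matrix.

    Weighting schemes: ``count`` raw term frequency, ``binary`` presence,
    ``relfreq`` count normalized by the document's total count, ``tfidf``
    count times ``ln(N / df)`` with N documents and df the number of
    documents containing the term.
    """
    if not documents:
        raise ValueError("need at least one document")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}; one of {WEIGHTINGS}")
    stoplist = frozenset(stoplist) if stoplist is not None else load_stopwords()

    from collections import Counter

    doc_counts: list[Counter] = []
    for doc in documents:
        doc_counts.append(Counter(preprocess_document(doc.text, stoplist, max_n)))

    vocabulary = sorted(set().union(*doc_counts))
    index = {t: j for j, t in enumerate(vocabulary)}

    rows, cols, data = [], [], []
    for i, counts in enumerate(doc_counts):
        for term, c in counts.items():
            rows.append(i)
            cols.append(index[term])
            data.append(float(c))
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(documents), len(vocabulary))
    )

    if weighting == "binary":
        mat.data = np.ones_like(mat.data)
    elif weighting == "relfreq":
        totals = np.asarray(mat.sum(axis=1)).ravel()
        scale = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
        mat = sp.diags(scale) @ mat
    elif weighting == "tfidf":
        n_docs = len(documents)
        df = np.asarray((mat > 0).sum(axis=0)).ravel()
        idf = np.log(n_docs / np.maximum(df, 1))
        mat = mat @ sp.diags(idf)
    mat = sp.csr_matrix(mat)
    mat.eliminate_zeros()

    empty = frozenset(
        documents[i].drug_name for i, c in enumerate(doc_counts) if not c
    )
    return DocTermMatrix(
        [d.drug_name for d in documents], vocabulary, mat, weighting, empty
    )
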