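"""Synthetic review corpora with known latent drug-class structure.

The generator emulates the corpus shape the pipeline assumes — many short
free-text reviews per drug — with a planted signal: drugs belong to
classes, each class owns a private vocabulary, and every token is drawn
either from the drug's class vocabulary or from a vocabulary shared by all
drugs.  ``shared_fraction`` is the signal-to-noise knob: at 0 the classes
have disjoint vocabularies (between-class cosine and Jaccard similarity
are exactly zero in the unigram setting); as it grows toward 1 the classes
blur together.

Tokens are pure-alphabetic lowercase words, so they survive the cleaning
stage unchanged, and are not English stopwords.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .corpus_io import ReviewCorpus, ReviewRecord
from .exceptions import ConfigError

__all__ = ["SyntheticConfig", "generate_corpus"]

_LETTERS = string.ascii_lowercase


def _alpha(i: int, width: int = 3) -> str:
    """Fixed-width base-26 encoding of an index as lowercase letters."""
    out = []
    for _ in range(width):
        out.append(_LETTERS[i % 26])
        i //= 26
    return "".join(reversed(out))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-class review generator.

    Defaults describe a well-separated two-class corpus of realistic desk
    scale: 8 drugs, 200 reviews each, mean review length 20 tokens
    (Poisson, minimum 1), 150-word private vocabulary per class, 100-word
    shared vocabulary, and a 20% chance that any token is drawn from the
    shared vocabulary.
    """

    n_classes: int = 2
    drugs_per_class: int = 4
    reviews_per_drug: int = 200
    class_vocab_size: int = 150
    shared_vocab_size: int = 100
    shared_fraction: float = 0.2
    tokens_per_review: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_classes >= 1, "n_classes must be >= 1"),
            (self.drugs_per_class >= 1, "drugs_per_class must be >= 1"),
            (self.reviews_per_drug >= 1, "reviews_per_drug must be >= 1"),
            (self.class_vocab_size >= 10, "class_vocab_size must be >= 10"),
            (self.shared_vocab_size >= 0, "shared_vocab_size must be >= 0"),
            (0.0 <= self.shared_fraction <= 1.0, "shared_fraction must be in [0, 1]"),
            (self.tokens_per_review >= 1, "tokens_per_review must be >= 1"),
            (
                self.shared_fraction == 0.0 or self.shared_vocab_size > 0,
                "shared_fraction > 0 needs a nonempty shared vocabulary",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @property
    def n_drugs(self) -> int:
        return self.n_classes * self.drugs_per_class

    def class_vocabulary(self, c: int) -> list[str]:
        return [f"k{_alpha(c, 2)}v{_alpha(i)}" for i in range(self.class_vocab_size)]

    def shared_vocabulary(self) -> list[str]:
        return [f"sv{_alpha(i)}" for i in range(self.shared_vocab_size)]

    def drug_names(self) -> list[str]:
        return [f"drug{_alpha(k, 2)}" for k in range(self.n_drugs)]


def generate_corpus(cfg: SyntheticConfig) -> tuple[ReviewCorpus, dict[str, int]]:
    """Generate a review corpus; returns (corpus, drug -> class index).

    Deterministic given ``cfg.seed``.  Each review's length is
    Poisson(tokens_per_review) clipped to at least 1; each token comes from
    the shared vocabulary with probability ``shared_fraction``, otherwise
    uniformly from the drug's class vocabulary.  The token sequence is
    split between the side-effects field (first half) and the comments
    field (rest).
    """
    rng = np.random.default_rng(cfg.seed)
    class_vocabs = [cfg.class_vocabulary(c) for c in range(cfg.n_classes)]
    shared_vocab = cfg.shared_vocabulary()
    names = cfg.drug_names()
    classes = {name: k // cfg.drugs_per_class for k, name in enumerate(names)}

    records: list[ReviewRecord] = []
    for name in names:
        vocab = class_vocabs[classes[name]]
        for _ in range(cfg.reviews_per_drug):
            length = max(1, int(rng.poisson(cfg.tokens_per_review)))
            from_shared = rng.random(length) < cfg.shared_fraction
            class_idx = rng.integers(0, len(vocab), size=length)
            shared_idx = rng.integers(0, max(len(shared_vocab), 1), size=length)
            tokens = [
                shared_vocab[j] if s else vocab[i]
                for s, i, j in zip(from_shared, class_idx, shared_idx)
            ]
            half = (length + 1) // 2
            records.append(
                ReviewRecord(
                    drug_name=name,
                    rating=int(rng.integers(1, 6)),
                    side_effects=" ".join(tokens[:half]),
                    comments=" ".join(tokens[half:]),
                )
            )
    return ReviewCorpus(records, roster=names), classes
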