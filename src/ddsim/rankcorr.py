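"""Similarity-based rankings and second-order Pearson correlation analyses.

Because the four measures live on incompatible scales, each drug's row of
similarities (or distances) is converted to a ranking of all drugs: rank 1
is the most similar (or nearest) drug, which for an exact diagonal is the
drug itself.  Two analyses are built on those rankings:

* **drug-drug correlation** — for one measure, the Pearson correlation
  between the full ranking rows of two drugs (self ranks included): a
  second-order similarity saying "these two drugs order the whole roster
  alike";
* **measure agreement** — for one drug, the Pearson correlation between its
  ranking rows under two different measures.

On ranking rows (permutations of 1..n) Pearson correlation coincides with
Spearman's rho of the underlying orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import LabeledMatrix
from .exceptions import UndefinedCorrelationError

__all__ = [
    "pearson",
    "rank_rows",
    "CorrelationBlock",
    "drug_drug_correlation",
    "average_correlations",
    "AgreementTable",
    "MEASURE_PAIRS",
    "measure_agreement",
]

#: canonical order of unordered measure pairs in the agreement analysis
MEASURE_PAIRS = (
    ("CS", "ED"),
    ("ED", "MD"),
    ("CS", "MD"),
    ("CS", "JC"),
    ("ED", "JC"),
    ("MD", "JC"),
)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation.

    Computed as ``(n*Sxy - Sx*Sy) / sqrt((n*Sxx - Sx^2) * (n*Syy - Sy^2))``;
    symmetric and invariant to positive affine transforms of either
    argument.  Undefined (raises) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pearson needs two equal-length vectors of length >= 2")
    n = len(x)
    sx, sy = x.sum(), y.sum()
    vx = n * (x * x).sum() - sx * sx
    vy = n * (y * y).sum() - sy * sy
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float((n * (x * y).sum() - sx * sy) / np.sqrt(vx * vy))


def rank_rows(matrix: LabeledMatrix, tie_break: str = "source-order") -> LabeledMatrix:
    """Convert a similarity or distance matrix to per-row rankings.

    Per row, drugs are sorted by value — descending for similarity,
    ascending for distance — and assigned ranks ``1..n``.  The row drug
    itself participates; its exact diagonal makes it rank 1.  Ties are
    broken by label order in the matrix (the only supported tie_break,
    ``"source-order"``).
    """
    if tie_break != "source-order":
        raise ValueError(f"unsupported tie_break {tie_break!r}")
    if matrix.orientation not in ("similarity", "distance"):
        raise ValueError(
            f"cannot rank a matrix with orientation {matrix.orientation!r}"
        )
    descending = matrix.orientation == "similarity"
    n = len(matrix.labels)
    ranks = np.zeros((n, n), dtype=float)
    for i in range(n):
        key = -matrix.values[i] if descending else matrix.values[i]
        order = np.argsort(key, kind="stable")  # stable = label-order ties
        ranks[i, order] = np.arange(1, n + 1)
    return LabeledMatrix(list(matrix.labels), ranks, "rank")


@dataclass
class CorrelationBlock:
    """Drug x drug second-order correlations under one measure."""

    measure: str
    matrix: LabeledMatrix

    def __post_init__(self) -> None:
        if self.matrix.orientation != "correlation":
            raise ValueError("CorrelationBlock requires a correlation matrix")


def drug_drug_correlation(ranks: LabeledMatrix, measure: str = "") -> CorrelationBlock:
    """Pearson correlation between every two drugs' full ranking rows.

    Entry (A, B) correlates the complete rank vectors of A and B over all
    drugs, self ranks included; symmetric with unit diagonal by
    construction.
    """
    if ranks.orientation != "rank":
        raise ValueError("drug_drug_correlation requires a rank matrix")
    n = len(ranks.labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pearson(ranks.values[i], ranks.values[j])
    return CorrelationBlock(measure, LabeledMatrix(list(ranks.labels), values, "correlation"))


def average_correlations(
    blocks: Sequence[CorrelationBlock], exclude: Iterable[str] = ()
) -> LabeledMatrix:
    """Entrywise mean of correlation blocks, with optional drugs removed.

    In the published case study the overall matrix averages the four
    measures and omits the brand-name duplicate entry from the roster.
    """
    if not blocks:
        raise ValueError("need at least one correlation block")
    labels = blocks[0].matrix.labels
    for b in blocks[1:]:
        if b.matrix.labels != labels:
            raise ValueError("correlation blocks have mismatched labels")
    exclude = set(exclude)
    unknown = exclude - set(labels)
    if unknown:
        raise KeyError(f"exclude labels not in matrix: {sorted(unknown)}")
    mean = np.mean([b.matrix.values for b in blocks], axis=0)
    out = LabeledMatrix(list(labels), mean, "correlation")
    return out.drop(exclude) if exclude else out


@dataclass
class AgreementTable:
    """Per-drug agreement between measures, as Pearson correlations.

    ``values[i, k]`` correlates drug i's ranking row under the two measures
    of ``MEASURE_PAIRS[k]``.
    """

    labels: list[str]
    pair_names: list[str]
    values: np.ndarray

    def per_pair_averages(self) -> dict[str, float]:
        """Column means: average agreement of each measure pair over drugs."""
        means = self.values.mean(axis=0)
        return dict(zip(self.pair_names, means.tolist()))

    def per_drug_averages(self) -> dict[str, float]:
        """Row means: each drug's average agreement over the six pairs."""
        means = self.values.mean(axis=1)
        return dict(zip(self.labels, means.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.pair_names)
        df["AVG"] = self.values.mean(axis=1)
        return df


def measure_agreement(ranks_by_measure: Mapping[str, LabeledMatrix]) -> AgreementTable:
    """Agreement analysis across the measures present in the mapping.

    For each drug and each unordered measure pair, correlates the drug's
    two ranking rows; all matrices must share labels.
    """
    measures = set(ranks_by_measure)
    pairs = [(a, b) for a, b in MEASURE_PAIRS if a in measures and b in measures]
    if not pairs:
        raise ValueError("need at least two known measures for agreement analysis")
    first = next(iter(ranks_by_measure.values()))
    labels = first.labels
    for m, r in ranks_by_measure.items():
        if r.orientation != "rank":
            raise ValueError(f"{m}: agreement analysis requires rank matrices")
        if r.labels != labels:
            raise ValueError(f"{m}: rank matrices have mismatched labels")
    values = np.zeros((len(labels), len(pairs)))
    for k, (m1, m2) in enumerate(pairs):
        r1, r2 = ranks_by_measure[m1], ranks_by_measure[m2]
        for i in range(len(labels)):
            values[i, k] = pearson(r1.values[i], r2.values[i])
    return AgreementTable(list(labels), [f"{a}&{b}" for a, b in pairs], values)
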