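"""Threshold evaluation of predicted similar drug pairs against ground truth.

Pairs whose averaged second-order correlation reaches a threshold tau
(inclusive, >=) are predicted "similar" and compared with a reference
pair table.  Because the reference names drugs by active compound while
the review corpus may list formulations or brand names, a synonym map
joins the two namespaces: one ground-truth name may map to several corpus
labels (e.g. Valproic Acid to the two divalproex formulations).

Counting conventions: precision counts predicted label pairs individually
(a predicted pair is a true positive if its mapped form matches any
ground-truth pair); recall counts ground-truth pairs, each recalled if ANY
of its mapped label pairs was predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import GroundTruthTable, LabeledMatrix
from .exceptions import FormatError

__all__ = [
    "SynonymMap",
    "default_synonyms",
    "predict_pairs",
    "ThresholdMetrics",
    "EvaluationReport",
    "evaluate",
]


@dataclass(frozen=True)
class SynonymMap:
    """Maps ground-truth drug names to sets of corpus labels.

    Names absent from the mapping resolve to themselves.
    """

    mapping: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def resolve(self, name: str) -> frozenset[str]:
        return self.mapping.get(name, frozenset((name,)))

    def check_resolvable(self, names: Iterable[str], labels: Iterable[str]) -> None:
        labels = set(labels)
        bad = sorted(
            n for n in names if not (self.resolve(n) & labels)
        )
        if bad:
            raise FormatError(
                f"ground-truth names unresolvable to matrix labels: {bad}"
            )

    @classmethod
    def from_csv(cls, path) -> "SynonymMap":
        """Read a two-column (gt_name, corpus_label) synonym table."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise FormatError("synonym file needs columns gt_name, corpus_label")
        mapping: dict[str, set[str]] = {}
        for name, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
            mapping.setdefault(name, set()).add(label)
        return cls({k: frozenset(v) for k, v in mapping.items()})


def default_synonyms() -> SynonymMap:
    """The case-study join between reference names and roster labels."""
    return SynonymMap(
        {
            "Valproic Acid": frozenset({"Divalproex", "Divalproex-ER"}),
            "Klonopin": frozenset({"Clonazepam"}),
        }
    )


def predict_pairs(avg: LabeledMatrix, tau: float) -> set[frozenset]:
    """All unordered label pairs with averaged correlation >= tau."""
    if avg.orientation != "correlation":
        raise ValueError("predict_pairs expects a correlation matrix")
    out: set[frozenset] = set()
    n = len(avg.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if avg.values[i, j] >= tau:
                out.add(frozenset((avg.labels[i], avg.labels[j])))
    return out


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    n_predicted: int
    tp: int  # predicted pairs matching ground truth (precision numerator)
    fp: int
    fn: int  # ground-truth pairs not recalled
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # no pair predicted at this threshold


@dataclass
class EvaluationReport:
    rows: list[ThresholdMetrics]
    n_ground_truth: int

    def at(self, tau: float) -> ThresholdMetrics:
        for r in self.rows:
            if abs(r.threshold - tau) < 1e-12:
                return r
        raise KeyError(f"threshold {tau} not evaluated")

    def to_dataframe(self, decimals: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "threshold": r.threshold,
                    "n_predicted": r.n_predicted,
                    "tp": r.tp,
                    "fp": r.fp,
                    "fn": r.fn,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f1": r.f1,
                    "degenerate": r.degenerate,
                }
                for r in self.rows
            ]
        )
        if decimals is not None:
            for c in ("precision", "recall", "f1"):
                df[c] = df[c].round(decimals)
        return df


def evaluate(
    avg: LabeledMatrix,
    gt: GroundTruthTable,
    syn: SynonymMap | None = None,
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.75, 0.8),
) -> EvaluationReport:
    """Precision / recall / F1 of thresholded pair predictions.

    For each ground-truth pair the synonym map expands both members into
    corpus labels, yielding a set of acceptable label pairs.  Per
    threshold: TP = predicted pairs whose labels match some ground-truth
    pair; a ground-truth pair is recalled if any of its label pairs is
    predicted; FN = ground-truth pairs never recalled.
    """
    syn = syn or default_synonyms()
    labels = set(avg.labels)
    syn.check_resolvable(gt.drug_names(), labels)

    mapped_per_pair: list[set[frozenset]] = []
    for p in gt.pairs:
        s1 = syn.resolve(p.drug_1) & labels
        s2 = syn.resolve(p.drug_2) & labels
        mapped = {frozenset((a, b)) for a in s1 for b in s2 if a != b}
        mapped_per_pair.append(mapped)
    all_mapped: set[frozenset] = set().union(*mapped_per_pair) if mapped_per_pair else set()

    rows = []
    for tau in thresholds:
        pred = predict_pairs(avg, tau)
        tp = len(pred & all_mapped)
        fp = len(pred) - tp
        recalled = sum(1 for m in mapped_per_pair if m & pred)
        fn = len(mapped_per_pair) - recalled
        precision = tp / len(pred) if pred else 0.0
        recall = recalled / len(mapped_per_pair) if mapped_per_pair else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows.append(
            ThresholdMetrics(
                threshold=float(tau),
                n_predicted=len(pred),
                tp=tp,
                fp=fp,
                fn=fn,
                precision=precision,
                recall=recall,
                f1=f1,
                degenerate=not pred,
            )
        )
    return EvaluationReport(rows, len(mapped_per_pair))
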