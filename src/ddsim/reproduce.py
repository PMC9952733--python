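"""Regression harness over the packaged published case-study tables.

The raw review corpus behind the published 14-drug anti-epileptic study is
not redistributable, so the four printed similarity matrices are the
pipeline's entry point here: everything downstream — rankings,
second-order correlations, their four-measure average, the
measure-agreement analysis and the threshold evaluation — is recomputed by
this package and diffed cell-by-cell against the published values at
2-decimal rounding.

Two published quirks are handled explicitly:

* rankings were evidently computed from unrounded similarities, so ranks
  recomputed from the 2-decimal matrices may legally swap neighbors that
  are tied at 2 decimals — ranking comparison is per tie group of the
  source values;
* a packaged errata file lists published correlation cells that are
  internally inconsistent (one drug's cosine row duplicates its Manhattan
  row and contradicts both the symmetric cells and recomputation); those
  cells are reported as known inconsistencies, not failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .corpus_io import LabeledMatrix, load_fixture, load_reference
from .evaluation import EvaluationReport, default_synonyms, evaluate
from .rankcorr import (
    AgreementTable,
    CorrelationBlock,
    average_correlations,
    drug_drug_correlation,
    measure_agreement,
    rank_rows,
)

__all__ = ["TableDiff", "ReproductionReport", "reproduce_tables", "PUBLISHED_THRESHOLDS"]

#: the published threshold grid of the evaluation table
PUBLISHED_THRESHOLDS = (0.5, 0.6, 0.7, 0.75, 0.8)

_SIMILARITY_FIXTURES = {
    "CS": "table2_cs",
    "ED": "table3_ed",
    "MD": "table4_md",
    "JC": "table5_jc",
}
_RANK_FIXTURES = {
    "CS": "table6_cs_rank",
    "ED": "table7_ed_rank",
    "MD": "table8_md_rank",
    "JC": "table9_jc_rank",
}

#: drug removed from the averaged matrix (brand-name duplicate of
#: Clonazepam in the published roster)
EXCLUDED_FROM_AVERAGE = ("Klonopin",)

_TOL = 0.005 + 1e-9  # published values carry 2 decimals


@dataclass
class TableDiff:
    """Cell-by-cell comparison of one recomputed table with its reference."""

    table: str
    n_compared: int = 0
    mismatches: list[tuple] = field(default_factory=list)
    known_inconsistencies: list[tuple] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def summary(self) -> str:
        status = "OK" if self.ok else f"{len(self.mismatches)} MISMATCH(ES)"
        extra = (
            f", {len(self.known_inconsistencies)} known inconsistency(ies) skipped"
            if self.known_inconsistencies
            else ""
        )
        return f"{self.table}: {self.n_compared} cells compared, {status}{extra}"


@dataclass
class ReproductionReport:
    diffs: list[TableDiff]
    evaluation: EvaluationReport
    average_matrix: LabeledMatrix
    agreement: AgreementTable

    @property
    def ok(self) -> bool:
        return all(d.ok for d in self.diffs)

    def summary(self) -> str:
        lines = [d.summary() for d in self.diffs]
        lines.append("overall: " + ("all asserted cells match" if self.ok else "MISMATCHES FOUND"))
        return "\n".join(lines)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _diff_rankings() -> tuple[TableDiff, dict[str, LabeledMatrix]]:
    """Recompute rankings from the similarity matrices; compare per tie group."""
    diff = TableDiff("rankings (similarity -> rank tables)")
    recomputed: dict[str, LabeledMatrix] = {}
    for m, src_name in _SIMILARITY_FIXTURES.items():
        source = load_fixture(src_name)
        printed = load_fixture(_RANK_FIXTURES[m])
        assert isinstance(source, LabeledMatrix) and isinstance(printed, LabeledMatrix)
        mine = rank_rows(source)
        recomputed[m] = mine
        for i, drug in enumerate(source.labels):
            vals = source.values[i]
            for v in np.unique(vals):
                cols = np.where(vals == v)[0]
                a = sorted(int(r) for r in mine.values[i, cols])
                b = sorted(int(r) for r in printed.values[i, cols])
                diff.n_compared += len(cols)
                if a != b:
                    diff.mismatches.append(
                        (m, drug, [source.labels[c] for c in cols], a, b)
                    )
    return diff, recomputed


def _diff_correlations(
    printed_ranks: dict[str, LabeledMatrix]
) -> tuple[TableDiff, list[CorrelationBlock]]:
    """Second-order correlations from the printed rank tables vs reference."""
    diff = TableDiff("second-order correlations")
    ref = load_reference("table10_corr")
    errata = load_reference("errata")
    skip = {
        (r.row_drug, r.measure, r.col_drug)
        for r in errata.itertuples(index=False)
        if r.table == "table10"
    }
    blocks = []
    for m in ("CS", "ED", "MD", "JC"):
        block = drug_drug_correlation(printed_ranks[m], measure=m)
        blocks.append(block)
        sub = ref[ref["measure"] == m]
        for _, row in sub.iterrows():
            drug = str(row["drug"])
            for col in block.matrix.labels:
                mine = block.matrix.loc(drug, col)
                printed = float(row[col])
                cell = (drug, m, col)
                if cell in skip:
                    diff.known_inconsistencies.append(cell + (printed, round(mine, 4)))
                    continue
                diff.n_compared += 1
                if abs(mine - printed) > _TOL:
                    diff.mismatches.append(cell + (printed, round(mine, 4)))
    return diff, blocks


def _diff_average(blocks: list[CorrelationBlock]) -> tuple[TableDiff, LabeledMatrix]:
    diff = TableDiff("averaged correlations")
    avg = average_correlations(blocks, exclude=EXCLUDED_FROM_AVERAGE)
    ref = load_reference("table11_avg_corr")
    for a in avg.labels:
        for b in avg.labels:
            mine = avg.loc(a, b)
            printed = float(ref.loc[a, b])
            diff.n_compared += 1
            if abs(mine - printed) > _TOL:
                diff.mismatches.append((a, b, printed, round(mine, 4)))
    return diff, avg


def _diff_agreement(
    printed_ranks: dict[str, LabeledMatrix]
) -> tuple[TableDiff, AgreementTable]:
    """Agreement cells and column averages at 2 decimals.

    The published per-drug average column was computed from the already
    rounded cells, so it is checked against the half-up-rounded mean of the
    published 2-decimal cells rather than against full-precision values.
    """
    diff = TableDiff("measure agreement")
    agreement = measure_agreement(printed_ranks)
    ref = load_reference("table12_agreement")
    ref_cells = ref.iloc[:-1]
    ref_colavg = ref.iloc[-1]
    for i, drug in enumerate(agreement.labels):
        row = ref_cells.iloc[i]
        assert str(row["drug"]).lower() == drug.lower()
        for k, pair in enumerate(agreement.pair_names):
            mine = agreement.values[i, k]
            printed = float(row[pair])
            diff.n_compared += 1
            if abs(mine - printed) > _TOL:
                diff.mismatches.append((drug, pair, printed, round(mine, 4)))
        # per-drug average, from the published rounded cells
        rounded_mean = sum(float(row[p]) for p in agreement.pair_names) / len(
            agreement.pair_names
        )
        diff.n_compared += 1
        if abs(_round2(rounded_mean) - float(row["AVG"])) > 1e-9:
            diff.mismatches.append((drug, "AVG", float(row["AVG"]), rounded_mean))
    for pair, mean in agreement.per_pair_averages().items():
        diff.n_compared += 1
        printed = float(ref_colavg[pair])
        if abs(mean - printed) > _TOL:
            diff.mismatches.append(("column average", pair, printed, round(mean, 4)))
    return diff, agreement


def _diff_evaluation(avg: LabeledMatrix) -> tuple[TableDiff, EvaluationReport]:
    """Threshold evaluation against the published metrics.

    The published matrix carries 2 decimals, so thresholding happens on the
    2-decimal rounded average.  The recall column is asserted for the four
    lowest thresholds, the full triple at tau = 0.75, and the position of
    the best F1; published precision at the lowest thresholds followed a
    pair-counting convention that is not recoverable and is reported
    without assertion.
    """
    diff = TableDiff("threshold evaluation")
    gt = load_fixture("table13_groundtruth")
    report = evaluate(avg.round(2), gt, default_synonyms(), PUBLISHED_THRESHOLDS)
    ref = load_reference("table14_evaluation")
    ref = ref.set_index("threshold")
    for tau in (0.5, 0.6, 0.7, 0.75):
        mine = report.at(tau).recall
        printed = float(ref.loc[tau, "recall"])
        diff.n_compared += 1
        if abs(mine - printed) > _TOL:
            diff.mismatches.append((tau, "recall", printed, round(mine, 4)))
    row = report.at(0.75)
    for metric, mine in (
        ("precision", row.precision),
        ("recall", row.recall),
        ("f1", row.f1),
    ):
        printed = float(ref.loc[0.75, metric])
        diff.n_compared += 1
        if abs(mine - printed) > _TOL:
            diff.mismatches.append((0.75, metric, printed, round(mine, 4)))
    best = max(report.rows, key=lambda r: r.f1)
    diff.n_compared += 1
    if abs(best.threshold - 0.75) > 1e-12:
        diff.mismatches.append(("best-F1 threshold", 0.75, best.threshold))
    return diff, report


def reproduce_tables() -> ReproductionReport:
    """Recompute the full downstream chain and diff against the published tables."""
    rank_diff, _ = _diff_rankings()
    printed_ranks = {m: load_fixture(name) for m, name in _RANK_FIXTURES.items()}
    corr_diff, blocks = _diff_correlations(printed_ranks)
    avg_diff, avg = _diff_average(blocks)
    agree_diff, agreement = _diff_agreement(printed_ranks)
    eval_diff, report = _diff_evaluation(avg)
    return ReproductionReport(
        diffs=[rank_diff, corr_diff, avg_diff, agree_diff, eval_diff],
        evaluation=report,
        average_matrix=avg,
        agreement=agreement,
    )
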