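"""Reading, writing and aggregation of the pipeline's tabular formats.

Three families of files are handled here:

* **review tables** — one row per patient review of a drug, with free-text
  side-effect and comment fields plus light metadata (rating, sex, age, ...);
* **labeled square matrices** — drug x drug similarity / distance / rank /
  correlation tables with the drug names on both axes;
* **ground-truth pair tables** — pairwise reference drug similarities with
  per-modality components (structure, target, pathway, gene-ontology) and a
  precomputed average, using literal ``NA`` for missing components.

The module also exposes the packaged reference matrices (the published
14-drug anti-epileptic case-study tables) through :func:`load_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "ReviewRecord",
    "ReviewCorpus",
    "DrugDocument",
    "LabeledMatrix",
    "GroundTruthPair",
    "GroundTruthTable",
    "ORIENTATIONS",
    "read_reviews_csv",
    "write_reviews_csv",
    "aggregate_documents",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_ground_truth_csv",
    "gt_average",
    "load_fixture",
    "load_reference",
    "FIXTURE_NAMES",
]

#: canonical review-table columns; only drug_name is mandatory in a source file
REVIEW_COLUMNS = (
    "drug_name",
    "rating",
    "reason",
    "side_effects",
    "comments",
    "sex",
    "age",
    "duration_dosage",
    "date_posted",
)

ORIENTATIONS = ("similarity", "distance", "rank", "correlation")


@dataclass(frozen=True)
class ReviewRecord:
    """A single patient review of one drug."""

    drug_name: str
    rating: int | None = None
    reason: str = ""
    side_effects: str = ""
    comments: str = ""
    sex: str | None = None
    age: int | None = None
    duration_dosage: str | None = None
    date_posted: date | None = None

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise FormatError("review record with empty drug_name")


@dataclass
class ReviewCorpus:
    """An ordered collection of reviews plus the roster of distinct drugs.

    The roster preserves order of first appearance unless supplied
    explicitly.
    """

    records: list[ReviewRecord]
    roster: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roster:
            seen: dict[str, None] = {}
            for r in self.records:
                seen.setdefault(r.drug_name, None)
            self.roster = list(seen)
        if len(set(self.roster)) != len(self.roster):
            raise FormatError("duplicate drug names in roster")
        missing = {r.drug_name for r in self.records} - set(self.roster)
        if missing:
            raise FormatError(f"records reference drugs not in roster: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def review_counts(self) -> dict[str, int]:
        counts = {d: 0 for d in self.roster}
        for r in self.records:
            counts[r.drug_name] += 1
        return counts


@dataclass(frozen=True)
class DrugDocument:
    """All selected review text for one drug, concatenated."""

    drug_name: str
    text: str
    n_reviews: int


@dataclass
class LabeledMatrix:
    """A square drug x drug matrix with a declared orientation.

    ``orientation`` states what the values mean and fixes the structural
    invariants: a *similarity* matrix is symmetric with unit diagonal, a
    *distance* matrix is symmetric and nonnegative with zero diagonal, a
    *rank* matrix has every row a permutation of ``1..n`` (rows are NOT
    symmetric in general), and a *correlation* matrix is symmetric with unit
    diagonal and entries in ``[-1, 1]``.
    """

    labels: list[str]
    values: np.ndarray
    orientation: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in matrix")
        if self.orientation not in ORIENTATIONS:
            raise FormatError(f"unknown orientation {self.orientation!r}")
        self.validate()

    # -- structural invariants ------------------------------------------
    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        n = v.shape[0]
        if self.orientation in ("similarity", "distance", "correlation"):
            if not np.allclose(v, v.T, atol=atol):
                raise FormatError(f"{self.orientation} matrix is not symmetric")
        diag = np.diag(v)
        if self.orientation == "similarity" and not np.allclose(diag, 1.0, atol=atol):
            raise FormatError("similarity matrix diagonal must be 1")
        if self.orientation == "distance":
            if not np.allclose(diag, 0.0, atol=atol):
                raise FormatError("distance matrix diagonal must be 0")
            if (v < -atol).any():
                raise FormatError("distance matrix has negative entries")
        if self.orientation == "correlation":
            if not np.allclose(diag, 1.0, atol=atol):
                raise FormatError("correlation matrix diagonal must be 1")
            if (v < -1 - atol).any() or (v > 1 + atol).any():
                raise FormatError("correlation entries outside [-1, 1]")
        if self.orientation == "rank":
            expect = np.arange(1, n + 1)
            for i in range(n):
                if not np.array_equal(np.sort(v[i]), expect):
                    raise FormatError(
                        f"rank row {self.labels[i]!r} is not a permutation of 1..{n}"
                    )

    # -- conveniences ----------------------------------------------------
    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def row(self, label: str) -> np.ndarray:
        return self.values[self.index(label)]

    def drop(self, labels: Iterable[str]) -> "LabeledMatrix":
        """Return a copy with the given labels (rows and columns) removed."""
        drop = set(labels)
        unknown = drop - set(self.labels)
        if unknown:
            raise KeyError(f"labels not in matrix: {sorted(unknown)}")
        keep = [i for i, lab in enumerate(self.labels) if lab not in drop]
        return LabeledMatrix(
            [self.labels[i] for i in keep],
            self.values[np.ix_(keep, keep)],
            self.orientation,
        )

    def round(self, decimals: int) -> "LabeledMatrix":
        return LabeledMatrix(list(self.labels), self.values.round(decimals), self.orientation)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class GroundTruthPair:
    """One reference drug pair with per-modality similarity components."""

    drug_1: str
    drug_2: str
    structure: float | None
    target: float | None
    pathway: float | None
    go_cc: float | None
    go_mf: float | None
    go_bp: float | None
    average: float

    def key(self) -> frozenset[str]:
        return frozenset((self.drug_1, self.drug_2))


#: components entering the stored Average column.  The pathway component is
#: excluded: it is present for only a handful of pairs and the stored
#: averages are consistent, row for row, only with the mean of the other
#: five components (missing values skipped).  This is an erratum-style
#: reading of the published table, applied uniformly.
GT_AVERAGE_COMPONENTS = ("structure", "target", "go_cc", "go_mf", "go_bp")


def gt_average(components: Mapping[str, float | None]) -> float:
    """Recompute the average reference similarity for one pair.

    Mean of the structure, target and three gene-ontology components,
    skipping missing values; the pathway component is not part of the
    average (see :data:`GT_AVERAGE_COMPONENTS`).
    """
    vals = [
        components[k]
        for k in GT_AVERAGE_COMPONENTS
        if components.get(k) is not None and not (
            isinstance(components.get(k), float) and math.isnan(components[k])  # type: ignore[arg-type]
        )
    ]
    if not vals:
        raise FormatError("all average components missing")
    return float(sum(vals) / len(vals))


@dataclass
class GroundTruthTable:
    """A table of reference similar drug pairs."""

    pairs: list[GroundTruthPair]

    def __post_init__(self) -> None:
        keys = [p.key() for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate pair in ground-truth table")
        for p in self.pairs:
            recomputed = gt_average(
                {k: getattr(p, k) for k in GT_AVERAGE_COMPONENTS}
            )
            if abs(round(recomputed, 3) - p.average) > 5e-4 + 1e-12:
                raise FormatError(
                    f"stored average {p.average} for {p.drug_1}-{p.drug_2} "
                    f"does not match recomputed {recomputed:.3f}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def drug_names(self) -> set[str]:
        return {p.drug_1 for p in self.pairs} | {p.drug_2 for p in self.pairs}


# ---------------------------------------------------------------------------
# review tables
# ---------------------------------------------------------------------------

def _opt_int(value: str, what: str, rownum: int) -> int | None:
    if value == "":
        return None
    try:
        return int(float(value))
    except ValueError:
        raise FormatError(f"row {rownum}: invalid {what} {value!r}") from None


def read_reviews_csv(
    path, column_map: Mapping[str, str] | None = None
) -> ReviewCorpus:
    """Read a review table (UTF-8, comma separated, header row required).

    ``column_map`` maps canonical column names (see :data:`REVIEW_COLUMNS`)
    to the headers actually used in the file.  Optional columns that are
    absent yield empty strings (free text) or missing values (metadata).
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    cols = {c: column_map.get(c, c) for c in REVIEW_COLUMNS}
    if cols["drug_name"] not in df.columns:
        raise FormatError(
            f"no drug-name column {cols['drug_name']!r} in {list(df.columns)}"
        )

    def get(rowdict, canon):
        return rowdict.get(cols[canon], "")

    records = []
    for i, rowdict in enumerate(df.to_dict("records")):
        rownum = i + 2  # 1-based, after the header line
        name = get(rowdict, "drug_name").strip()
        if not name:
            raise FormatError(f"row {rownum}: empty drug name")
        posted = get(rowdict, "date_posted")
        try:
            posted_date = date.fromisoformat(posted) if posted else None
        except ValueError:
            raise FormatError(f"row {rownum}: invalid date {posted!r}") from None
        records.append(
            ReviewRecord(
                drug_name=name,
                rating=_opt_int(get(rowdict, "rating"), "rating", rownum),
                reason=get(rowdict, "reason"),
                side_effects=get(rowdict, "side_effects"),
                comments=get(rowdict, "comments"),
                sex=get(rowdict, "sex") or None,
                age=_opt_int(get(rowdict, "age"), "age", rownum),
                duration_dosage=get(rowdict, "duration_dosage") or None,
                date_posted=posted_date,
            )
        )
    return ReviewCorpus(records)


def write_reviews_csv(corpus: ReviewCorpus, path) -> None:
    rows = []
    for r in corpus.records:
        rows.append(
            {
                "drug_name": r.drug_name,
                "rating": "" if r.rating is None else r.rating,
                "reason": r.reason,
                "side_effects": r.side_effects,
                "comments": r.comments,
                "sex": r.sex or "",
                "age": "" if r.age is None else r.age,
                "duration_dosage": r.duration_dosage or "",
                "date_posted": r.date_posted.isoformat() if r.date_posted else "",
            }
        )
    pd.DataFrame(rows, columns=list(REVIEW_COLUMNS)).to_csv(path, index=False)


def aggregate_documents(
    corpus: ReviewCorpus,
    min_reviews: int = 150,
    fields: Sequence[str] = ("side_effects", "comments"),
) -> list[DrugDocument]:
    """Aggregate each drug's reviews into one document.

    Drugs with fewer than ``min_reviews`` reviews are dropped (the
    case-study cutoff of 150 keeps only drugs with a substantial review
    base).  For the remaining drugs the selected free-text fields are
    concatenated in corpus row order, single-space separated.
    """
    if min_reviews < 0:
        raise ValueError("min_reviews must be >= 0")
    for f in fields:
        if f not in REVIEW_COLUMNS:
            raise ValueError(f"unknown review field {f!r}")
    counts = corpus.review_counts()
    parts: dict[str, list[str]] = {d: [] for d in corpus.roster}
    for r in corpus.records:
        for f in fields:
            val = getattr(r, f)
            if val:
                parts[r.drug_name].append(str(val))
    return [
        DrugDocument(d, " ".join(parts[d]), counts[d])
        for d in corpus.roster
        if counts[d] >= min_reviews
    ]


# ---------------------------------------------------------------------------
# labeled matrices
# ---------------------------------------------------------------------------

def read_matrix_csv(path, orientation: str | None = None) -> LabeledMatrix:
    """Read a labeled square matrix.

    Layout: an optional first comment line ``# orientation=<kind>``, then a
    header row of drug labels, then one row per drug with the label in the
    first column.  ``orientation`` passed by the caller overrides the file
    metadata.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    meta = None
    if first.startswith("#"):
        text = first.lstrip("#").strip()
        if text.startswith("orientation="):
            meta = text.split("=", 1)[1].strip()
    orientation = orientation or meta
    if orientation is None:
        raise FormatError(f"{path}: no orientation metadata and none supplied")
    df = pd.read_csv(path, comment="#", index_col=0)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(rows) != len(cols):
        raise FormatError(f"{path}: matrix is {len(rows)}x{len(cols)}, not square")
    if rows != cols:
        raise FormatError(f"{path}: row labels do not match column labels")
    try:
        values = df.values.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    return LabeledMatrix(rows, values, orientation)


def write_matrix_csv(matrix: LabeledMatrix, path, decimals: int = 6) -> None:
    """Write a labeled matrix; ``decimals=2`` mirrors the published tables."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# orientation={matrix.orientation}\n")
        fh.write("," + ",".join(matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            if matrix.orientation == "rank":
                cells = [str(int(v)) for v in row]
            else:
                cells = [f"{v:.{decimals}f}" for v in row]
            fh.write(lab + "," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def read_ground_truth_csv(path) -> GroundTruthTable:
    """Read a pairwise reference-similarity table (literal ``NA`` = missing)."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    required = {"drug_1", "drug_2", "average"}
    if not required <= set(df.columns):
        raise FormatError(
            f"ground-truth table missing columns {sorted(required - set(df.columns))}"
        )
    pairs = []
    for row in df.itertuples(index=False):
        def comp(name):
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        pairs.append(
            GroundTruthPair(
                drug_1=str(row.drug_1),
                drug_2=str(row.drug_2),
                structure=comp("structure"),
                target=comp("target"),
                pathway=comp("pathway"),
                go_cc=comp("go_cc"),
                go_mf=comp("go_mf"),
                go_bp=comp("go_bp"),
                average=float(row.average),
            )
        )
    return GroundTruthTable(pairs)


# ---------------------------------------------------------------------------
# packaged fixtures (published case-study tables)
# ---------------------------------------------------------------------------

_MATRIX_FIXTURES = {
    "table2_cs": ("table2_cs.csv", "similarity"),
    "table3_ed": ("table3_ed.csv", "distance"),
    "table4_md": ("table4_md.csv", "distance"),
    "table5_jc": ("table5_jc.csv", "similarity"),
    "table6_cs_rank": ("table6_cs_rank.csv", "rank"),
    "table7_ed_rank": ("table7_ed_rank.csv", "rank"),
    "table8_md_rank": ("table8_md_rank.csv", "rank"),
    "table9_jc_rank": ("table9_jc_rank.csv", "rank"),
}

FIXTURE_NAMES = tuple(_MATRIX_FIXTURES) + ("table13_groundtruth",)


def _data_path(filename: str):
    return resources.files("ddsim.data").joinpath(filename)


def load_fixture(name: str) -> LabeledMatrix | GroundTruthTable:
    """Load one of the packaged case-study tables by short name."""
    if name == "table13_groundtruth":
        with resources.as_file(_data_path("table13_groundtruth.csv")) as p:
            return read_ground_truth_csv(p)
    if name not in _MATRIX_FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        )
    filename, orientation = _MATRIX_FIXTURES[name]
    with resources.as_file(_data_path(filename)) as p:
        return read_matrix_csv(p, orientation=orientation)


def load_reference(name: str) -> pd.DataFrame:
    """Load a packaged downstream reference table as a raw DataFrame.

    These hold the published values that the regression harness recomputes
    and diffs against: ``table10_corr`` (second-order correlations, long
    format), ``table11_avg_corr``, ``table12_agreement``,
    ``table14_evaluation`` and ``errata`` (published cells known to be
    internally inconsistent, excluded from cell-by-cell comparison).
    """
    files = {
        "table10_corr": "table10_corr.csv",
        "table11_avg_corr": "table11_avg_corr.csv",
        "table12_agreement": "table12_agreement.csv",
        "table14_evaluation": "table14_evaluation.csv",
        "errata": "errata.csv",
    }
    if name not in files:
        raise KeyError(f"unknown reference table {name!r}")
    with resources.as_file(_data_path(files[name])) as p:
        if name == "table11_avg_corr":
            return pd.read_csv(p, comment="#", index_col=0)
        return pd.read_csv(p, comment="#")
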