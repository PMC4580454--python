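"""Tabular input/output for the time-course expression pipeline.

All tabular files are tab-separated UTF-8 with a header row and no field
quoting.  The three inputs are:

* a time-course design (``label``, ``phase``, ``hour``) fixing the
  experimental collection order used by every downstream profile operation;
* a gene x time-point expression table in FPKM units, first column
  ``gene_id`` and one column per design label;
* a gene-to-GO annotation table, either a two-column TSV
  (``gene_id``, ``term_id``) or a GAF 2.x file, of which only the object
  identifier (column 2) and GO identifier (column 5) are used.

FPKM values are written with 6 significant digits, which is below any
biological meaning while keeping write/read round trips exact at that
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "InputFormatError",
    "TimePoint",
    "TimeCourseDesign",
    "ExpressionMatrix",
    "AnnotationMap",
    "ResultBundle",
    "read_design",
    "read_expression_table",
    "read_annotation_table",
    "write_expression_table",
    "write_results",
]

FPKM_FORMAT = "%.6g"
_PHASES = {"light", "dark"}


class InputFormatError(ValueError):
    """An input file violates the documented tabular contract."""


@dataclass(frozen=True)
class TimePoint:
    label: str
    phase: str  # "light" or "dark"
    hour: int


@dataclass(frozen=True)
class TimeCourseDesign:
    """Ordered collection time points of a light/dark time course.

    The order of ``points`` is the experimental collection order; it is
    authoritative for every operation that walks a profile (consecutive
    differences, peak calling, ramp checks).
    """

    points: Tuple[TimePoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise InputFormatError("design must have >= 2 time points")
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise InputFormatError(f"duplicate time-point labels in design: {labels}")
        for p in self.points:
            if not p.label:
                raise InputFormatError("empty time-point label")
            if p.phase not in _PHASES:
                raise InputFormatError(
                    f"unknown phase {p.phase!r} for time point {p.label!r}"
                )
            if p.hour < 0:
                raise InputFormatError(f"negative hour for time point {p.label!r}")

    @property
    def labels(self) -> List[str]:
        return [p.label for p in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in design") from None


#: The 7-point 12h:12h photoperiod design (hours into dark/light phase),
#: in collection order starting mid-dark.
DEFAULT_DESIGN = TimeCourseDesign(
    points=(
        TimePoint("D6", "dark", 6),
        TimePoint("D10", "dark", 10),
        TimePoint("L1", "light", 1),
        TimePoint("L4", "light", 4),
        TimePoint("L6", "light", 6),
        TimePoint("L10", "light", 10),
        TimePoint("D1", "dark", 1),
    )
)


@dataclass
class ExpressionMatrix:
    """Non-negative FPKM values for G genes over T ordered time points."""

    gene_ids: List[str]
    values: np.ndarray  # shape (G, T)
    design: TimeCourseDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputFormatError("expression values must be a 2-D table")
        if self.values.shape != (len(self.gene_ids), len(self.design)):
            raise InputFormatError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.design)} time points"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputFormatError("duplicate gene_id in expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise InputFormatError("non-finite expression value")
        if np.any(self.values < 0):
            g = self.gene_ids[int(np.argwhere(self.values < 0)[0][0])]
            raise InputFormatError(f"negative expression value for gene {g!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.design.labels,
        )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class AnnotationMap:
    """Many-to-many gene -> GO-term assignment over an annotation universe.

    ``universe`` may be a strict superset of the assigned genes: genes with
    zero terms are legitimate background members (most genes in a de novo
    annotated genome have no functional assignment).
    """

    assignments: Dict[str, FrozenSet[str]]
    universe: Set[str]

    def __post_init__(self) -> None:
        for g, terms in self.assignments.items():
            if not terms:
                raise InputFormatError(f"gene {g!r} maps to an empty term set")
        missing = set(self.assignments) - self.universe
        if missing:
            raise InputFormatError(
                f"assigned genes missing from universe: {sorted(missing)[:5]}"
            )

    def terms_of(self, gene_id: str) -> FrozenSet[str]:
        return self.assignments.get(gene_id, frozenset())

    def genes_with(self, term: str) -> Set[str]:
        return {g for g, ts in self.assignments.items() if term in ts}

    @property
    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.assignments.values())


@dataclass
class ResultBundle:
    """Everything the pipeline produces for one run."""

    scores: pd.DataFrame  # gene_id, score, rank
    selected: List[str]
    relmatrix: "pd.DataFrame"  # z-scored selected genes x design labels
    clusters: "object"  # ClusterResult (kept loose to avoid import cycle)
    enrichment: pd.DataFrame
    patterns: pd.DataFrame
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_design(path) -> TimeCourseDesign:
    """Read a design TSV (columns ``label``, ``phase``, ``hour``).

    Row order in the file is the collection order and is preserved.
    """
    df = _read_tsv(path)
    required = {"label", "phase", "hour"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"design file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) < 2:
        raise InputFormatError("design must have >= 2 time points")
    points = []
    for i, row in df.iterrows():
        phase = row["phase"].strip().lower()
        if phase not in _PHASES:
            raise InputFormatError(
                f"unknown phase {row['phase']!r} in design row {i + 1}"
            )
        try:
            hour = int(row["hour"])
        except ValueError:
            raise InputFormatError(
                f"non-integer hour {row['hour']!r} in design row {i + 1}"
            ) from None
        points.append(TimePoint(row["label"].strip(), phase, hour))
    labels = [p.label for p in points]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise InputFormatError(f"duplicate label(s) in design: {sorted(dupes)}")
    return TimeCourseDesign(points=tuple(points))


def read_expression_table(path, design: TimeCourseDesign) -> ExpressionMatrix:
    """Read an FPKM table; columns are reordered to design order."""
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise InputFormatError(
            f"first column of expression table must be 'gene_id', got {df.columns[0]!r}"
        )
    missing = [c for c in design.labels if c not in df.columns]
    if missing:
        raise InputFormatError(f"expression table missing design column(s): {missing}")
    gene_ids = df["gene_id"].tolist()
    dupes = {g for g in gene_ids if gene_ids.count(g) > 1} if len(set(gene_ids)) != len(gene_ids) else set()
    if dupes:
        raise InputFormatError(f"duplicate gene_id(s): {sorted(dupes)[:5]}")
    values = np.empty((len(gene_ids), len(design)), dtype=float)
    for j, label in enumerate(design.labels):
        col = pd.to_numeric(df[label], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            g = gene_ids[bad[0]]
            raise InputFormatError(
                f"non-numeric value {df[label][bad[0]]!r} for gene {g!r}, column {label!r}"
            )
        neg = col.index[col < 0]
        if len(neg):
            raise InputFormatError(
                f"negative value for gene {gene_ids[neg[0]]!r}, column {label!r}"
            )
        values[:, j] = col.to_numpy()
    return ExpressionMatrix(gene_ids=gene_ids, values=values, design=design)


def read_annotation_table(path) -> AnnotationMap:
    """Read gene->GO pairs from a two-column TSV (duplicates collapse)."""
    assignments: Dict[str, Set[str]] = {}
    universe: Set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputFormatError(
                    f"annotation line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            gene, term = fields[0].strip(), fields[1].strip()
            if lineno == 1 and gene.lower() == "gene_id":
                continue  # optional header
            if not gene or not term:
                raise InputFormatError(f"annotation line {lineno}: empty field")
            assignments.setdefault(gene, set()).add(term)
            universe.add(gene)
    return AnnotationMap(
        assignments={g: frozenset(ts) for g, ts in assignments.items()},
        universe=universe,
    )


def read_gaf(path) -> AnnotationMap:
    """Read a GAF 2.x file, using only object ID (col 2) and GO ID (col 5).

    Qualifiers and evidence codes are ignored: no evidence-based filtering
    is applied.
    """
    assignments: Dict[str, Set[str]] = {}
    universe: Set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise InputFormatError(
                    f"GAF line {lineno}: expected >= 5 tab-separated fields"
                )
            gene, term = fields[1].strip(), fields[4].strip()
            if not gene or not term:
                raise InputFormatError(f"GAF line {lineno}: empty object or GO ID")
            assignments.setdefault(gene, set()).add(term)
            universe.add(gene)
    return AnnotationMap(
        assignments={g: frozenset(ts) for g, ts in assignments.items()},
        universe=universe,
    )


# ---------------------------------------------------------------------------
# writers


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=FPKM_FORMAT)


def write_design(design: TimeCourseDesign, path) -> None:
    pd.DataFrame(
        {"label": design.labels,
         "phase": [p.phase for p in design.points],
         "hour": [p.hour for p in design.points]}
    ).to_csv(path, sep="\t", index=False)


def write_annotation_table(annotations: AnnotationMap, path) -> None:
    rows = sorted(
        (g, t) for g, ts in annotations.assignments.items() for t in ts
    )
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(bundle: ResultBundle, outdir) -> List[Path]:
    """Write the seven pipeline outputs; byte-identical across re-runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _w(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, **kw)
        written.append(p)

    _w("scores.tsv", bundle.scores, float_format=FPKM_FORMAT)
    _w("selected.tsv", pd.DataFrame({"gene_id": bundle.selected}))
    rel = bundle.relmatrix.reset_index()
    _w("relmatrix.tsv", rel, float_format=FPKM_FORMAT)
    group_of = bundle.clusters.group_of
    _w("clusters.tsv", pd.DataFrame(
        {"gene_id": list(group_of), "group": [group_of[g] for g in group_of]}
    ))
    _w("enrichment.tsv", bundle.enrichment, float_format="%.6g")
    _w("patterns.tsv", bundle.patterns, float_format=FPKM_FORMAT)

    group_sizes: Dict[str, int] = {}
    for g in group_of.values():
        group_sizes[str(g)] = group_sizes.get(str(g), 0) + 1
    sig_counts: Dict[str, int] = {}
    if len(bundle.enrichment):
        sig = bundle.enrichment[bundle.enrichment["significant"]]
        for grp, cnt in sig.groupby("group").size().items():
            sig_counts[str(grp)] = int(cnt)
    summary = {
        "n_genes_selected": len(bundle.selected),
        "group_sizes": dict(sorted(group_sizes.items(), key=lambda kv: int(kv[0]))),
        "significant_terms_per_group": dict(sorted(sig_counts.items())),
        "provenance": bundle.provenance,
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
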