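"""GO-term overrepresentation per expression group.

For each group of co-expressed genes and each GO term annotated to at
least one group member, a 2x2 table is formed against a background
universe (by default, all genes in the expression matrix; genes without
annotations count among the term-negative cells) and the one-sided
Fisher exact (hypergeometric tail) p-value

    p = P(X >= a),  X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b)

is computed.  Significance uses a fixed cutoff alpha (default 0.05) with
an adaptive rule: if a group yields more significant terms than
``overflow_threshold`` (default 100), significance is re-assessed at
``strict_alpha`` (default 1e-7) and the applied cutoff is recorded.  No
multiple-testing correction is applied by default; Benjamini-Hochberg is
available as an option.  GO terms are opaque flat labels — no ontology
ancestor propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_tables import AnnotationMap

__all__ = [
    "ContingencyCounts",
    "EnrichmentRecord",
    "CutoffPolicy",
    "contingency_counts",
    "fisher_overrep_p",
    "enrich_group",
    "enrich_all_groups",
    "overrepresentation_bars",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 table: group membership x term annotation.

    a: in group, has term; b: in group, lacks term;
    c: outside group, has term; d: outside group, lacks term.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def group_size(self) -> int:
        return self.a + self.b

    @property
    def term_total(self) -> int:
        return self.a + self.c

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CutoffPolicy:
    alpha: float = 0.05
    overflow_threshold: int = 100
    strict_alpha: float = 1e-7

    def __post_init__(self) -> None:
        if not (0 < self.strict_alpha < self.alpha < 1):
            raise ValueError("require 0 < strict_alpha < alpha < 1")
        if self.overflow_threshold < 1:
            raise ValueError("overflow_threshold must be >= 1")


@dataclass
class EnrichmentRecord:
    group: object
    term: str
    counts: ContingencyCounts
    p_value: float
    pct_in_group: float
    pct_in_genome: float
    significant: bool
    cutoff_applied: float = float("nan")


def contingency_counts(
    group_genes: Set[str],
    term: str,
    annotations: AnnotationMap,
    universe: Set[str],
) -> ContingencyCounts:
    """Counts of the group x term table against an explicit universe."""
    outside = group_genes - universe
    if outside:
        raise ValueError(
            f"group genes outside universe: {sorted(outside)[:5]}"
        )
    with_term = annotations.genes_with(term) & universe
    a = len(with_term & group_genes)
    c = len(with_term) - a
    b = len(group_genes) - a
    d = len(universe) - len(group_genes) - c
    return ContingencyCounts(a=a, b=b, c=c, d=d)


def fisher_overrep_p(counts: ContingencyCounts) -> float:
    """One-sided overrepresentation p-value, P(X >= a).

    Computed through the hypergeometric survival function, which is exact
    (log-space internals) for margins well beyond 1e5.
    """
    if counts.a == 0:
        return 1.0
    p = float(
        hypergeom.sf(
            counts.a - 1, counts.universe_size, counts.term_total,
            counts.group_size,
        )
    )
    return min(p, 1.0)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def enrich_group(
    group_genes: Set[str],
    annotations: AnnotationMap,
    universe: Set[str],
    policy: CutoffPolicy = CutoffPolicy(),
    group_label: object = None,
    fdr: bool = False,
) -> List[EnrichmentRecord]:
    """Test every term annotated to >= 1 group member.

    Records are sorted by ascending p-value, ties by term id.  If more than
    ``policy.overflow_threshold`` records are significant at ``policy.alpha``,
    significance is re-assessed at ``policy.strict_alpha``; the applied
    cutoff is available from :func:`applied_cutoff` on the returned list.
    """
    if not group_genes:
        raise ValueError("group must be non-empty")
    terms = sorted({t for g in group_genes for t in annotations.terms_of(g)})
    records: List[EnrichmentRecord] = []
    for term in terms:
        counts = contingency_counts(group_genes, term, annotations, universe)
        p = fisher_overrep_p(counts)
        records.append(
            EnrichmentRecord(
                group=group_label,
                term=term,
                counts=counts,
                p_value=p,
                pct_in_group=100.0 * counts.a / counts.group_size,
                pct_in_genome=100.0 * counts.term_total / counts.universe_size,
                significant=False,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.term))
    pvals = np.array([r.p_value for r in records])
    if fdr and len(pvals):
        pvals = _bh_adjust(pvals)
    cutoff = policy.alpha
    n_sig = int(np.sum(pvals <= cutoff))
    if n_sig > policy.overflow_threshold:
        cutoff = policy.strict_alpha
    for r, p in zip(records, pvals):
        r.significant = bool(p <= cutoff)
        r.cutoff_applied = cutoff
    return records


def applied_cutoff(records: Sequence[EnrichmentRecord]) -> float:
    """The cutoff actually used for a group's records."""
    if not records:
        raise ValueError("no records")
    return records[0].cutoff_applied


def enrich_all_groups(
    group_of: Dict[str, int],
    annotations: AnnotationMap,
    universe: Set[str],
    policy: CutoffPolicy = CutoffPolicy(),
    background: str = "all",
    fdr: bool = False,
) -> pd.DataFrame:
    """Enrichment table over all groups.

    ``background`` selects the universe convention: "all" keeps the given
    universe (typically every gene in the expression matrix), "annotated"
    restricts it to genes carrying at least one annotation.  Groups are
    intersected with the chosen universe so the counts stay consistent.
    """
    if background == "annotated":
        universe = universe & set(annotations.assignments)
    elif background != "all":
        raise ValueError("background must be 'all' or 'annotated'")
    rows = []
    for label in sorted(set(group_of.values())):
        genes = {g for g, grp in group_of.items() if grp == label} & universe
        if not genes:
            continue
        for r in enrich_group(
            genes, annotations, universe, policy, group_label=label, fdr=fdr
        ):
            rows.append(
                {
                    "group": label,
                    "term": r.term,
                    "a": r.counts.a,
                    "b": r.counts.b,
                    "c": r.counts.c,
                    "d": r.counts.d,
                    "p_value": r.p_value,
                    "pct_in_group": r.pct_in_group,
                    "pct_in_genome": r.pct_in_genome,
                    "significant": r.significant,
                    "cutoff_applied": r.cutoff_applied,
                }
            )
    cols = ["group", "term", "a", "b", "c", "d", "p_value", "pct_in_group",
            "pct_in_genome", "significant", "cutoff_applied"]
    return pd.DataFrame(rows, columns=cols)


def overrepresentation_bars(
    records: Iterable[EnrichmentRecord],
) -> pd.DataFrame:
    """Percent-in-group vs percent-in-genome for significant terms.

    These are the two bar series of a group's overrepresentation chart:
    the share of group members carrying each term against the share of the
    background universe carrying it.
    """
    rows = [
        {"term": r.term, "pct_in_group": r.pct_in_group,
         "pct_in_genome": r.pct_in_genome}
        for r in records
        if r.significant
    ]
    return pd.DataFrame(rows, columns=["term", "pct_in_group", "pct_in_genome"])
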