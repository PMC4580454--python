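"""Synthetic FPKM time courses with known group and enrichment structure.

The generator emulates a diurnal bulk RNA-seq experiment sampled at the
7-point light/dark design: K expression groups, each built on a
deterministic unit-variance template over the design (a peak at one time
point for K <= T, plus rising/falling ramps for larger K), and a flat
background population.  Gene i in group g has

    FPKM_t = b_i * exp(amplitude * z_g(t) + eps_{i,t}),
    eps ~ Normal(0, noise_sd^2),   b_i ~ LogNormal(baseline_log_mean,
                                                   baseline_log_sd),

so values are strictly positive, noise is multiplicative (FPKM scales are
heterogeneous across genes), and background genes (amplitude 0) vary only
by noise.  Templates are z-normalized with the sample standard deviation,
matching the pipeline's row normalization, so in the noiseless limit the
z-normalized log-profile of a group member equals its template exactly.

GO annotations give every gene ``terms_per_gene`` random terms from a
fixed vocabulary; additionally each group has one planted term assigned to
members with elevated probability, giving a known overrepresentation
signal for enrichment tests.

Everything is reproducible from the seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
import pandas as pd

from .io_tables import (
    DEFAULT_DESIGN,
    AnnotationMap,
    ExpressionMatrix,
    TimeCourseDesign,
    write_annotation_table,
    write_design,
    write_expression_table,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "group_templates",
    "simulate_timecourse",
    "simulate_annotations",
    "write_simulation",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic time course (defaults shown)."""

    design: TimeCourseDesign = DEFAULT_DESIGN
    n_groups: int = 7
    genes_per_group: int = 100
    n_background: int = 4300
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    amplitude: float = 0.8          # multiple of template z-units, log scale
    noise_sd: float = 0.2           # log-scale (z-unit) noise sd
    terms_per_gene: int = 3
    planted_term_in_group_prob: float = 0.5
    planted_term_background_prob: float = 0.05
    vocabulary_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.planted_term_in_group_prob,
                  self.planted_term_background_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_groups, self.genes_per_group) < 0 or self.n_background < 0:
            raise ValueError("counts must be >= 0")
        if self.n_groups > len(self.design) + 2:
            raise ValueError(
                f"at most T + 2 = {len(self.design) + 2} templates available "
                f"for a {len(self.design)}-point design"
            )


@dataclass
class TruthLabels:
    """Ground truth emitted alongside a simulated dataset."""

    group_of: Dict[str, object]          # gene -> 1..K or "background"
    planted_terms: Dict[int, str]        # group -> GO id
    pattern_class_of: Dict[str, str]     # gene -> designed pattern class


def _znorm(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def group_templates(design: TimeCourseDesign, K: int) -> np.ndarray:
    """K deterministic unit-variance templates over the design.

    The first min(K, T) templates peak at successive time points (one-hot,
    z-normalized); templates T+1 and T+2 are a rising and a falling ramp.
    """
    T = len(design)
    if K > T + 2:
        raise ValueError(f"at most {T + 2} templates for a {T}-point design")
    rows = []
    for t in range(min(K, T)):
        e = np.zeros(T)
        e[t] = 1.0
        rows.append(_znorm(e))
    if K > T:
        rows.append(_znorm(np.arange(T, dtype=float)))       # rising ramp
    if K > T + 1:
        rows.append(_znorm(-np.arange(T, dtype=float)))      # falling ramp
    return np.vstack(rows)


def _designed_class(
    template_index: int, design: TimeCourseDesign, amplitude: float,
    min_fold: float = 2.0,
) -> str:
    """Pattern class a template is constructed to express.

    Decided from the template's structure alone: peak templates place
    their maximum at one time point and are flat elsewhere, so the class
    follows from the peak label and the amplitude-driven fold change;
    ramp templates peak at an end point of the design.
    """
    T = len(design)
    tpl = group_templates(design, min(template_index + 1, T + 2))[template_index]
    fold = float(np.exp(amplitude * (tpl.max() - tpl.min())))
    if fold < min_fold:
        return "other"
    peak_label = design.labels[int(np.argmax(tpl))]
    if peak_label in {"D10", "L1"}:
        return "dark_to_dawn_peak"
    if template_index < T and peak_label in {"L4", "L6", "L10"}:
        return "late_light_peak"
    return "other"


def _gene_ids(n: int) -> List[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_timecourse(
    config: SimulationConfig,
) -> Tuple[ExpressionMatrix, TruthLabels]:
    """Draw one FPKM matrix plus its ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    K, per, nbg = config.n_groups, config.genes_per_group, config.n_background
    T = len(config.design)
    n = K * per + nbg
    gene_ids = _gene_ids(n)
    templates = group_templates(config.design, K) if K else np.zeros((0, T))

    group_of: Dict[str, object] = {}
    pattern_of: Dict[str, str] = {}
    log_signal = np.zeros((n, T))
    for g in range(K):
        cls = _designed_class(g, config.design, config.amplitude)
        for i in range(g * per, (g + 1) * per):
            group_of[gene_ids[i]] = g + 1
            pattern_of[gene_ids[i]] = cls
        log_signal[g * per : (g + 1) * per] = config.amplitude * templates[g]
    for i in range(K * per, n):
        group_of[gene_ids[i]] = BACKGROUND
        pattern_of[gene_ids[i]] = "other"

    log_b = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    eps = rng.normal(0.0, config.noise_sd, size=(n, T))
    values = np.exp(log_b[:, None] + log_signal + eps)

    planted = {g + 1: f"GO:{9000000 + g + 1}" for g in range(K)}
    truth = TruthLabels(
        group_of=group_of, planted_terms=planted, pattern_class_of=pattern_of
    )
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, values=values, design=config.design
    )
    return matrix, truth


def simulate_annotations(
    truth: TruthLabels, config: SimulationConfig
) -> AnnotationMap:
    """Random vocabulary terms per gene plus the planted group terms.

    Uses a seed offset from the expression seed so matrix and annotations
    are independent draws of the same configuration.
    """
    rng = np.random.default_rng((config.seed + 1_000_003) % (2**31))
    vocab = [f"GO:{i + 1:07d}" for i in range(config.vocabulary_size)]
    genes = sorted(truth.group_of)
    assignments: Dict[str, set] = {}
    for gene in genes:
        if config.terms_per_gene:
            k = min(config.terms_per_gene, len(vocab))
            terms = set(rng.choice(len(vocab), size=k, replace=False))
            assignments[gene] = {vocab[i] for i in terms}
        else:
            assignments[gene] = set()
    for grp, term in truth.planted_terms.items():
        for gene in genes:
            p = (
                config.planted_term_in_group_prob
                if truth.group_of[gene] == grp
                else config.planted_term_background_prob
            )
            if rng.random() < p:
                assignments[gene].add(term)
    return AnnotationMap(
        assignments={
            g: frozenset(ts) for g, ts in assignments.items() if ts
        },
        universe=set(genes),
    )


def write_simulation(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Write expression.tsv, annotations.tsv, design.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_timecourse(config)
    annotations = simulate_annotations(truth, config)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotations": outdir / "annotations.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_table(matrix, paths["expression"])
    write_annotation_table(annotations, paths["annotations"])
    write_design(config.design, paths["design"])
    pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "group": [truth.group_of[g] for g in matrix.gene_ids],
            "pattern_class": [truth.pattern_class_of[g] for g in matrix.gene_ids],
            "planted_term": [
                truth.planted_terms.get(truth.group_of[g], "")
                for g in matrix.gene_ids
            ],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
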