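"""MeanNeighbor gene selection.

The MeanNeighbor statistic of an expression profile x over T ordered time
points is the mean absolute difference between consecutive values,

    MeanNeighbor(x) = (1/(T-1)) * sum_{t=1..T-1} |x_{t+1} - x_t|,

with no wraparound term between the last and first point.  Because the
differences are taken on the raw FPKM scale, the score is large only for
genes that are both highly expressed and temporally variable: it is
positively homogeneous (scaling a profile by c > 0 scales the score by c)
and invariant to adding a constant to every time point.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .io_tables import ExpressionMatrix

__all__ = ["mean_neighbor", "score_all", "select_top_n"]


def mean_neighbor(values: Sequence[float]) -> float:
    """Mean absolute consecutive difference of a single profile.

    Parameters
    ----------
    values:
        FPKM values in design (collection) order; length T >= 2.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("mean_neighbor requires a 1-D profile of length >= 2")
    return float(np.mean(np.abs(np.diff(x))))


def score_all(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Score every gene; ranks are 1-based by descending score.

    Ties are broken by ascending lexicographic gene_id so selection is
    deterministic and independent of input row order.
    """
    scores = np.abs(np.diff(matrix.values, axis=1)).mean(axis=1)
    df = pd.DataFrame({"gene_id": matrix.gene_ids, "score": scores})
    order = df.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).index
    rank = pd.Series(np.arange(1, len(df) + 1), index=order)
    df["rank"] = rank.sort_index().to_numpy()
    return df.sort_values("rank").reset_index(drop=True)


def select_top_n(scores: pd.DataFrame, n: int) -> List[str]:
    """The min(n, G) top-ranked gene_ids in rank order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = scores.sort_values("rank")
    return ordered["gene_id"].head(n).tolist()
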