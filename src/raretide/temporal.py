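"""Seasonality analysis: Bray-Curtis dissimilarity, lag similarity, ANOSIM.

The lag-similarity curve asks how alike two communities are as a function of
the calendar time separating them: a seasonal community is most similar to
itself one year apart and least similar half a year apart.  ANOSIM tests
whether between-group dissimilarities are systematically larger than
within-group ones, on ranks, with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables import AbundanceTable


@dataclass
class LagSimilarity:
    """Mean similarity (1 - Bray-Curtis) over all sample pairs at one lag."""

    lag_months: int
    mean_similarity: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("a reported lag needs at least one pair")


def braycurtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity from a count table.

    BC(a,b) = sum|x_ai - x_bi| / sum(x_ai + x_bi); symmetric, zero diagonal,
    values in [0, 1].  Invariant to feature order and to a common scaling of
    a sample's counts only through the ratio (raw counts are used; columns
    are samples).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.counts.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    mat = table.counts.T.to_numpy(dtype=float)
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _month_lag(d1: pd.Timestamp, d2: pd.Timestamp) -> int:
    return abs((d2.year - d1.year) * 12 + (d2.month - d1.month))


def lag_similarity(
    dissim: pd.DataFrame, dates: Sequence[pd.Timestamp]
) -> list[LagSimilarity]:
    """Mean similarity (1 - dissimilarity) per whole-month lag.

    Lags come from calendar-month differencing of the sample dates; lags with
    no pairs are omitted.  Returned sorted by lag.
    """
    dates = [pd.Timestamp(d) for d in dates]
    if len(dates) != dissim.shape[0]:
        raise ValueError("one date per sample required")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    arr = dissim.to_numpy()
    for i in range(len(dates)):
        for j in range(i + 1, len(dates)):
            lag = _month_lag(dates[i], dates[j])
            if lag == 0:
                continue
            sums[lag] = sums.get(lag, 0.0) + (1.0 - arr[i, j])
            counts[lag] = counts.get(lag, 0) + 1
    return [
        LagSimilarity(lag_months=lag, mean_similarity=sums[lag] / counts[lag], n_pairs=counts[lag])
        for lag in sorted(sums)
    ]


def anosim(
    dissim: pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with M the
    number of off-diagonal pairs, ranks over all pairwise dissimilarities with
    average-rank ties; R is in [-1, 1].  p = (1 + #{permuted R >= observed})
    / (1 + n_perm) over random label permutations.
    """
    groups = np.asarray(groups)
    n = dissim.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dissim.to_numpy()[iu])
    m = len(ranks)
    denom = m / 2.0

    def r_stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(groups)
    rng = np.random.default_rng(seed)
    hits = sum(
        r_stat(rng.permutation(groups)) >= observed for _ in range(n_perm)
    )
    p = (1 + hits) / (1 + n_perm)
    return float(observed), float(p)


def write_distance_matrix(dissim: pd.DataFrame, path: str | Path) -> None:
    out = dissim.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def write_lag_table(lags: list[LagSimilarity], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"lag_months": l.lag_months, "mean_similarity": l.mean_similarity, "n_pairs": l.n_pairs}
            for l in lags
        ]
    ).to_csv(path, sep="\t", index=False)
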