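"""Compositional differential abundance between two read fractions.

Counts are treated as compositions: per sample, Monte-Carlo instances of the
underlying proportions are drawn from a Dirichlet(counts + 0.5) posterior,
CLR-transformed, and the two groups are compared within every instance with a
Welch t-test and a Wilcoxon rank-sum test.  A feature is called significant
only when the two tests converge, i.e. both expected p-values (means over the
MC instances) fall below alpha — the intersection makes the call conservative.
The effect size is the median over instances of the difference of the
group-median CLR values (a log-fold on the CLR scale).

Each sample's MC stream is seeded from the master seed mixed with a CRC32 of
the sample id, so the draws do not depend on which table the sample sits in:
swapping the two tables flips every direction and negates every effect but
leaves the significance calls untouched.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable

logger = logging.getLogger(__name__)

Direction = Literal["enriched_a", "enriched_b", "none"]
PresenceClass = Literal["only_a", "only_b", "shared", "absent"]


@dataclass
class DifferentialResult:
    feature_id: str
    expected_p_welch: float
    expected_p_wilcoxon: float
    effect_clr: float
    significant: bool
    direction: str
    presence_class: str
    expected_p_welch_bh: Optional[float] = None
    expected_p_wilcoxon_bh: Optional[float] = None


def _sample_rng(seed: int, sample_id: str, occurrence: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample_id.encode()), occurrence])
    )


def _check_features(tableA: AbundanceTable, tableB: AbundanceTable) -> None:
    if tableA.feature_ids != tableB.feature_ids:
        raise ValueError("tables must share the same feature set, in the same order")


def dirichlet_instances(
    table: AbundanceTable, n_mc: int, seed: int
) -> np.ndarray:
    """Dirichlet(counts + 0.5) proportion draws, shape (n_mc, features, samples).

    The per-sample streams depend only on (seed, sample id), not on column
    position, so the same sample yields the same draws wherever it appears.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    counts = table.counts.to_numpy(dtype=float)
    n_feat, n_samp = counts.shape
    out = np.empty((n_mc, n_feat, n_samp))
    seen: dict[str, int] = {}
    for j, sid in enumerate(table.sample_ids):
        occ = seen.get(sid, 0)
        seen[sid] = occ + 1
        rng = _sample_rng(seed, sid, occ)
        gammas = rng.standard_gamma(counts[:, j] + 0.5, size=(n_mc, n_feat))
        out[:, :, j] = gammas / gammas.sum(axis=1, keepdims=True)
    return out


def mc_clr_instances(
    tableA: AbundanceTable,
    tableB: AbundanceTable,
    n_mc: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """CLR-transformed MC instances over the concatenated samples of A and B.

    Returns shape (n_mc, n_features, n_samples_A + n_samples_B); within every
    instance each sample's CLR vector sums to 0.
    """
    _check_features(tableA, tableB)
    props = np.concatenate(
        [
            dirichlet_instances(tableA, n_mc, seed),
            dirichlet_instances(tableB, n_mc, seed),
        ],
        axis=2,
    )
    logs = np.log(props)
    return logs - logs.mean(axis=1, keepdims=True)


def aldex_like_test(
    tableA: AbundanceTable,
    tableB: AbundanceTable,
    n_mc: int = 128,
    alpha: float = 0.05,
    seed: int = 0,
    use_bh: bool = False,
) -> list[DifferentialResult]:
    """Dirichlet-MC CLR differential test with the Welch+Wilcoxon convergence rule.

    significant <=> both expected p-values < alpha (raw by default; with
    ``use_bh`` the Benjamini-Hochberg-adjusted expected p-values are used
    instead — a stricter call).  Positive ``effect_clr`` means enriched in A.
    """
    _check_features(tableA, tableB)
    nA, nB = tableA.shape[1], tableB.shape[1]
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 samples")
    clr = mc_clr_instances(tableA, tableB, n_mc=n_mc, seed=seed)
    a, b = clr[:, :, :nA], clr[:, :, nA:]

    with np.errstate(invalid="ignore", divide="ignore"):
        welch = stats.ttest_ind(a, b, axis=2, equal_var=False).pvalue
        wilcox = stats.mannwhitneyu(a, b, axis=2, alternative="two-sided").pvalue
    n_degenerate = int(np.isnan(welch).sum())
    if n_degenerate:
        logger.warning(
            "%d instance/feature Welch tests degenerate (constant CLR); p set to 1",
            n_degenerate,
        )
    welch = np.nan_to_num(welch, nan=1.0)
    wilcox = np.nan_to_num(wilcox, nan=1.0)

    ep_welch = welch.mean(axis=0)
    ep_wilcox = wilcox.mean(axis=0)
    effect = np.median(np.median(a, axis=2) - np.median(b, axis=2), axis=0)

    bh_welch = _bh_adjust(ep_welch)
    bh_wilcox = _bh_adjust(ep_wilcox)
    if use_bh:
        sig = (bh_welch < alpha) & (bh_wilcox < alpha)
    else:
        sig = (ep_welch < alpha) & (ep_wilcox < alpha)

    dir_a, dir_b = _direction_labels(tableA, tableB)
    presence = classify_presence(tableA, tableB)

    results = []
    for i, fid in enumerate(tableA.feature_ids):
        if sig[i]:
            direction = dir_a if effect[i] > 0 else dir_b
        else:
            direction = "none"
        results.append(
            DifferentialResult(
                feature_id=fid,
                expected_p_welch=float(ep_welch[i]),
                expected_p_wilcoxon=float(ep_wilcox[i]),
                effect_clr=float(effect[i]),
                significant=bool(sig[i]),
                direction=direction,
                presence_class=presence[fid],
                expected_p_welch_bh=float(bh_welch[i]),
                expected_p_wilcoxon_bh=float(bh_wilcox[i]),
            )
        )
    return results


def _direction_labels(tableA: AbundanceTable, tableB: AbundanceTable) -> tuple[str, str]:
    la, lb = tableA.fraction_label, tableB.fraction_label
    if la and lb and la != lb:
        return f"enriched_{la}", f"enriched_{lb}"
    return "enriched_a", "enriched_b"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def classify_presence(
    tableA: AbundanceTable, tableB: AbundanceTable
) -> dict[str, str]:
    """Per-feature presence class from total counts: only_a / only_b / shared / absent."""
    _check_features(tableA, tableB)
    totA = tableA.counts.sum(axis=1).to_numpy()
    totB = tableB.counts.sum(axis=1).to_numpy()
    out = {}
    for fid, ta, tb in zip(tableA.feature_ids, totA, totB):
        if ta > 0 and tb == 0:
            out[fid] = "only_a"
        elif tb > 0 and ta == 0:
            out[fid] = "only_b"
        elif ta == 0 and tb == 0:
            out[fid] = "absent"
        else:
            out[fid] = "shared"
    return out


def write_results(results: list[DifferentialResult], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in results])
    df.to_csv(path, sep="\t", index=False)
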