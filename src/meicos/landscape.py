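"""Windowed CO landscapes, arm/pericentromere counts and group comparisons.

COs are assigned to windows by midpoint only (no fractional spreading), so
window counts conserve the total event count exactly.  The arm-scaled
profile maps each physical window center onto the telomere(0) ->
centromere(1) scale of its arm and averages window frequencies within
equal-width scaled bins, pooling all arms with equal weight per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import per_individual_counts
from .genome import GenomeMap, window_index

logger = logging.getLogger(__name__)


def window_co_frequency(
    events: pd.DataFrame,
    genome: GenomeMap,
    n_individuals: int,
    window_bp: int = 300_000,
) -> pd.DataFrame:
    """Per-window CO counts and frequency per F2 individual.

    Returns ``chrom, start, end, count, freq_per_individual`` over the
    half-open window tiling of every chromosome.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    windows = genome.partition_windows(window_bp)
    counts = np.zeros(len(windows), dtype=np.int64)
    offsets = {}
    off = 0
    for chrom in genome.names:
        offsets[chrom] = off
        off += genome.n_windows(window_bp, chrom)
    for chrom, sub in events.groupby("chrom", observed=True):
        if chrom not in genome:
            raise ValueError(f"events on unknown chromosome {chrom!r}")
        mids = sub["midpoint"].to_numpy(dtype=float)
        if mids.size and (mids.min() < 1 or mids.max() > genome[chrom].length):
            raise ValueError(f"CO midpoint outside chromosome {chrom}")
        idx = offsets[str(chrom)] + window_index(mids, window_bp)
        np.add.at(counts, idx, 1)
    out = windows.copy()
    out["count"] = counts
    out["freq_per_individual"] = counts / n_individuals
    return out


def arm_scaled_profile(
    landscape: pd.DataFrame,
    genome: GenomeMap,
    n_bins: int = 100,
    combine: str = "mean",
) -> pd.DataFrame:
    """Average a physical window landscape onto the TEL(0)->CEN(1) scale.

    Each window contributes its frequency at the scaled coordinate of its
    center; scaled bins pool every arm of every chromosome with equal
    weight per window.  ``combine`` is ``"mean"`` (default) or ``"sum"``.
    """
    if combine not in ("mean", "sum"):
        raise ValueError("combine must be 'mean' or 'sum'")
    centers = 0.5 * (landscape["start"] + landscape["end"] - 1)
    scaled = np.empty(len(landscape))
    for i, (chrom, center) in enumerate(zip(landscape["chrom"], centers)):
        scaled[i], _ = genome.arm_scaled_coordinate(chrom, min(center, genome[chrom].length))
    bin_idx = np.clip((scaled * n_bins).astype(int), 0, n_bins - 1)
    freq = landscape["freq_per_individual"].to_numpy(dtype=float)
    sums = np.zeros(n_bins)
    cnts = np.zeros(n_bins)
    np.add.at(sums, bin_idx, freq)
    np.add.at(cnts, bin_idx, 1)
    value = sums if combine == "sum" else np.divide(
        sums, cnts, out=np.full(n_bins, np.nan), where=cnts > 0
    )
    return pd.DataFrame(
        {
            "scaled_bin": (np.arange(n_bins) + 0.5) / n_bins,
            "mean_freq" if combine == "mean" else "sum_freq": value,
            "n_windows": cnts.astype(int),
        }
    )


def region_counts(
    events: pd.DataFrame, genome: GenomeMap, individuals
) -> pd.DataFrame:
    """Per-individual CO counts split into chromosome arms vs pericentromeres.

    Returns ``individual, arm, pericentromere, total`` with zero rows for
    event-free individuals; arm + pericentromere = total by construction.
    """
    individuals = list(individuals)
    rows = {ind: [0, 0] for ind in individuals}
    for chrom, sub in events.groupby("chrom", observed=True):
        labels = genome.classify_regions(str(chrom), sub["midpoint"].to_numpy())
        for ind, lab in zip(sub["individual"], labels):
            rows[ind][0 if lab == "arm" else 1] += 1
    out = pd.DataFrame(
        {
            "individual": individuals,
            "arm": [rows[i][0] for i in individuals],
            "pericentromere": [rows[i][1] for i in individuals],
        }
    )
    out["total"] = out["arm"] + out["pericentromere"]
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Dunn's post hoc z-test on pooled ranks with tie correction."""
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = samples[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = float(2.0 * stats.norm.sf(abs(z)))
            out[f"{a}_vs_{b}"] = {"z": float(z), "p": p, "p_adjusted": bonferroni(p, n_pairs)}
    return out


def compare_groups(counts: pd.DataFrame, group_col: str = "group") -> dict:
    """Rank-based comparison of per-individual CO counts between groups.

    ``counts`` carries one row per individual with a group label, a
    ``total`` column and optionally ``arm`` / ``pericentromere`` columns.
    Totals get a Kruskal-Wallis omnibus plus Dunn pairwise tests; every
    metric present gets pairwise two-sided Wilcoxon rank-sum tests.  All
    pairwise p-values are reported raw and Bonferroni-adjusted (factor =
    number of pairs within each metric family).
    """
    if group_col not in counts.columns:
        raise ValueError(f"missing group column {group_col!r}")
    names = list(dict.fromkeys(counts[group_col]))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    metrics = [m for m in ("arm", "pericentromere", "total") if m in counts.columns]
    if "total" not in metrics:
        raise ValueError("counts must include a 'total' column")
    samples = {
        m: {g: counts.loc[counts[group_col] == g, m].to_numpy(dtype=float) for g in names}
        for m in metrics
    }
    for g in names:
        if samples["total"][g].size < 2:
            raise ValueError(f"group {g!r} has < 2 individuals")

    kw_stat, kw_p = stats.kruskal(*(samples["total"][g] for g in names))
    n_pairs = len(names) * (len(names) - 1) // 2
    wilcoxon = {}
    for m in metrics:
        wilcoxon[m] = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                res = stats.mannwhitneyu(
                    samples[m][a], samples[m][b], alternative="two-sided"
                )
                p = float(res.pvalue)
                wilcoxon[m][f"{a}_vs_{b}"] = {
                    "U": float(res.statistic),
                    "p": p,
                    "p_adjusted": bonferroni(p, n_pairs),
                }
    return {
        "groups": {g: int(samples["total"][g].size) for g in names},
        "kruskal_wallis": {"statistic": float(kw_stat), "p": float(kw_p)},
        "dunn_total": _dunn_pairwise(samples["total"]),
        "wilcoxon": wilcoxon,
    }


# ---------------------------------------------------------------------------
# summary arithmetic
# ---------------------------------------------------------------------------

def percent_change_summary(reference: float, group_means) -> dict:
    """Percent and percentage-point changes of group means vs a reference.

    ``percent_change`` is 100 * (group - reference) / reference per group;
    ``pooled_percent_change`` applies the same formula to the unweighted
    mean of the group means.  For quantities already expressed in percent,
    ``point_change`` reports plain differences (percentage points) and
    ``mean_point_change`` their mean.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    if isinstance(group_means, dict):
        names, values = list(group_means), np.array(list(group_means.values()), dtype=float)
    else:
        values = np.asarray(list(group_means), dtype=float)
        names = [f"group{i + 1}" for i in range(values.size)]
    pct = 100.0 * (values - reference) / reference
    pts = values - reference
    return {
        "reference": float(reference),
        "percent_change": dict(zip(names, pct.tolist())),
        "pooled_percent_change": float(100.0 * (values.mean() - reference) / reference),
        "point_change": dict(zip(names, pts.tolist())),
        "mean_point_change": float(pts.mean()),
    }


__all__ = [
    "window_co_frequency",
    "arm_scaled_profile",
    "region_counts",
    "compare_groups",
    "percent_change_summary",
    "bonferroni",
    "per_individual_counts",
]
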