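"""Crossover interference analysis: cis-DCOs, resampled nulls, gamma fits,
positional permutation test and coefficient-of-coincidence profiles.

A *cis* double crossover (cis-DCO) is a pair of COs on the same transmitted
haplotype, visible in an F2 genotype track as a parental-heterozygous-
parental segment triple with the same parental genotype on both sides
(AA-AB-AA or BB-AB-BB).  The distance between the two transition midpoints
measures inter-CO spacing on one chromatid; comparing the observed
distance distribution against distances between randomly re-paired CO
midpoints quantifies interference:

* coefficient of coincidence (CoC) < 1 at short distances: positive
  interference (COs repel);
* CoC > 1 at short distances: negative interference (COs cluster).

Two CoC modes are provided.  ``distance_histogram`` divides the observed
cis-DCO distance frequency by the resampled expected frequency per bin,
optionally rescaling the expected series to an independence DCO rate.
``interval_pairs`` is the classical cross-check: chromosomes are tiled
into intervals and, for every interval pair, the fraction of individuals
with a CO in both is divided by the product of the single-interval
fractions, aggregated by inter-interval distance class.  Under
independent CO placement both modes sit at CoC = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeMap, window_index

logger = logging.getLogger(__name__)

DCO_COLUMNS = [
    "individual", "chrom", "mid_left", "mid_right", "distance",
    "flank", "midpoint", "norm_end_dist", "overlapping",
]


@dataclass
class AnalysisParams:
    """Knobs of the interference analysis (base pairs unless noted).

    Defaults mirror a genome-scale F2 experiment: 3.15-Mb distance bins,
    200 resampled CO-midpoint pairs per chromosome, 10,000 permutation
    iterations, and a 5-Mb cutoff defining "short" cis-DCOs.
    """

    bin_width: float = 3_150_000.0
    n_pairs: int = 200
    n_perm: int = 10_000
    short_dco_max: float = 5_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.bin_width, self.n_pairs, self.short_dco_max) <= 0:
            raise ValueError("bin_width, n_pairs and short_dco_max must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


# ---------------------------------------------------------------------------
# cis-DCO extraction
# ---------------------------------------------------------------------------

def extract_cis_dcos(segments: pd.DataFrame, genome: GenomeMap) -> pd.DataFrame:
    """Extract cis-DCO events from a population segment table.

    Every consecutive segment triple (P, AB, P) with the same parental P on
    both sides yields one event; (AA, AB, BB) trans triples are excluded.
    Overlapping triples (a segment flanking two events) are all counted and
    flagged ``overlapping``.  Returns a frame with ``DCO_COLUMNS``:
    the two flanking-CO midpoints, their distance, the flanking parental
    genotype, the event midpoint (mean of the CO midpoints) and its
    distance to the nearest chromosome end normalized by chromosome length.
    """
    if not len(segments):
        return pd.DataFrame(columns=DCO_COLUMNS)
    df = segments.sort_values(["individual", "chrom", "first"], kind="stable").reset_index(drop=True)
    ind = df["individual"].to_numpy()
    chrom = df["chrom"].to_numpy()
    geno = df["genotype"].to_numpy()
    first = df["first"].to_numpy(dtype=float)
    last = df["last"].to_numpy(dtype=float)

    n = len(df)
    if n < 3:
        return pd.DataFrame(columns=DCO_COLUMNS)
    same01 = (ind[:-2] == ind[1:-1]) & (chrom[:-2] == chrom[1:-1])
    same12 = (ind[1:-1] == ind[2:]) & (chrom[1:-1] == chrom[2:])
    qual = (
        same01 & same12
        & np.isin(geno[:-2], ("AA", "BB"))
        & (geno[1:-1] == "AB")
        & (geno[2:] == geno[:-2])
    )
    idx = np.flatnonzero(qual)
    if idx.size == 0:
        return pd.DataFrame(columns=DCO_COLUMNS)

    mid_left = 0.5 * (last[idx] + first[idx + 1])
    mid_right = 0.5 * (last[idx + 1] + first[idx + 2])
    midpoint = 0.5 * (mid_left + mid_right)
    lengths = np.array([genome[c].length for c in chrom[idx]], dtype=float)
    norm_end = np.minimum(midpoint, lengths - midpoint) / lengths

    # triples starting <=2 segments apart on the same track share a segment
    qual_full = np.zeros(n, dtype=bool)
    qual_full[idx] = True
    overlap = np.zeros(n, dtype=bool)
    for d in (1, 2):
        same = (ind[:-d] == ind[d:]) & (chrom[:-d] == chrom[d:])
        both = qual_full[:-d] & qual_full[d:] & same
        overlap[:-d] |= both
        overlap[d:] |= both

    out = pd.DataFrame(
        {
            "individual": ind[idx],
            "chrom": chrom[idx],
            "mid_left": mid_left,
            "mid_right": mid_right,
            "distance": mid_right - mid_left,
            "flank": geno[idx],
            "midpoint": midpoint,
            "norm_end_dist": norm_end,
            "overlapping": overlap[idx],
        }
    )
    if int(out["overlapping"].sum()):
        logger.info("%d cis-DCOs share a flanking segment with another event",
                    int(out["overlapping"].sum()))
    return out


# ---------------------------------------------------------------------------
# expected-distance resampling
# ---------------------------------------------------------------------------

def expected_distance_sample(
    midpoints_by_chrom: dict[str, np.ndarray],
    params: AnalysisParams,
    rng,
) -> np.ndarray:
    """Null inter-CO distances by random re-pairing of observed CO midpoints.

    Per chromosome, ``n_pairs`` pairs are drawn uniformly *with replacement*
    from that chromosome's pooled midpoints (two independent draws per pair;
    identical positions are permitted and give distance 0).  Chromosomes
    with fewer than two midpoints are skipped with a warning.  Per-
    chromosome samples are concatenated for genome-wide summaries.
    """
    samples = []
    for chrom, mids in midpoints_by_chrom.items():
        mids = np.asarray(mids, dtype=float)
        if mids.size < 2:
            logger.warning("chromosome %s has < 2 CO midpoints; skipped", chrom)
            continue
        a = rng.choice(mids, size=params.n_pairs, replace=True)
        b = rng.choice(mids, size=params.n_pairs, replace=True)
        samples.append(np.abs(a - b))
    if not samples:
        return np.empty(0)
    return np.concatenate(samples)


# ---------------------------------------------------------------------------
# gamma fitting
# ---------------------------------------------------------------------------

@dataclass
class GammaFit:
    shape: float
    rate: float
    converged: bool
    loglik: float
    method: str  # "mle" | "mom"
    n: int
    n_zero_offset: int = 0

    @property
    def mean(self) -> float:
        return self.shape / self.rate


def fit_gamma(distances, method: str = "mle") -> GammaFit:
    """Fit a gamma distribution to positive distances.

    Zeros are offset by half the smallest positive distance (the gamma
    density needs positive support); the number of affected points is
    logged and recorded.  ``method="mom"`` returns the method-of-moments
    estimate (also the MLE initializer); ``"mle"`` maximizes the
    likelihood with the location fixed at zero.

    Raises ``ValueError`` for fewer than five observations or degenerate
    (all-equal) data.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 5:
        raise ValueError(f"gamma fit needs >= 5 distances, got {x.size}")
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    n_zero = int((x == 0).sum())
    if n_zero:
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("all distances are zero; gamma fit undefined")
        x = np.where(x == 0, 0.5 * positive.min(), x)
        logger.info("offset %d zero distances by half the minimum positive distance", n_zero)
    if np.ptp(x) == 0:
        raise ValueError("degenerate (all-equal) distances; gamma fit undefined")

    m, v = x.mean(), x.var()
    mom_shape = m * m / v
    mom_rate = m / v
    if method == "mom":
        ll = float(stats.gamma.logpdf(x, mom_shape, scale=1.0 / mom_rate).sum())
        return GammaFit(mom_shape, mom_rate, True, ll, "mom", x.size, n_zero)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    try:
        a, _, scale = stats.gamma.fit(x, mom_shape, floc=0, scale=1.0 / mom_rate)
        converged = np.isfinite(a) and np.isfinite(scale) and a > 0 and scale > 0
    except Exception:  # pragma: no cover - solver failure fallback
        a, scale, converged = mom_shape, 1.0 / mom_rate, False
    ll = float(stats.gamma.logpdf(x, a, scale=scale).sum())
    return GammaFit(float(a), float(1.0 / scale), bool(converged), ll, "mle", x.size, n_zero)


# ---------------------------------------------------------------------------
# distance binning
# ---------------------------------------------------------------------------

@dataclass
class DistanceDistribution:
    """Binned observed vs expected inter-CO distance frequencies."""

    edges: np.ndarray
    observed_counts: np.ndarray
    observed_freq: np.ndarray
    expected_counts: np.ndarray
    expected_freq: np.ndarray
    observed_median: float
    expected_median: float
    observed_fit: GammaFit | None = None
    expected_fit: GammaFit | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.edges[:-1],
                "bin_end": self.edges[1:],
                "observed_count": self.observed_counts,
                "observed_freq": self.observed_freq,
                "expected_count": self.expected_counts,
                "expected_freq": self.expected_freq,
            }
        )


def bin_distances(
    observed, expected, params: AnalysisParams, fit: bool = True
) -> DistanceDistribution:
    """Bin observed and expected distances into uniform ``bin_width`` bins
    ``[k*w, (k+1)*w)`` and normalize each series to frequencies summing to 1.
    Medians of both series are recorded; gamma fits are attempted when
    ``fit`` is true (``None`` on too-few/degenerate data)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size == 0:
        raise ValueError("no observed distances to bin")
    if np.any(obs < 0) or np.any(exp < 0):
        raise ValueError("distances must be non-negative")
    w = params.bin_width
    top = max(obs.max(), exp.max() if exp.size else 0.0)
    n_bins = max(1, int(np.floor(top / w)) + 1)
    edges = np.arange(n_bins + 1, dtype=float) * w
    obs_counts, _ = np.histogram(obs, bins=edges)
    exp_counts, _ = np.histogram(exp, bins=edges)

    def _freq(c):
        t = c.sum()
        return c / t if t else c.astype(float)

    def _try_fit(x):
        if not fit:
            return None
        try:
            return fit_gamma(x)
        except ValueError as err:
            logger.warning("gamma fit skipped: %s", err)
            return None

    return DistanceDistribution(
        edges=edges,
        observed_counts=obs_counts,
        observed_freq=_freq(obs_counts),
        expected_counts=exp_counts,
        expected_freq=_freq(exp_counts),
        observed_median=float(np.median(obs)),
        expected_median=float(np.median(exp)) if exp.size else float("nan"),
        observed_fit=_try_fit(obs),
        expected_fit=_try_fit(exp),
    )


# ---------------------------------------------------------------------------
# positional permutation test
# ---------------------------------------------------------------------------

@dataclass
class PositionTestResult:
    observed_mean: float
    p_one_sided: float  # toward chromosome ends (small normalized distances)
    p_two_sided: float
    n_events: int
    n_perm: int


def short_dco_position_test(
    dcos: pd.DataFrame, genome: GenomeMap, params: AnalysisParams, rng
) -> PositionTestResult:
    """Permutation test for chromosome-end bias of short cis-DCOs.

    Events are filtered to ``distance < short_dco_max``.  The statistic is
    the mean normalized distance of event midpoints to the nearest
    chromosome end.  Each permutation replaces every event midpoint with a
    uniform random position on its own chromosome.  The one-sided p-value
    (add-one corrected, never zero) counts null means <= the observed mean,
    i.e. placement at least as end-biased as observed; the two-sided
    variant doubles the smaller tail.
    """
    short = dcos.loc[dcos["distance"] < params.short_dco_max]
    if not len(short):
        raise ValueError("no cis-DCOs below short_dco_max; nothing to test")
    observed = float(short["norm_end_dist"].mean())
    lengths = np.array([genome[c].length for c in short["chrom"]], dtype=float)
    u = rng.uniform(0.0, lengths, size=(params.n_perm, lengths.size))
    null_means = (np.minimum(u, lengths - u) / lengths).mean(axis=1)
    n_low = int((null_means <= observed).sum())
    n_high = int((null_means >= observed).sum())
    p_low = (1 + n_low) / (1 + params.n_perm)
    p_high = (1 + n_high) / (1 + params.n_perm)
    return PositionTestResult(
        observed_mean=observed,
        p_one_sided=p_low,
        p_two_sided=min(1.0, 2.0 * min(p_low, p_high)),
        n_events=int(len(short)),
        n_perm=params.n_perm,
    )


# ---------------------------------------------------------------------------
# coefficient of coincidence
# ---------------------------------------------------------------------------

@dataclass
class CoCProfile:
    bin_centers: np.ndarray     # inter-interval distance, base pairs
    coc: np.ndarray             # NaN where masked
    observed: np.ndarray        # numerator series (mode-dependent)
    expected: np.ndarray        # denominator series (mode-dependent)
    mask: np.ndarray            # True where CoC is defined
    mode: str
    n_individuals: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_bp": self.bin_centers,
                "coc": self.coc,
                "n_obs": self.observed,
                "n_exp": self.expected,
                "mode": self.mode,
            }
        )


def independent_dco_rate(counts: pd.DataFrame) -> float:
    """Expected DCOs per individual under independent placement.

    For each chromosome, a Poisson CO count with the observed per-individual
    mean m_c yields on average m_c^2/2 unordered CO pairs; summing over
    chromosomes gives the genome-wide independence DCO rate used to scale
    the expected distance series.  ``counts`` is the
    :func:`~meicos.calling.per_individual_counts` table.
    """
    chrom_cols = [c for c in counts.columns if c != "total"]
    m = counts[chrom_cols].mean(axis=0).to_numpy(dtype=float)
    return float((m * m / 2.0).sum())


def coc_distance_histogram(
    distribution: DistanceDistribution,
    observed_rate: float | None = None,
    expected_rate: float | None = None,
) -> CoCProfile:
    """CoC per distance bin from a binned distance distribution.

    CoC(bin) = observed_freq / expected_freq, with the two series put on a
    per-individual rate scale when both rates are supplied (observed DCOs
    per individual vs the independence rate from
    :func:`independent_dco_rate`).  Without rates the ratio is taken on the
    normalized frequencies directly.  Bins with zero expected frequency are
    masked (NaN), never infinite.
    """
    exp = distribution.expected_freq.astype(float)
    obs = distribution.observed_freq.astype(float)
    if not exp.sum():
        raise ValueError("expected distance series is empty/all-zero")
    scale = 1.0
    if observed_rate is not None and expected_rate is not None:
        if expected_rate <= 0:
            raise ValueError("expected_rate must be positive")
        scale = observed_rate / expected_rate
    mask = exp > 0
    coc = np.full(obs.size, np.nan)
    coc[mask] = scale * obs[mask] / exp[mask]
    return CoCProfile(
        bin_centers=distribution.bin_centers,
        coc=coc,
        observed=obs,
        expected=exp,
        mask=mask,
        mode="distance_histogram",
    )


def coc_interval_pairs(
    events: pd.DataFrame,
    genome: GenomeMap,
    individuals,
    params: AnalysisParams,
) -> CoCProfile:
    """Classical interval-pair CoC from called CO events.

    Chromosomes are tiled into ``bin_width`` intervals.  For an interval
    pair (i, j): observed = fraction of individuals with >= 1 CO midpoint
    in both, expected = f_i * f_j (product of single-interval fractions).
    The CoC of distance class d = |i - j| >= 1 is the ratio of observed and
    expected sums pooled over all pairs of that class across chromosomes
    (weighting chromosomes by their CO content).
    """
    individuals = list(individuals)
    n_ind = len(individuals)
    if n_ind == 0:
        raise ValueError("individuals list must not be empty")
    ind_index = {ind: k for k, ind in enumerate(individuals)}
    w = params.bin_width
    max_classes = max(genome.n_windows(int(w), c) for c in genome.names) - 1
    if max_classes < 1:
        raise ValueError("bin_width too large: need >= 2 intervals per chromosome")
    num = np.zeros(max_classes)
    den = np.zeros(max_classes)
    for chrom in genome.names:
        n_win = genome.n_windows(int(w), chrom)
        sub = events.loc[events["chrom"] == chrom]
        present = np.zeros((n_ind, n_win), dtype=bool)
        if len(sub):
            rows = np.array([ind_index[i] for i in sub["individual"]])
            cols = window_index(sub["midpoint"].to_numpy(), int(w))
            present[rows, cols] = True
        p = present.astype(float)
        joint = (p.T @ p) / n_ind          # fraction with a CO in both intervals
        f = p.mean(axis=0)
        indep = np.outer(f, f)
        for d in range(1, n_win):
            num[d - 1] += np.trace(joint, offset=d)
            den[d - 1] += np.trace(indep, offset=d)
    mask = den > 0
    coc = np.full(max_classes, np.nan)
    coc[mask] = num[mask] / den[mask]
    return CoCProfile(
        bin_centers=w * np.arange(1, max_classes + 1),
        coc=coc,
        observed=num,
        expected=den,
        mask=mask,
        mode="interval_pairs",
        n_individuals=n_ind,
    )


def coc_profile(
    mode: str = "distance_histogram",
    *,
    distribution: DistanceDistribution | None = None,
    observed_rate: float | None = None,
    expected_rate: float | None = None,
    events: pd.DataFrame | None = None,
    genome: GenomeMap | None = None,
    individuals=None,
    params: AnalysisParams | None = None,
) -> CoCProfile:
    """Dispatch to :func:`coc_distance_histogram` or :func:`coc_interval_pairs`."""
    if mode == "distance_histogram":
        if distribution is None:
            raise ValueError("distance_histogram mode needs a DistanceDistribution")
        return coc_distance_histogram(distribution, observed_rate, expected_rate)
    if mode == "interval_pairs":
        if events is None or genome is None or individuals is None or params is None:
            raise ValueError("interval_pairs mode needs events, genome, individuals, params")
        return coc_interval_pairs(events, genome, individuals, params)
    raise ValueError(f"unknown CoC mode {mode!r}")
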