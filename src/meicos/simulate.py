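"""Synthetic F2 meiosis simulator with tunable crossover interference.

An F2 individual carries the products of two independent meioses, one per
F1 gamete.  Each gamete receives crossovers (COs) per chromosome from one
of three generative models:

``poisson``
    No interference: the gamete CO count is Poisson with the configured
    intensity and positions are i.i.d. uniform (optionally end-biased).
``gamma_renewal``
    Positive interference: chiasma positions on the *bivalent* follow a
    stationary renewal process with gamma(nu, rate) inter-event distances,
    rate = 2 * intensity * nu / length, so the bivalent carries twice the
    gamete intensity.  Each chiasma is then independently retained on the
    gamete with probability 1/2 (chromatid thinning).  nu = 1 recovers a
    Poisson process; larger nu spaces chiasmata more evenly.
``clustered``
    Negative interference: a Neyman-Scott cluster process.  Cluster seeds
    are Poisson-distributed and placed uniformly; each seed spawns
    1 + Poisson(cluster_size_mean - 1) COs at Laplace-distributed offsets,
    clipped to the chromosome.

Marker genotypes are emitted at a shared Poisson-spaced SNP grid with
configurable missingness; ground-truth CO positions are retained for
oracle tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genome import GenomeMap, uniform_genome

logger = logging.getLogger(__name__)

GENOTYPE_CATEGORIES = ["NA", "AA", "AB", "BB"]  # code -1, 0, 1, 2 (+1 offset)

_MAX_OBLIGATE_REDRAWS = 1000


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic F2 population.

    Intensities are expressed per gamete per chromosome; when a single
    scalar is given it is allocated across chromosomes proportionally to
    chromosome length (relative to the mean length), so unequal genomes
    receive COs roughly per-Mb.  Defaults emulate a wild-type-like
    Col x Ler F2 experiment: ~8.4 COs per individual over five
    chromosomes, 50-kb marker spacing, 10% missing calls.
    """

    genome: GenomeMap = field(default_factory=uniform_genome)
    co_intensity: float = 0.84
    model: str = "gamma_renewal"  # poisson | gamma_renewal | clustered
    nu: float = 5.0
    cluster_rate: float = 0.42
    cluster_size_mean: float = 2.0
    cluster_scale: float = 1_000_000.0
    obligate_co: bool = False
    end_bias: float = 0.0
    n_individuals: int = 260
    marker_spacing: float = 50_000.0
    marker_layout: str = "poisson"  # poisson | grid
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.co_intensity <= 0:
            raise ValueError("co_intensity must be positive")
        if self.model not in ("poisson", "gamma_renewal", "clustered"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "gamma_renewal" and self.nu < 1:
            raise ValueError("nu must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        if self.cluster_size_mean < 1:
            raise ValueError("cluster_size_mean must be >= 1")

    def chrom_intensity(self, chrom: str) -> float:
        """Per-gamete CO intensity for one chromosome (length-proportional)."""
        lengths = np.array([c.length for c in self.genome], dtype=float)
        return self.co_intensity * self.genome[chrom].length / lengths.mean()

    def chrom_cluster_rate(self, chrom: str) -> float:
        lengths = np.array([c.length for c in self.genome], dtype=float)
        return self.cluster_rate * self.genome[chrom].length / lengths.mean()


@dataclass
class MeiosisTruth:
    """Ground truth for one gamete on one chromosome.

    The transmitted haplotype at position x is ``founder`` flipped once per
    CO left of x (parity rule).
    """

    individual: str
    parent: str  # "maternal" | "paternal"
    chromosome: str
    founder: str  # "P1" | "P2"
    co_positions: np.ndarray  # strictly increasing, inside (1, length)

    def haplotype_at(self, positions) -> np.ndarray:
        """0 for P1, 1 for P2 at each queried position."""
        base = 0 if self.founder == "P1" else 1
        flips = np.searchsorted(self.co_positions, np.asarray(positions, dtype=float))
        return (base + flips) % 2


def wt_preset(**overrides) -> SimulationConfig:
    """Wild-type-like: strong positive interference, ~8.4 COs/individual."""
    return replace(SimulationConfig(), **overrides)

def no_interference_preset(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(model="poisson"), **overrides)

def clustered_preset(**overrides) -> SimulationConfig:
    """Mutant-like negative interference: ~14 COs/individual, clustered."""
    base = SimulationConfig(model="clustered", co_intensity=1.4, cluster_rate=0.7)
    return replace(base, **overrides)

PRESETS = {
    "wt": wt_preset,
    "no_interference": no_interference_preset,
    "clustered": clustered_preset,
}


# ---------------------------------------------------------------------------
# gamma renewal internals
# ---------------------------------------------------------------------------

def _stationary_first_arrival(nu: float, rate: float, upper: float, rng) -> float:
    """Draw the first event position of a *stationary* gamma renewal process.

    Uses inversion of the equilibrium (stationary-excess) distribution
    F_e(x) = (rate*x/nu) * S_nu(x) + F_{nu+1}(x), where S/F are the gamma
    survival/CDF at the renewal's shape and rate.  Returns inf if the first
    event falls beyond *upper*.
    """
    u = rng.random()
    scale = 1.0 / rate

    def F_e(x: float) -> float:
        return (rate * x / nu) * stats.gamma.sf(x, nu, scale=scale) + stats.gamma.cdf(
            x, nu + 1, scale=scale
        )

    if F_e(upper) <= u:
        return np.inf
    return optimize.brentq(lambda x: F_e(x) - u, 0.0, upper, xtol=1e-6 * upper)


def draw_bivalent_chiasmata(config: SimulationConfig, chrom: str, rng) -> np.ndarray:
    """Chiasma positions on the bivalent for one meiosis (gamma_renewal).

    Stationary start, gamma(nu, rate = 2*intensity*nu/length) increments.
    Exposed so tests can check renewal statistics before chromatid thinning.
    """
    length = float(config.genome[chrom].length)
    intensity = config.chrom_intensity(chrom)
    nu = config.nu
    rate = 2.0 * intensity * nu / length
    first = _stationary_first_arrival(nu, rate, length, rng)
    if not np.isfinite(first):
        return np.empty(0)
    events = [first]
    # mean inter-event = nu/rate; expected count ~ 2*intensity, draw in blocks
    while True:
        gaps = rng.gamma(shape=nu, scale=1.0 / rate, size=8)
        for g in gaps:
            nxt = events[-1] + g
            if nxt >= length:
                return np.array(events)
            events.append(nxt)


def _draw_positions_uniform(n: int, length: float, end_bias: float, rng) -> np.ndarray:
    """Uniform positions on (1, length); with end_bias > 0 the density is
    proportional to d^(-end_bias), d = normalized distance to the nearest
    chromosome end, truncated at d = 0.01 (rejection sampling)."""
    if n == 0:
        return np.empty(0)
    if end_bias <= 0:
        return rng.uniform(1.0, length, size=n)
    cap = 0.01 ** (-end_bias)
    out: list[float] = []
    while len(out) < n:
        x = rng.uniform(1.0, length, size=4 * (n - len(out)) + 8)
        d = np.minimum(x - 1.0, length - x) / ((length - 1.0) / 2.0)
        w = np.minimum(np.maximum(d, 1e-12) ** (-end_bias), cap) / cap
        out.extend(x[rng.random(x.size) < w])
    return np.array(out[:n])


def simulate_gamete(
    config: SimulationConfig,
    chrom: str,
    rng,
    individual: str = "",
    parent: str = "maternal",
) -> MeiosisTruth:
    """Simulate one gamete's COs on one chromosome.

    With ``obligate_co`` the *bivalent* is redrawn until it carries at least
    one chiasma (capped); chromatid thinning may still leave the gamete
    CO-free, matching the per-bivalent nature of the obligate CO.
    """
    length = float(config.genome[chrom].length)
    founder = "P1" if rng.random() < 0.5 else "P2"

    if config.model == "poisson":
        intensity = config.chrom_intensity(chrom)
        for attempt in range(_MAX_OBLIGATE_REDRAWS):
            n = rng.poisson(intensity)
            if n > 0 or not config.obligate_co:
                break
        else:
            raise RuntimeError("obligate_co: redraw cap exceeded (intensity too low)")
        positions = _draw_positions_uniform(n, length, config.end_bias, rng)

    elif config.model == "gamma_renewal":
        for attempt in range(_MAX_OBLIGATE_REDRAWS):
            chiasmata = draw_bivalent_chiasmata(config, chrom, rng)
            if chiasmata.size > 0 or not config.obligate_co:
                break
        else:
            raise RuntimeError("obligate_co: redraw cap exceeded (intensity too low)")
        keep = rng.random(chiasmata.size) < 0.5
        positions = chiasmata[keep]

    else:  # clustered
        c_rate = config.chrom_cluster_rate(chrom)
        for attempt in range(_MAX_OBLIGATE_REDRAWS):
            n_seeds = rng.poisson(c_rate)
            seeds = rng.uniform(1.0, length, size=n_seeds)
            sizes = 1 + rng.poisson(config.cluster_size_mean - 1.0, size=n_seeds)
            offsets = rng.laplace(0.0, config.cluster_scale, size=int(sizes.sum()))
            positions = np.repeat(seeds, sizes) + offsets
            positions = np.clip(positions, 1.0 + 1e-3, length - 1e-3)
            if positions.size > 0 or not config.obligate_co:
                break
        else:
            raise RuntimeError("obligate_co: redraw cap exceeded (cluster_rate too low)")

    positions = np.sort(positions[(positions > 1.0) & (positions < length)])
    return MeiosisTruth(
        individual=individual,
        parent=parent,
        chromosome=chrom,
        founder=founder,
        co_positions=positions,
    )


def simulate_f2_individual(
    config: SimulationConfig, rng, individual: str = ""
) -> list[MeiosisTruth]:
    """Two independent meioses (maternal + paternal gamete) per chromosome."""
    truths = []
    for chrom in config.genome.names:
        for parent in ("maternal", "paternal"):
            truths.append(simulate_gamete(config, chrom, rng, individual, parent))
    return truths


# ---------------------------------------------------------------------------
# marker emission
# ---------------------------------------------------------------------------

def draw_marker_map(
    genome: GenomeMap, spacing: float, rng, layout: str = "poisson"
) -> dict[str, np.ndarray]:
    """SNP marker grid shared by the population.

    ``layout="poisson"`` (default, emulating irregular real SNP density):
    per chromosome, a Poisson number (mean length/spacing) of distinct
    integer positions.  ``layout="grid"``: evenly spaced markers at exactly
    *spacing*, useful when a hard bound on midpoint resolution is needed.
    """
    markers = {}
    for c in genome:
        if layout == "grid":
            pos = np.arange(int(spacing) // 2, c.length + 1, int(spacing), dtype=np.int64)
        elif layout == "poisson":
            n = rng.poisson(c.length / spacing)
            pos = np.unique(rng.integers(1, c.length + 1, size=n))
        else:
            raise ValueError(f"unknown marker layout {layout!r}")
        markers[c.name] = pos
    return markers


def genotype_markers(
    truth_pair: Sequence[MeiosisTruth],
    marker_positions: np.ndarray,
    missing_rate: float,
    rng,
) -> np.ndarray:
    """Genotype codes at sorted markers for one chromosome of one individual.

    0 = AA (P1/P1), 1 = AB, 2 = BB (P2/P2), -1 = missing.  The genotype is
    the unordered pair of the two gametes' alleles, each given by the
    founder-parity rule on that gamete's CO list.
    """
    pos = np.asarray(marker_positions)
    if pos.size > 1 and np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted")
    if len(truth_pair) != 2:
        raise ValueError("need exactly two gametes for an F2 genotype")
    codes = (truth_pair[0].haplotype_at(pos) + truth_pair[1].haplotype_at(pos)).astype(
        np.int8
    )
    if missing_rate > 0:
        codes[rng.random(pos.size) < missing_rate] = -1
    return codes


@dataclass
class Population:
    """A simulated F2 population: observed genotypes plus ground truth."""

    genotypes: pd.DataFrame  # individual, chrom, position, genotype (categorical)
    truth: list[MeiosisTruth]
    markers: dict[str, np.ndarray]
    config: SimulationConfig

    @property
    def individuals(self) -> list[str]:
        seen = dict.fromkeys(t.individual for t in self.truth)
        return list(seen)

    def truth_by_track(self) -> dict[tuple[str, str], list[MeiosisTruth]]:
        """Map (individual, chromosome) -> [maternal, paternal] truths."""
        out: dict[tuple[str, str], list[MeiosisTruth]] = {}
        for t in self.truth:
            out.setdefault((t.individual, t.chromosome), []).append(t)
        return out


def generate_population(config: SimulationConfig) -> Population:
    """Simulate the full population deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    markers = draw_marker_map(
        config.genome, config.marker_spacing, rng, config.marker_layout
    )

    truths: list[MeiosisTruth] = []
    ind_code_col: list[np.ndarray] = []
    chrom_code_col: list[np.ndarray] = []
    pos_col: list[np.ndarray] = []
    code_col: list[np.ndarray] = []
    n_digits = max(4, len(str(config.n_individuals)))

    individuals = [f"F2-{i + 1:0{n_digits}d}" for i in range(config.n_individuals)]
    chrom_names = config.genome.names
    for k, ind in enumerate(individuals):
        ind_truths = simulate_f2_individual(config, rng, ind)
        truths.extend(ind_truths)
        by_chrom: dict[str, list[MeiosisTruth]] = {}
        for t in ind_truths:
            by_chrom.setdefault(t.chromosome, []).append(t)
        for ci, chrom in enumerate(chrom_names):
            pos = markers[chrom]
            codes = genotype_markers(by_chrom[chrom], pos, config.missing_rate, rng)
            ind_code_col.append(np.full(pos.size, k, dtype=np.int32))
            chrom_code_col.append(np.full(pos.size, ci, dtype=np.int8))
            pos_col.append(pos)
            code_col.append(codes)

    # categorical id columns keep multi-million-row tables small
    df = pd.DataFrame(
        {
            "individual": pd.Categorical.from_codes(
                np.concatenate(ind_code_col), categories=individuals
            ),
            "chrom": pd.Categorical.from_codes(
                np.concatenate(chrom_code_col), categories=chrom_names
            ),
            "position": np.concatenate(pos_col),
            "genotype": pd.Categorical.from_codes(
                np.concatenate(code_col) + 1, categories=GENOTYPE_CATEGORIES
            ),
        }
    )
    return Population(genotypes=df, truth=truths, markers=markers, config=config)
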