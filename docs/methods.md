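# Methods

This note documents the models, estimators and numerical choices behind
`meicos`, in the spirit of a statistical-software methods appendix. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model

Positions are 1-based inclusive base pairs. Windows are half-open
`[start, start + w)` tilings of `[1, L]`, the last window truncated at the
chromosome end, so window counts always conserve event totals. Each
chromosome has a centromere midpoint splitting it into a left arm
`[1, cen]` and right arm `[cen, L]`; the arm-scaled coordinate maps each
arm linearly to telomere = 0, centromere = 1. Pericentromere intervals are
closed and are *inputs*: on real data they come from DNA-methylation
profiles, which are out of scope here; synthetic genomes place them as a
central fraction (default 20%) of each chromosome. A centromere at a
chromosome end degenerates to a single arm; this is permitted (and logged)
so toy fixtures remain valid.

## Simulator

An F2 individual is the product of two independent meioses; each gamete
receives COs per chromosome from one of three generative models.

**Poisson (no interference).** Gamete CO count ~ Poisson(intensity),
positions i.i.d. uniform on (1, L). This is exactly a homogeneous Poisson
process, the natural null for every interference statistic.

**Gamma renewal (positive interference).** Chiasmata on the *bivalent*
follow a stationary renewal process with gamma(ν, λ) inter-event
distances, λ = 2·intensity·ν/L, so the bivalent carries twice the gamete
intensity. The first event is drawn from the equilibrium (stationary-
excess) distribution, whose CDF has the closed form
F_e(x) = (λx/ν)·S_ν(x) + F_{ν+1}(x) with S/F the gamma survival/CDF; it is
inverted numerically (Brent's method) per gamete. Each chiasma is then
independently retained on the gamete with probability 1/2 (chromatid
thinning, assuming no chromatid interference). Thinning preserves the
pair-correlation structure, so gamete-level interference is real but
weaker than bivalent-level — the standard behaviour of the gamma model.
ν = 1 reduces exactly to Poisson (verified by a KS test in the suite).

**Clustered (negative interference).** A Neyman–Scott process: cluster
seeds ~ Poisson(rate) placed uniformly; each seed spawns
1 + Poisson(mean − 1) COs at Laplace(scale) offsets, clipped to the
chromosome. This is the minimal generator of a "short-distance excess"
signature; it makes no mechanistic claim about how clustering arises.

**Obligate CO** (off by default) redraws the bivalent until it carries at
least one chiasma (capped at 1,000 redraws, then an error). The
obligation is per bivalent: thinning may still leave a gamete CO-free.

**Defaults as study conditions.** The wild-type-like preset uses
intensity 0.84 COs/gamete/chromosome on five chromosomes (≈ 8.4 COs per
F2 individual genome-wide), ν = 5, Poisson-spaced markers at mean 50 kb,
10% missing calls. A scalar intensity is allocated across chromosomes
proportionally to length, i.e. a constant per-Mb rate; per-chromosome
intensities may be supplied implicitly by scaling lengths. Marker grids
default to Poisson spacing (emulating irregular real SNP density); an
even-grid layout exists for analyses that need a hard bound on midpoint
resolution, since under Poisson spacing the CO midpoint error is bounded
only by half the local gap and ~13.5% of gaps exceed twice the mean.

**What the simulator does not emulate:** read-level noise (genotyping
errors other than missingness), gene conversion, chromatid interference,
sex-specific maps, segregation distortion, and the two-pathway (class I /
class II) mixture. Passing tests therefore demonstrate correctness of the
*analysis machinery* under clean generative assumptions, not robustness
to every artefact of real GBS data.

## CO caller

Missing calls are dropped (no imputation); maximal runs of identical
genotype become segments; runs supported by fewer than `min_support`
markers (default 3) are dissolved — their markers ignored — and flanking
same-genotype segments merge; the pass repeats to a fixpoint. Dissolution
is simultaneous within a pass: all sub-threshold runs are removed before
runs are recomputed. This is deterministic and order-free; a sequential
(shortest-first) rule can differ on pathological alternating tracks.

One CO event is emitted per adjacent segment pair, bounded by the last
marker of the left segment and the first of the right, and positioned at
the interval midpoint, which every downstream stage uses. An AA↔BB
adjacency implies two allele changes and is emitted as two stacked,
flagged events sharing the same bounds. The caller deliberately replaces
hidden-Markov smoothing over read counts: inputs here are genotype-level,
and the support threshold absorbs residual flicker.

## Interference analysis

**cis-DCO extraction.** Every consecutive segment triple (P, AB, P) with
the same parental P on both flanks yields one event; (AA, AB, BB) trans
triples are excluded (those two COs necessarily sit on different
gametes — a parity argument the suite checks exhaustively against the
truth archive). Overlapping triples are all counted and flagged. The
event distance is the difference of the two transition midpoints; the
event midpoint is their mean, and its distance to the nearest chromosome
end is normalized by chromosome length.

**Expected distances.** Per chromosome, `n_pairs` (default 200) pairs of
CO midpoints are drawn uniformly *with replacement* from the pooled
called midpoints; the distance is the absolute difference. With
replacement is well defined for small pools; identical draws give
distance 0. Chromosomes with fewer than two midpoints are skipped with a
warning.

**Binning and gamma fits.** Distances are binned at 3.15 Mb (default)
into `[kw, (k+1)w)` bins; each series is normalized to frequencies.
Gamma parameters are estimated by maximum likelihood (location fixed at
zero) with method-of-moments initialization; zero distances are offset by
half the smallest positive distance before fitting, with the count of
affected points recorded. Fewer than five observations or all-equal data
raise an error rather than returning a meaningless fit.

**Chromosome-end permutation test.** Events with distance < 5 Mb
(default) qualify. The statistic is the mean normalized end distance of
event midpoints; each of `n_perm` (default 10,000) permutations replaces
every midpoint with a uniform position on its own chromosome. The
one-sided p counts null means ≤ observed (end-biased direction) with the
add-one correction p = (1 + k)/(1 + n_perm), so p is never zero and is
uniform under the null (verified by KS over 200 replicate datasets); the
two-sided p doubles the smaller tail, capped at 1.

**CoC.** Two modes, which must agree at CoC = 1 under no interference
(the suite checks both):

- *distance_histogram* — observed cis-DCO frequency divided by expected
  frequency per bin. When rates are supplied the ratio is rescaled by
  (observed DCOs per individual) / (independence DCO rate), where the
  independence rate is Σ_c m_c²/2 with m_c the observed mean CO count per
  individual on chromosome c — the expected number of unordered CO pairs
  under a Poisson count at the observed mean. Without rates the scale is
  1 and the ratio compares shapes only.
- *interval_pairs* — chromosomes tiled into bin-width intervals; for pair
  (i, j), observed = fraction of individuals with ≥ 1 CO midpoint in
  both, expected = f_i·f_j. The CoC of distance class d = |i−j| is the
  ratio of observed and expected sums pooled over all pairs of the class
  across chromosomes, which weights chromosomes by their CO content.
  Classes with zero expected mass are masked (NaN), never infinite.

## Group statistics

Totals get a Kruskal–Wallis omnibus and Dunn's post hoc z-tests on pooled
ranks with tie correction; every metric (arm, pericentromere, total) gets
pairwise two-sided Wilcoxon rank-sum tests. Bonferroni adjustment
multiplies by the number of pairs within each metric family, capped at 1.
Rank tests are delegated to scipy; Dunn's test is implemented here (no
installed dependency provides it) and the Wilcoxon path is validated
against exhaustive enumeration of rank assignments on a 3-vs-3 fixture.
`percent_change_summary` reports 100·(group − reference)/reference per
group and for the pooled group mean, plus plain percentage-point
differences for quantities already on a percent scale.

## Problem sizes and determinism

The acceptance script and the heavier tests use 2,000-individual
populations on five 30-Mb chromosomes at 0.85 COs/gamete/chromosome —
large enough that the interval-pair CoC of the shortest distance class is
estimated to within a few percent, small enough to run in seconds to
minutes on one CPU. Every random stage consumes a numpy Generator seeded
from a single configuration seed (child seeds via `SeedSequence.spawn`),
so identical configurations reproduce byte-identical outputs.

## Known limitations

- Two same-gamete COs with no marker between them are invisible to any
  genotype-level caller; at 50-kb spacing this loses < 1% of COs under
  the default intensities but biases the very shortest cis-DCO distances
  downward in heavily clustered populations.
- The distance-histogram CoC depends on the resampled null, which
  inherits the *called* CO landscape; strong landscape distortions move
  the null with the observation. The interval-pair mode is the
  self-contained cross-check.
- Gamma fits describe distance distributions; they are not a likelihood
  estimate of the interference parameter ν (no Housworth–Stahl fitting).
- The pericentromere classifier is only as good as the supplied
  intervals; nothing is inferred from sequence or methylation.
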