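"""cis-DCO extraction, resampled nulls, gamma fits, permutation test, CoC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meicos import (
    AnalysisParams,
    bin_distances,
    coc_distance_histogram,
    coc_interval_pairs,
    coc_profile,
    expected_distance_sample,
    extract_cis_dcos,
    fit_gamma,
    independent_dco_rate,
    short_dco_position_test,
)
from meicos.calling import SEGMENT_COLUMNS


def _segments(rows):
    """rows: (individual, chrom, genotype, first, last)"""
    return pd.DataFrame(
        [(i, c, g, f, l, 5) for i, c, g, f, l in rows], columns=SEGMENT_COLUMNS
    )


class TestExtractCisDCOs:
    def test_pattern_arithmetic(self, toy_genome):
        # transitions at (2.5+3.5)/2 = 3 and (7.5+8.5)/2 = 8 on a 1-Mb scale
        segs = _segments(
            [
                ("i", "tc1", "AA", 1e5, 2.5e5),
                ("i", "tc1", "AB", 3.5e5, 7.5e5),
                ("i", "tc1", "AA", 8.5e5, 9.5e5),
            ]
        )
        dcos = extract_cis_dcos(segs, toy_genome)
        assert len(dcos) == 1
        e = dcos.iloc[0]
        assert (e.mid_left, e.mid_right, e.distance) == (3e5, 8e5, 5e5)
        assert e.flank == "AA"
        assert e.midpoint == 5.5e5
        # nearest end of a 1-Mb chromosome: min(5.5e5, 4.5e5)/1e6
        assert e.norm_end_dist == pytest.approx(0.45)

    def test_trans_configuration_excluded(self, toy_genome):
        segs = _segments(
            [
                ("i", "tc1", "AA", 1e5, 2e5),
                ("i", "tc1", "AB", 3e5, 6e5),
                ("i", "tc1", "BB", 7e5, 9e5),
            ]
        )
        assert len(extract_cis_dcos(segs, toy_genome)) == 0

    def test_overlapping_triples_all_counted_and_flagged(self, toy_genome):
        segs = _segments(
            [
                ("i", "tc1", "AA", 1e5, 2e5),
                ("i", "tc1", "AB", 2.5e5, 3.5e5),
                ("i", "tc1", "AA", 4e5, 5e5),
                ("i", "tc1", "AB", 5.5e5, 6.5e5),
                ("i", "tc1", "AA", 7e5, 9e5),
            ]
        )
        dcos = extract_cis_dcos(segs, toy_genome)
        assert len(dcos) == 2
        assert dcos["overlapping"].all()

    def test_track_boundaries_respected(self, toy_genome):
        # the AA|AB|AA pattern spans two individuals: no event
        segs = _segments(
            [
                ("a", "tc1", "AA", 1e5, 2e5),
                ("a", "tc1", "AB", 3e5, 9e5),
                ("b", "tc1", "AA", 1e5, 9e5),
            ]
        )
        assert len(extract_cis_dcos(segs, toy_genome)) == 0

    def test_every_cis_dco_is_same_gamete(self, noiseless_pop):
        """Parity oracle: both transitions of a cis-DCO sit on one gamete."""
        from meicos import call_population

        segs, _ = call_population(noiseless_pop.genotypes, min_support=1)
        dcos = extract_cis_dcos(segs, noiseless_pop.config.genome)
        assert len(dcos) > 20
        tracks = noiseless_pop.truth_by_track()
        markers = noiseless_pop.markers
        checked = 0
        for e in dcos.itertuples():
            pair = tracks[(e.individual, e.chrom)]
            pos = markers[e.chrom]
            parents = []
            for mid in (e.mid_left, e.mid_right):
                lo = pos[np.searchsorted(pos, mid) - 1]
                hi = pos[np.searchsorted(pos, mid)]
                inside = [
                    p.parent
                    for p in pair
                    for co in p.co_positions
                    if lo < co < hi
                ]
                parents.append(inside)
            if len(parents[0]) == 1 and len(parents[1]) == 1:
                assert parents[0][0] == parents[1][0]
                checked += 1
        assert checked >= 0.9 * len(dcos)


class TestExpectedDistances:
    def test_identical_midpoints_give_zero_distances(self):
        params = AnalysisParams(n_pairs=50)
        d = expected_distance_sample({"c": np.full(5, 7e6)}, params, np.random.default_rng(0))
        assert np.all(d == 0)

    def test_two_point_pool_support(self):
        params = AnalysisParams(n_pairs=500)
        d = expected_distance_sample({"c": np.array([2e6, 9e6])}, params, np.random.default_rng(1))
        assert set(np.unique(d)) <= {0.0, 7e6}
        assert (d == 7e6).any() and (d == 0).any()

    def test_small_pool_skipped_with_warning(self, caplog):
        params = AnalysisParams(n_pairs=10)
        with caplog.at_level("WARNING"):
            d = expected_distance_sample({"c": np.array([1e6])}, params, np.random.default_rng(0))
        assert d.size == 0
        assert "skipped" in caplog.text

    def test_uniform_pool_gives_triangular_distances(self):
        """|U - V| for U,V uniform on [0, L] has mean L/3."""
        L = 30e6
        rng = np.random.default_rng(2)
        mids = rng.uniform(0, L, size=10_000)
        params = AnalysisParams(n_pairs=10_000)
        d = expected_distance_sample({"c": mids}, params, rng)
        se = L * np.sqrt(1 / 18) / np.sqrt(d.size)
        assert abs(d.mean() - L / 3) < 4 * se + 0.003 * L


class TestBinDistances:
    def test_identical_series_identical_frequencies(self):
        params = AnalysisParams(bin_width=1e6)
        x = np.array([0.2e6, 1.4e6, 1.5e6, 4.2e6, 4.3e6, 8e6])
        dist = bin_distances(x, x, params, fit=False)
        np.testing.assert_allclose(dist.observed_freq, dist.expected_freq)
        assert dist.observed_median == dist.expected_median

    def test_single_short_distance_in_bin_zero(self):
        dist = bin_distances([1e6], [1e6], AnalysisParams(), fit=False)
        assert dist.observed_freq[0] == 1.0
        assert len(dist.observed_freq) == 1

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        dist = bin_distances(
            rng.uniform(0, 3e7, 200), rng.uniform(0, 3e7, 500),
            AnalysisParams(), fit=False,
        )
        assert dist.observed_freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert dist.expected_freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            bin_distances([], [1.0], AnalysisParams())


class TestFitGamma:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(shape=2.0, scale=1 / 4e-7, size=1_000)
        fit = fit_gamma(x)
        assert fit.converged
        assert fit.shape == pytest.approx(2.0, rel=0.1)
        assert fit.rate == pytest.approx(4e-7, rel=0.15)

    def test_exponential_is_shape_one(self):
        rng = np.random.default_rng(5)
        fit = fit_gamma(rng.exponential(scale=5e6, size=1_000))
        assert fit.shape == pytest.approx(1.0, rel=0.1)

    def test_mle_likelihood_at_least_mom(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.gamma(rng.uniform(0.5, 8), rng.uniform(1e5, 1e7), size=300)
            mle = fit_gamma(x, method="mle")
            mom = fit_gamma(x, method="mom")
            assert mle.loglik >= mom.loglik - 1e-6

    def test_zero_offsetting(self):
        x = np.array([0.0, 0.0, 2.0, 4.0, 8.0, 16.0])
        fit = fit_gamma(x)
        assert fit.n_zero_offset == 2
        assert np.isfinite(fit.loglik)

    @pytest.mark.parametrize("bad", [[1, 2, 3], [5.0] * 10])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_gamma(bad)


class TestPositionPermutationTest:
    def _dcos(self, chroms, midpoints, genome, distance=1e5):
        lengths = np.array([genome[c].length for c in chroms], dtype=float)
        m = np.asarray(midpoints, dtype=float)
        return pd.DataFrame(
            {
                "individual": "i",
                "chrom": chroms,
                "distance": distance,
                "midpoint": m,
                "norm_end_dist": np.minimum(m, lengths - m) / lengths,
            }
        )

    def test_maximal_end_bias(self, toy_genome):
        params = AnalysisParams(n_perm=999)
        dcos = self._dcos(["tc1"] * 10, [1.0] * 10, toy_genome)
        res = short_dco_position_test(dcos, toy_genome, params, np.random.default_rng(0))
        assert res.observed_mean <= 2e-6  # events at position 1 on a 1-Mb chromosome
        assert res.p_one_sided <= 2 / (1 + 999)

    def test_single_central_event(self, toy_genome):
        params = AnalysisParams(n_perm=999)
        dcos = self._dcos(["tc1"], [500_000], toy_genome)
        res = short_dco_position_test(dcos, toy_genome, params, np.random.default_rng(0))
        assert res.observed_mean == pytest.approx(0.5)
        assert res.p_one_sided > 0.99

    def test_long_events_excluded_by_distance_filter(self, toy_genome):
        params = AnalysisParams(n_perm=100)
        dcos = self._dcos(["tc1"] * 3, [1.0, 2.0, 3.0], toy_genome, distance=9e6)
        with pytest.raises(ValueError, match="short_dco_max"):
            short_dco_position_test(dcos, toy_genome, params, np.random.default_rng(0))

    def test_p_uniform_under_uniform_placement(self, toy_genome):
        """Null calibration at reduced replication (full check in acceptance)."""
        rng = np.random.default_rng(7)
        params = AnalysisParams(n_perm=199)
        pvals = []
        for _ in range(60):
            m = rng.uniform(1, 1_000_000, size=25)
            dcos = self._dcos(["tc1"] * 25, m, toy_genome)
            pvals.append(short_dco_position_test(dcos, toy_genome, params, rng).p_one_sided)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005


class TestCoC:
    def test_identical_series_give_unit_coc(self):
        params = AnalysisParams(bin_width=1e6)
        x = np.array([0.5e6, 2.2e6, 2.4e6, 5.5e6, 7.7e6])
        dist = bin_distances(x, x, params, fit=False)
        coc = coc_distance_histogram(dist)
        np.testing.assert_allclose(coc.coc[coc.mask], 1.0)

    def test_doubled_shortest_bin(self):
        """Observed mass doubled in bin 0 (removed proportionally elsewhere)
        gives CoC exactly 2 there."""
        params = AnalysisParams(bin_width=1e6)
        expected = [0.5e6] * 2 + [1.5e6] * 4 + [2.5e6] * 4   # freqs .2/.4/.4
        observed = [0.5e6] * 4 + [1.5e6] * 3 + [2.5e6] * 3   # freqs .4/.3/.3
        dist = bin_distances(observed, expected, params, fit=False)
        coc = coc_distance_histogram(dist)
        assert coc.coc[0] == pytest.approx(2.0)
        assert coc.coc[1] == pytest.approx(0.75)

    def test_rate_scaling(self):
        params = AnalysisParams(bin_width=1e6)
        x = np.array([0.5e6, 1.5e6, 2.5e6, 3.5e6, 4.5e6])
        dist = bin_distances(x, x, params, fit=False)
        coc = coc_distance_histogram(dist, observed_rate=2.0, expected_rate=4.0)
        np.testing.assert_allclose(coc.coc[coc.mask], 0.5)

    def test_zero_expected_bins_masked(self):
        params = AnalysisParams(bin_width=1e6)
        dist = bin_distances([0.5e6, 5.5e6], [0.5e6, 0.6e6], params, fit=False)
        coc = coc_distance_histogram(dist)
        assert not coc.mask[5]
        assert np.isnan(coc.coc[5])
        assert np.all(coc.coc[coc.mask] >= 0)

    def test_interval_pairs_all_present_is_unit(self, toy_genome):
        params = AnalysisParams(bin_width=250_000)
        rows = []
        for ind in ("a", "b", "c"):
            for mid in (100_000, 350_000, 600_000, 900_000):
                rows.append((ind, "tc1", mid))
        events = pd.DataFrame(rows, columns=["individual", "chrom", "midpoint"])
        coc = coc_interval_pairs(events, toy_genome, ["a", "b", "c"], params)
        np.testing.assert_allclose(coc.coc[coc.mask], 1.0)

    def test_dispatcher(self, toy_genome):
        params = AnalysisParams(bin_width=250_000)
        events = pd.DataFrame(
            [("a", "tc1", 1e5), ("b", "tc1", 6e5)],
            columns=["individual", "chrom", "midpoint"],
        )
        p = coc_profile("interval_pairs", events=events, genome=toy_genome,
                        individuals=["a", "b"], params=params)
        assert p.mode == "interval_pairs"
        with pytest.raises(ValueError, match="unknown CoC mode"):
            coc_profile("nope")


def test_independent_dco_rate_arithmetic():
    counts = pd.DataFrame({"c1": [2, 2, 2], "c2": [1, 1, 1], "total": [3, 3, 3]})
    # Poisson pair expectation: 2^2/2 + 1^2/2 = 2.5
    assert independent_dco_rate(counts) == pytest.approx(2.5)
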