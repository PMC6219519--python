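"""Dynamic photon distribution analysis: occupancy-time distribution,
analytic pmfs, limits and fitting."""

import numpy as np
import pytest

from nucfret.fret import CorrectionSet, FretPair
from nucfret.pda import (
    DynamicPDA,
    PdaHistogram,
    dynamic_pmf,
    make_histograms,
    occupancy_density,
    static_species_pmf,
)
from nucfret.simulate import (
    ExchangingPair,
    FretSpecies,
    SimConfig,
    simulate_bursts,
    simulate_two_state_trajectory,
)


def _mk(k_ab, k_ba):
    return ExchangingPair(
        FretSpecies("a", 61.1, 2.0), FretSpecies("b", 46.1, 2.0), k_ab, k_ba
    )


class TestOccupancyDensity:
    def test_absorbing_state_concentrates_at_full_occupancy(self):
        occ = occupancy_density(_mk(0.0, 1e4), 2e-3)
        assert occ.atom_a == pytest.approx(1.0)
        assert occ.atom_b == pytest.approx(0.0, abs=1e-12)

    def test_total_mass_is_one(self):
        for k1, k2, T in [(33.4e3, 13.2e3, 2e-3), (300.0, 200.0, 1e-3),
                          (1e5, 1e5, 5e-4), (500.0, 9e3, 2e-3)]:
            occ = occupancy_density(_mk(k1, k2), T)
            assert occ.total_mass() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "k1,k2,T",
        [(33.4e3, 13.2e3, 2e-3), (2e3, 5e3, 1e-3), (1e5, 4e4, 5e-4)],
    )
    def test_moments_match_closed_forms(self, k1, k2, T):
        occ = occupancy_density(_mk(k1, k2), T)
        mean, var = occ.numeric_moments()
        assert mean == pytest.approx(occ.mean(), abs=1e-5)
        assert var == pytest.approx(occ.var(), rel=1e-4)

    def test_mean_matches_monte_carlo_oracle(self):
        pair = _mk(8e3, 5e3)
        rng = np.random.default_rng(7)
        occ_mc = [
            simulate_two_state_trajectory(pair, 1e-3, rng).occupancy_a()
            for _ in range(4000)
        ]
        occ = occupancy_density(pair, 1e-3)
        se = np.std(occ_mc) / np.sqrt(len(occ_mc))
        assert occ.mean() == pytest.approx(np.mean(occ_mc), abs=3 * se)
        se_var = np.var(occ_mc) * np.sqrt(2.0 / len(occ_mc))
        assert occ.var() == pytest.approx(np.var(occ_mc), abs=3 * se_var)

    def test_published_rates_are_deep_in_averaged_regime(self):
        # atoms ~ exp(-27)/exp(-67): the 2 ms window averages the exchange
        occ = occupancy_density(_mk(33.4e3, 13.2e3), 2e-3)
        assert occ.atom_a < np.exp(-26)
        assert occ.atom_b < np.exp(-26)
        peak = occ.grid[np.argmax(occ.density)]
        assert peak == pytest.approx(13.2 / 46.6, abs=0.02)

    def test_both_rates_zero_rejected(self):
        with pytest.raises(ValueError):
            occupancy_density(_mk(0.0, 0.0), 1e-3)


def _uniform_hist(F=50, tw=1e-3, bg=0.0):
    """Histogram shell with a degenerate count distribution (model input)."""
    return PdaHistogram(
        time_window=tw,
        bin_edges=np.linspace(-0.1, 1.1, 41),
        counts=np.zeros(40),
        n_windows=1,
        f_values=np.array([F]),
        f_weights=np.array([1.0]),
        bg_green_counts=bg,
        bg_red_counts=bg,
    )


class TestAnalyticPmfs:
    def test_pmfs_normalize(self, corrections, pair):
        hist = _uniform_hist(F=80, bg=0.35e3 * 1e-3)
        sp = FretSpecies("MF", 61.1, 2.0)
        assert static_species_pmf(sp, hist, corrections, pair).sum() == pytest.approx(
            1.0, abs=1e-9
        )
        pmf = dynamic_pmf(_mk(33.4e3, 13.2e3), hist, corrections, pair)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_efficiency_species_is_all_green(self, pair):
        hist = _uniform_hist(F=50)
        sp = FretSpecies("D0", 500.0, 0.0)  # E ~ 0
        pmf = static_species_pmf(sp, hist, CorrectionSet(), pair)
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        assert pmf[np.abs(centers - 0.0).argmin()] == pytest.approx(1.0, abs=1e-4)

    def test_fixed_count_even_split_is_exact_binomial(self, pair):
        from scipy.stats import binom

        hist = _uniform_hist(F=50)
        sp = FretSpecies("at_r0", 55.6, 0.0)  # E = 0.5 exactly
        pmf = static_species_pmf(sp, hist, CorrectionSet(), pair)
        # rebuild the expected histogram of k/50 over the same bins
        k = np.arange(51)
        expected = np.zeros(40)
        bins = np.digitize(k / 50.0, hist.bin_edges) - 1
        np.add.at(expected, bins, binom.pmf(k, 50, 0.5))
        np.testing.assert_allclose(pmf, expected, atol=5e-4)

    def test_static_species_pmf_matches_simulation(self, corrections, pair):
        cfg = SimConfig(seed=51, donor_only_fraction=0.0)
        sp = FretSpecies("MF", 61.1, 2.0, 1.0)
        stream = simulate_bursts([sp], cfg, 700)
        hist = make_histograms(stream, [2e-3], corrections)[0]
        pmf = static_species_pmf(sp, hist, corrections, pair)
        expected = hist.n_windows * pmf
        chi2 = np.sum((hist.counts - expected) ** 2 / np.maximum(expected, 1.0))
        assert chi2 / hist.counts.size < 1.5

    def test_dynamic_pmf_matches_simulation_at_published_rates(
        self, corrections, pair, exchange_pair
    ):
        cfg = SimConfig(seed=52, donor_only_fraction=0.0)
        stream = simulate_bursts([], cfg, 700, dynamic=exchange_pair, dyn_fraction=1.0)
        hist = make_histograms(stream, [2e-3], corrections)[0]
        pmf = dynamic_pmf(exchange_pair, hist, corrections, pair)
        expected = hist.n_windows * pmf
        chi2 = np.sum((hist.counts - expected) ** 2 / np.maximum(expected, 1.0))
        assert chi2 / hist.counts.size < 1.5

    def test_slow_exchange_limit_equals_static_mixture(self, pair):
        hist = _uniform_hist(F=60)
        corr = CorrectionSet()
        slow = _mk(1e-3, 1e-3)
        pmf_dyn = dynamic_pmf(slow, hist, corr, pair)
        pmf_a = static_species_pmf(FretSpecies("a", 61.1, 2.0), hist, corr, pair)
        pmf_b = static_species_pmf(FretSpecies("b", 46.1, 2.0), hist, corr, pair)
        mix = 0.5 * (pmf_a + pmf_b)
        assert 0.5 * np.abs(pmf_dyn - mix).sum() < 1e-3

    def test_fast_exchange_limit_equals_averaged_species(self, pair):
        from nucfret.fret import distance_from_efficiency, efficiency_from_distance

        hist = _uniform_hist(F=60)
        corr = CorrectionSet()
        fast = ExchangingPair(
            FretSpecies("a", 61.1, 0.0), FretSpecies("b", 46.1, 0.0), 1e9, 1e9
        )
        pmf_dyn = dynamic_pmf(fast, hist, corr, pair, n_occ=400)
        e_avg = 0.5 * (
            efficiency_from_distance(61.1, pair) + efficiency_from_distance(46.1, pair)
        )
        sp = FretSpecies("avg", distance_from_efficiency(e_avg, pair), 0.0)
        pmf_static = static_species_pmf(sp, hist, corr, pair)
        assert 0.5 * np.abs(pmf_dyn - pmf_static).sum() < 1e-3


class TestDynamicPDAFit:
    def test_self_consistency_refit_of_noise_free_histogram(
        self, corrections, pair, exchange_pair
    ):
        cfg = SimConfig(seed=53, donor_only_fraction=0.10)
        mf = FretSpecies("MF", 61.1, 2.0, 0.40)
        lf = FretSpecies("LF", 85.8, 2.0, 0.15)
        stream = simulate_bursts([mf, lf], cfg, 800, dynamic=exchange_pair,
                                 dyn_fraction=0.35)
        hists = make_histograms(stream, [1e-3, 2e-3], corrections)
        model = DynamicPDA(hists, [mf, lf], donor_only_fraction=0.10,
                           dynamic=exchange_pair, corrections=corrections, pair=pair)
        # replace observed counts with the model's own expectation
        params = model.make_params([])
        for h, pmf in zip(hists, model.expected_pmf(params)):
            h.counts = h.n_windows * pmf
        start = model.make_params(["x_MF", "r_dyn_b", "log10_k_open"])
        start["x_MF"].value = 0.5
        start["r_dyn_b"].value = 48.0
        start["log10_k_open"].value = np.log10(2.5e4)
        res = model.fit(params=start, grid_refine=False)
        assert res.value("x_MF") == pytest.approx(0.40, abs=1e-3)
        assert res.value("r_dyn_b") == pytest.approx(46.1, abs=0.05)
        assert res.k_open == pytest.approx(33.4e3, rel=0.01)
        assert res.chi2_red < 1e-4

    def test_static_fraction_recovery_from_synthetic_data(self, corrections, pair):
        cfg = SimConfig(seed=54, donor_only_fraction=0.20)
        mf = FretSpecies("MF", 61.1, 2.0, 0.50)
        lf = FretSpecies("LF", 85.8, 2.0, 0.30)
        stream = simulate_bursts([mf, lf], cfg, 1500)
        hists = make_histograms(stream, [1e-3], corrections)
        model = DynamicPDA(hists, [mf, lf], donor_only_fraction=0.20,
                           corrections=corrections, pair=pair)
        res = model.fit(vary=["x_MF", "x_LF", "x_donor_only"])
        for name, truth in [("x_MF", 0.5), ("x_LF", 0.3), ("x_donor_only", 0.2)]:
            err = res.stderr(name) or 0.02
            assert res.value(name) == pytest.approx(truth, abs=max(3 * err, 0.03))

    def test_identifiability_guard_names_degenerate_parameters(
        self, corrections, pair, exchange_pair, mixture_stream
    ):
        stream, cfg, (mf, lf) = mixture_stream
        hists = make_histograms(stream, [1e-3], corrections)
        model = DynamicPDA(hists, [mf, lf], donor_only_fraction=0.10,
                           dynamic=exchange_pair, corrections=corrections, pair=pair)
        with pytest.raises(ValueError, match="log10_k_open"):
            model.make_params(["r_dyn_b", "log10_k_open", "log10_k_close"])

    def test_window_slicing_drops_trailing_remainder(self, mixture_stream, corrections):
        stream, cfg, _ = mixture_stream
        hists = make_histograms(stream, [1e-3, 2e-3], corrections)
        # more 1 ms than 2 ms windows, both well populated
        assert hists[0].n_windows > hists[1].n_windows > 50
        assert hists[0].counts.sum() == hists[0].n_windows
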