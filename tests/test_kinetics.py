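"""Four-state octasome/hexasome kinetics: identities, steady state,
concentration dependence and global fits."""

import numpy as np
import pytest
from dataclasses import replace

from nucfret.fret import FretPair, efficiency_from_distance
from nucfret.kinetics import (
    TABLE_150MM,
    FourStateScheme,
    apparent_exchange,
    constrained_fractions,
    equilibrium_constant,
    fit_concentration_series,
    fit_salt_series,
    free_dimer_concentration,
    mean_dyn_efficiency,
    relaxation_time,
    steady_state,
)


class TestClosedFormIdentities:
    def test_relaxation_time_of_published_exchange_rates(self):
        # (33.4 + 13.2) ms^-1 -> 21.46 us, printed as (21.6 +/- 1.4) us
        t_r = relaxation_time(33.4e3, 13.2e3)
        assert t_r * 1e6 == pytest.approx(21.6, abs=1.4)

    def test_relaxation_time_of_hexasome_step(self):
        # (54 + 17) x10^3 s^-1 -> 14.08 us, printed (14 +/- 6) us
        assert relaxation_time(54e3, 17e3) * 1e6 == pytest.approx(14.0, abs=6.0)

    def test_one_sided_exchange_reduces_to_reciprocal_rate(self):
        assert relaxation_time(250.0, 0.0) == pytest.approx(1 / 250.0)

    def test_equilibrium_constants_match_printed_table(self):
        assert equilibrium_constant(13e3, 8e3) == pytest.approx(1.6, abs=0.2)
        assert equilibrium_constant(54e3, 17e3) == pytest.approx(3.3, abs=0.5)
        assert equilibrium_constant(5.0, 5.0) == 1.0

    def test_mean_dyn_efficiency_weighting(self, pair):
        e_mf = efficiency_from_distance(61.2, pair)
        e_hf = efficiency_from_distance(46.7, pair)
        x_open = 33.4 / 46.6  # occupancy of HF from the printed rates
        e_dyn = mean_dyn_efficiency(1 - x_open, x_open, e_mf, e_hf)
        by_hand = (13.2 * e_mf + 33.4 * e_hf) / 46.6
        assert e_dyn == pytest.approx(by_hand, abs=1e-12)
        assert mean_dyn_efficiency(1.0, 0.0, e_mf, e_hf) == e_mf
        assert mean_dyn_efficiency(0.5, 0.5, 0.2, 0.6) == pytest.approx(0.4)

    def test_free_dimer_bookkeeping(self):
        assert free_dimer_concentration(1e-9, 0.0) == 0.0
        assert free_dimer_concentration(1e-9, 1.0) == pytest.approx(1e-9)
        # one dimer per hexasome, two per tetrasome
        assert free_dimer_concentration(2e-9, 0.25, 0.25) == pytest.approx(
            2e-9 * 0.75
        )


class TestSteadyState:
    def test_populations_sum_to_one_and_obey_detailed_balance(self):
        frac, d = steady_state(TABLE_150MM, 1e-9)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)
        s = TABLE_150MM
        assert frac["O_cl"] / frac["O_st"] == pytest.approx(s.K_st_cl, rel=1e-9)
        assert frac["O_op"] / frac["O_cl"] == pytest.approx(s.K_cl_op_O, rel=1e-9)
        assert frac["H_op"] / frac["H_cl"] == pytest.approx(s.K_cl_op_H, rel=1e-9)
        assert frac["H_cl"] * d / frac["O_op"] == pytest.approx(
            s.K_dis_OH, rel=1e-9
        )

    def test_total_dimer_conserved_by_solver(self):
        for c in (2e-11, 1e-10, 1e-9, 1e-8):
            frac, d = steady_state(TABLE_150MM, c)
            x_h = frac["H_cl"] + frac["H_op"]
            # free dimer balance: every hexasome released exactly one dimer
            assert abs(d - c * x_h) / (c * x_h) < 1e-8

    def test_no_rebinding_limit_is_concentration_independent(self):
        scheme = replace(TABLE_150MM, k_H_O=0.0)
        out = [apparent_exchange(scheme, c) for c in (1e-11, 1e-9, 1e-7)]
        k_f = [o[0] for o in out]
        assert np.ptp(k_f) < 1e-9 * max(k_f)

    def test_high_concentration_pushes_to_octasome_forward_rate(self):
        k_f, _, _ = apparent_exchange(TABLE_150MM, 1e-2)
        assert k_f == pytest.approx(TABLE_150MM.k_Ocl_Oop, rel=1e-3)

    def test_apparent_rate_and_efficiency_decrease_with_concentration(self):
        c_grid = np.geomspace(1e-12, 1e-8, 25)
        out = np.array([apparent_exchange(TABLE_150MM, c) for c in c_grid])
        assert np.all(np.diff(out[:, 0]) < 0)  # forward rate falls
        assert np.all(np.diff(out[:, 2]) < 0)  # <E>_dyn falls
        # relaxation time rises roughly threefold over 20 pM -> 2 nM
        t20 = 1.0 / sum(apparent_exchange(TABLE_150MM, 20e-12)[:2])
        t2n = 1.0 / sum(apparent_exchange(TABLE_150MM, 2e-9)[:2])
        assert t2n / t20 > 1.5


class TestConcentrationSeriesFit:
    def _observations(self, scheme, c_grid):
        obs = np.array([apparent_exchange(scheme, c) for c in c_grid])
        return obs[:, 0], obs[:, 1], obs[:, 2]

    def test_noise_free_series_recovered_exactly(self):
        c_grid = np.geomspace(2e-11, 2e-9, 6)
        k_f, k_b, e_dyn = self._observations(TABLE_150MM, c_grid)
        start = replace(TABLE_150MM, k_Ocl_Oop=10e3, k_Hcl_Hop=40e3,
                        k_Oop_Ocl=6e3, k_Hop_Hcl=20e3)
        res = fit_concentration_series(c_grid, k_f, k_b, e_dyn, start=start)
        assert res.scheme.k_Ocl_Oop == pytest.approx(13e3, rel=1e-3)
        assert res.scheme.k_Hcl_Hop == pytest.approx(54e3, rel=1e-3)
        assert res.scheme.k_Oop_Ocl == pytest.approx(8e3, rel=1e-3)
        assert res.scheme.k_Hop_Hcl == pytest.approx(17e3, rel=1e-3)

    def test_noisy_series_recovers_rates_within_fifteen_percent(self):
        rng = np.random.default_rng(17)
        c_grid = np.geomspace(2e-11, 2e-9, 6)
        k_f0, k_b0, e0 = self._observations(TABLE_150MM, c_grid)
        bias = {k: [] for k in ("k_Ocl_Oop", "k_Hcl_Hop", "k_Oop_Ocl", "k_Hop_Hcl")}
        for _ in range(15):
            k_f = k_f0 * (1 + rng.normal(0, 0.05, 6))
            k_b = k_b0 * (1 + rng.normal(0, 0.05, 6))
            e = e0 + rng.normal(0, 0.01, 6)
            try:
                res = fit_concentration_series(c_grid, k_f, k_b, e)
            except Exception:
                continue
            for k in bias:
                truth = getattr(TABLE_150MM, k)
                bias[k].append((getattr(res.scheme, k) - truth) / truth)
        for k, v in bias.items():
            assert len(v) >= 10
            assert abs(np.median(v)) < 0.15, k

    def test_unidentifiable_kdis_guard(self):
        scheme = replace(TABLE_150MM, k_H_O=0.0)
        c_grid = np.geomspace(2e-11, 2e-9, 6)
        k_f, k_b, e = self._observations(scheme, c_grid)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_concentration_series(c_grid, k_f, k_b, e, start=scheme)


class TestSaltSeries:
    def test_fraction_constraints_hold_identically(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x_lf, x_mf = rng.uniform(0, 0.5, 2)
            K = rng.uniform(0.1, 10)
            x_mfs, x_hf = constrained_fractions(x_lf, x_mf, K)
            assert x_mfs + x_hf == pytest.approx(1 - x_lf - x_mf, abs=1e-12)
            assert x_hf / x_mfs == pytest.approx(K, rel=1e-12)

    def test_synthetic_salt_series_recovers_midpoint(self):
        # generating truth: shared c_1/2 = 635 mM as printed for the rates
        rng = np.random.default_rng(11)
        c = np.linspace(150, 1000, 10)
        k_f_true = 8e3 + (33.4e3 - 8e3) / (1 + np.exp((c - 635.0) / 120.0))
        k_b_true = 13.2e3 + (30e3 - 13.2e3) / (1 + np.exp(-(c - 635.0) / 120.0))
        mids = []
        for _ in range(25):
            res = fit_salt_series(
                c,
                k_f_true * (1 + rng.normal(0, 0.04, c.size)),
                k_b_true * (1 + rng.normal(0, 0.04, c.size)),
            )
            mids.append(res.c_half)
        assert np.mean(mids) == pytest.approx(635.0, abs=20.0)

    def test_equilibrium_constant_consistent_with_fractions(self):
        c = np.linspace(150, 1000, 10)
        k_f = 8e3 + (33.4e3 - 8e3) / (1 + np.exp((c - 635.0) / 120.0))
        k_b = 13.2e3 + (30e3 - 13.2e3) / (1 + np.exp(-(c - 635.0) / 120.0))
        res = fit_salt_series(c, k_f, k_b)
        K = res.equilibrium_constant(400.0)
        x_mfs, x_hf = res.fractions(400.0, 0.1, 0.5)
        assert x_hf / x_mfs == pytest.approx(K, rel=1e-9)
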