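"""Steady-state extraction, I-V aggregation, reversal interpolation, Po."""

import numpy as np
import pytest
from scipy.optimize import brentq

import tevckit as tk
from tevckit.analysis import (
    AnalysisError,
    build_iv,
    estimate_reversal_potential,
    extract_steady_state,
    relative_open_probability,
    IVCurve,
    StepMeasurement,
)
from tevckit.simulate import channel_driving_current


def _const_trace(value, v=-100.0, n=200, oocyte="oo"):
    return tk.TraceSet(
        oocyte_id=oocyte,
        injection="cRNA",
        cnmp="8Br-cAMP",
        bath_label="b",
        time_s=np.arange(n) / 1000.0,
        step_voltages_mV=np.array([v]),
        currents_uA=np.full((1, n), value),
    )


class TestExtractSteadyState:
    def test_constant_sweep_returns_exact_value(self):
        m = extract_steady_state(_const_trace(-1.25), window_s=0.05)
        assert m[0].steady_state_uA == -1.25
        assert m[0].instantaneous_uA == -1.25

    def test_zero_window_rejected(self):
        with pytest.raises(AnalysisError):
            extract_steady_state(_const_trace(1.0), window_s=0.0)

    def test_window_exceeding_step_rejected(self):
        with pytest.raises(AnalysisError):
            extract_steady_state(_const_trace(1.0), window_s=5.0)

    def test_noiseless_relaxation_steady_state_within_one_percent(self, noiseless_cfg):
        """With the window in the final 10% of a 2 s step (> 3 tau in),
        the residual A exp(-t/tau) bias is below 1% of the asymptote."""
        tr = tk.simulate_recording(noiseless_cfg)
        meas = extract_steady_state(tr, window_s=0.2)
        for m in meas:
            v = m.command_mV
            p_inf = tk.boltzmann_open_probability(v, noiseless_cfg.gating, noiseless_cfg.env)
            i_inf = p_inf * channel_driving_current(noiseless_cfg, v) + (
                noiseless_cfg.leak_conductance_uS * (v - noiseless_cfg.leak_reversal_mV) * 1e-3
            )
            if abs(i_inf) > 0.05:
                assert m.steady_state_uA == pytest.approx(i_inf, rel=0.01)


class TestBuildIV:
    def test_hand_arithmetic_mean_and_sd(self):
        meas = [
            StepMeasurement(-100.0, -1.0, -1.0, "a"),
            StepMeasurement(-100.0, -3.0, -3.0, "b"),
        ]
        iv = build_iv(meas)
        assert iv.mean_uA[0] == pytest.approx(-2.0)
        assert iv.sd_uA[0] == pytest.approx(np.sqrt(2.0))
        assert iv.n[0] == 2

    def test_single_oocyte_sd_zero_n_one(self):
        iv = build_iv([StepMeasurement(-100.0, -1.0, -1.0, "a")])
        assert iv.sd_uA[0] == 0.0 and iv.n[0] == 1

    def test_duplicate_oocyte_voltage_rejected(self):
        meas = [
            StepMeasurement(-100.0, -1.0, -1.0, "a"),
            StepMeasurement(-100.0, -2.0, -2.0, "a"),
        ]
        with pytest.raises(AnalysisError, match="duplicate"):
            build_iv(meas)

    def test_mean_permutation_invariant(self):
        rng = np.random.default_rng(2)
        meas = [
            StepMeasurement(v, rng.normal(), 0.0, f"oo{k}")
            for v in (-100.0, -60.0, 0.0)
            for k in range(5)
        ]
        a = build_iv(meas)
        b = build_iv(meas[::-1])
        assert np.allclose(a.mean_uA, b.mean_uA)
        assert np.allclose(a.sd_uA, b.sd_uA)

    def test_cohort_n_propagates(self):
        cfg = tk.SimulationConfig(n_oocytes=13, amplitude_cv=0.2, seed=3)
        meas = []
        for tr in tk.generate_cohort(cfg):
            meas.extend(extract_steady_state(tr, 0.2))
        iv = build_iv(meas)
        assert np.all(iv.n == 13)


def _iv(v, i):
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    return IVCurve(v, i, np.zeros_like(i), np.ones(len(i), dtype=int))


class TestReversalEstimate:
    def test_two_point_midpoint(self):
        est = estimate_reversal_potential(_iv([-20.0, 0.0], [-1.0, 1.0]))
        assert est.e_rev_mV == pytest.approx(-10.0)

    def test_exact_zero_wins(self):
        est = estimate_reversal_potential(_iv([-30.0, -10.0, 10.0], [-1.0, 0.0, 1.0]))
        assert est.e_rev_mV == -10.0
        assert est.method == "exact-zero"

    def test_all_same_sign_raises(self):
        with pytest.raises(AnalysisError):
            estimate_reversal_potential(_iv([-20.0, 0.0], [1.0, 2.0]))

    def test_agrees_with_piecewise_linear_root_on_random_monotone_curves(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            v = np.sort(rng.uniform(-120, 40, size=rng.integers(4, 12)))
            i = np.sort(rng.uniform(-5, 5, size=len(v)))
            i = i[np.abs(i) > 1e-6]
            v = v[: len(i)]
            if len(v) < 2 or i[0] >= 0 or i[-1] <= 0:
                continue
            est = estimate_reversal_potential(_iv(v, i))
            # brute-force zero of the piecewise-linear interpolant
            k = np.flatnonzero(np.diff(np.sign(i)) > 0)[0]
            root = brentq(lambda x: np.interp(x, v, i), v[k], v[k + 1], xtol=1e-12)
            assert est.e_rev_mV == pytest.approx(root, abs=1e-9)

    def test_two_point_rule_close_to_analytic_reversal_on_ghk_iv(self, noiseless_cfg):
        cfg = noiseless_cfg
        e_true = tk.ghk_reversal_potential(cfg.permeabilities, cfg.external, cfg.internal, cfg.env)

        def steady(v):
            return tk.boltzmann_open_probability(v, cfg.gating, cfg.env) * channel_driving_current(
                cfg, float(v)
            )

        for grid, tol in ((np.arange(40.0, -121.0, -20.0), 2.0), (np.arange(40.0, -121.0, -1.0), 0.05)):
            iv = _iv(np.sort(grid), [steady(v) for v in np.sort(grid)])
            est = estimate_reversal_potential(iv)
            assert est.e_rev_mV == pytest.approx(e_true, abs=tol)


class TestRelativeOpenProbability:
    def test_ohmic_iv_gives_unit_po(self):
        v = np.array([-100.0, -60.0, -20.0, 20.0])
        i = 0.05 * (v - (-10.0))
        po = relative_open_probability(_iv(v, i), e_rev_mV=-10.0)
        assert all(p == pytest.approx(1.0) for _, p in po)

    def test_point_at_reversal_excluded(self):
        v = np.array([-30.0, -10.0, 10.0])
        i = np.array([-1.0, 0.0, 1.0])
        po = relative_open_probability(_iv(v, i), e_rev_mV=-10.0, exclusion_mV=5.0)
        assert [-10.0 not in dict(po)]
        assert set(dict(po)) == {-30.0, 10.0}

    def test_bounded_and_normalized(self):
        rng = np.random.default_rng(4)
        v = np.arange(-120.0, 41.0, 20.0)
        g = rng.uniform(0.01, 0.05, size=len(v))
        i = g * (v - (-10.0))
        po = relative_open_probability(_iv(v, i), e_rev_mV=-10.0)
        vals = [p for _, p in po]
        assert max(vals) == pytest.approx(1.0, abs=1e-15)
        assert all(0 < p <= 1.0 + 1e-12 for p in vals)

    def test_round_trip_recovers_gating_curve(self, noiseless_cfg):
        """Noiseless simulation -> chord-conductance Po matches the Boltzmann
        curve normalized to Pmax within 1e-3."""
        cfg = tk.SimulationConfig(
            noise_sd_uA=0.0, amplitude_cv=0.0, leak_conductance_uS=0.0, tau_s=0.05, seed=7
        )
        tr = tk.simulate_recording(cfg)
        iv = build_iv(extract_steady_state(tr, 0.02))
        e_rev = tk.ghk_reversal_potential(cfg.permeabilities, cfg.external, cfg.internal, cfg.env)
        po = relative_open_probability(iv, e_rev)
        # chord conductance of GHK flux is voltage dependent; compare against
        # the forward model's own chord-normalized prediction
        vs = np.array([p[0] for p in po])
        expected = tk.boltzmann_open_probability(vs, cfg.gating, cfg.env) * np.array(
            [channel_driving_current(cfg, float(v)) for v in vs]
        ) / (vs - e_rev)
        expected = expected / expected.max()
        got = np.array([p[1] for p in po])
        assert np.allclose(got, expected, atol=1e-3)

    def test_all_points_excluded_raises(self):
        with pytest.raises(AnalysisError):
            relative_open_probability(_iv([-12.0, -8.0], [-0.1, 0.1]), e_rev_mV=-10.0)
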