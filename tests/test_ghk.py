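"""Nernst/GHK equations and the permeability-ratio inverse problem."""

import numpy as np
import pytest

import tevckit as tk
from tevckit.ghk import (
    GHKCondition,
    GHKConditionSet,
    GHKError,
    IdentifiabilityError,
    solve_permeability_ratios,
)

INTERNAL = tk.DEFAULT_INTERNAL


class TestEnvironment:
    def test_thermal_voltage_at_recording_temperature(self, env):
        # RT/F with CODATA constants at 20 degC
        assert env.thermal_voltage_mV == pytest.approx(25.2617124583796, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(GHKError):
            tk.Environment(temperature=0.0)


class TestNernst:
    @pytest.mark.parametrize(
        "ion, c_in, c_out, expected",
        [
            ("K", 96.0, 96.0, 0.0),
            ("K", 9.6, 96.0, 58.1672425301669),  # (RT/F) ln 10 at 293.15 K
            ("Cl", 9.6, 96.0, -58.1672425301669),  # sign flip via z = -1
        ],
    )
    def test_closed_form(self, ion, c_in, c_out, expected, env):
        assert tk.nernst_potential(ion, c_in, c_out, env) == pytest.approx(expected, abs=1e-9)

    def test_zero_concentration_rejected(self, env):
        with pytest.raises(GHKError):
            tk.nernst_potential("K", 0.0, 96.0, env)

    def test_divalent_ion_rejected(self):
        with pytest.raises(GHKError):
            tk.IonSpecies("Ca", +2)


class TestGHKReversal:
    def test_equal_single_ion_gives_zero(self, env):
        perms = tk.PermeabilitySet({"K": 1.0})
        c = tk.Composition({"K": 96.0})
        assert tk.ghk_reversal_potential(perms, c, c, env) == pytest.approx(0.0, abs=1e-12)

    def test_single_ion_reduces_to_nernst_over_random_pairs(self, env):
        rng = np.random.default_rng(11)
        for ion in ("K", "Cl"):
            perms = tk.PermeabilitySet({ion: 1.0}, reference=ion)
            for _ in range(500):
                c_in, c_out = rng.uniform(0.5, 200.0, size=2)
                ghk = tk.ghk_reversal_potential(
                    perms, tk.Composition({ion: c_out}), tk.Composition({ion: c_in}), env
                )
                nernst = tk.nernst_potential(ion, c_in, c_out, env)
                assert ghk == pytest.approx(nernst, abs=1e-9)

    def test_mixed_bath_closed_form(self, reference_perms, env):
        ext = tk.Composition({"K": 48.0, "Na": 48.0, "Cl": 96.0})
        # frozen from a 30-digit evaluation of the GHK voltage formula
        assert tk.ghk_reversal_potential(reference_perms, ext, INTERNAL, env) == pytest.approx(
            -10.3138504554360, abs=1e-9
        )

    def test_ratio_only_identifiability(self, env):
        """Scaling all permeabilities by a common factor leaves E_rev unchanged."""
        ext = tk.Composition({"K": 48.0, "Na": 48.0, "Cl": 96.0})
        base = {"Na": 0.63, "Cl": 0.03}
        e1 = tk.ghk_reversal_potential(
            tk.PermeabilitySet({"K": 1.0, **base}), ext, INTERNAL, env
        )
        scaled = tk.PermeabilitySet(
            {"Na": 0.63 / 0.03, "Cl": 1.0, "K": 1.0 / 0.03}, reference="Cl"
        )
        e2 = tk.ghk_reversal_potential(scaled, ext, INTERNAL, env)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_all_zero_permeability_undefined(self, env):
        with pytest.raises(GHKError):
            tk.ghk_reversal_potential(
                tk.PermeabilitySet({"K": 1.0, "Na": 0.0}),
                tk.Composition({"Na": 96.0}),
                tk.Composition({"Na": 10.0}),
                env,
            )


class TestGHKCurrent:
    def test_zero_at_equal_concentrations_and_zero_voltage(self, env):
        assert tk.ghk_current_density(1e-6, "K", 0.0, 96.0, 96.0, env) == 0.0

    def test_zero_flux_at_nernst_potential(self, env):
        rng = np.random.default_rng(5)
        for _ in range(200):
            c_in, c_out = rng.uniform(1.0, 200.0, size=2)
            for ion in ("K", "Cl"):
                e = tk.nernst_potential(ion, c_in, c_out, env)
                i = tk.ghk_current_density(1e-6, ion, e, c_in, c_out, env)
                scale = abs(tk.ghk_current_density(1e-6, ion, e + 10.0, c_in, c_out, env))
                assert abs(i) <= 1e-10 * max(scale, 1e-30)

    def test_v0_limit_matches_series_expansion(self, env):
        # exact limit P z F (c_in - c_out) checked against evaluation at +/-1e-6 mV
        i0 = tk.ghk_current_density(1e-6, "K", 0.0, 110.0, 48.0, env)
        expected = 1e-6 * 1e-2 * env.faraday * (110.0 - 48.0) * 100.0
        assert i0 == pytest.approx(expected, rel=1e-9)
        for v in (1e-6, -1e-6):
            assert tk.ghk_current_density(1e-6, "K", v, 110.0, 48.0, env) == pytest.approx(
                i0, rel=1e-6
            )

    def test_inward_current_negative_sign_convention(self, env):
        # cation influx (out >> in, hyperpolarized) must be a negative current
        assert tk.ghk_current_density(1e-6, "Na", -100.0, 10.0, 96.0, env) < 0

    def test_total_current_zero_at_multiion_reversal(self, reference_perms, env):
        ext = tk.Composition({"K": 48.0, "Na": 48.0, "Cl": 96.0})
        e_rev = tk.ghk_reversal_potential(reference_perms, ext, INTERNAL, env)
        i = tk.total_ghk_current(reference_perms, e_rev, ext, INTERNAL, env)
        scale = abs(tk.total_ghk_current(reference_perms, -100.0, ext, INTERNAL, env))
        assert abs(i) < 1e-9 * scale


class TestSolver:
    def _conditions(self, perms, bath_names, baths):
        conds = [
            GHKCondition(
                external=baths[b],
                e_rev_mV=tk.ghk_reversal_potential(perms, baths[b], INTERNAL),
            )
            for b in bath_names
        ]
        return GHKConditionSet(conds, internal=INTERNAL)

    def test_four_bath_round_trip_recovers_published_ratios(self, reference_perms, baths):
        cs = self._conditions(reference_perms, ("NaK_1_1", "NaK_1_4", "gluconate", "NMDG"), baths)
        sol = solve_permeability_ratios(cs, free_ions=("Na", "Cl"))
        assert sol.perms.get("Na") == pytest.approx(0.63, abs=1e-6)
        assert sol.perms.get("Cl") == pytest.approx(0.03, abs=1e-6)
        assert np.all(np.abs(sol.residuals_mV) < 1e-8)

    def test_solution_invariant_to_condition_order(self, reference_perms, baths):
        names = ("NaK_1_1", "NaK_1_4", "gluconate", "NMDG")
        a = solve_permeability_ratios(
            self._conditions(reference_perms, names, baths), free_ions=("Na", "Cl")
        )
        b = solve_permeability_ratios(
            self._conditions(reference_perms, names[::-1], baths), free_ions=("Na", "Cl")
        )
        assert a.perms.get("Na") == pytest.approx(b.perms.get("Na"), abs=1e-9)
        assert a.perms.get("Cl") == pytest.approx(b.perms.get("Cl"), abs=1e-9)

    def test_truly_impermeant_ion_recovered_as_zero(self, baths):
        truth = tk.PermeabilitySet({"K": 1.0, "Na": 0.63, "Cl": 0.0})
        cs = self._conditions(truth, ("NaK_1_1", "gluconate", "NaK_1_4"), baths)
        sol = solve_permeability_ratios(cs, free_ions=("Na", "Cl"))
        assert sol.perms.get("Cl") < 1e-8

    def test_underdetermined_system_raises(self, reference_perms, baths):
        cs = self._conditions(reference_perms, ("NaK_1_1",), baths)
        with pytest.raises(IdentifiabilityError):
            solve_permeability_ratios(cs, free_ions=("Na", "Cl"))

    def test_weighted_fit_uses_sd_and_n(self, reference_perms, baths):
        # perturb one condition; down-weighting it (large SD) must pull the
        # solution back toward the clean-data optimum
        names = ("NaK_1_1", "NaK_1_4", "gluconate", "NMDG")
        clean = [tk.ghk_reversal_potential(reference_perms, baths[b], INTERNAL) for b in names]
        conds_eq = [
            GHKCondition(baths[b], e + (5.0 if i == 0 else 0.0), sd_mV=1.0, n=5)
            for i, (b, e) in enumerate(zip(names, clean))
        ]
        conds_dn = [
            GHKCondition(baths[b], e + (5.0 if i == 0 else 0.0), sd_mV=(50.0 if i == 0 else 1.0), n=5)
            for i, (b, e) in enumerate(zip(names, clean))
        ]
        sol_eq = solve_permeability_ratios(
            GHKConditionSet(conds_eq, INTERNAL), free_ions=("Na", "Cl")
        )
        sol_dn = solve_permeability_ratios(
            GHKConditionSet(conds_dn, INTERNAL), free_ions=("Na", "Cl")
        )
        assert abs(sol_dn.perms.get("Na") - 0.63) < abs(sol_eq.perms.get("Na") - 0.63)
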