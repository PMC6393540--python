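"""Unit and property tests for the cooperative tri-molecular binding model."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopfold import itc_binding as itc


def grid_scan_complex(ka: float, a_tot: float, d_tot: float, n: int = 10_000_000) -> float:
    """Independent oracle: locate the mass-balance root by dense grid scan.

    Evaluates f(C) = K (A-2C)^2 (D-C) - C on an n-point grid of the feasible
    interval and takes the sign change, refined once by local bisection on
    the bracketing cell.
    """
    c_max = min(a_tot / 2.0, d_tot)
    if ka == 0 or c_max == 0:
        return 0.0
    lo_val = ka * a_tot**2 * d_tot
    lo, hi = 0.0, c_max
    # two-stage scan keeps memory bounded at ~8 MB per chunk
    for stage_points in (int(math.sqrt(n)), int(math.sqrt(n))):
        grid = np.linspace(lo, hi, stage_points)
        f = ka * (a_tot - 2 * grid) ** 2 * (d_tot - grid) - grid
        k = int(np.argmax(f < 0))
        lo, hi = grid[max(k - 1, 0)], grid[k]
    return 0.5 * (lo + hi)


class TestSolveTrimolecular:
    def test_zero_ka_means_no_binding(self):
        s = itc.solve_trimolecular_equilibrium(0.0, 1e-5, 5e-6)
        assert s.complex == 0.0
        assert s.free_dimer == 1e-5

    def test_zero_duplex(self):
        s = itc.solve_trimolecular_equilibrium(1e12, 1e-5, 0.0)
        assert s.complex == 0.0
        assert s.free_dimer == 1e-5

    def test_saturating_limit(self):
        s = itc.solve_trimolecular_equilibrium(1e20, 10e-6, 5e-6)
        assert s.complex == pytest.approx(5e-6, rel=1e-3)
        assert s.free_duplex < 1e-3 * 5e-6

    def test_matches_grid_scan_oracle(self):
        ka, a_tot, d_tot = 1e12, 20e-6, 5e-6
        n = 10_000_000
        expected = grid_scan_complex(ka, a_tot, d_tot, n=n)
        s = itc.solve_trimolecular_equilibrium(ka, a_tot, d_tot)
        # oracle is exact to one grid cell of the feasible interval
        assert s.complex == pytest.approx(expected, abs=d_tot / n)

    def test_residual_tolerance(self):
        ka, a_tot, d_tot = 3e13, 2e-5, 9e-6
        s = itc.solve_trimolecular_equilibrium(ka, a_tot, d_tot)
        resid = ka * s.free_dimer**2 * s.free_duplex - s.complex
        assert abs(resid) < 1e-10 * max(1.0, d_tot)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            itc.solve_trimolecular_equilibrium(-1.0, 1e-6, 1e-6)
        with pytest.raises(ValueError):
            itc.solve_trimolecular_equilibrium(1e12, -1e-6, 1e-6)
        with pytest.raises(ValueError):
            itc.solve_trimolecular_equilibrium(float("nan"), 1e-6, 1e-6)

    @given(
        log_ka=st.floats(6, 18),
        a_um=st.floats(0.01, 100),
        d_um=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_balance_property(self, log_ka, a_um, d_um):
        a_tot, d_tot = a_um * 1e-6, d_um * 1e-6
        s = itc.solve_trimolecular_equilibrium(10**log_ka, a_tot, d_tot)
        assert s.free_dimer + 2 * s.complex == pytest.approx(a_tot, rel=1e-10)
        assert s.free_duplex + s.complex == pytest.approx(d_tot, rel=1e-10)
        assert s.free_dimer >= 0 and s.free_duplex >= 0 and s.complex >= 0

    def test_bound_fraction_monotone_in_ka(self):
        fractions = [
            itc.solve_trimolecular_equilibrium(ka, 1e-5, 5e-6).bound_duplex_fraction()
            for ka in np.logspace(8, 18, 21)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestSpeciationCurve:
    def test_zero_ratio_means_no_complex(self):
        states = itc.speciation_curve(1e13, 5e-6, [0.0, 1.0])
        assert states[0].complex == 0.0

    def test_stoichiometric_saturation_at_ratio_two(self):
        ratios = np.arange(0.0, 4.0 + 1e-9, 0.1)
        states = itc.speciation_curve(1e20, 5e-6, ratios)
        bound = np.array([s.bound_duplex_fraction() for s in states])
        first = ratios[np.argmax(bound >= 0.99)]
        assert first == pytest.approx(2.0)

    def test_near_saturation_at_stoichiometry_finite_ka(self):
        # direct solve: at a realistic finite constant, ratio 2.0 is close
        # to but not at complete saturation
        state = itc.speciation_curve(3e13, 5e-6, [2.0])[0]
        frac = state.bound_duplex_fraction()
        assert 0.90 < frac < 0.99

    def test_bound_fraction_monotone_in_ratio(self):
        ratios = np.linspace(0, 4, 41)
        states = itc.speciation_curve(5e12, 5e-6, ratios)
        bound = [s.bound_duplex_fraction() for s in states]
        assert all(b >= a - 1e-12 for a, b in zip(bound, bound[1:]))


def sequential_grid_oracle(k1, k2, a_tot, d_tot, n=4000):
    """2-D refinement oracle for the stepwise model (free dimer grid scan)."""
    lo, hi = 0.0, a_tot
    for _ in range(3):
        grid = np.linspace(lo, hi, n)
        d = d_tot / (1 + k1 * grid + k1 * k2 * grid**2)
        g = grid + (k1 * grid + 2 * k1 * k2 * grid**2) * d - a_tot
        k = int(np.argmax(g > 0))
        lo, hi = grid[max(k - 1, 0)], grid[k]
    a = 0.5 * (lo + hi)
    d = d_tot / (1 + k1 * a + k1 * k2 * a**2)
    return {
        "free_duplex": d / d_tot,
        "intermediate": k1 * a * d / d_tot,
        "saturated": k1 * k2 * a**2 * d / d_tot,
    }


class TestSequentialModel:
    def test_k2_zero_reduces_to_one_site(self):
        out = itc.sequential_two_site_speciation(1e6, 0.0, 1e-5, 5e-6)
        assert out["saturated"] == 0.0
        assert out["intermediate"] > 0.0

    def test_matches_2d_grid_oracle(self):
        k = math.sqrt(3e13)
        ours = itc.sequential_two_site_speciation(k, k, 10e-6, 5e-6)
        oracle = sequential_grid_oracle(k, k, 10e-6, 5e-6)
        for key in ("free_duplex", "intermediate", "saturated"):
            assert ours[key] == pytest.approx(oracle[key], abs=1e-6)

    def test_cooperative_limit_suppresses_intermediate(self):
        ka_macro = 3e13
        fracs = []
        for ratio in (1.0, 1e3, 1e6):
            k1 = math.sqrt(ka_macro / ratio)
            k2 = ratio * k1
            fracs.append(itc.max_intermediate_fraction(k1, k2, 5e-6))
        assert fracs[0] > fracs[1] > fracs[2]
        assert fracs[2] < 1e-3

    def test_converges_to_trimolecular_speciation(self):
        ka_macro = 3e13
        k1 = math.sqrt(ka_macro / 1e6)
        k2 = ka_macro / k1
        for r in (0.5, 1.0, 2.0, 3.0):
            a_tot, d_tot = r * 5e-6, 5e-6
            seq = itc.sequential_two_site_speciation(k1, k2, a_tot, d_tot)
            tri = itc.solve_trimolecular_equilibrium(ka_macro, a_tot, d_tot)
            assert abs(seq["saturated"] - tri.bound_duplex_fraction()) < 1e-3
            assert seq["intermediate"] < 1e-3

    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            itc.sequential_two_site_speciation(-1.0, 1.0, 1e-6, 1e-6)


class TestSimulateIsotherm:
    def test_no_binding_gives_offset_only(self):
        proto = itc.TitrationProtocol(cell_conc=2e-5, syringe_conc=9e-5,
                                      injection_volumes_ul=(2.0,) * 10)
        params = itc.BindingParameters(ka=0.0, dh=-19.0, offset=0.37)
        exp = itc.simulate_isotherm(params, proto, noise_sd=0.0)
        assert np.allclose(exp.ndh, 0.37)

    def test_heat_conservation_without_dilution(self):
        proto = itc.TitrationProtocol(cell_conc=2e-5, syringe_conc=9e-5,
                                      injection_volumes_ul=(2.0,) * 20)
        params = itc.BindingParameters(ka=1e20, dh=-19.0, offset=0.0)
        exp = itc.simulate_isotherm(params, proto, noise_sd=0.0, dilution="none")
        v0_l = proto.cell_volume_ul * 1e-6
        raw = [
            h * dv * 1e-6 * proto.syringe_conc
            for h, dv in zip(exp.ndh, proto.injection_volumes_ul)
        ]
        d_final = sum(proto.injection_volumes_ul) * 1e-6 * proto.syringe_conc / v0_l
        c_final = itc.solve_trimolecular_equilibrium(
            params.ka, proto.cell_conc, d_final
        ).complex
        assert sum(raw) == pytest.approx(v0_l * params.dh * c_final, rel=1e-9)

    def test_inflection_at_half_molar_ratio(self, wild_type_protocol):
        # 2:1 dimer:duplex stoichiometry puts the equivalence point of a
        # duplex-into-dimer titration at injectant:cell ratio 0.5
        params = itc.BindingParameters(ka=3e13, dh=-19.0, offset=0.0)
        exp = itc.simulate_isotherm(params, wild_type_protocol, noise_sd=0.0)
        ratio = exp.molar_ratio
        ndh = np.asarray(exp.ndh)
        slope = np.gradient(ndh, ratio)
        inflection = ratio[np.argmax(slope)]
        assert inflection == pytest.approx(0.5, abs=0.1)

    def test_molar_ratio_strictly_increasing(self, wild_type_protocol):
        params = itc.BindingParameters(ka=3e13, dh=-19.0)
        exp = itc.simulate_isotherm(params, wild_type_protocol, noise_sd=0.0)
        assert np.all(np.diff(exp.molar_ratio) > 0)

    def test_seed_reproducibility(self, wild_type_protocol):
        params = itc.BindingParameters(ka=3e13, dh=-19.0)
        a = itc.simulate_isotherm(params, wild_type_protocol, 0.2, seed=7)
        b = itc.simulate_isotherm(params, wild_type_protocol, 0.2, seed=7)
        c = itc.simulate_isotherm(params, wild_type_protocol, 0.2, seed=8)
        assert a.ndh == b.ndh
        assert a.ndh != c.ndh


class TestFitIsotherm:
    def test_noiseless_self_consistency(self):
        proto = itc.TitrationProtocol(cell_conc=2e-5, syringe_conc=9e-5,
                                      injection_volumes_ul=(2.0,) * 25)
        truth = itc.BindingParameters(ka=1e12, dh=-15.0, offset=0.0)
        exp = itc.simulate_isotherm(truth, proto, noise_sd=0.0)
        fit = itc.fit_isotherm(exp)
        assert fit.converged
        assert fit.params.ka == pytest.approx(1e12, rel=1e-6)
        assert fit.params.dh == pytest.approx(-15.0, rel=1e-6)
        assert abs(fit.params.offset) < 1e-6

    def test_grid_search_brackets_same_minimum(self, wild_type_protocol):
        truth = itc.BindingParameters(ka=3e13, dh=-19.0, offset=0.0)
        exp = itc.simulate_isotherm(truth, wild_type_protocol, 0.05, seed=2)
        fit = itc.fit_isotherm(exp)

        obs = np.asarray(exp.ndh)

        def sse(log_ka, dh):
            params = itc.BindingParameters(ka=10**log_ka, dh=dh,
                                           offset=fit.params.offset)
            model = itc.model_ndh(params, wild_type_protocol)
            return float(np.sum((model - obs) ** 2))

        log_grid = np.linspace(fit.log10_ka - 1.0, fit.log10_ka + 1.0, 41)
        dh_grid = np.linspace(fit.params.dh - 3.0, fit.params.dh + 3.0, 41)
        values = np.array([[sse(lk, dh) for dh in dh_grid] for lk in log_grid])
        i, j = np.unravel_index(np.argmin(values), values.shape)
        # optimizer minimum must sit inside the grid's bracketing cell
        assert abs(log_grid[i] - fit.log10_ka) <= (log_grid[1] - log_grid[0])
        assert abs(dh_grid[j] - fit.params.dh) <= (dh_grid[1] - dh_grid[0])

    def test_recovery_median_over_seeds(self, wild_type_protocol):
        truth = itc.BindingParameters(ka=3.0e13, dh=-19.0, offset=0.0)
        clean = itc.simulate_isotherm(truth, wild_type_protocol, 0.0)
        noise = 0.01 * max(abs(h) for h in clean.ndh)
        log_kas = []
        for seed in range(10):
            exp = itc.simulate_isotherm(truth, wild_type_protocol, noise, seed)
            log_kas.append(itc.fit_isotherm(exp).log10_ka)
        assert abs(np.median(log_kas) - math.log10(3.0e13)) <= 0.3

    def test_dg_reporting(self):
        proto = itc.TitrationProtocol(cell_conc=2e-5, syringe_conc=9e-5,
                                      injection_volumes_ul=(2.0,) * 20)
        truth = itc.BindingParameters(ka=1e12, dh=-10.0)
        fit = itc.fit_isotherm(itc.simulate_isotherm(truth, proto, 0.0))
        expected = -itc.GAS_CONSTANT_KCAL * itc.STANDARD_TEMPERATURE_K * math.log(
            fit.params.ka
        )
        assert fit.dg == pytest.approx(expected, rel=1e-12)

    def test_flat_isotherm_flags_lower_bound(self):
        # saturating K: every injection sees complete binding, so the data
        # carry no information about K beyond a lower bound
        proto = itc.TitrationProtocol(cell_conc=2e-5, syringe_conc=9e-5,
                                      injection_volumes_ul=(2.0,) * 15)
        truth = itc.BindingParameters(ka=1e24, dh=-12.0)
        exp = itc.simulate_isotherm(truth, proto, noise_sd=0.05, seed=1)
        fit = itc.fit_isotherm(exp)
        assert fit.ka_lower_bound

    def test_too_few_injections_rejected(self):
        proto = itc.TitrationProtocol(cell_conc=2e-5, syringe_conc=9e-5,
                                      injection_volumes_ul=(2.0,) * 4)
        exp = itc.simulate_isotherm(itc.BindingParameters(1e12, -10.0), proto, 0.0)
        with pytest.raises(ValueError):
            itc.fit_isotherm(exp)


class TestTypes:
    def test_binding_parameters_validation(self):
        with pytest.raises(ValueError):
            itc.BindingParameters(ka=-1.0, dh=-10.0)
        with pytest.raises(ValueError):
            itc.BindingParameters(ka=1e12, dh=float("nan"))

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            itc.TitrationProtocol(cell_volume_ul=0.0)
        with pytest.raises(ValueError):
            itc.TitrationProtocol(injection_volumes_ul=())

    def test_experiment_length_check(self):
        proto = itc.TitrationProtocol(injection_volumes_ul=(2.0,) * 3)
        with pytest.raises(ValueError):
            itc.TitrationExperiment(protocol=proto, ndh=(1.0, 2.0))
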