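"""Multi-exponential recovery fitting, model order, sweeps and exposure series."""

import numpy as np
import pytest

from clcgating import (
    ChannelSpec,
    IonCondition,
    StateScheme,
    build_generator,
    component_fractions,
    condition_sweep,
    exposure_series_fit,
    fit_recovery,
    normalize_to_preacid,
    preset_scheme,
    relaxation_spectrum,
    select_model_order,
    simulate_macroscopic,
)
from clcgating.recovery_analysis import ExpFitResult

from conftest import mono_exp_trace, multi_exp_trace, recovery_protocol


def make_fit(amps, taus, c=1.0):
    comps = sorted(zip(amps, taus), key=lambda p: p[1])
    return ExpFitResult(
        n=len(amps), components=comps, c=c, rss=0.0, dof=10, aic=0.0,
        recovery_start=0.0, span=10.0 * max(taus), n_points=100,
    )


class TestFitRecovery:
    def test_noiseless_mono_exponential_exact(self):
        # 1 - exp(-t/2000): the slow recovery scale at -40 mV
        trace = mono_exp_trace(tau=2000.0, noise_sd=0.0, seed=0, span=12000.0)
        fit = fit_recovery(trace, recovery_start=0.0, n=1)
        a, tau = fit.components[0]
        assert tau == pytest.approx(2000.0, rel=1e-3)
        assert fit.c == pytest.approx(1.0, abs=1e-3)
        assert a == pytest.approx(-1.0, abs=1e-3)

    def test_curve_at_start_equals_offset_plus_amplitudes(self):
        trace = mono_exp_trace(tau=100.0, noise_sd=0.01, seed=1, span=800.0)
        fit = fit_recovery(trace, recovery_start=0.0, n=1)
        assert fit.evaluate(np.array([0.0]))[0] == pytest.approx(
            fit.c + fit.amplitudes.sum()
        )

    def test_deterministic_model2_taus_match_eigen_oracle(self, c212s_scheme):
        spec = ChannelSpec(slow_scheme=c212s_scheme, single_pore_amplitude=-0.6, noise_sd=0.0)
        proto = recovery_protocol(v_m=40.0, rec_ms=9000.0)
        trace = simulate_macroscopic(spec, proto, 400, mode="deterministic", seed=0)
        norm = normalize_to_preacid(trace, 300.0, 200.0)
        fit = fit_recovery(norm, recovery_start=800.0, n=3)
        gen = build_generator(c212s_scheme, "pH7.4")
        eigen_taus = np.sort(
            relaxation_spectrum(
                gen, np.array([0.0, 0.4, 0.4, 0.2]), c212s_scheme.conducting_vector()
            ).taus
        )
        assert np.allclose(np.sort(fit.taus), eigen_taus, rtol=0.005)

    def test_biexponential_recovery_with_noise(self):
        # tau 10 and 100 ms, equal fractions, noise SD 0.02
        trace = multi_exp_trace(
            amps=[-0.5, -0.5], taus=[10.0, 100.0], noise_sd=0.02, seed=3, span=800.0,
            dt=0.5,
        )
        fit = fit_recovery(trace, recovery_start=0.0, n=2)
        assert fit.taus[0] == pytest.approx(10.0, rel=0.10)
        assert fit.taus[1] == pytest.approx(100.0, rel=0.10)
        assert np.allclose(fit.fractions, [0.5, 0.5], atol=0.05)

    def test_collinear_components_warn(self):
        # noiseless truth with tau ratio 1.4 (< 1.5): the fit lands on nearly
        # collinear components and must say so
        trace = multi_exp_trace(
            amps=[-0.5, -0.5], taus=[50.0, 70.0], noise_sd=0.0, seed=4,
            span=600.0, dt=0.2,
        )
        with pytest.warns(UserWarning, match="collinear"):
            fit_recovery(trace, recovery_start=0.0, n=2)

    def test_invalid_order_rejected(self):
        trace = mono_exp_trace(tau=50.0, noise_sd=0.0, seed=0, span=400.0)
        with pytest.raises(ValueError):
            fit_recovery(trace, recovery_start=0.0, n=4)


class TestComponentFractions:
    def test_simple_ratios(self):
        assert np.allclose(component_fractions(make_fit([3.0, 1.0], [10.0, 100.0])), [0.75, 0.25])

    def test_single_component_is_unity(self):
        assert np.allclose(component_fractions(make_fit([-0.8], [50.0])), [1.0])

    def test_three_component_identity(self):
        f = component_fractions(make_fit([0.2, 0.3, 0.5], [1.0, 10.0, 100.0]))
        assert np.allclose(f, [0.2, 0.3, 0.5])

    def test_fractions_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            amps = -rng.uniform(0.1, 2.0, 3)
            f = component_fractions(make_fit(amps, [1.0, 10.0, 100.0]))
            assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_sum_raises(self):
        with pytest.raises(ValueError):
            component_fractions(make_fit([1.0, -1.0], [10.0, 100.0]))

    def test_mixed_signs_warn(self):
        with pytest.warns(UserWarning, match="mixed-sign"):
            component_fractions(make_fit([1.0, -0.5], [10.0, 100.0]))


class TestModelOrder:
    def test_noiseless_mono_selects_one(self):
        trace = mono_exp_trace(tau=100.0, noise_sd=0.005, seed=5, span=800.0)
        sel = select_model_order(trace, 0.0)
        assert sel.best_n == 1

    def test_triexponential_selects_three(self):
        trace = multi_exp_trace(
            amps=[-0.3, -0.35, -0.35], taus=[10.0, 100.0, 1000.0],
            noise_sd=0.02, seed=6, span=7000.0,
        )
        sel = select_model_order(trace, 0.0)
        assert sel.best_n == 3

    def test_underfit_leaves_residual_structure_and_coverage_short(self):
        trace = multi_exp_trace(
            amps=[-0.3, -0.35, -0.35], taus=[10.0, 100.0, 1000.0],
            noise_sd=0.01, seed=7, span=7000.0,
        )
        sel = select_model_order(trace, 0.0)
        assert sel.residual_structure_flags[1]
        # mono fit cannot cover the observed rise
        assert sel.amplitude_coverage[1] < sel.amplitude_coverage[3] + 0.05

    def test_ftest_criterion_agrees_on_clear_cases(self):
        trace = multi_exp_trace(
            amps=[-0.5, -0.5], taus=[10.0, 200.0], noise_sd=0.01, seed=8, span=1500.0,
        )
        assert select_model_order(trace, 0.0, criterion="Ftest").best_n >= 2


def cl_sweep_items(seed=0):
    """Recovery traces at several symmetric [Cl-]; higher Cl- opens faster."""
    items = []
    for i, (cl, k_open) in enumerate([(40.0, 0.0004), (90.0, 0.001), (140.0, 0.002), (190.0, 0.004)]):
        lbl, lbl_acid = f"cl{int(cl)}", f"cl{int(cl)}-acid"
        scheme = StateScheme(
            states=[("O", True), ("I", False)],
            edges=[("O", "I", "kc"), ("I", "O", "ko")],
            rate_table={
                lbl: {"kc": 0.0, "ko": k_open},
                lbl_acid: {"kc": 0.05, "ko": 0.0},
            },
        )
        anions = {"Cl": cl}
        cond_neutral = IonCondition(v_m=-40.0, anion_in=anions, anion_out=anions, label=lbl)
        cond_acid = IonCondition(
            v_m=-40.0, ph_i=5.0, anion_in=anions, anion_out=anions, label=lbl_acid
        )
        from clcgating import Protocol

        proto = Protocol(
            segments=[(300.0, cond_neutral), (300.0, cond_acid), (12000.0, cond_neutral)],
            sampling_interval=2.0,
        )
        spec = ChannelSpec(slow_scheme=scheme, single_pore_amplitude=-0.6, noise_sd=0.5)
        trace = simulate_macroscopic(spec, proto, 300, mode="deterministic", seed=seed + i)
        items.append((cond_neutral, normalize_to_preacid(trace, 300.0, 200.0)))
    return items


class TestConditionSweep:
    def test_tau_rec_decreases_with_chloride(self):
        items = cl_sweep_items()
        result = condition_sweep(items, recovery_start=600.0, n_policy=1)
        taus = result.table.sort_values("cl_in_mM")["tau_ms"].to_numpy()
        assert np.all(np.diff(taus) < 0)

    def test_identical_conditions_give_consistent_summaries(self):
        items = cl_sweep_items()
        twice = [items[2], items[2]]
        result = condition_sweep(twice, recovery_start=600.0, n_policy=1)
        assert result.summary["n_replicates"].iloc[0] == 2
        assert result.summary["tau_ms_sem"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_component_labels_never_swap_order(self, c212s_scheme):
        spec = ChannelSpec(slow_scheme=c212s_scheme, single_pore_amplitude=-0.6, noise_sd=1.0)
        items = []
        for i, v in enumerate([-40.0, 40.0]):
            proto = recovery_protocol(v_m=v, rec_ms=8000.0)
            trace = simulate_macroscopic(spec, proto, 400, mode="deterministic", seed=30 + i)
            cond = IonCondition(v_m=v)
            items.append((cond, normalize_to_preacid(trace, 300.0, 200.0)))
        result = condition_sweep(items, recovery_start=800.0, n_policy=3)
        for _, grp in result.table.groupby(["v_m_mv", "replicate"]):
            ordered = grp.sort_values("tau_ms")["component"].tolist()
            assert ordered == sorted(ordered)

    def test_needs_at_least_two_entries(self):
        with pytest.raises(ValueError):
            condition_sweep(cl_sweep_items()[:1], recovery_start=600.0)


class TestExposureSeries:
    @staticmethod
    def synthetic_series(decay_tau=370.0, plateau=0.05, f0=0.9, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        results = []
        for T in [50.0, 150.0, 250.0, 400.0, 600.0, 800.0, 1000.0, 1250.0]:
            f_fast = plateau + (f0 - plateau) * np.exp(-T / decay_tau)
            if noise > 0:
                f_fast += rng.normal(0.0, noise)
            f_slow = 1.0 - f_fast
            fit = make_fit([-f_fast, -f_slow], [10.0, 500.0])
            results.append((T, fit))
        return results

    def test_noiseless_curve_recovered_exactly(self):
        series = exposure_series_fit(self.synthetic_series())
        assert series.time_dependent
        assert series.decay_tau == pytest.approx(370.0, rel=1e-3)
        assert series.plateau == pytest.approx(0.05, abs=1e-3)

    def test_constant_fractions_select_constant_model(self):
        results = []
        for T in [50.0, 250.0, 600.0, 1250.0]:
            fit = make_fit([-0.4, -0.6], [10.0, 500.0])
            results.append((T, fit))
        series = exposure_series_fit(results)
        assert not series.time_dependent
        assert series.decay_tau is None

    def test_requires_four_exposures(self):
        with pytest.raises(ValueError):
            exposure_series_fit(self.synthetic_series()[:3])

    def test_unmatched_fast_component_raises(self):
        results = self.synthetic_series()
        # replace one fit with components far from the 10-ms reference
        results[3] = (results[3][0], make_fit([-0.5, -0.5], [200.0, 2000.0]))
        with pytest.raises(ValueError, match="no component matching"):
            exposure_series_fit(results)
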