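"""Synaptopathy mechanisms: identity contracts, dynamics and phenotypes."""

import math

import numpy as np
import pytest

import synapsim.metrics as mt
from synapsim import (
    ScenarioSpec,
    ScenarioState,
    apply_dcycloserine,
    apply_fxs,
    apply_shank_ng,
    apply_tsc,
    distortion_score,
)

ALL_MECHANISMS = ["fxs", "tsc_nam", "tsc_pam", "dcycloserine", "shank_ng", "chr15"]


class TestIdentityContracts:
    @pytest.mark.parametrize("mechanism", ALL_MECHANISMS)
    def test_neutral_scenario_is_bitwise_identity(self, mechanism, short_config,
                                                  baseline_run):
        """Every mechanism with neutral parameters and zero noise is a no-op."""
        spec = ScenarioSpec(mechanism=mechanism).neutral()
        assert spec.is_identity
        run = short_config.replace(scenario=spec).run()
        healthy = short_config.run()
        for key in run.series:
            assert np.array_equal(run.series[key], healthy.series[key]), key

    @pytest.mark.parametrize("mechanism", ALL_MECHANISMS)
    def test_seeded_noise_reproducible(self, mechanism, short_config):
        spec = ScenarioSpec(mechanism=mechanism, noise_sigma=0.5, noise_seed=13)
        a = short_config.replace(scenario=spec).run()
        b = short_config.replace(scenario=spec).run()
        for key in a.series:
            assert np.array_equal(a.series[key], b.series[key]), key


class TestFxs:
    def test_zero_rate_is_identity(self):
        spec = ScenarioSpec(mechanism="fxs", k_fmrp=0.0)
        st = ScenarioState.initial(spec)
        for _ in range(100):
            assert apply_fxs(1.0, st, spec, dt=1e-3) == 1.0
        assert st.influx == 0.0

    def test_constant_current_gives_linear_ramp(self):
        spec = ScenarioSpec(mechanism="fxs", k_fmrp=0.4, k_t=2.0)
        st = ScenarioState.initial(spec)
        dt, i0, n = 1e-3, 0.7, 500
        for _ in range(n):
            apply_fxs(i0, st, spec, dt)
        assert st.influx == pytest.approx(-0.4 * 2.0 * i0 * n * dt, rel=1e-12)


class TestTsc:
    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            ScenarioSpec(mechanism="tsc_nam", k_nam=1.0, k_mGluR5=1.0, k_pam=1.0)

    def test_nam_rate_falls_and_saturates(self):
        spec = ScenarioSpec(mechanism="tsc_nam")
        st = ScenarioState.initial(spec)
        for _ in range(4000):
            ov = apply_tsc(spec, "nam", st, dt=1e-3)
        assert st.k_mGluR5_t == pytest.approx(spec.tsc_k_min_frac * spec.k_mGluR5)
        assert st.cap_events > 0
        assert ov["ism_scale"] < 1.0 and ov["gain"] < 1.0

    def test_pam_rate_rises_and_saturates(self):
        spec = ScenarioSpec(mechanism="tsc_pam")
        st = ScenarioState.initial(spec)
        for _ in range(4000):
            ov = apply_tsc(spec, "pam", st, dt=1e-3)
        assert st.k_mGluR5_t == pytest.approx(spec.tsc_k_max_frac * spec.k_mGluR5)
        assert ov["gain"] > 1.0

    def test_nam_phenotype_more_events_lower_peak(self, scenario_config,
                                                  baseline_run):
        """Negative modulation: lower activation threshold, more supra-threshold
        events, attenuated amplitude (the high-frequency filter phenotype)."""
        nam = scenario_config.replace(
            scenario=ScenarioSpec(mechanism="tsc_nam")).run()
        m = ~baseline_run.warmup_mask
        n_base = mt.count_suprathreshold(baseline_run.output()[m],
                                         baseline_run.series["I_Sm_eff"][m])
        n_nam = mt.count_suprathreshold(nam.output()[m], nam.series["I_Sm_eff"][m])
        assert n_nam >= n_base
        assert nam.output().max() <= baseline_run.output().max()

    def test_pam_phenotype_higher_peak(self, scenario_config, baseline_run):
        """Positive modulation raises the output amplitude (Fig-6A-style)."""
        pam = scenario_config.replace(
            scenario=ScenarioSpec(mechanism="tsc_pam")).run()
        assert pam.output().max() >= baseline_run.output().max()


class TestDcycloserine:
    def test_equilibrium_algebra(self):
        # derivative zero at x with (x)*k_glut - N*k_dcs + 1/k_adjust = 0
        spec = ScenarioSpec(mechanism="dcycloserine", k_glutamate=0.5,
                            k_dcs=2.0, N_conc=0.6, k_adjust=4.0)
        x_star = (spec.N_conc * spec.k_dcs - 1 / spec.k_adjust) / spec.k_glutamate
        st = ScenarioState.initial(spec)
        st.x_dcs = x_star
        out = apply_dcycloserine(0.0, spec, st, dt=1e-3)
        assert out == pytest.approx(x_star)
        assert st.x_dcs == pytest.approx(x_star, rel=1e-12)

    def test_zero_inhibition_grows(self):
        spec = ScenarioSpec(mechanism="dcycloserine", k_glutamate=0.5,
                            k_dcs=1.0, N_conc=0.0, k_adjust=2.0)
        st = ScenarioState.initial(spec)
        vals = [apply_dcycloserine(0.1, spec, st, dt=1e-2) for _ in range(200)]
        assert vals[-1] > vals[0]
        assert np.all(np.diff(vals) >= 0)

    def test_zero_k_adjust_rejected(self):
        with pytest.raises(ValueError, match="k_adjust"):
            ScenarioSpec(mechanism="dcycloserine", k_adjust=0.0)

    def test_noise_increases_distortion(self, scenario_config):
        quiet = scenario_config.replace(
            scenario=ScenarioSpec(mechanism="dcycloserine")).run()
        noisy = scenario_config.replace(
            scenario=ScenarioSpec(mechanism="dcycloserine", noise_sigma=0.5,
                                  noise_seed=4)).run()
        assert distortion_score(noisy, quiet) > 1.0


class TestShankNeuroglin:
    def test_unit_gains_identity(self):
        spec = ScenarioSpec(mechanism="shank_ng", k_shank=1.0, k_neuroglin=1.0,
                            k_adjust_sh=1.0)
        assert apply_shank_ng(0.37, spec) == 0.37

    def test_cancelling_gains_identity(self):
        spec = ScenarioSpec(mechanism="shank_ng", k_shank=2.0, k_neuroglin=0.5,
                            k_adjust_sh=1.0)
        assert apply_shank_ng(0.37, spec) == pytest.approx(0.37)

    def test_pointwise_scaling_of_trace(self, short_config, baseline_run):
        spec = ScenarioSpec(mechanism="shank_ng", k_shank=1.5, k_neuroglin=1.0,
                            k_adjust_sh=1.0, k_nmdar=1.0)
        run = short_config.replace(scenario=spec).run()
        healthy = short_config.run()
        assert np.allclose(run.series["Isyn_eff"],
                           1.5 * healthy.series["Isyn_in"], rtol=1e-12)

    def test_nmdar_gain_raises_weight(self, short_config):
        spec = ScenarioSpec(mechanism="shank_ng", k_shank=1.0, k_neuroglin=1.0,
                            k_adjust_sh=1.0, k_nmdar=2.0)
        run = short_config.replace(scenario=spec).run()
        healthy = short_config.run()
        assert run.series["omega"][-1] > healthy.series["omega"][-1]


class TestChr15:
    def test_suppresses_mediator_peak(self, scenario_config, baseline_run):
        strong = scenario_config.replace(
            scenario=ScenarioSpec(mechanism="chr15", k_chr15=5.0)).run()
        assert strong.series["Sm"].max() < baseline_run.series["Sm"].max()

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(mechanism="chr15", k_chr15=-0.5)


class TestNoiseMonotonicity:
    def test_distortion_nondecreasing_in_amplitude(self, scenario_config):
        """Distortion score grows with the scenario noise amplitude."""
        quiet = scenario_config.replace(
            scenario=ScenarioSpec(mechanism="dcycloserine")).run()
        scores = []
        for sigma in (0.0, 0.1, 0.25, 0.5, 1.0):
            noisy = scenario_config.replace(
                scenario=ScenarioSpec(mechanism="dcycloserine",
                                      noise_sigma=sigma, noise_seed=7)).run()
            scores.append(distortion_score(noisy, quiet))
        assert scores[0] == pytest.approx(1.0)
        assert all(b >= a for a, b in zip(scores, scores[1:]))
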