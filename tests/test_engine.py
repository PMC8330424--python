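"""Engine behavior: determinism, fixed points, warm-up, delay, quantization,
and fidelity between the discretized and reference modes."""

import numpy as np
import pytest

from synapsim import (
    EngineConfig,
    IntegrationError,
    PostSynParams,
    PreSynParams,
    RunConfig,
    ScenarioSpec,
    SpikeTrain,
    periodic_spike_train,
    quantize,
    rms_error,
    simulate_discretized,
    simulate_reference,
    syn_current_closed,
)


class TestQuantize:
    def test_double_is_identity(self):
        for x in (0.1, -3.7e200, 1e-300):
            assert quantize(x, "double") == x

    def test_single_rounds_to_binary32(self):
        assert quantize(0.1, "single") == pytest.approx(0.100000001490116, abs=1e-15)

    def test_unit_roundoff_bound(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1e30, 1e30, 200)
        q = quantize(x, "single")
        assert np.all(np.abs(q - x) <= 2.0**-24 * np.abs(x) + 1e-300)


class TestDeterminism:
    def test_discretized_bit_identical(self, short_config):
        a = short_config.run()
        b = short_config.run()
        for key in a.series:
            assert np.array_equal(a.series[key], b.series[key]), key

    def test_reference_bit_identical(self, short_config):
        a = short_config.run("reference")
        b = short_config.run("reference")
        for key in a.series:
            assert np.array_equal(a.series[key], b.series[key]), key


class TestRestFixedPoint:
    @pytest.mark.parametrize("mode", ["discretized", "reference"])
    def test_no_drive_traces_constant(self, mode, presyn, postsyn):
        """Empty stimulus and zero messenger drive leave every trace at its
        equilibrium value."""
        cfg = EngineConfig(mode=mode, horizon=0.5, delta=5e-4, rm_value=0.0)
        stim = SpikeTrain(times=np.array([]), horizon=0.5)
        sim = simulate_reference if mode == "reference" else simulate_discretized
        tr = sim(presyn, postsyn, ScenarioSpec(), stim, cfg)
        for key in ("RMtrace", "Inh", "C", "D", "omega", "Y", "Z", "Cc", "m",
                    "Sm", "Vpost", "Wpost"):
            s = tr.series[key]
            assert np.max(np.abs(s - s[0])) < 1e-6, key


class TestSteadyStates:
    def test_rmtrace_reaches_tau_r_times_rm(self, presyn, postsyn):
        """Constant messenger drive: RMtrace converges to tau_r * RM."""
        cfg = EngineConfig(mode="reference", horizon=1.5, delta=1e-3,
                           rm_value=0.8, init="rest")
        stim = SpikeTrain(times=np.array([]), horizon=1.5)
        tr = simulate_reference(presyn, postsyn, ScenarioSpec(), stim, cfg)
        assert tr.series["RMtrace"][-1] == pytest.approx(
            presyn.tau_r * 0.8, rel=1e-3)

    def test_omega_starts_at_zero_and_never_decreases(self, short_config):
        tr = short_config.run()
        om = tr.series["omega"]
        assert om[0] == 0.0
        assert np.all(np.diff(om) >= 0)


class TestWarmup:
    def test_mask_flags_without_altering_values(self, short_config):
        tr = short_config.run()
        n_warm = tr.metadata["warmup_samples"]
        assert n_warm == int(round(0.031 / short_config.engine.delta))
        assert tr.warmup_mask.sum() == n_warm
        assert np.all(tr.warmup_mask[:n_warm])
        # stored values under the mask are real samples, not sentinels
        assert np.all(np.isfinite(tr.output()))
        assert tr.output().size == tr.output(after_warmup=True).size + n_warm


class TestFeedbackDelay:
    def test_messenger_delayed_by_configured_cycles(self, presyn):
        """The delay line shifts the produced messenger by exactly L steps."""
        # steepen RM(Cc) and drive the post-synaptic side through the
        # competitive channel so the fed-back messenger actually varies
        postsyn = PostSynParams(rm_k2=0.5, rm_k1=2.0)
        scen = ScenarioSpec(mechanism="dcycloserine", noise_sigma=0.3,
                            noise_seed=5)
        L = 25
        cfg = EngineConfig(horizon=1.0, delta=5e-4, rm_mode="feedback",
                           feedback_delay_steps=L)
        stim = periodic_spike_train(10.0, 1.0)
        tr = simulate_discretized(presyn, postsyn, scen, stim, cfg)
        produced = tr.series["RM"]
        fed = tr.series["RM_in"]
        assert np.ptp(produced) > 0  # varies, so the lag is observable
        assert np.array_equal(fed[L:], produced[:-L])
        # the fed series correlates maximally with the produced series at lag L
        a, b = np.diff(produced), np.diff(fed)
        corrs = {
            k: float(np.corrcoef(a[: a.size - k], b[k:])[0, 1])
            for k in range(0, 2 * L + 1)
        }
        assert corrs[L] == pytest.approx(1.0)
        assert corrs[L] >= max(corrs.values()) - 1e-12


class TestSpikeBinning:
    def test_two_spikes_in_one_bin_count_once(self, presyn, postsyn):
        cfg = EngineConfig(horizon=0.2, delta=1e-2)
        stim = SpikeTrain(times=np.array([0.05, 0.052, 0.11]), horizon=0.2)
        tr = simulate_discretized(presyn, postsyn, ScenarioSpec(), stim, cfg)
        assert tr.metadata["events"]["spike_bin_collisions"] == 1
        # Z jumped twice in total (one merged bin + one later bin), never three
        assert tr.series["Z"].max() < 1.5

    def test_spike_increments_z_by_one(self, presyn, postsyn):
        cfg = EngineConfig(horizon=0.1, delta=1e-3)
        stim = SpikeTrain(times=np.array([0.05]), horizon=0.1)
        tr = simulate_discretized(presyn, postsyn, ScenarioSpec(), stim, cfg)
        z = tr.series["Z"]
        k = int(round(0.05 / 1e-3))
        assert z[k] == pytest.approx(0.0)        # pre-jump sample
        assert z[k + 1] == pytest.approx(1.0, abs=0.01)


class TestReferenceAccuracy:
    def test_solver_refinement_changes_little(self, short_config):
        """Tightening the adaptive tolerances leaves the solution unchanged
        to well under 0.1% relative RMS."""
        coarse = short_config.run("reference")
        tight = short_config.replace(
            engine=short_config.engine.replace(
                mode="reference", solver_rtol=1e-10, solver_atol=1e-13)).run()
        for key in ("Isyn_eff", "omega", "Cc", "Vpost"):
            r = coarse.series[key]
            t = tight.series[key]
            denom = np.sqrt(np.mean(t**2))
            if denom > 0:
                assert np.sqrt(np.mean((r - t) ** 2)) / denom < 1e-3, key

    def test_alpha_current_matches_closed_form(self, short_config, presyn):
        """Reference Y/Z integration equals the closed-form superposition."""
        tr = short_config.run("reference")
        stim = short_config.build_stimulus()
        closed = syn_current_closed(tr.time, stim, 1.0, presyn.tau_syn)
        err = rms_error(tr.series["Y"], closed)
        assert err < 0.1


class TestModeFidelity:
    def test_discretized_tracks_reference_on_short_run(self, short_config):
        disc = short_config.run("discretized")
        ref = short_config.run("reference")
        m = ~disc.warmup_mask
        assert rms_error(disc.output()[m], ref.output()[m]) < 2.0

    def test_euler_first_order_convergence(self):
        """Halving the step roughly halves the deviation from the reference
        (measured on identical equations, so only the scheme differs)."""
        cfg = RunConfig(engine=EngineConfig(horizon=1.5))
        errs = []
        deltas = [8e-4, 2e-4]
        for d in deltas:
            e = cfg.engine.replace(mode="discretized", delta=d, equations="exact")
            disc = cfg.replace(engine=e).run()
            ref = cfg.replace(engine=e.replace(mode="reference", dt=d)).run()
            m = ~disc.warmup_mask
            errs.append(rms_error(disc.output()[m], ref.output()[m]))
        ratio = errs[0] / errs[1]
        assert 2.0 < ratio < 8.0  # consistent with first order over a 4x step change


class TestPrecision:
    def test_single_precision_states_are_binary32(self, presyn, postsyn):
        cfg = EngineConfig(horizon=0.5, delta=5e-4, precision="single")
        stim = periodic_spike_train(10.0, 0.5)
        tr = simulate_discretized(presyn, postsyn, ScenarioSpec(), stim, cfg)
        om = tr.series["omega"]
        assert np.array_equal(om[1:], om[1:].astype(np.float32).astype(float))

    def test_single_close_to_double(self, presyn, postsyn):
        stim = periodic_spike_train(10.0, 1.0)
        runs = {}
        for precision in ("double", "single"):
            cfg = EngineConfig(horizon=1.0, delta=5e-4, precision=precision)
            runs[precision] = simulate_discretized(
                presyn, postsyn, ScenarioSpec(), stim, cfg)
        m = ~runs["double"].warmup_mask
        out_d = runs["double"].output()[m]
        out_s = runs["single"].output()[m]
        assert rms_error(out_s, out_d) < 0.1


class TestErrors:
    def test_blowup_names_variable_and_step(self, presyn, postsyn):
        bad = presyn.replace(tau_syn=1e-5)  # Euler-unstable at this step
        stim = periodic_spike_train(10.0, 1.0)
        cfg = EngineConfig(horizon=1.0, delta=1e-3)
        with pytest.raises(IntegrationError):
            simulate_discretized(bad, postsyn, ScenarioSpec(), stim, cfg)

    def test_reference_rejects_active_scenarios(self, presyn, postsyn):
        cfg = EngineConfig(mode="reference", horizon=0.1)
        stim = SpikeTrain(times=np.array([]), horizon=0.1)
        with pytest.raises(NotImplementedError):
            simulate_reference(presyn, postsyn,
                               ScenarioSpec(mechanism="fxs"), stim, cfg)


class TestTraceSetIO:
    def test_csv_and_json_roundtrip(self, short_config, tmp_path):
        tr = short_config.replace(
            engine=short_config.engine.replace(horizon=0.2)).run()
        tr.to_csv(tmp_path / "t.csv")
        tr.to_json(tmp_path / "t.json")
        from synapsim import TraceSet

        back = TraceSet.from_json(tmp_path / "t.json")
        assert np.array_equal(back.time, tr.time)
        for key in tr.series:
            assert np.array_equal(back.series[key], tr.series[key])
        import pandas as pd

        df = pd.read_csv(tmp_path / "t.csv")
        assert df.columns[0] == "time"
        assert df.shape[0] == tr.time.size
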