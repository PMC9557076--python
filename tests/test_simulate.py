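import math

import numpy as np
import pytest

from phaselge import (
    CardiacTiming,
    SequenceParams,
    TissueCompartment,
    apparent_t1,
    generate_stack,
    plan_acquisition,
    pulsed_steady_state,
    simulate_pulse_train,
    two_sphere_phantom,
)
from phaselge.phantom import PhantomConfigError
from phaselge.simulate import compartment_signals, resolve_noise_sd
from phaselge.timing import InvalidParameterError

from oracles import apparent_t1_by_fit, steady_state_by_iteration


class TestPulsedSteadyState:
    def test_zero_flip_is_identity(self):
        assert pulsed_steady_state(910, 0.0, 5.0, m0=2.5) == pytest.approx(2.5)

    def test_reference_value(self):
        # fixed-point iteration oracle, and the frozen value ~0.801
        got = pulsed_steady_state(910, 3.0, 5.0)
        assert got == pytest.approx(steady_state_by_iteration(910, 3.0, 5.0), rel=1e-10)
        assert got == pytest.approx(0.8008, abs=5e-4)

    def test_full_recovery_limit(self):
        assert pulsed_steady_state(910, 3.0, 1e7) == pytest.approx(1.0)

    def test_invalid_flip(self):
        with pytest.raises(InvalidParameterError):
            pulsed_steady_state(910, 95.0, 5.0)


class TestApparentT1:
    def test_zero_flip_equals_t1(self):
        assert apparent_t1(910, 0.0, 5.0) == pytest.approx(910.0)

    @pytest.mark.parametrize(
        "t1, expected", [(910.0, 728.3), (489.0, 431.2)]
    )
    def test_reference_values(self, t1, expected):
        assert apparent_t1(t1, 3.0, 5.0) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize("t1", [350.0, 650.0, 910.0])
    def test_matches_dense_recovery_fit_oracle(self, t1):
        assert apparent_t1(t1, 3.0, 5.0) == pytest.approx(
            apparent_t1_by_fit(t1, 3.0, 5.0), rel=1e-6
        )

    def test_shorter_than_t1(self):
        assert apparent_t1(910, 3.0, 5.0) < 910.0


class TestPulseTrain:
    def test_pre_inversion_steady_state_signal(self, params_3t, timing_60, plan_60):
        comp = TissueCompartment("x", 910.0)
        train = simulate_pulse_train(comp, params_3t, timing_60, plan_60)
        expected = pulsed_steady_state(910, 3.0, 5.0) * math.sin(math.radians(3))
        assert train.steady_state_signal == pytest.approx(expected, rel=1e-2)

    def test_signal_reapproaches_steady_state(self, timing_60):
        # deviation from the pulsed steady state decays as exp(-TI/T1*):
        # after a long enough train the last readout is back within 1%
        params = SequenceParams(tr_ms=5, flip_deg=3, recovery_beats=5)
        plan = plan_acquisition(params, timing_60)
        comp = TissueCompartment("x", 910.0)
        train = simulate_pulse_train(comp, params, timing_60, plan)
        assert train.signal[-1] == pytest.approx(
            train.steady_state_signal, rel=1e-2
        )

    def test_two_beat_recovery_residual(self, params_3t, timing_60, plan_60):
        # at two beats the residual deviation is ~2 exp(-2 RR / T1*)
        comp = TissueCompartment("x", 489.0)
        train = simulate_pulse_train(comp, params_3t, timing_60, plan_60)
        t1s = apparent_t1(489.0, 3.0, 5.0)
        k = np.argmin(np.abs(train.ti_ms - 2000.0))
        residual = 1.0 - train.signal[k] / train.steady_state_signal
        assert residual == pytest.approx(2 * math.exp(-2000.0 / t1s), rel=1e-2)

    @pytest.mark.parametrize("t1", [489.0, 910.0])
    def test_fit_recovers_apparent_t1(self, params_3t, timing_60, plan_60, t1):
        from phaselge.fitting import fit_ir_two_param

        comp = TissueCompartment("x", t1)
        train = simulate_pulse_train(comp, params_3t, timing_60, plan_60)
        signed, realized = train.sample_plan(plan_60)
        for phase in (0, plan_60.n_phases // 2, plan_60.n_phases - 1):
            fit = fit_ir_two_param(realized[phase], signed[phase])
            assert fit.t1_star_ms == pytest.approx(
                apparent_t1(t1, 3.0, 5.0), rel=1e-2
            )

    def test_inversion_efficiency_scales_inverted_signal(self, timing_60):
        params_full = SequenceParams(tr_ms=5, flip_deg=3)
        params_partial = SequenceParams(tr_ms=5, flip_deg=3, inv_efficiency=0.8)
        plan = plan_acquisition(params_full, timing_60)
        comp = TissueCompartment("x", 650.0)
        s_full = simulate_pulse_train(comp, params_full, timing_60, plan)
        s_part = simulate_pulse_train(comp, params_partial, timing_60, plan)
        # early signal deficit relative to steady state shrinks with efficiency
        d_full = s_full.steady_state_signal - s_full.signal[0]
        d_part = s_part.steady_state_signal - s_part.signal[0]
        assert d_part < d_full

    def test_realized_tis_on_tr_grid(self, params_3t, timing_60, plan_60):
        comp = TissueCompartment("x", 489.0)
        train = simulate_pulse_train(comp, params_3t, timing_60, plan_60)
        _, realized = train.sample_plan(plan_60)
        np.testing.assert_allclose(realized % params_3t.tr_ms, 0.0, atol=1e-9)
        assert np.all(np.abs(realized - plan_60.ti_ms) <= params_3t.tr_ms / 2 + 1e-9)


class TestGenerateStack:
    def test_shapes_and_ti_count(self, params_3t, timing_60, plan_60):
        spec = two_sphere_phantom(shape=(32, 32), radius=6)
        (stack,) = generate_stack(spec, params_3t, timing_60, plan_60)
        assert stack.data.shape == (18, 6, 32, 32)
        assert stack.ti_ms.shape == (18, 6)

    def test_zero_noise_repetitions_identical(self, params_3t, timing_60, plan_60):
        spec = two_sphere_phantom(shape=(24, 24), radius=5)
        stacks = generate_stack(spec, params_3t, timing_60, plan_60, n_repetitions=3)
        assert np.array_equal(stacks[0].data, stacks[1].data)
        assert np.array_equal(stacks[0].data, stacks[2].data)

    def test_roi_means_match_pulse_train(self, params_3t, timing_60, plan_60):
        spec = two_sphere_phantom(shape=(24, 24), radius=5)
        (stack,) = generate_stack(spec, params_3t, timing_60, plan_60)
        sigs, _ = compartment_signals(spec, params_3t, timing_60, plan_60)
        for c, comp in enumerate(spec.compartments):
            m = spec.compartment_mask(comp.label)
            roi_mean = stack.data[:, :, m].mean(axis=-1)
            np.testing.assert_allclose(roi_mean, np.abs(sigs[c]), atol=1e-9)

    def test_seed_mandatory_with_noise(self, params_3t, timing_60, plan_60):
        spec = two_sphere_phantom(shape=(16, 16), radius=4, noise_sd=0.001)
        with pytest.raises(PhantomConfigError):
            generate_stack(spec, params_3t, timing_60, plan_60)

    def test_same_seed_reproduces(self, params_3t, timing_60, plan_60):
        spec = two_sphere_phantom(shape=(16, 16), radius=4, noise_sd=0.001)
        a = generate_stack(spec, params_3t, timing_60, plan_60, seed=7)
        b = generate_stack(spec, params_3t, timing_60, plan_60, seed=7)
        assert np.array_equal(a[0].data, b[0].data)

    def test_snr_definition_consistency(self, params_3t, timing_60):
        spec = two_sphere_phantom(
            shape=(16, 16), radius=4, baseline_snr=20.0, snr_reference="blood"
        )
        sd = resolve_noise_sd(spec, params_3t)
        ss = pulsed_steady_state(489.0, 3.0, 5.0) * math.sin(math.radians(3))
        assert ss / sd == pytest.approx(20.0)

    def test_unknown_snr_reference_rejected(self):
        with pytest.raises(PhantomConfigError):
            two_sphere_phantom(
                shape=(16, 16), radius=4, baseline_snr=20.0, snr_reference="bone"
            )

    def test_motion_changes_label_maps_per_phase(self, params_3t, coarse_timing):
        from phaselge import cardiac_phantom

        plan = plan_acquisition(params_3t, coarse_timing)
        n_p = plan.n_phases
        contraction = np.linspace(1.0, 0.8, n_p)
        spec = cardiac_phantom(shape=(48, 48), contraction=contraction)
        (stack,) = generate_stack(spec, params_3t, coarse_timing, plan)
        assert not np.array_equal(stack.data[0], stack.data[-1])


class TestNoiseCov:
    def test_higher_t1_more_variable_absolute_sd(self, params_3t, timing_60, plan_60):
        # the absolute spread of fitted T1* grows with the simulated T1
        from phaselge.fitting import fit_magnitude

        spreads = {}
        for t1, seed in ((350.0, 5), (650.0, 6)):
            comp = TissueCompartment("x", t1)
            train = simulate_pulse_train(comp, params_3t, timing_60, plan_60)
            signed, realized = train.sample_plan(plan_60)
            sd = train.steady_state_signal / 20.0
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(40):
                noisy = np.abs(signed[0] + rng.normal(0, sd, signed[0].shape))
                vals.append(fit_magnitude(realized[0], noisy).t1_star_ms)
            spreads[t1] = np.std(vals, ddof=1)
        assert spreads[650.0] > spreads[350.0]
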