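import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frailtykit as fk
from frailtykit.errors import FeatureUnavailable
from frailtykit.features import (
    FEATURE_NAMES,
    PHENOTYPE_GROUPS,
    coefficient_of_variation,
    exhaustion_delta,
    extract_features,
    per_cycle_primitives,
)


def test_feature_enumeration_matches_phenotype_groups():
    sizes = {k: len(v) for k, v in PHENOTYPE_GROUPS.items()}
    assert sizes == {
        "slowness": 7,
        "weakness": 1,
        "rigidity": 1,
        "exhaustion": 4,
        "unsteadiness": 7,
    }
    assert sum(sizes.values()) == len(FEATURE_NAMES) == 20


class TestPerCyclePrimitives:
    def test_sinusoid_closed_forms(self, make_sine):
        # ω = A·sin(2πft): per-cycle speed range 2A; acceleration amplitude
        # A·2πf so power = (2A)·(2A·2πf) = 8πfA²
        A, f = 100.0, 0.5
        s = make_sine(amplitude=A, freq=f)
        v = per_cycle_primitives(s, fk.segment(s))
        assert v.speed == pytest.approx(2 * A, rel=0.01)
        assert v.power == pytest.approx(8 * np.pi * f * A**2, rel=0.02)
        assert v.cycle_time == pytest.approx(1.0 / f, abs=0.02)

    def test_zero_signal_yields_empty_primitives(self, make_sine):
        s = make_sine(amplitude=0.0)
        v = per_cycle_primitives(s, fk.segment(s))
        assert v.n_full_cycles == 0
        assert v.half_rom.size == 0


class TestExhaustionDelta:
    def test_constant_values_give_zero(self):
        mids = np.linspace(0.5, 19.5, 20)
        assert exhaustion_delta(np.full(20, 7.0), mids, 10.0) == pytest.approx(0.0)

    def test_decline_hand_computed(self):
        # first-window mean 10, last-window mean 8, overall 9 → −22.22%
        values = np.array([10.0, 10.0, 8.0, 8.0])
        mids = np.array([2.0, 5.0, 12.0, 15.0])
        assert exhaustion_delta(values, mids, 10.0) == pytest.approx(-200.0 / 9.0)

    def test_increase_hand_computed(self):
        # means 10 and 20, overall 15 → +66.67%
        values = np.array([10.0, 10.0, 20.0, 20.0])
        mids = np.array([2.0, 5.0, 12.0, 15.0])
        assert exhaustion_delta(values, mids, 10.0) == pytest.approx(200.0 / 3.0)

    def test_empty_window_flagged_unavailable(self):
        with pytest.raises(FeatureUnavailable, match="window"):
            exhaustion_delta(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 10.0)


class TestCoefficientOfVariation:
    def test_identical_values_zero(self):
        assert coefficient_of_variation(np.full(5, 3.3)) == 0.0

    def test_two_values_hand_computed(self):
        # {8, 12}: sd = 2·sqrt(2), mean 10 → 28.28%
        assert coefficient_of_variation(np.array([8.0, 12.0])) == pytest.approx(
            100.0 * 2.0 * np.sqrt(2.0) / 10.0
        )

    def test_single_value_unavailable(self):
        with pytest.raises(FeatureUnavailable):
            coefficient_of_variation(np.array([1.0]))

    def test_zero_mean_unavailable(self):
        with pytest.raises(FeatureUnavailable):
            coefficient_of_variation(np.array([-1.0, 1.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(1.0, 1e3), min_size=2, max_size=30),
        st.floats(0.1, 100.0),
    )
    def test_scale_invariance(self, values, c):
        v = np.asarray(values)
        assert coefficient_of_variation(c * v) == pytest.approx(
            coefficient_of_variation(v), rel=1e-9, abs=1e-9
        )


class TestExtractFeatures:
    def test_exactly_twenty_fields_on_valid_recording(self, params):
        _, noisy = fk.generate_omega(params)
        feats = extract_features(noisy, fk.segment(noisy))
        d = feats.to_dict()
        assert len(d) == 20
        assert all(v is not None for v in d.values())

    def test_stationary_sinusoid_has_no_drift_or_variability(self, make_sine):
        s = make_sine(amplitude=100.0, freq=0.5)
        feats = extract_features(s, fk.segment(s))
        for name in PHENOTYPE_GROUPS["exhaustion"]:
            assert abs(getattr(feats, name)) < 1.0, name
        for name in PHENOTYPE_GROUPS["unsteadiness"]:
            assert getattr(feats, name) < 1.0, name

    def test_sinusoid_level_features(self, make_sine):
        s = make_sine(amplitude=100.0, freq=0.5)
        feats = extract_features(s, fk.segment(s))
        assert feats.flexion_time == pytest.approx(1.0, abs=0.03)
        assert feats.rise_time == pytest.approx(0.5, abs=0.03)
        assert feats.cycle_time == pytest.approx(2.0, abs=0.05)
        assert feats.n_repetitions == 10
        assert feats.speed == pytest.approx(200.0, rel=0.01)

    def test_empty_cycles_all_unavailable_with_reason(self, make_sine):
        s = make_sine(amplitude=0.0)
        feats = extract_features(s, fk.segment(s))
        assert feats.to_dict() == {name: None for name in FEATURE_NAMES}
        assert set(feats.unavailable) == set(FEATURE_NAMES)
        assert "no movement" in feats.unavailable["speed"]
        with pytest.raises(FeatureUnavailable, match="speed"):
            feats.require("speed")

    def test_programmed_decay_recovered_in_delta_speed(self):
        p = fk.SyntheticParams(
            seed=4, decay=0.2, period_jitter_cv=0.0, amplitude_jitter_cv=0.0, omega_noise_sd=2.0
        )
        _, noisy = fk.generate_omega(p)
        smoothed = fk.AngularVelocitySeries(
            noisy.t, fk.normalize_sign(fk.lowpass(noisy.omega, noisy.rate, 6.0))
        )
        feats = extract_features(smoothed, fk.segment(smoothed))
        assert feats.delta_speed == pytest.approx(-20.0, abs=2.0)


def _dilate(series, k):
    return fk.AngularVelocitySeries(t=series.t * k, omega=series.omega / k)


class TestScalingProperties:
    def test_time_dilation(self, params):
        """Stretching time by k scales durations by k, speed by 1/k, power by
        1/k³, keeps ROM and all percent-valued features within 2%."""
        truth, _ = fk.generate_omega(params)
        k = 1.5
        base = extract_features(truth, fk.segment(truth)).to_dict()
        dil = _dilate(truth, k)
        scaled = extract_features(dil, fk.segment(dil)).to_dict()
        expected_factor = {
            "speed": 1 / k,
            "rise_time": k,
            "fall_time": k,
            "extension_time": k,
            "flexion_time": k,
            "cycle_time": k,
            "n_repetitions": 1.0,
            "power": 1 / k**3,
            "range_of_motion": 1.0,
        }
        for name, factor in expected_factor.items():
            assert scaled[name] == pytest.approx(base[name] * factor, rel=0.02), name
        for name in PHENOTYPE_GROUPS["exhaustion"] + PHENOTYPE_GROUPS["unsteadiness"]:
            assert scaled[name] == pytest.approx(base[name], rel=0.02, abs=0.3), name

    def test_amplitude_scaling(self, params):
        """Scaling ω by c scales speed by c, power by c², ROM by c and leaves
        percent-valued features within 2%."""
        truth, _ = fk.generate_omega(params)
        c = 2.5
        base = extract_features(truth, fk.segment(truth)).to_dict()
        big = fk.AngularVelocitySeries(t=truth.t, omega=c * truth.omega)
        scaled = extract_features(big, fk.segment(big)).to_dict()
        assert scaled["speed"] == pytest.approx(c * base["speed"], rel=0.02)
        assert scaled["power"] == pytest.approx(c**2 * base["power"], rel=0.02)
        assert scaled["range_of_motion"] == pytest.approx(c * base["range_of_motion"], rel=0.02)
        for name in ("flexion_time", "cycle_time", "n_repetitions"):
            assert scaled[name] == pytest.approx(base[name], rel=0.01), name
        for name in PHENOTYPE_GROUPS["exhaustion"] + PHENOTYPE_GROUPS["unsteadiness"]:
            assert scaled[name] == pytest.approx(base[name], rel=0.02, abs=0.3), name
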