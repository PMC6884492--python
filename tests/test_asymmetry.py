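import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freegait import (
    AsymmetryRecord,
    AsymmetryUndefinedError,
    EnvelopeError,
    Stride,
    StrideWaveforms,
    bout_asymmetry,
    discrete_asymmetry,
    emg_envelope,
    normalize_stride_waveforms,
    remove_outlier_asymmetries,
    waveform_asymmetry,
)
from freegait.asymmetry import GAIT_CYCLE_POINTS, time_normalize

SEMG_RATE = 250.0


class TestEmgEnvelope:
    def test_zero_input_zero_envelope(self):
        env = emg_envelope(np.zeros(2000), SEMG_RATE)
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_rectified_sine_mean(self):
        # 50 Hz tone of amplitude A: envelope ~ rectified mean 2A/pi
        amp = 0.8
        t = np.arange(int(8 * SEMG_RATE)) / SEMG_RATE
        x = amp * np.sin(2 * np.pi * 50.0 * t)
        env = emg_envelope(x, SEMG_RATE)
        interior = env[500:-500]
        assert np.mean(interior) == pytest.approx(2 * amp / np.pi, rel=0.10)

    def test_rectification_symmetry(self, rng):
        x = rng.normal(size=2000)
        np.testing.assert_allclose(
            emg_envelope(-x, SEMG_RATE), emg_envelope(x, SEMG_RATE), atol=1e-12
        )

    def test_nonnegative(self, rng):
        env = emg_envelope(rng.normal(size=3000), SEMG_RATE)
        assert np.all(env >= 0.0)

    def test_short_segment_errors(self):
        with pytest.raises(EnvelopeError):
            emg_envelope(np.zeros(10), SEMG_RATE)

    def test_low_rate_errors(self):
        with pytest.raises(EnvelopeError):
            emg_envelope(np.zeros(1000), 50.0)


class TestTimeNormalization:
    def test_constant_channel(self):
        t = np.linspace(0.0, 1.2, 40)
        out = time_normalize(t, np.full(40, 3.3), 0.0, 1.2)
        assert out.shape == (GAIT_CYCLE_POINTS,)
        np.testing.assert_allclose(out, 3.3)

    def test_linear_ramp_exact(self):
        t = np.linspace(0.0, 1.0, 64)
        out = time_normalize(t, 2.0 * t, 0.0, 1.0)
        np.testing.assert_allclose(out, 2.0 * np.linspace(0, 1, GAIT_CYCLE_POINTS), atol=1e-12)

    def test_full_cycle_phase(self):
        st_s = 1.1
        t = np.arange(0, st_s + 0.05, 1 / 250.0)
        x = np.sin(2 * np.pi * t / st_s)
        out = time_normalize(t, x, 0.0, st_s)
        assert out[0] == pytest.approx(out[-1], abs=1e-6)
        assert np.max(out) == pytest.approx(1.0, abs=1e-3)

    def test_normalize_stride_waveforms_channels(self):
        stride = Stride(leg="right", t_contact=0.0, t_off=0.66, t_next_contact=1.1)
        t = np.arange(0, 1.2, 1 / 31.25)
        wf = normalize_stride_waveforms(
            stride,
            accel_channels={"cc": (t, np.ones_like(t)), "ap": (t, t), "ml": (t, -t)},
            emg_channel=(t, np.abs(t)),
            accel_rate=31.25,
        )
        assert set(wf.channels) == {"cc", "ap", "ml", "emg"}
        assert wf.stance_boundary == round(0.6 * 100)


class TestDiscreteAsymmetry:
    def test_equal_is_zero(self):
        assert discrete_asymmetry(0.6, 0.6) == 0.0

    def test_fifty_percent_difference(self):
        assert discrete_asymmetry(0.15, 0.10) == pytest.approx(0.5)

    def test_zero_healthy_errors(self):
        with pytest.raises(AsymmetryUndefinedError):
            discrete_asymmetry(0.1, 0.0)

    def test_always_nonnegative(self, rng):
        for _ in range(50):
            i, h = rng.normal(), rng.normal()
            if h != 0:
                assert discrete_asymmetry(i, h) >= 0.0


class TestWaveformAsymmetry:
    def grid(self):
        return np.linspace(0, 2 * np.pi, GAIT_CYCLE_POINTS)

    def test_identical_is_zero(self):
        w = np.sin(self.grid())
        assert waveform_asymmetry(w, w) == pytest.approx(0.0, abs=1e-12)

    def test_negation_is_one(self):
        w = np.sin(self.grid())
        assert waveform_asymmetry(w, -w) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_is_half(self):
        g = self.grid()
        assert waveform_asymmetry(np.sin(g), np.cos(g)) == pytest.approx(0.5, abs=0.01)

    def test_zero_variance_errors(self):
        with pytest.raises(AsymmetryUndefinedError):
            waveform_asymmetry(np.ones(GAIT_CYCLE_POINTS), np.sin(self.grid()))

    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        offset=st.floats(min_value=-10.0, max_value=10.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance_and_bounds(self, scale, offset, seed):
        gen = np.random.default_rng(seed)
        a = gen.normal(size=GAIT_CYCLE_POINTS)
        b = gen.normal(size=GAIT_CYCLE_POINTS)
        base = waveform_asymmetry(a, b)
        assert 0.0 <= base <= 1.0
        assert waveform_asymmetry(scale * a + offset, b) == pytest.approx(base, abs=1e-9)


def make_waveforms(df=0.6, st_s=1.1, offset=0.0, emg_scale=1.0, n=3, leg="right"):
    """Synthetic per-stride waveforms with controllable content."""
    grid = np.linspace(0, 1, GAIT_CYCLE_POINTS)
    out = []
    for k in range(n):
        stride = Stride(
            leg=leg,
            t_contact=k * st_s + offset,
            t_off=k * st_s + offset + df * st_s,
            t_next_contact=(k + 1) * st_s + offset,
        )
        channels = {
            "cc": 1.0 + 0.3 * np.sin(2 * np.pi * grid),
            "ap": 0.2 * np.cos(2 * np.pi * grid),
            "ml": 0.1 * np.sin(4 * np.pi * grid),
            "emg": emg_scale * (0.1 + np.sin(np.pi * grid) ** 2),
        }
        out.append(StrideWaveforms(stride=stride, channels=channels))
    return out


class TestBoutAsymmetry:
    def test_mirrored_legs_all_zero(self):
        wf = {"right": make_waveforms(leg="right"), "left": make_waveforms(leg="left")}
        record = bout_asymmetry(wf, injured_leg="left")
        for name, value in record.indices().items():
            assert value == pytest.approx(0.0, abs=1e-9), name
        assert record.composite == pytest.approx(0.0, abs=1e-9)

    def test_df_asymmetry_recovered_exactly(self):
        wf = {
            "right": make_waveforms(df=0.60, leg="right"),
            "left": make_waveforms(df=0.678, leg="left"),
        }
        record = bout_asymmetry(wf, injured_leg="left")
        assert record.a_df == pytest.approx(0.13, abs=1e-9)

    def test_emg_scale_cancels_under_normalization(self):
        wf = {
            "right": make_waveforms(leg="right"),
            "left": make_waveforms(emg_scale=3.0, leg="left"),
        }
        record = bout_asymmetry(wf, injured_leg="left")
        assert record.a_emg_stance == pytest.approx(0.0, abs=1e-9)
        assert record.a_emg_t == pytest.approx(0.0, abs=1e-9)

    def test_composite_is_mean_to_1e12(self):
        record = AsymmetryRecord(
            a_df=0.2, a_emg_stance=0.2, a_emg_swing=0.2, a_emg_t=0.2,
            a_cc_t=0.2, a_ap_t=0.2, a_ml_t=0.2,
        )
        assert abs(record.composite - 0.2) < 1e-12
        mixed = AsymmetryRecord(
            a_df=0.1, a_emg_stance=0.2, a_emg_swing=0.3, a_emg_t=0.15,
            a_cc_t=0.05, a_ap_t=0.25, a_ml_t=0.02,
        )
        assert abs(mixed.composite - np.mean(list(mixed.indices().values()))) < 1e-12

    def test_too_few_strides_errors(self):
        wf = {"right": make_waveforms(n=2), "left": make_waveforms(n=1)}
        with pytest.raises(AsymmetryUndefinedError):
            bout_asymmetry(wf, injured_leg="left")


def make_records(composites, subject="P1"):
    out = []
    for i, c in enumerate(composites):
        out.append(
            AsymmetryRecord(
                a_df=c, a_emg_stance=c, a_emg_swing=c, a_emg_t=c,
                a_cc_t=c, a_ap_t=c, a_ml_t=c,
                bout_id=f"b{i}", subject_id=subject,
            )
        )
    return out


class TestOutlierRemoval:
    def test_gross_outlier_removed(self):
        records = make_records([0.2] * 9 + [5.0])
        kept = remove_outlier_asymmetries(records)
        assert len(kept) == 9
        assert all(r.composite == pytest.approx(0.2) for r in kept)

    def test_identical_values_all_kept(self):
        records = make_records([0.3] * 6)
        assert len(remove_outlier_asymmetries(records)) == 6

    def test_small_sample_passthrough(self):
        records = make_records([0.1, 0.2, 9.0])
        assert len(remove_outlier_asymmetries(records)) == 3

    def test_per_subject_screening(self):
        records = make_records([0.2] * 5 + [5.0], subject="A") + make_records(
            [5.0] * 5 + [0.2], subject="B"
        )
        kept = remove_outlier_asymmetries(records)
        by_subject = {}
        for r in kept:
            by_subject.setdefault(r.subject_id, []).append(r.composite)
        assert by_subject["A"] == pytest.approx([0.2] * 5)
        assert by_subject["B"] == pytest.approx([5.0] * 5)
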