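"""Envelope chain and time-domain features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synkick import preprocess as pp
from synkick.emg_io import PHASES, CycleEvents


FS = 2000.0


def _sine(freq, fs=FS, dur=4.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_passband_tone_preserved(self, make_rec):
        rec = make_rec(np.vstack([_sine(50.0)] * 2))
        out = pp.bandpass(rec)
        mid = slice(2000, 6000)
        ratio = out.signal[0, mid].std() / rec.signal[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_subsonic_tone_removed(self, make_rec):
        rec = make_rec(np.vstack([_sine(1.0)] * 2))
        out = pp.bandpass(rec)
        mid = slice(2000, 6000)
        assert out.signal[0, mid].std() < 0.05 * rec.signal[0, mid].std()

    def test_dc_rejected(self, make_rec):
        rec = make_rec(np.full((2, 4000), 3.0))
        out = pp.bandpass(rec)
        assert np.abs(out.signal).max() < 0.05

    def test_fs_too_low(self, make_rec):
        rec = make_rec(np.zeros((2, 100)), fs=700.0)
        with pytest.raises(ValueError, match="too low"):
            pp.bandpass(rec, high=400.0)

    def test_demean(self, make_rec, rng):
        sig = rng.normal(5.0, 2.0, size=(3, 1000))
        out = pp.demean(make_rec(sig))
        for ch in out.signal:
            assert abs(ch.mean()) < 1e-9 * ch.std()
        const = pp.demean(make_rec(np.full((2, 100), 7.0)))
        np.testing.assert_allclose(const.signal, 0.0, atol=1e-12)

    def test_rectify(self, make_rec):
        rec = make_rec(np.array([[1.0, -2.0, 3.0], [-1.0, -1.0, -1.0]]))
        out = pp.rectify(rec)
        np.testing.assert_array_equal(out.signal[0], [1, 2, 3])
        np.testing.assert_array_equal(out.signal[1], [1, 1, 1])
        again = pp.rectify(out)
        np.testing.assert_array_equal(again.signal, out.signal)


class TestEnvelope:
    def test_dc_gain_unity(self, make_rec):
        out = pp.envelope(make_rec(np.full((2, 8000), 2.5)))
        interior = out.signal[:, 1000:-1000]
        np.testing.assert_allclose(interior, 2.5, rtol=0.01)

    def test_rectified_tone_mean(self, make_rec):
        """|A sin| has mean 2A/pi; the 10 Hz low-pass should recover it."""
        A = 3.0
        rec = make_rec(np.abs(np.vstack([_sine(100.0, amp=A)] * 2)))
        out = pp.envelope(rec)
        interior = out.signal[0, 2000:-2000]
        assert interior.mean() == pytest.approx(2 * A / np.pi, rel=0.02)
        assert interior.std() < 0.05 * interior.mean()

    def test_output_non_negative(self, make_rec, rng):
        rec = make_rec(np.abs(rng.normal(size=(2, 4000))))
        out = pp.envelope(rec)
        assert out.signal.min() >= 0.0


class TestPeakNormalize:
    def test_inter_muscle_scale_removed(self, make_rec):
        sig = np.vstack([5.0 * np.abs(_sine(2.0, dur=1.0)),
                         50.0 * np.abs(_sine(2.0, dur=1.0))])
        out = pp.peak_normalize(make_rec(sig))
        np.testing.assert_allclose(out.signal.max(axis=1), 1.0)

    def test_idempotent(self, make_rec, rng):
        rec = make_rec(np.abs(rng.normal(size=(3, 500))))
        once = pp.peak_normalize(rec)
        twice = pp.peak_normalize(once)
        np.testing.assert_allclose(once.signal, twice.signal)

    def test_zero_channel_named(self, make_rec):
        sig = np.vstack([np.ones(100), np.zeros(100)])
        with pytest.raises(ValueError, match="ch1"):
            pp.peak_normalize(make_rec(sig))


class TestSegmentation:
    def test_exactly_101_points_per_phase(self, make_rec, simple_events, rng):
        rec = make_rec(rng.random(size=(3, int(1.4 * FS))))
        cycles = pp.segment_and_time_normalize(rec, simple_events)
        mat, fr = cycles[0]
        assert mat.shape == (3, 404)
        assert fr.shape == (404,)

    def test_linear_ramp_exact(self, make_rec, simple_events):
        n = int(1.4 * FS)
        ramp = np.linspace(0.0, 1.0, n)
        rec = make_rec(np.vstack([ramp, 2 * ramp]))
        (mat, fr), = pp.segment_and_time_normalize(rec, simple_events)
        # linear interpolation reproduces a linear signal exactly
        t_expected = fr * (1.4 - 1 / FS) / 1.4  # sample times span [0, (n-1)/fs]
        np.testing.assert_allclose(mat[0], np.interp(fr * 1.4, np.arange(n) / FS, ramp),
                                   atol=1e-9)
        assert np.all(np.diff(fr) >= -1e-12)

    def test_fraction_map_boundaries(self, make_rec, simple_events, rng):
        rec = make_rec(rng.random(size=(2, int(1.4 * FS))))
        (_, fr), = pp.segment_and_time_normalize(rec, simple_events)
        assert fr[0] == 0.0
        assert fr[-1] == pytest.approx(1.0)
        # block boundaries at the cumulative phase fractions of a 1.4 s cycle
        assert fr[100] == pytest.approx(0.4 / 1.4)
        assert fr[201] == pytest.approx(0.6 / 1.4)
        assert fr[302] == pytest.approx(0.9 / 1.4)

    def test_short_phase_rejected(self, make_rec):
        events = CycleEvents(pd.DataFrame({
            "cycle": [1] * 4,
            "phase": list(PHASES),
            "start_s": [0.0, 0.0002, 0.6, 0.9],
            "end_s": [0.0002, 0.6, 0.9, 1.4],
        }))
        rec = make_rec(np.random.default_rng(0).random((2, int(1.4 * FS))))
        with pytest.raises(ValueError, match="shorter"):
            pp.segment_and_time_normalize(rec, events)


class TestEnsemble:
    def test_middle_three_of_five(self):
        assert pp.select_cycles(5) == [1, 2, 3]
        assert pp.select_cycles(2) == [0, 1]
        assert pp.select_cycles(7, "all") == list(range(7))

    def test_identical_cycles_unchanged(self, rng):
        mat = rng.random((3, 404))
        fr = np.linspace(0, 1, 404)
        out = pp.ensemble_average([(mat.copy(), fr)] * 5, ["a", "b", "c"])
        np.testing.assert_allclose(out.values, mat)

    def test_mean_of_two(self, rng):
        a = rng.random((2, 404))
        b = rng.random((2, 404))
        fr = np.linspace(0, 1, 404)
        out = pp.ensemble_average([(a, fr), (b, fr)], ["x", "y"])
        np.testing.assert_allclose(out.values, (a + b) / 2)

    def test_shape_mismatch(self, rng):
        fr = np.linspace(0, 1, 404)
        with pytest.raises(ValueError, match="shape"):
            pp.ensemble_average(
                [(rng.random((2, 404)), fr), (rng.random((2, 400)), fr[:400])],
                ["x", "y"],
            )


class TestTimeDomainFeatures:
    def test_iemg_unit_rectangle(self):
        assert pp.compute_iemg(np.ones(2000), fs=2000.0) == pytest.approx(1.0)

    def test_iemg_small_example(self):
        assert pp.compute_iemg(np.array([1.0, -2.0, 3.0]), fs=2000.0) == pytest.approx(
            6 / 2000
        )

    def test_iemg_matches_brute_force(self, rng):
        x = rng.normal(size=777)
        brute = sum(abs(v) * (1 / FS) for v in x)
        assert pp.compute_iemg(x, FS) == pytest.approx(brute)

    def test_rms_examples(self):
        assert pp.compute_rms(np.full(10, -4.0)) == pytest.approx(4.0)
        assert pp.compute_rms(np.array([3.0, -4.0])) == pytest.approx(np.sqrt(12.5))
        assert pp.compute_rms(_sine(10.0, dur=1.0, amp=2.0)) == pytest.approx(
            2.0 / np.sqrt(2), rel=1e-3
        )

    def test_empty_segment(self):
        with pytest.raises(ValueError):
            pp.compute_iemg(np.array([]), FS)
        with pytest.raises(ValueError):
            pp.compute_rms(np.array([]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(10, 200), st.integers(1, 9))
    def test_iemg_additive_over_subsegments(self, n, cut_frac):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        cut = max(1, n * cut_frac // 10)
        whole = pp.compute_iemg(x, FS)
        parts = pp.compute_iemg(x[:cut], FS) + pp.compute_iemg(x[cut:], FS)
        assert whole == pytest.approx(parts)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(-10, 10, allow_nan=False), st.integers(5, 50))
    def test_rms_scale_equivariant(self, a, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        assert pp.compute_rms(a * x) == pytest.approx(abs(a) * pp.compute_rms(x),
                                                      abs=1e-9)

    def test_feature_table_schema(self, make_rec, simple_events, rng):
        rec = make_rec(rng.normal(size=(2, int(1.4 * FS))))
        df = pp.time_domain_features(rec, simple_events)
        assert len(df) == 2 * 4  # muscles x phases
        assert (df["iemg_uvs"] >= 0).all()
        assert (df["rms_uv"] >= 0).all()


class TestFullChain:
    def test_deterministic_and_order_preserving(self, make_rec, simple_events, rng):
        sig = rng.normal(size=(3, int(1.4 * FS)))
        rec = make_rec(sig)
        env1 = pp.extract_envelope_matrix(rec, simple_events)
        env2 = pp.extract_envelope_matrix(make_rec(sig.copy()), simple_events)
        np.testing.assert_array_equal(env1.values, env2.values)
        assert env1.muscle_labels == rec.muscle_labels
        assert env1.values.shape == (3, 404)
        assert env1.values.min() >= 0
        assert env1.values.max() <= 1.0 + 1e-9
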