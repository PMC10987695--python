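"""The acoustic feature battery: block ledger, hand-computed values,
signal-level sanity properties, and the full-table builder."""

import numpy as np
import pytest

import segvoice as sv
from segvoice import _dsp
from segvoice.features import (
    BLOCK_ORDER,
    FrameSpec,
    binwise_var_mean,
    expected_block_sizes,
    f0_and_voiced,
    feature_matrix,
    feature_time_map,
    framewise_scalars,
    hpss_variance,
    tonal_blocks,
    windowed_variance,
)

TABLE_SIZES = {
    "raw_variance": 1_200,
    "hpss_variance": 2_400,
    "flatness": 47,
    "centroid": 47,
    "f0": 47,
    "voiced": 94,
    "rolloff": 94,
    "bandwidth": 47,
    "zcr": 47,
    "rms": 47,
    "contrast": 188,
    "tonnetz": 282,
    "chroma": 564,
    "pitch_track": 2_050,
    "pitch_mag": 2_050,
    "magnitude": 2_050,
    "phase": 2_050,
    "mfcc": 940,
}


class TestBlockLedger:
    def test_declared_sizes_sum_to_total(self):
        assert sum(TABLE_SIZES.values()) == 14_244

    def test_formulas_reproduce_declared_sizes(self):
        assert expected_block_sizes(24_000) == TABLE_SIZES

    def test_full_vector_has_14244_entries(self, anger_segment):
        fv = sv.extract_feature_vector(anger_segment)
        assert len(fv) == 14_244
        assert list(fv.blocks) == list(BLOCK_ORDER)
        for name, size in TABLE_SIZES.items():
            assert fv.blocks[name].size == size

    def test_three_second_window_scales_by_formula(self):
        sizes = expected_block_sizes(48_000)
        assert sizes["raw_variance"] == 2_400
        assert sizes["flatness"] == 1 + 48_000 // 512 == 94
        seg = sv.synth_segment("joy", sv.SynthConfig(duration=3.0, seed=1), 0)
        fv = sv.extract_feature_vector(seg)
        assert len(fv) == sum(sizes.values())

    def test_frame_count_law(self):
        assert _dsp.n_frames_for(24_000) == 47
        assert _dsp.n_frames_for(48_000) == 94
        assert _dsp.n_frames_for(80_000) == 157  # 5 s at 16 kHz


class TestWindowedVariance:
    def test_24000_samples_give_1200_values(self):
        assert windowed_variance(np.random.default_rng(0).uniform(size=24_000)).size == 1_200

    def test_constant_input_is_all_zero(self):
        out = windowed_variance(np.full(24_000, 0.3))
        np.testing.assert_allclose(out, 0, atol=1e-30)  # exact up to float residue

    def test_hand_computed_two_point_windows(self):
        np.testing.assert_allclose(
            windowed_variance(np.array([0.0, 1.0, 0.0, 1.0]), win=2), [0.25, 0.25]
        )

    def test_non_divisible_length_raises(self):
        with pytest.raises(ValueError, match="24001"):
            windowed_variance(np.zeros(24_001))


class TestBinwiseVarMean:
    def test_hand_computed(self):
        m = np.array([[1.0, 3.0], [2.0, 2.0]])
        np.testing.assert_allclose(binwise_var_mean(m, n_bins=2), [1.0, 0.0, 2.0, 2.0])

    def test_constant_matrix(self):
        m = np.full((1025, 47), 7.0)
        out = binwise_var_mean(m)
        assert np.all(out[:1025] == 0) and np.all(out[1025:] == 7.0)

    def test_wrong_row_count_raises(self):
        with pytest.raises(ValueError, match="1025"):
            binwise_var_mean(np.zeros((100, 47)))


class TestFramewiseScalars:
    def test_block_lengths(self, anger_segment):
        scalars = framewise_scalars(anger_segment)
        for name in ("flatness", "centroid", "bandwidth", "zcr", "rms"):
            assert scalars[name].size == 47
        assert scalars["rolloff"].size == 94

    def test_centroid_of_pure_sine(self, sine_segment):
        centroid = framewise_scalars(sine_segment)["centroid"]
        bin_width = 16_000 / 2_048
        interior = centroid[5:-5]
        assert np.all(np.abs(interior - 440.0) < 2 * bin_width)

    def test_rolloff_ordering_and_silence(self, sine_segment, silence_segment):
        roll = framewise_scalars(sine_segment)["rolloff"]
        assert np.all(roll[:47] >= roll[47:])  # 85% curve sits above 15% curve
        assert np.all(framewise_scalars(silence_segment)["rolloff"] == 0)

    def test_rms_scales_linearly_and_zcr_is_scale_free(self, anger_segment):
        doubled = sv.AudioSegment(samples=0.5 * anger_segment.samples, rate=16_000)
        s1 = framewise_scalars(anger_segment)
        s2 = framewise_scalars(doubled)
        np.testing.assert_allclose(s2["rms"], 0.5 * s1["rms"], rtol=1e-9)
        np.testing.assert_array_equal(s2["zcr"], s1["zcr"])


class TestVoicing:
    def test_200hz_harmonic_voice_recovered(self):
        t = np.arange(24_000) / 16_000
        x = sum((1.0 / k) * np.sin(2 * np.pi * 200.0 * k * t) for k in range(1, 7))
        seg = sv.AudioSegment(samples=x / np.abs(x).max(), rate=16_000)
        out = f0_and_voiced(seg)
        interior = out["f0"][5:-5]
        assert np.all((interior > 190) & (interior < 210))
        assert out["voiced"].size == 94

    def test_silence_is_unvoiced(self, silence_segment):
        out = f0_and_voiced(silence_segment)
        assert np.all(out["f0"] == 0)
        assert np.all(out["voiced"] == 0)

    def test_probability_bounded(self, anger_segment):
        prob = f0_and_voiced(anger_segment)["voiced"][47:]
        assert np.all((prob >= 0) & (prob <= 1))


class TestHpssAndTonal:
    def test_hpss_lengths(self, anger_segment):
        assert hpss_variance(anger_segment).size == 2_400

    def test_stationary_sine_is_mostly_harmonic(self, sine_segment):
        out = hpss_variance(sine_segment)
        harmonic, percussive = out[:1_200], out[1_200:]
        assert percussive.sum() < 0.1 * (harmonic.sum() + percussive.sum())

    def test_silence_gives_zero_variance(self, silence_segment):
        assert np.allclose(hpss_variance(silence_segment), 0, atol=1e-12)

    def test_tonal_block_sizes(self, anger_segment):
        tonal = tonal_blocks(anger_segment)
        assert {k: v.size for k, v in tonal.items()} == {
            "contrast": 188, "tonnetz": 282, "chroma": 564, "mfcc": 940,
        }

    def test_white_noise_chroma_is_roughly_uniform(self):
        rng = np.random.default_rng(42)
        seg = sv.AudioSegment(samples=rng.standard_normal(24_000) * 0.1, rate=16_000)
        chroma = tonal_blocks(seg)["chroma"].reshape(12, 47)
        row_means = chroma.mean(axis=1)
        assert row_means.max() / row_means.min() < 2.0

    def test_silence_mfcc_constant_over_time(self, silence_segment):
        mfcc = tonal_blocks(silence_segment)["mfcc"].reshape(20, 47)
        assert np.allclose(mfcc.var(axis=1), 0, atol=1e-12)

    def test_chroma_shape_is_amplitude_invariant(self, anger_segment):
        halved = sv.AudioSegment(samples=0.5 * anger_segment.samples, rate=16_000)
        c1 = tonal_blocks(anger_segment)["chroma"]
        c2 = tonal_blocks(halved)["chroma"]
        np.testing.assert_allclose(c1, c2, atol=1e-9)


class TestAssembly:
    def test_determinism(self, anger_segment):
        v1 = sv.extract_feature_vector(anger_segment).values
        v2 = sv.extract_feature_vector(anger_segment).values
        np.testing.assert_array_equal(v1, v2)

    def test_all_finite_even_for_silence(self, silence_segment):
        values = sv.extract_feature_vector(silence_segment).values
        assert values.size == 14_244 and np.all(np.isfinite(values))

    def test_wrong_length_raises(self):
        seg = sv.AudioSegment(samples=np.zeros(10_001), rate=16_000)
        with pytest.raises(ValueError):
            sv.extract_feature_vector(seg)

    def test_feature_matrix_counts_and_determinism(self, tiny_dataset_dir):
        _, manifest = tiny_dataset_dir
        df1 = feature_matrix(manifest)
        assert df1.shape == (18, 14_245)  # 14,244 features + label column
        df2 = feature_matrix(manifest)
        assert df1.drop(columns="label").equals(df2.drop(columns="label"))
        assert list(df1["label"]) == [r.label for r in manifest]


class TestTimeMap:
    def test_covers_all_features_and_48_segments(self):
        fmap = feature_time_map(24_000)
        assert fmap.size == 14_244
        timed = fmap[fmap >= 0]
        assert set(np.unique(timed)) == set(range(48))

    def test_binwise_summaries_have_no_time_location(self):
        fmap = feature_time_map(24_000)
        sizes = expected_block_sizes(24_000)
        offset = sum(sizes[b] for b in BLOCK_ORDER[: BLOCK_ORDER.index("pitch_track")])
        untimed = fmap[offset : offset + 4 * 2_050]
        assert np.all(untimed == -1)
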