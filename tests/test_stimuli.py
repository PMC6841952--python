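"""Stimulus construction: levels, crossfades, geometry, contours, masker search."""

import numpy as np
import pytest

from soundtexture import (
    AudioSignal,
    ContourShape,
    StimulusSpec,
    apply_contour,
    build_2afc_detection_trial,
    build_interrupted_stimulus,
    crossfade_concat,
    find_masker_level,
    set_level,
)
from soundtexture.stimuli import _ramp, masker_difference_curve

RATE = 48_000


def noise(duration, seed=0, rms=0.1):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(round(duration * RATE)))
    return AudioSignal(x * rms / np.sqrt(np.mean(x**2)), RATE)


class TestSetLevel:
    def test_zero_db_gives_unit_rms(self):
        out = set_level(noise(1.0), 0.0)
        assert out.rms() == pytest.approx(1.0, abs=1e-9)

    def test_plus_6db_amplitude_ratio(self):
        a = set_level(noise(1.0), 0.0)
        b = set_level(a, 6.0)
        assert b.rms() / a.rms() == pytest.approx(10 ** (6 / 20), rel=1e-9)

    def test_idempotent(self):
        once = set_level(noise(1.0), -12.0)
        twice = set_level(once, -12.0)
        assert np.allclose(once.samples, twice.samples)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            set_level(AudioSignal(np.zeros(100), RATE), 0.0)


class TestCrossfade:
    def test_ramps_are_complementary(self):
        r = _ramp(960)
        assert np.allclose(r + r[::-1], 1.0, atol=1e-12)

    def test_experiment_geometry_sample_exact(self):
        segs = [noise(2.01, seed=1), noise(2.02, seed=2), noise(1.01, seed=3)]
        out = crossfade_concat(segs, ramp_ms=20)
        assert out.n_samples == 5 * RATE  # exactly 5.000 s
        # crossfade midpoints at 2 s and 4 s: the first segment's fade-out
        # starts 960 samples before sample 96480, centred on sample 96000
        ramp = int(0.02 * RATE)
        first_overlap_start = segs[0].n_samples - ramp
        assert first_overlap_start + ramp // 2 == 2 * RATE
        second_overlap_start = segs[0].n_samples + segs[1].n_samples - 2 * ramp
        assert second_overlap_start + ramp // 2 == 4 * RATE

    def test_single_segment_unchanged(self):
        s = noise(1.0)
        assert crossfade_concat([s]) is s

    def test_constant_segments_join_seamlessly(self):
        a = AudioSignal(np.ones(RATE), RATE)
        b = AudioSignal(np.ones(RATE), RATE)
        out = crossfade_concat([a, b], ramp_ms=20)
        assert np.allclose(out.samples, 1.0, atol=1e-12)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="ramp"):
            crossfade_concat([noise(1.0), AudioSignal(np.ones(100), RATE)], 20)


class TestInterruptedStimulus:
    def test_default_geometry_masks_inducer(self):
        inducer = noise(5.0, seed=1)
        masker = noise(2.1, seed=2)
        spec = StimulusSpec(snr_db=-10)
        out = build_interrupted_stimulus(inducer, masker, spec)
        assert out.n_samples == 5 * RATE
        # strictly inside the masker (excluding the crossfades) the inducer
        # waveform contributes nothing: the output there is a scaled copy of
        # the masker
        lo = int(round(2.05 * RATE))
        hi = int(round(3.95 * RATE))
        pre_len = int(round(2.01 * RATE))
        mask_scaled = set_level(
            AudioSignal(masker.samples[:int(round(2.02 * RATE))], RATE), 10.0)
        start_in_masker = lo - (pre_len - int(round(0.02 * RATE)))
        segment = out.samples[lo:hi]
        expected = mask_scaled.samples[start_in_masker:start_in_masker + len(segment)]
        assert np.allclose(segment, expected, atol=1e-12)

    def test_gaps_flank_the_masker(self):
        inducer = noise(5.0, seed=3)
        masker = noise(2.1, seed=4)
        spec = StimulusSpec(snr_db=-10, gap_before=True, gap_after=True)
        out = build_interrupted_stimulus(inducer, masker, spec)
        pre_len = int(round(2.01 * RATE))
        gap = int(round(0.2 * RATE))
        # first 200 ms of the masker region (after the pre-segment fade) silent
        ramp = int(round(0.02 * RATE))
        gap1 = out.samples[pre_len:pre_len - ramp + gap]
        assert np.max(np.abs(gap1)) < 1e-12
        mask_end = pre_len - ramp + int(round(2.02 * RATE))
        gap2 = out.samples[mask_end - gap:mask_end - ramp]
        assert np.max(np.abs(gap2)) < 1e-12
        # masker core between gaps is loud
        core = out.samples[pre_len + gap + ramp:mask_end - gap - ramp]
        assert np.sqrt(np.mean(core**2)) > 1.0

    def test_control_superimposes_inducer_above_masker(self):
        inducer = noise(5.0, seed=5)
        masker = noise(2.1, seed=6)
        plain = build_interrupted_stimulus(
            inducer, masker, StimulusSpec(snr_db=6, control=True, superimpose=True,
                                          control_snr_db=6))
        absent = build_interrupted_stimulus(inducer, masker, StimulusSpec(snr_db=6))
        mid = slice(int(2.5 * RATE), int(3.5 * RATE))
        diff = plain.samples[mid] - absent.samples[mid]
        # the residual is the physically present inducer at +6 dB re the masker
        masker_rms = np.sqrt(np.mean(absent.samples[mid] ** 2))
        resid_rms = np.sqrt(np.mean(diff**2))
        assert 20 * np.log10(resid_rms / masker_rms) == pytest.approx(6.0, abs=1.0)

    def test_superimpose_without_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            build_interrupted_stimulus(noise(5.0), noise(2.1),
                                       StimulusSpec(superimpose=True))


class TestContours:
    def test_absent_yields_masker_alone(self):
        tex, mask = noise(2.0, seed=1), noise(2.0, seed=2)
        out = apply_contour(tex, "absent", mask)
        assert np.array_equal(out.samples, mask.samples)

    def test_continuous_preserves_texture_level(self):
        tex, mask = noise(2.0, seed=3), noise(2.0, seed=4)
        out = apply_contour(tex, "continuous", mask)
        resid = out.samples - mask.samples
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(tex.rms(), rel=1e-9)

    def test_dip_suppresses_center(self):
        tex, mask = noise(2.0, seed=5), noise(2.0, seed=6)
        out = apply_contour(tex, "dip", mask)
        resid = out.samples - mask.samples
        n = len(resid)
        edge_rms = np.sqrt(np.mean(resid[: n // 10] ** 2))
        center = resid[int(0.45 * n):int(0.55 * n)]
        center_rms = np.sqrt(np.mean(center**2))
        assert 20 * np.log10(center_rms / edge_rms) <= -20

    def test_envelope_bounds_and_shapes(self):
        for name in ("continuous", "fade-out", "dip", "glimpse", "fade-in", "absent"):
            env = ContourShape(name).envelope(800)
            assert env.min() >= 0 and env.max() <= 1

    def test_unknown_contour_rejected(self):
        with pytest.raises(ValueError, match="unknown contour"):
            ContourShape("wiggle")


class TestDetectionTrial:
    def test_reproducible_for_fixed_seed(self):
        tex = noise(2.0, seed=7)
        a1, b1, ans1 = build_2afc_detection_trial(tex, -6.0, seed=11)
        a2, b2, ans2 = build_2afc_detection_trial(tex, -6.0, seed=11)
        assert ans1 == ans2
        assert np.array_equal(a1.samples, a2.samples)

    def test_high_snr_target_detectable_by_energy(self):
        tex = noise(2.0, seed=8)
        i1, i2, ans = build_2afc_detection_trial(tex, 60.0, seed=1)
        energies = [i1.rms(), i2.rms()]
        assert int(np.argmax(energies)) == ans

    def test_unique_noise_across_trials(self):
        tex = noise(2.0, seed=9)
        waves = []
        for seed in range(4):
            i1, i2, _ = build_2afc_detection_trial(tex, -6.0, seed=seed)
            waves += [i1.samples, i2.samples]
        for i in range(len(waves)):
            for j in range(i + 1, len(waves)):
                assert not np.array_equal(waves[i], waves[j])


class TestMaskerLevelSearch:
    @pytest.fixture(scope="class")
    def pair(self):
        return noise(2.0, seed=20), noise(2.0, seed=21)

    def test_difference_monotone_in_masker_level(self, pair):
        inducer, masker = pair
        grid = np.arange(-30.0, 30.5, 5.0)
        diffs = masker_difference_curve(inducer, masker, grid)
        assert np.all(np.diff(diffs) >= -1e-6)  # rises with SNR (quieter masker)

    def test_returned_level_is_boundary_on_half_db_grid(self, pair):
        inducer, masker = pair
        res = find_masker_level(inducer, masker, criterion_db=3.0)
        diffs = masker_difference_curve(inducer, masker,
                                        np.array([res.snr_db, res.snr_db + 0.5]))
        assert diffs[0] <= 3.0 < diffs[1]

    def test_silent_inducer_degenerate(self, pair):
        _, masker = pair
        res = find_masker_level(AudioSignal(np.zeros(2 * RATE), RATE), masker)
        assert res.degenerate
        assert res.snr_db == 30.0
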