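"""Texture statistics vs an independent loop-based oracle, plus vector ops."""

import numpy as np
import pytest

from soundtexture import (
    average_statistics,
    compute_envelope_correlations,
    compute_envelope_moments,
    compute_modulation_correlations,
    compute_modulation_power,
    interpolate_statistics,
    measure_texture_statistics,
    zscore_statistics,
    MORPH_GRID,
)
from soundtexture.frontend import EnvelopeSet, ModulationSet
from soundtexture.stats import (
    MOD_CORR_BANDS,
    MOD_CORR_OFFSETS,
    statistics_from_envelopes,
    uniform_window,
)

from conftest import am_noise


# --------------------------------------------------------------------------
# independent oracle: plain Python loops over time, straight from the
# weighted-moment definitions


def oracle_moments(env, w):
    K, T = env.shape
    mu = np.zeros(K)
    var = np.zeros(K)
    m3 = np.zeros(K)
    for k in range(K):
        for t in range(T):
            mu[k] += w[t] * env[k, t]
        for t in range(T):
            var[k] += w[t] * (env[k, t] - mu[k]) ** 2
            m3[k] += w[t] * (env[k, t] - mu[k]) ** 3
    cv2 = var / mu**2
    skew = m3 / var**1.5
    return mu, cv2, skew, var


def oracle_env_corr(env, w):
    K = env.shape[0]
    mu, _, _, var = oracle_moments(env, w)
    out = []
    for d in range(1, 9):
        for j in range(K - d):
            k = j + d
            cov = sum(w[t] * (env[j, t] - mu[j]) * (env[k, t] - mu[k])
                      for t in range(env.shape[1]))
            out.append(cov / np.sqrt(var[j] * var[k]))
    return np.array(out)


def oracle_mod_power(bands, env, w):
    K, N, T = bands.shape
    _, _, _, var_env = oracle_moments(env, w)
    out = np.zeros((K, N))
    for k in range(K):
        for n in range(N):
            mu = sum(w[t] * bands[k, n, t] for t in range(T))
            v = sum(w[t] * (bands[k, n, t] - mu) ** 2 for t in range(T))
            out[k, n] = v / var_env[k]
    return out


def oracle_mod_corr(bands, w):
    K, N, T = bands.shape
    mu = np.zeros((K, N))
    var = np.zeros((K, N))
    for k in range(K):
        for n in range(N):
            mu[k, n] = sum(w[t] * bands[k, n, t] for t in range(T))
            var[k, n] = sum(w[t] * (bands[k, n, t] - mu[k, n]) ** 2 for t in range(T))
    out = []
    for b in MOD_CORR_BANDS:
        if b > N:
            continue
        n = b - 1
        for d in MOD_CORR_OFFSETS:
            for j in range(K - d):
                k = j + d
                cov = sum(w[t] * (bands[j, n, t] - mu[j, n]) * (bands[k, n, t] - mu[k, n])
                          for t in range(T))
                out.append(cov / np.sqrt(var[j, n] * var[k, n]))
    return np.array(out)


@pytest.fixture(scope="module")
def random_model_outputs():
    rng = np.random.default_rng(7)
    K, N, T = 34, 18, 60
    env = np.abs(rng.standard_normal((K, T))) + 0.05
    bands = rng.standard_normal((K, N, T))
    w = rng.random(T)
    w /= w.sum()
    return env, bands, w


class TestOracleEquivalence:
    def test_moments_match_oracle(self, random_model_outputs):
        env, _, w = random_model_outputs
        mu, cv2, skew, _ = oracle_moments(env, w)
        m, c, s, flags = compute_envelope_moments(EnvelopeSet(env, 400.0), w)
        assert not flags.any()
        assert np.allclose(m, mu, atol=1e-12, rtol=0)
        assert np.allclose(c, cv2, atol=1e-12, rtol=0)
        assert np.allclose(s, skew, atol=1e-12, rtol=0)

    def test_envelope_correlations_match_oracle(self, random_model_outputs):
        env, _, w = random_model_outputs
        expected = oracle_env_corr(env, w)
        got, bad = compute_envelope_correlations(EnvelopeSet(env, 400.0), w)
        assert not bad.any()
        assert np.allclose(got, expected, atol=1e-12, rtol=0)

    def test_modulation_power_matches_oracle(self, random_model_outputs):
        env, bands, w = random_model_outputs
        expected = oracle_mod_power(bands, env, w)
        mods = ModulationSet(bands, np.arange(18) + 1.0, 400.0)
        got, bad = compute_modulation_power(mods, EnvelopeSet(env, 400.0), w)
        assert not bad.any()
        assert np.allclose(got, expected, atol=1e-12, rtol=0)

    def test_modulation_correlations_match_oracle(self, random_model_outputs):
        env, bands, w = random_model_outputs
        expected = oracle_mod_corr(bands, w)
        mods = ModulationSet(bands, np.arange(18) + 1.0, 400.0)
        got, bad = compute_modulation_correlations(mods, w)
        assert not bad.any()
        assert np.allclose(got, expected, atol=1e-12, rtol=0)


class TestHandValues:
    def test_small_envelope_moments(self):
        env = np.array([[1.0, 2.0, 3.0, 4.0]])
        w = uniform_window(4)
        mu, cv2, skew, flags = compute_envelope_moments(EnvelopeSet(env, 400.0), w)
        assert mu[0] == pytest.approx(2.5)
        assert cv2[0] == pytest.approx(1.25 / 6.25)  # var 1.25, mean^2 6.25
        assert skew[0] == pytest.approx(0.0, abs=1e-12)  # symmetric

    def test_constant_envelope_degenerate(self):
        env = np.full((1, 10), 3.0)
        mu, cv2, skew, flags = compute_envelope_moments(EnvelopeSet(env, 400.0))
        assert mu[0] == pytest.approx(3.0)
        assert cv2[0] == 0.0 and skew[0] == 0.0
        assert flags[0]

    def test_perfect_anti_and_self_correlation(self):
        env = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1], [1.0, 2, 3, 4]])
        got, _ = compute_envelope_correlations(EnvelopeSet(env, 400.0))
        # pairs at offset 1: (0,1), (1,2); offset 2: (0,2)
        assert got[0] == pytest.approx(-1.0)
        assert got[1] == pytest.approx(-1.0)
        assert got[2] == pytest.approx(1.0)

    def test_identical_modulation_bands_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal(50)
        bands = np.tile(one, (3, 13, 1))
        mods = ModulationSet(bands, np.arange(13) + 1.0, 400.0)
        got, _ = compute_modulation_correlations(mods)
        assert np.allclose(got, 1.0)

    def test_mod_power_unity_when_band_equals_centered_envelope(self):
        rng = np.random.default_rng(1)
        env = np.abs(rng.standard_normal((2, 40))) + 0.1
        w = uniform_window(40)
        centered = env - (env @ w)[:, None]
        bands = centered[:, None, :]
        mods = ModulationSet(bands, np.array([1.0]), 400.0)
        got, _ = compute_modulation_power(mods, EnvelopeSet(env, 400.0), w)
        assert np.allclose(got, 1.0)


class TestFullMeasurement:
    def test_flattened_length_and_partition(self, white_noise_1s):
        stats = measure_texture_statistics(white_noise_1s)
        assert len(stats) == 1340
        slices = stats.class_slices()
        # partitions disjoint and exhaustive
        stops = [s.stop for s in slices.values()]
        starts = [s.start for s in slices.values()]
        assert starts == [0] + stops[:-1]
        assert stops[-1] == 1340

    def test_gain_scaling_law(self, white_noise_1s):
        base = measure_texture_statistics(white_noise_1s)
        from soundtexture import AudioSignal

        scaled = measure_texture_statistics(
            AudioSignal(white_noise_1s.samples * 10.0, 48_000))
        assert np.allclose(scaled.env_mean, base.env_mean * 10**0.3, rtol=1e-6)
        for name in ("env_cv2", "env_skew", "env_corr", "mod_corr", "mod_power"):
            assert np.allclose(scaled.classes()[name], base.classes()[name],
                               rtol=1e-6, atol=1e-9), name

    def test_gaussian_noise_has_small_skewness(self, white_noise_5s):
        # Compressed envelopes of stationary Gaussian noise are nearly
        # symmetric.  The estimator's sampling error grows as channel
        # bandwidth shrinks (few independent envelope samples in 5 s for the
        # narrow low-frequency channels), so the strict bound applies to the
        # wideband channels and a looser one to the full set.
        stats = measure_texture_statistics(white_noise_5s)
        assert np.all(np.abs(stats.env_skew[10:]) < 0.3)
        assert np.all(np.abs(stats.env_skew) < 0.6)
        assert np.median(np.abs(stats.env_skew)) < 0.15

    def test_deterministic(self, white_noise_1s):
        a = measure_texture_statistics(white_noise_1s)
        b = measure_texture_statistics(white_noise_1s)
        assert np.array_equal(a.flatten(), b.flatten())

    def test_circular_shift_stability(self):
        sig = am_noise(duration=5.0, seed=11)
        shifted = type(sig)(np.roll(sig.samples, sig.n_samples // 3), sig.rate)
        a = measure_texture_statistics(sig)
        b = measure_texture_statistics(shifted)
        for name, va in a.classes().items():
            vb = b.classes()[name]
            rel = np.linalg.norm(va - vb) / np.linalg.norm(va)
            assert rel < 0.05, f"{name}: {rel:.3f}"


class TestVectorOps:
    def _random_stats(self, seed, n=2):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            env = np.abs(rng.standard_normal((34, 50))) + 0.05
            bands = rng.standard_normal((34, 18, 50))
            envs = EnvelopeSet(env, 400.0)
            mods = ModulationSet(bands, np.arange(18) + 1.0, 400.0)
            out.append(statistics_from_envelopes(envs, mods))
        return out

    def test_average_matches_direct_mean(self):
        stats = self._random_stats(3, n=50)
        avg = average_statistics(stats)
        direct = np.mean([s.flatten() for s in stats], axis=0)
        assert np.allclose(avg.flatten(), direct, atol=1e-12)

    def test_average_of_identical_is_identity(self):
        s = self._random_stats(4, n=1)[0]
        # equal up to the one-ulp rounding of summation
        assert np.allclose(average_statistics([s, s, s]).flatten(), s.flatten(),
                           rtol=1e-14, atol=0)

    def test_average_of_two_is_midpoint(self):
        a, b = self._random_stats(5)
        avg = average_statistics([a, b])
        mid = interpolate_statistics(a, b, 0.5)
        assert np.allclose(avg.flatten(), mid.flatten(), atol=1e-12)

    def test_interpolation_endpoints(self):
        a, b = self._random_stats(6)
        assert np.allclose(interpolate_statistics(a, b, 0.0).flatten(),
                           a.flatten(), atol=1e-15)
        f1 = interpolate_statistics(a, b, 1.0)
        assert np.allclose(f1.env_mean, b.env_mean)
        assert np.allclose(f1.mod_power, b.mod_power)

    def test_morph_grid_preset(self):
        assert MORPH_GRID == (0.0, 0.25, 0.35, 0.4, 0.45, 0.55, 0.6, 0.65, 0.75, 1.0)

    def test_pin_env_mean(self):
        a, b = self._random_stats(7)
        out = interpolate_statistics(a, b, 0.8, pin_env_mean=True)
        assert np.array_equal(out.env_mean, a.env_mean)
        assert np.allclose(out.env_cv2, 0.2 * a.env_cv2 + 0.8 * b.env_cv2)

    def test_fraction_out_of_range_rejected(self):
        a, b = self._random_stats(8)
        with pytest.raises(ValueError):
            interpolate_statistics(a, b, 1.5)

    def test_zscore_columns_standardised(self):
        stats = self._random_stats(9, n=12)
        zs, record = zscore_statistics(stats)
        mat = np.stack(zs)
        assert np.allclose(mat.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(mat.std(axis=0), 1.0, atol=1e-10)

    def test_zscore_matches_bruteforce(self):
        stats = self._random_stats(10, n=6)
        zs, record = zscore_statistics(stats)
        mat = np.stack([s.flatten() for s in stats])
        expected = (mat - mat.mean(0)) / mat.std(0)
        assert np.allclose(np.stack(zs), expected, atol=1e-12)

    def test_zscore_needs_two(self):
        s = self._random_stats(11, n=1)
        with pytest.raises(ValueError):
            zscore_statistics(s)

    def test_serialization_roundtrip(self):
        s = self._random_stats(12, n=1)[0]
        from soundtexture.stats import TextureStatistics

        back = TextureStatistics.from_json(s.to_json())
        assert np.array_equal(back.flatten(), s.flatten())

    def test_config_mismatch_rejected_on_load(self, white_noise_1s):
        s = measure_texture_statistics(white_noise_1s)
        from soundtexture.stats import TextureStatistics

        with pytest.raises(ValueError, match="configuration"):
            TextureStatistics.from_json(s.to_json(), expected_config={"rate": 44100})

    def test_csv_roundtrip(self, tmp_path, white_noise_1s):
        from soundtexture.io import save_statistics_csv, load_statistics_vector_csv

        s = measure_texture_statistics(white_noise_1s)
        path = tmp_path / "stats.csv"
        save_statistics_csv(path, s)
        vec = load_statistics_vector_csv(path)
        assert np.allclose(vec, s.flatten(), rtol=0, atol=0)
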