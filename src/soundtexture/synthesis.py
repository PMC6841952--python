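"""Statistics-imposition texture synthesis.

A target statistic vector is imposed on the cochlear envelopes of a Gaussian
noise seed by an analysis--synthesis loop: decompose the current signal,
optimise the compressed envelope matrix with L-BFGS so that its measured
statistics match the target (the objective is the per-class-normalised sum of
squared statistic errors, with analytic gradients for all six classes),
impose the optimised envelopes back on the subbands (divide each subband by
its own envelope and multiply by the optimised one, both taken through the
same decompress/upsample pathway), reconstruct, and repeat until every class
reaches the convergence criterion (error SNR, default 20 dB) or the outer
iteration cap is hit.  Seeding with different noise samples yields distinct
exemplars with matching statistics.

Morphs synthesize from statistics interpolated between a mean texture and a
reference (spectrum pinned to the mean); steps synthesize two textures, the
second seeded with the first, and splice them with rectangular windows so the
statistics change at a chosen time without a waveform discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft
from scipy.optimize import minimize
from scipy.signal import hilbert

from .frontend import (
    AudioSignal,
    EnvelopeSet,
    SubbandSet,
    TextureModel,
    DEFAULT_MODEL,
    reconstruct_waveform,
    upsample_envelopes,
)
from .stats import (
    CLASS_NAMES,
    TextureStatistics,
    env_corr_pairs,
    interpolate_statistics,
    mod_corr_triples,
    statistics_from_envelopes,
    uniform_window,
)

_SNR_CAP_DB = 300.0


@dataclass(frozen=True)
class SynthesisConfig:
    """Settings for the statistics-imposition loop.

    ``convergence_db`` is the per-class error SNR target; ``max_outer_iterations``
    caps the analysis--synthesis loop; ``inner_iterations`` caps each L-BFGS
    envelope optimisation.
    """

    duration: float = 5.0
    seed: int = 0
    max_outer_iterations: int = 60
    convergence_db: float = 20.0
    inner_iterations: int = 80
    lbfgs_memory: int = 10
    noise_rms: float = 0.1
    gain_passes: int = 2  # per-channel envelope-mean corrections per outer loop

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.convergence_db <= 0:
            raise ValueError("convergence_db must be positive")


@dataclass
class ConvergenceReport:
    """Per-class error SNR (dB) per outer iteration, plus the final verdict."""

    class_snr_db: list[dict] = field(default_factory=list)
    converged: bool = False
    iterations_used: int = 0
    convergence_db: float = 20.0

    def final_snrs(self) -> dict:
        return self.class_snr_db[-1] if self.class_snr_db else {}


def class_error_snr_db(measured: TextureStatistics, target: TextureStatistics) -> dict:
    """Error SNR per statistic class: 10*log10(sum target^2 / sum error^2)."""
    out = {}
    mc, tc = measured.classes(), target.classes()
    for name in CLASS_NAMES:
        sig = float(np.sum(tc[name] ** 2))
        err = float(np.sum((mc[name] - tc[name]) ** 2))
        if err == 0.0:
            out[name] = _SNR_CAP_DB
        elif sig == 0.0:
            out[name] = -_SNR_CAP_DB
        else:
            out[name] = min(10.0 * np.log10(sig / err), _SNR_CAP_DB)
    return out


class _Objective:
    """Normalised squared statistic error and its gradient w.r.t. envelopes.

    Envelopes enter as a (K, T) matrix of compressed envelope frames.  Each
    class's squared errors are divided by the mean squared magnitude of the
    target values in that class, so classes with different natural scales
    contribute comparably.
    """

    def __init__(self, target: TextureStatistics, model: TextureModel, n_frames: int):
        self.target = target
        self.model = model
        self.K = target.n_channels
        self.T = n_frames
        self.w = uniform_window(n_frames)
        self.mod_h = model.mod_filter_responses(n_frames)  # (N, F)
        self.N = self.mod_h.shape[0]
        self.ej, self.ek = env_corr_pairs(self.K)
        self.mj, self.mk, self.mn = mod_corr_triples(self.K, self.N)
        # per-offset chunks of the pair/triple arrays: within a chunk the j
        # (and k) indices are unique and contiguous, so gradient accumulation
        # can use slice adds instead of the much slower np.add.at
        self.e_chunks = []
        pos = 0
        for d in range(1, 9):
            if d >= self.K:
                continue
            n_pairs = self.K - d
            self.e_chunks.append((d, slice(pos, pos + n_pairs)))
            pos += n_pairs
        self.m_chunks = []
        pos = 0
        from .stats import MOD_CORR_BANDS, MOD_CORR_OFFSETS

        for b in MOD_CORR_BANDS:
            if b > self.N:
                continue
            for d in MOD_CORR_OFFSETS:
                if d >= self.K:
                    continue
                n_pairs = self.K - d
                self.m_chunks.append((b - 1, d, slice(pos, pos + n_pairs)))
                pos += n_pairs
        tc = target.classes()
        self.norms = {
            name: float(np.mean(tc[name] ** 2)) + 1e-12 for name in CLASS_NAMES
        }

    def _mod_bands(self, spec: np.ndarray) -> np.ndarray:
        return irfft(spec[:, None, :] * self.mod_h[None, :, :], n=self.T, axis=2)

    def __call__(self, x: np.ndarray):
        K, T, w = self.K, self.T, self.w
        E = x.reshape(K, T)
        t = self.target

        mu = E @ w
        d = E - mu[:, None]
        var = (d**2) @ w
        var = np.maximum(var, 1e-300)
        sd = np.sqrt(var)
        m3 = (d**3) @ w

        spec = rfft(E, axis=1)
        B = self._mod_bands(spec)  # (K, N, T)
        mu_b = B @ w
        dB = B - mu_b[..., None]
        var_b = (dB**2) @ w
        sd_b = np.sqrt(np.maximum(var_b, 1e-300))

        # --- statistic values -------------------------------------------------
        cv2 = var / np.maximum(mu, 1e-300) ** 2
        skew = m3 / sd**3
        cov_e = (d[self.ej] * d[self.ek]) @ w
        corr_e = cov_e / (sd[self.ej] * sd[self.ek])
        mod_pow = var_b / var[:, None]
        cov_b = (dB[self.mj, self.mn] * dB[self.mk, self.mn]) @ w
        corr_b = cov_b / (sd_b[self.mj, self.mn] * sd_b[self.mk, self.mn])
        # degenerate modulation bands (no energy at the band's rate, e.g. a
        # period longer than the signal) measure as zero correlation; mirror
        # that here and give them zero gradient
        deg_b = var_b <= 1e-20 * max(var_b.max(), 1e-300)
        bad_pairs = deg_b[self.mj, self.mn] | deg_b[self.mk, self.mn]
        corr_b = np.where(bad_pairs, 0.0, corr_b)

        r_mean = mu - t.env_mean
        r_cv2 = cv2 - t.env_cv2
        r_skew = skew - t.env_skew
        r_ec = corr_e - t.env_corr
        r_mp = mod_pow - t.mod_power
        r_mc = corr_b - t.mod_corr

        value = (
            np.sum(r_mean**2) / self.norms["env_mean"]
            + np.sum(r_cv2**2) / self.norms["env_cv2"]
            + np.sum(r_skew**2) / self.norms["env_skew"]
            + np.sum(r_ec**2) / self.norms["env_corr"]
            + np.sum(r_mp**2) / self.norms["mod_power"]
            + np.sum(r_mc**2) / self.norms["mod_corr"]
        )

        # --- gradient ---------------------------------------------------------
        g_mean = 2.0 * r_mean / self.norms["env_mean"]
        g_cv2 = 2.0 * r_cv2 / self.norms["env_cv2"]
        g_skew = 2.0 * r_skew / self.norms["env_skew"]
        g_ec = 2.0 * r_ec / self.norms["env_corr"]
        g_mp = 2.0 * r_mp / self.norms["mod_power"]
        g_mc = np.where(bad_pairs, 0.0, 2.0 * r_mc / self.norms["mod_corr"])

        grad = np.zeros_like(E)
        # env_mean: d mu / dE = w
        grad += g_mean[:, None] * w[None, :]
        # env_cv2: d(var/mu^2)/dE_t = 2 w_t (d_t / mu^2 - var / mu^3)
        mu_safe = np.maximum(mu, 1e-300)
        grad += g_cv2[:, None] * 2.0 * w[None, :] * (
            d / mu_safe[:, None] ** 2 - (var / mu_safe**3)[:, None]
        )
        # env_skew: d eta/dE_t = 3 w_t [ (d_t^2 - var)/var^(3/2) - m3 d_t / var^(5/2) ]
        grad += g_skew[:, None] * 3.0 * w[None, :] * (
            (d**2 - var[:, None]) / (sd**3)[:, None]
            - (m3 / sd**5)[:, None] * d
        )
        # env_corr: dc/dE_j = w [ d_k/(sd_j sd_k) - c d_j / sd_j^2 ]   (+ sym in k)
        j, k = self.ej, self.ek
        contrib_j = w[None, :] * (
            d[k] / (sd[j] * sd[k])[:, None] - (corr_e / var[j])[:, None] * d[j]
        )
        contrib_k = w[None, :] * (
            d[j] / (sd[j] * sd[k])[:, None] - (corr_e / var[k])[:, None] * d[k]
        )
        for off, sl in self.e_chunks:
            grad[: self.K - off] += g_ec[sl, None] * contrib_j[sl]
            grad[off:] += g_ec[sl, None] * contrib_k[sl]

        # mod_power: through B, d var_b / dB = 2 w dB; direct term through var.
        GB = g_mp[..., None] * (2.0 * w[None, None, :] * dB) / var[:, None, None]
        direct = -np.sum(g_mp * mod_pow, axis=1) / var  # coefficient of 2 w d
        grad += direct[:, None] * 2.0 * w[None, :] * d

        # mod_corr: dc/dB_j = w [ dB_k/(s_j s_k) - c dB_j / s_j^2 ]  (+ sym in k)
        mj, mk, mn = self.mj, self.mk, self.mn
        s_j = sd_b[mj, mn]
        s_k = sd_b[mk, mn]
        v_j = np.maximum(var_b[mj, mn], 1e-300)
        v_k = np.maximum(var_b[mk, mn], 1e-300)
        cb_j = w[None, :] * (dB[mk, mn] / (s_j * s_k)[:, None]
                             - (corr_b / v_j)[:, None] * dB[mj, mn])
        cb_k = w[None, :] * (dB[mj, mn] / (s_j * s_k)[:, None]
                             - (corr_b / v_k)[:, None] * dB[mk, mn])
        for band, off, sl in self.m_chunks:
            GB[: self.K - off, band] += g_mc[sl, None] * cb_j[sl]
            GB[off:, band] += g_mc[sl, None] * cb_k[sl]

        # chain GB back through the (symmetric, zero-phase) modulation filters
        gb_spec = rfft(GB, axis=2)
        grad += irfft(np.sum(gb_spec * self.mod_h[None, :, :], axis=1), n=T, axis=1)

        return value, grad.ravel()


def optimize_envelopes(envs: EnvelopeSet, target: TextureStatistics,
                       model: TextureModel, maxiter: int,
                       memory: int = 10) -> EnvelopeSet:
    """L-BFGS descent on the compressed envelope matrix toward target statistics.

    Envelope values are kept nonnegative by box bounds (projection).
    """
    obj = _Objective(target, model, envs.n_frames)
    x0 = envs.envelopes.ravel().copy()
    res = minimize(
        obj, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * len(x0),
        options={"maxiter": maxiter, "maxcor": memory, "ftol": 1e-14, "gtol": 1e-12},
    )
    E = np.clip(res.x.reshape(envs.envelopes.shape), 0.0, None)
    return EnvelopeSet(envelopes=E, env_rate=envs.env_rate,
                       compression_exponent=envs.compression_exponent)


def _audio_rate_envelope(envs: EnvelopeSet, rate: float, n_samples: int) -> np.ndarray:
    """Decompressed audio-rate envelopes: upsample, clip, undo the power law."""
    up = upsample_envelopes(envs.envelopes, envs.env_rate, rate, n_samples)
    return up ** (1.0 / envs.compression_exponent)


def impose_envelopes(subbands: SubbandSet, envs: EnvelopeSet,
                     model: TextureModel | None = None,
                     own_envs: EnvelopeSet | None = None) -> SubbandSet:
    """Rescale each bandpass subband so its envelope matches ``envs``.

    Both the divisor (the subband's own envelope) and the imposed envelope go
    through the same compress/downsample/upsample/decompress pathway, so
    imposing a subband's own envelope is the identity up to the epsilon guard.
    Edge-channel subbands are passed through untouched.
    """
    model = model or DEFAULT_MODEL
    bp = subbands.bandpass
    n = subbands.n_samples
    own = own_envs if own_envs is not None else model.envelopes(subbands)
    own_audio = _audio_rate_envelope(own, subbands.rate, n)
    new_audio = _audio_rate_envelope(envs, subbands.rate, n)
    eps = 1e-8 * max(own_audio.max(), 1e-30)
    scaled = bp * (new_audio / (own_audio + eps))
    out = subbands.subbands.copy()
    out[subbands.bank.bandpass_slice] = scaled
    return SubbandSet(subbands=out, rate=subbands.rate, bank=subbands.bank)


def _gain_correct(signal: AudioSignal, target: TextureStatistics,
                  model: TextureModel, passes: int) -> AudioSignal:
    """Match per-channel envelope means by iterated subband gains.

    Imposition leaves a small spectral residual (adjacent channels leak into
    one another on reconstruction); a few multiplicative per-channel gain
    passes remove it far faster than re-optimising, and leave the
    scale-invariant statistic classes essentially untouched.
    """
    for _ in range(passes):
        sb = model.decompose(signal)
        # the mean of the compressed envelope at the audio rate equals the
        # mean at 400 Hz up to resampler edge effects; good enough for the
        # multiplicative fixpoint and much cheaper than resampling
        mu = (np.abs(hilbert(sb.bandpass, axis=1)) ** model.compression).mean(axis=1)
        ratio = target.env_mean / np.maximum(mu, 1e-30)
        gain = np.clip(ratio, 0.25, 4.0) ** (1.0 / model.compression)
        out = sb.subbands.copy()
        out[sb.bank.bandpass_slice] *= gain[:, None]
        signal = reconstruct_waveform(
            SubbandSet(subbands=out, rate=sb.rate, bank=sb.bank)
        )
    return signal


def _seed_noise(cfg: SynthesisConfig, model: TextureModel) -> AudioSignal:
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * model.rate))
    x = rng.standard_normal(n)
    x *= cfg.noise_rms / np.sqrt(np.mean(x**2))
    return AudioSignal(samples=x, rate=model.rate)


def synthesize_texture(target: TextureStatistics, cfg: SynthesisConfig,
                       model: TextureModel | None = None,
                       seed_signal: AudioSignal | None = None):
    """Synthesize a waveform whose measured statistics match ``target``.

    Returns ``(AudioSignal, ConvergenceReport)``.  On non-convergence the best
    signal reached is returned with ``converged=False`` — never an exception.
    ``seed_signal`` overrides the Gaussian noise seed (used for texture steps).
    """
    model = model or DEFAULT_MODEL
    if target.n_channels != model.n_channels or target.n_mod_bands != model.n_mod_bands:
        raise ValueError(
            f"target statistics shape ({target.n_channels} channels, "
            f"{target.n_mod_bands} modulation bands) does not match the model "
            f"({model.n_channels}, {model.n_mod_bands})"
        )
    signal = seed_signal if seed_signal is not None else _seed_noise(cfg, model)
    report = ConvergenceReport(convergence_db=cfg.convergence_db)
    best_signal, best_min_snr = signal, -np.inf

    for outer in range(cfg.max_outer_iterations + 1):
        subbands = model.decompose(signal)
        envs = model.envelopes(subbands)
        mods = model.modulation(envs)
        measured = statistics_from_envelopes(envs, mods, config=model.config_dict())
        snrs = class_error_snr_db(measured, target)
        report.class_snr_db.append(snrs)
        min_snr = min(snrs.values())
        if min_snr > best_min_snr:
            best_signal, best_min_snr = signal, min_snr
        if min_snr >= cfg.convergence_db:
            report.converged = True
            break
        if outer == cfg.max_outer_iterations:
            break
        opt = optimize_envelopes(envs, target, model, cfg.inner_iterations,
                                 cfg.lbfgs_memory)
        subbands = impose_envelopes(subbands, opt, model, own_envs=envs)
        signal = reconstruct_waveform(subbands)
        if cfg.gain_passes:
            signal = _gain_correct(signal, target, model, cfg.gain_passes)
        report.iterations_used = outer + 1

    return best_signal, report


def synthesize_morph(reference: TextureStatistics, mean: TextureStatistics,
                     fraction: float, cfg: SynthesisConfig,
                     model: TextureModel | None = None):
    """Synthesize a texture at a fractional position between mean and reference.

    The target is ``interpolate_statistics(mean, reference, fraction)`` with
    the envelope means pinned to the mean texture's (constant spectrum across
    the morph line).  Returns ``(AudioSignal, ConvergenceReport)``.
    """
    target = interpolate_statistics(mean, reference, fraction, pin_env_mean=True)
    return synthesize_texture(target, cfg, model)


def synthesize_step(stats_first: TextureStatistics, stats_second: TextureStatistics,
                    step_time: float, cfg: SynthesisConfig,
                    model: TextureModel | None = None):
    """Synthesize a texture whose statistics change at ``step_time``.

    Signal A is synthesized from ``stats_first``; signal B from
    ``stats_second`` using A as the optimisation seed (so the fine structure
    is continuous across the step); the output is A and B spliced with
    rectangular windows at ``step_time``.  Returns
    ``(AudioSignal, (report_first, report_second))``.
    """
    model = model or DEFAULT_MODEL
    if not 0.0 < step_time < cfg.duration:
        raise ValueError(
            f"step_time ({step_time} s) must lie strictly inside (0, {cfg.duration}) s"
        )
    sig_a, rep_a = synthesize_texture(stats_first, cfg, model)
    sig_b, rep_b = synthesize_texture(stats_second, cfg, model, seed_signal=sig_a)
    n_step = int(round(step_time * model.rate))
    out = np.concatenate([sig_a.samples[:n_step], sig_b.samples[n_step:]])
    return AudioSignal(samples=out, rate=model.rate), (rep_a, rep_b)
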