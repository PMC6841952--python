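"""Texture statistics: time-averaged summary statistics of the model outputs.

The statistic vector zeta concatenates six classes, all computed as weighted
time averages under a window w(t) with sum_t w(t) = 1:

- ``env_mean``   mu_k          weighted mean of each compressed envelope
- ``env_cv2``    sigma_k^2/mu_k^2  envelope variance over squared mean
- ``env_skew``   eta_k         standardized third moment of each envelope
- ``env_corr``   c_jk          weighted Pearson correlations between envelopes
                               of the eight nearest cochlear-channel pairs
- ``mod_power``  sigma_{k,n}   modulation-band variance normalised by the
                               envelope variance of the same cochlear channel
- ``mod_corr``   c_{jk,n}      correlations between modulation bands of
                               cochlear neighbours (offsets 1 and 2) at the
                               1, 2, 4, 8, 16, and 32 Hz bands

With the default configuration (34 channels, 18 modulation bands) the
flattened vector has 34*3 + 236 + 612 + 390 = 1340 entries.  Envelope kurtosis
is deliberately not part of the set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .frontend import (
    AudioSignal,
    EnvelopeSet,
    ModulationSet,
    TextureModel,
    DEFAULT_MODEL,
)

ENV_CORR_OFFSETS = tuple(range(1, 9))
MOD_CORR_OFFSETS = (1, 2)
# 1-based modulation-band indices used for cross-channel modulation correlations
# (bands 3,5,7,9,11,13 = centers 1, 2, 4, 8, 16, 32 Hz with half-octave spacing).
MOD_CORR_BANDS = (3, 5, 7, 9, 11, 13)

#: Morph-grid preset: fractional positions between the mean texture (0) and a
#: reference texture (1) used for morph stimuli.
MORPH_GRID = (0.0, 0.25, 0.35, 0.4, 0.45, 0.55, 0.6, 0.65, 0.75, 1.0)

CLASS_NAMES = ("env_mean", "env_cv2", "env_skew", "env_corr", "mod_power", "mod_corr")

_DEGENERATE_REL = 1e-20  # variance below this fraction of mean^2 counts as zero


def uniform_window(n_frames: int) -> np.ndarray:
    """The default measurement window: w(t) = 1/T."""
    return np.full(n_frames, 1.0 / n_frames)


def _check_window(w: np.ndarray, n_frames: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n_frames,):
        raise ValueError(f"window length {w.shape} does not match frame count {n_frames}")
    if np.any(w < 0):
        raise ValueError("window weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("window weights must sum to 1 (within 1e-12)")
    return w


def env_corr_pairs(n_channels: int, offsets=ENV_CORR_OFFSETS):
    """(j, k) index arrays for envelope correlations, k - j in ``offsets``."""
    j, k = [], []
    for d in offsets:
        if d >= n_channels:
            continue
        jj = np.arange(n_channels - d)
        j.append(jj)
        k.append(jj + d)
    return np.concatenate(j), np.concatenate(k)


def mod_corr_triples(n_channels: int, n_mod_bands: int,
                     offsets=MOD_CORR_OFFSETS, bands=MOD_CORR_BANDS):
    """(j, k, n) index arrays for modulation correlations (n zero-based)."""
    usable = [b - 1 for b in bands if b <= n_mod_bands]
    j, k, n = [], [], []
    for b in usable:
        for d in offsets:
            if d >= n_channels:
                continue
            jj = np.arange(n_channels - d)
            j.append(jj)
            k.append(jj + d)
            n.append(np.full(n_channels - d, b))
    return np.concatenate(j), np.concatenate(k), np.concatenate(n)


@dataclass(frozen=True)
class TextureStatistics:
    """The texture parameter vector zeta, partitioned into six classes."""

    env_mean: np.ndarray  # (K,)
    env_cv2: np.ndarray  # (K,)
    env_skew: np.ndarray  # (K,)
    env_corr: np.ndarray  # (n_pairs,)
    mod_power: np.ndarray  # (K, N)
    mod_corr: np.ndarray  # (n_triples,)
    config: dict = field(default_factory=dict)
    source_id: str | None = None
    degenerate_channels: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return len(self.env_mean)

    @property
    def n_mod_bands(self) -> int:
        return self.mod_power.shape[1]

    def classes(self) -> dict[str, np.ndarray]:
        return {
            "env_mean": self.env_mean,
            "env_cv2": self.env_cv2,
            "env_skew": self.env_skew,
            "env_corr": self.env_corr,
            "mod_power": self.mod_power.ravel(),
            "mod_corr": self.mod_corr,
        }

    def flatten(self) -> np.ndarray:
        """Flattened zeta in fixed class order."""
        return np.concatenate(list(self.classes().values()))

    def class_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, vals in self.classes().items():
            out[name] = slice(start, start + len(vals))
            start += len(vals)
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self.classes().values())

    def _shape_key(self):
        return (self.env_mean.shape, self.env_corr.shape, self.mod_power.shape,
                self.mod_corr.shape)

    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "config_hash": self.config_hash(),
            "source_id": self.source_id,
            "classes": {
                "env_mean": self.env_mean.tolist(),
                "env_cv2": self.env_cv2.tolist(),
                "env_skew": self.env_skew.tolist(),
                "env_corr": self.env_corr.tolist(),
                "mod_power": self.mod_power.tolist(),
                "mod_corr": self.mod_corr.tolist(),
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str, expected_config: dict | None = None) -> "TextureStatistics":
        payload = json.loads(text)
        stats = cls(
            env_mean=np.asarray(payload["classes"]["env_mean"], dtype=float),
            env_cv2=np.asarray(payload["classes"]["env_cv2"], dtype=float),
            env_skew=np.asarray(payload["classes"]["env_skew"], dtype=float),
            env_corr=np.asarray(payload["classes"]["env_corr"], dtype=float),
            mod_power=np.asarray(payload["classes"]["mod_power"], dtype=float),
            mod_corr=np.asarray(payload["classes"]["mod_corr"], dtype=float),
            config=payload.get("config", {}),
            source_id=payload.get("source_id"),
        )
        if expected_config is not None:
            expected_hash = hashlib.sha256(
                json.dumps(expected_config, sort_keys=True).encode()
            ).hexdigest()[:16]
            if payload.get("config_hash") != expected_hash:
                raise ValueError(
                    "statistics were measured under a different model configuration "
                    f"(stored hash {payload.get('config_hash')}, expected {expected_hash})"
                )
        return stats

    def to_frame(self):
        """Flattened vector as a DataFrame with (class, j, k, n) index labels."""
        import pandas as pd

        K, N = self.n_channels, self.n_mod_bands
        rows = []
        for ch in range(K):
            rows.append(("env_mean", ch + 1, None, None))
        for ch in range(K):
            rows.append(("env_cv2", ch + 1, None, None))
        for ch in range(K):
            rows.append(("env_skew", ch + 1, None, None))
        j, k = env_corr_pairs(K)
        for a, b in zip(j, k):
            rows.append(("env_corr", int(a) + 1, int(b) + 1, None))
        for ch in range(K):
            for n in range(N):
                rows.append(("mod_power", ch + 1, None, n + 1))
        jj, kk, nn = mod_corr_triples(K, N)
        for a, b, c in zip(jj, kk, nn):
            rows.append(("mod_corr", int(a) + 1, int(b) + 1, int(c) + 1))
        frame = pd.DataFrame(rows, columns=["class", "j", "k", "n"])
        frame["value"] = self.flatten()
        return frame


def compute_envelope_moments(envs: EnvelopeSet, w: np.ndarray | None = None):
    """Weighted mean, coefficient of variation squared, and skewness per channel.

    A channel with (numerically) zero weighted variance is degenerate:
    its cv2 and skewness are reported as 0 and the channel is flagged.
    Returns ``(mu, cv2, skew, degenerate)``.
    """
    e = envs.envelopes
    w = uniform_window(e.shape[1]) if w is None else _check_window(w, e.shape[1])
    mu = e @ w
    d = e - mu[:, None]
    var = (d**2) @ w
    m3 = (d**3) @ w
    degenerate = var <= _DEGENERATE_REL * np.maximum(mu, 1e-300) ** 2
    safe_var = np.where(degenerate, 1.0, var)
    safe_mu2 = np.where(mu == 0, 1.0, mu**2)
    cv2 = np.where(degenerate | (mu == 0), 0.0, var / safe_mu2)
    skew = np.where(degenerate, 0.0, m3 / safe_var**1.5)
    return mu, cv2, skew, degenerate


def compute_envelope_correlations(envs: EnvelopeSet, w: np.ndarray | None = None,
                                  offsets=ENV_CORR_OFFSETS):
    """Weighted Pearson correlations between the eight nearest channel pairs."""
    e = envs.envelopes
    K = e.shape[0]
    w = uniform_window(e.shape[1]) if w is None else _check_window(w, e.shape[1])
    mu = e @ w
    d = e - mu[:, None]
    var = (d**2) @ w
    degenerate = var <= _DEGENERATE_REL * np.maximum(mu, 1e-300) ** 2
    sd = np.sqrt(np.where(degenerate, 1.0, var))
    j, k = env_corr_pairs(K, offsets)
    cov = ((d[j] * d[k]) @ w)
    bad = degenerate[j] | degenerate[k]
    c = np.where(bad, 0.0, cov / (sd[j] * sd[k]))
    return c, bad


def compute_modulation_power(mods: ModulationSet, envs: EnvelopeSet,
                             w: np.ndarray | None = None):
    """Modulation-band variance normalised by the envelope variance (per channel)."""
    b = mods.bands
    w = uniform_window(b.shape[2]) if w is None else _check_window(w, b.shape[2])
    mu_b = b @ w
    var_b = ((b - mu_b[..., None]) ** 2) @ w
    e = envs.envelopes
    mu = e @ w
    var_e = ((e - mu[:, None]) ** 2) @ w
    degenerate = var_e <= _DEGENERATE_REL * np.maximum(mu, 1e-300) ** 2
    safe = np.where(degenerate, 1.0, var_e)
    power = np.where(degenerate[:, None], 0.0, var_b / safe[:, None])
    return power, degenerate


def compute_modulation_correlations(mods: ModulationSet, w: np.ndarray | None = None,
                                    offsets=MOD_CORR_OFFSETS, bands=MOD_CORR_BANDS):
    """Correlations between modulation bands of neighbouring cochlear channels.

    The denominator uses the weighted standard deviations of the modulation
    bands themselves, so values always lie in [-1, 1].
    """
    b = mods.bands
    K, N, T = b.shape
    w = uniform_window(T) if w is None else _check_window(w, T)
    mu_b = b @ w
    var_b = ((b - mu_b[..., None]) ** 2) @ w
    scale = np.max(var_b) if np.max(var_b) > 0 else 1.0
    degenerate = var_b <= 1e-20 * scale
    sd = np.sqrt(np.where(degenerate, 1.0, var_b))
    j, k, n = mod_corr_triples(K, N, offsets, bands)
    db = b - mu_b[..., None]
    cov = (db[j, n] * db[k, n]) @ w
    bad = degenerate[j, n] | degenerate[k, n]
    c = np.where(bad, 0.0, cov / (sd[j, n] * sd[k, n]))
    return c, bad


def statistics_from_envelopes(envs: EnvelopeSet, mods: ModulationSet,
                              w: np.ndarray | None = None,
                              config: dict | None = None,
                              source_id: str | None = None) -> TextureStatistics:
    """Assemble the full statistic vector from precomputed model outputs."""
    mu, cv2, skew, degenerate = compute_envelope_moments(envs, w)
    env_corr, _ = compute_envelope_correlations(envs, w)
    mod_power, _ = compute_modulation_power(mods, envs, w)
    mod_corr, _ = compute_modulation_correlations(mods, w)
    return TextureStatistics(
        env_mean=mu, env_cv2=cv2, env_skew=skew, env_corr=env_corr,
        mod_power=mod_power, mod_corr=mod_corr,
        config=config or {}, source_id=source_id,
        degenerate_channels=degenerate,
    )


def measure_texture_statistics(signal: AudioSignal,
                               window: np.ndarray | None = None,
                               model: TextureModel | None = None,
                               source_id: str | None = None) -> TextureStatistics:
    """Run the full cascade on a waveform and measure all six statistic classes.

    The default window is uniform.  Very short inputs (under four periods of
    the slowest modulation band) trigger a warning: slow-modulation statistics
    are then poorly estimated.
    """
    model = model or DEFAULT_MODEL
    signal = model.prepare_signal(signal)
    min_dur = 4.0 / model.mod_fmin
    if signal.duration < min_dur:
        warnings.warn(
            f"signal duration {signal.duration:.2f} s is below {min_dur:.0f} s "
            "(four periods of the slowest modulation band); slow-rate statistics "
            "will be unreliable",
            stacklevel=2,
        )
    envs = model.envelopes(signal)
    mods = model.modulation(envs)
    return statistics_from_envelopes(envs, mods, window,
                                     config=model.config_dict(), source_id=source_id)


def measure_windowed_statistics(signal: AudioSignal, t_start: float, t_stop: float,
                                model: TextureModel | None = None) -> TextureStatistics:
    """Statistics under a rectangular window over [t_start, t_stop) seconds.

    The whole signal is decomposed once and the window is applied as
    statistic weights, so slow modulation bands keep their full-signal
    filtering context (re-decomposing a short excerpt would corrupt bands
    whose impulse responses are longer than the excerpt).
    """
    model = model or DEFAULT_MODEL
    signal = model.prepare_signal(signal)
    envs = model.envelopes(signal)
    mods = model.modulation(envs)
    lo = int(round(t_start * model.env_rate))
    hi = int(round(t_stop * model.env_rate))
    if not 0 <= lo < hi <= envs.n_frames:
        raise ValueError(f"window [{t_start}, {t_stop}) s outside the signal")
    w = np.zeros(envs.n_frames)
    w[lo:hi] = 1.0 / (hi - lo)
    return statistics_from_envelopes(envs, mods, w, config=model.config_dict())


def _check_matching(stats_list) -> None:
    first = stats_list[0]
    for s in stats_list[1:]:
        if s._shape_key() != first._shape_key():
            raise ValueError("statistics have mismatched shapes/configurations")


def average_statistics(stats_list) -> TextureStatistics:
    """Elementwise arithmetic mean of a sequence of statistic vectors."""
    stats_list = list(stats_list)
    if not stats_list:
        raise ValueError("cannot average an empty list of statistics")
    _check_matching(stats_list)
    first = stats_list[0]
    return replace(
        first,
        env_mean=np.mean([s.env_mean for s in stats_list], axis=0),
        env_cv2=np.mean([s.env_cv2 for s in stats_list], axis=0),
        env_skew=np.mean([s.env_skew for s in stats_list], axis=0),
        env_corr=np.mean([s.env_corr for s in stats_list], axis=0),
        mod_power=np.mean([s.mod_power for s in stats_list], axis=0),
        mod_corr=np.mean([s.mod_corr for s in stats_list], axis=0),
        source_id="mean",
        degenerate_channels=None,
    )


def interpolate_statistics(a: TextureStatistics, b: TextureStatistics,
                           fraction: float,
                           pin_env_mean: bool = False) -> TextureStatistics:
    """Linear interpolation zeta = a + fraction * (b - a).

    Correlation classes are clipped to [-1, 1].  With ``pin_env_mean`` the
    envelope means (hence the spectrum) are copied from ``a`` regardless of
    the fraction — the convention used for morphs whose spectrum is held at
    the mean texture's.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    _check_matching([a, b])
    f = float(fraction)
    mix = lambda u, v: (1.0 - f) * u + f * v  # noqa: E731
    return replace(
        a,
        env_mean=a.env_mean if pin_env_mean else mix(a.env_mean, b.env_mean),
        env_cv2=mix(a.env_cv2, b.env_cv2),
        env_skew=mix(a.env_skew, b.env_skew),
        env_corr=np.clip(mix(a.env_corr, b.env_corr), -1.0, 1.0),
        mod_power=mix(a.mod_power, b.mod_power),
        mod_corr=np.clip(mix(a.mod_corr, b.mod_corr), -1.0, 1.0),
        source_id=f"interp({a.source_id},{b.source_id},{f})",
        degenerate_channels=None,
    )


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-statistic mean and sd across a sound set, for z-scoring."""

    mean: np.ndarray
    sd: np.ndarray
    zero_sd: np.ndarray  # flags for statistics constant across the set
    config_hash: str

    def standardize(self, stats: TextureStatistics) -> np.ndarray:
        if stats.config_hash() != self.config_hash:
            raise ValueError(
                "statistics configuration does not match the standardization record"
            )
        z = stats.flatten() - self.mean
        return np.where(self.zero_sd, 0.0, z / np.where(self.zero_sd, 1.0, self.sd))


def zscore_statistics(stats_list):
    """Z-score each statistic across a set of sounds.

    Returns ``(standardized_vectors, record)`` where ``record`` holds the
    per-statistic means and standard deviations.  Statistics with zero sd
    across the set map to 0 and are flagged.
    """
    stats_list = list(stats_list)
    if len(stats_list) < 2:
        raise ValueError("z-scoring needs at least 2 statistic vectors")
    _check_matching(stats_list)
    mat = np.stack([s.flatten() for s in stats_list])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    zero_sd = sd <= 1e-15 * np.maximum(np.abs(mean), 1.0)
    record = StandardizationRecord(mean=mean, sd=sd, zero_sd=zero_sd,
                                   config_hash=stats_list[0].config_hash())
    z = np.where(zero_sd[None, :], 0.0,
                 (mat - mean[None, :]) / np.where(zero_sd, 1.0, sd)[None, :])
    return list(z), record
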