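"""Scalar sound descriptors: stationarity, statistical distance, density, periodicity.

Stationarity quantifies how stable a sound's texture statistics are across
successive segments; it is corpus-relative because each statistic class's
segment-to-segment variability is normalised by its median across the analysed
sound set.  Statistical distance is the Euclidean norm between z-scored
statistic vectors.  Temporal/spectral density are the negative log of the
cochleagram's variance along time or frequency.  Periodicity is the largest
local peak of the normalised broadband-envelope autocorrelation at lags of
125-500 ms (modulation rates of 2-8 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, resample_poly

from .frontend import AudioSignal, TextureModel, DEFAULT_MODEL, compute_cochleagram
from .stats import (
    CLASS_NAMES,
    StandardizationRecord,
    TextureStatistics,
    statistics_from_envelopes,
)

DEFAULT_SEGMENT_LENGTHS = (0.125, 0.25, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class StationarityConfig:
    segment_lengths: tuple = DEFAULT_SEGMENT_LENGTHS
    classes: tuple = CLASS_NAMES
    model: TextureModel = field(default_factory=lambda: DEFAULT_MODEL)

    def __post_init__(self):
        if any(s <= 0 for s in self.segment_lengths):
            raise ValueError("segment lengths must be positive")


def _segment_class_stds(signal: AudioSignal, cfg: StationarityConfig) -> np.ndarray:
    """Per (segment length, class): sd of each statistic across adjacent segments,
    averaged within the class.  Shape (n_lengths, n_classes)."""
    model = cfg.model
    signal = model.prepare_signal(signal)
    envs = model.envelopes(signal)
    mods = model.modulation(envs)
    n_frames = envs.n_frames
    out = np.empty((len(cfg.segment_lengths), len(cfg.classes)))
    for li, seg_len in enumerate(cfg.segment_lengths):
        frames_per_seg = int(round(seg_len * model.env_rate))
        n_seg = n_frames // frames_per_seg
        if n_seg < 2:
            raise ValueError(
                f"signal of {signal.duration:.2f} s is too short for two segments "
                f"of {seg_len} s"
            )
        seg_stats = []
        for s in range(n_seg):
            sl = slice(s * frames_per_seg, (s + 1) * frames_per_seg)
            e = _slice_envelopes(envs, sl)
            m = _slice_mods(mods, sl)
            seg_stats.append(statistics_from_envelopes(e, m).flatten())
        mat = np.stack(seg_stats)  # (n_seg, n_stats)
        sds = mat.std(axis=0)  # population sd across segments
        ref = statistics_from_envelopes(
            _slice_envelopes(envs, slice(0, frames_per_seg)),
            _slice_mods(mods, slice(0, frames_per_seg)),
        )
        class_slices = ref.class_slices()
        for ci, name in enumerate(cfg.classes):
            out[li, ci] = sds[class_slices[name]].mean()
    return out


def _slice_envelopes(envs, sl):
    from .frontend import EnvelopeSet

    return EnvelopeSet(envelopes=envs.envelopes[:, sl], env_rate=envs.env_rate,
                       compression_exponent=envs.compression_exponent)


def _slice_mods(mods, sl):
    from .frontend import ModulationSet

    return ModulationSet(bands=mods.bands[:, :, sl],
                         mod_center_freqs=mods.mod_center_freqs,
                         env_rate=mods.env_rate, q_factor=mods.q_factor)


def stationarity(corpus, cfg: StationarityConfig | None = None) -> np.ndarray:
    """Per-sound stationarity of a corpus of waveforms.

    For each segment length: measure statistics in adjacent segments, take the
    sd of each statistic across segments, average within each statistic class,
    normalise each class by its median across the corpus, average across
    classes, then average across segment lengths and take the negative (natural)
    logarithm.  Higher values = more stationary.  Needs at least two sounds
    (the median normalisation is undefined for one).
    """
    corpus = list(corpus)
    if len(corpus) < 2:
        raise ValueError(
            "stationarity is corpus-relative (median normalisation); "
            "supply at least two sounds"
        )
    cfg = cfg or StationarityConfig()
    raw = np.stack([_segment_class_stds(sig, cfg) for sig in corpus])
    # raw: (n_sounds, n_lengths, n_classes)
    med = np.median(raw, axis=0, keepdims=True)
    med = np.where(med > 0, med, 1.0)
    normalised = raw / med
    variability = normalised.mean(axis=2).mean(axis=1)  # classes then lengths
    return -np.log(np.maximum(variability, 1e-300))


def statistical_distance(a: TextureStatistics, b: TextureStatistics,
                         record: StandardizationRecord) -> float:
    """Euclidean distance between z-scored statistic vectors."""
    za = record.standardize(a)
    zb = record.standardize(b)
    return float(np.linalg.norm(za - zb))


def temporal_density(signal: AudioSignal, model: TextureModel | None = None,
                     floor: float = 1e-12) -> float:
    """Negative log of the cochleagram's variance across time (channel-averaged)."""
    model = model or DEFAULT_MODEL
    cg = compute_cochleagram(model.prepare_signal(signal), "linear", model.bank,
                             model.compression, model.env_rate)
    v = float(cg.values.var(axis=1).mean())
    return -math.log(max(v, floor))


def spectral_density(signal: AudioSignal, model: TextureModel | None = None,
                     floor: float = 1e-12) -> float:
    """Negative log of the cochleagram's variance across frequency (time-averaged)."""
    model = model or DEFAULT_MODEL
    cg = compute_cochleagram(model.prepare_signal(signal), "linear", model.bank,
                             model.compression, model.env_rate)
    v = float(cg.values.var(axis=0).mean())
    return -math.log(max(v, floor))


@dataclass(frozen=True)
class PeriodicityResult:
    peak_value: float
    peak_lag_s: float
    has_peak: bool

    def __iter__(self):
        return iter((self.peak_value, self.peak_lag_s))


def periodicity(signal: AudioSignal, env_rate: float = 400.0,
                lag_window_s: tuple = (0.125, 0.5)) -> PeriodicityResult:
    """Envelope periodicity at modulation rates of 2-8 Hz.

    The Hilbert envelope of the broadband waveform is downsampled to
    ``env_rate``, mean-removed, and autocorrelated (normalised at lag 0).  The
    value and lag of the largest local peak with lag inside ``lag_window_s``
    are returned; if no interior local peak exists, the maximum value in the
    window is returned with ``has_peak=False``.
    """
    if signal.duration < 1.0:
        raise ValueError("periodicity needs at least 1 s of signal")
    env = np.abs(hilbert(signal.samples))
    down = int(round(signal.rate / env_rate))
    if down > 1:
        env = resample_poly(env, 1, down, padtype="line")
    env = env - env.mean()
    n = len(env)
    ac = np.correlate(env, env, mode="full")[n - 1:]
    if ac[0] <= 0:
        return PeriodicityResult(0.0, lag_window_s[0], False)
    ac = ac / ac[0]
    lags = np.arange(n) / env_rate
    lo = int(np.ceil(lag_window_s[0] * env_rate))
    hi = int(np.floor(lag_window_s[1] * env_rate))
    window = ac[lo:hi + 1]
    # local maxima strictly inside the full autocorrelation
    seg = ac[lo - 1:hi + 2]
    is_peak = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
    if np.any(is_peak):
        idx = np.flatnonzero(is_peak)
        best = idx[np.argmax(window[idx])]
        return PeriodicityResult(float(window[best]), float(lags[lo + best]), True)
    best = int(np.argmax(window))
    return PeriodicityResult(float(window[best]), float(lags[lo + best]), False)
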