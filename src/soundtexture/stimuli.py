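"""Stimulus construction for continuity-illusion experiments.

Builders for interrupted inducer/masker sequences (raised-cosine crossfades,
optional silent gaps flanking the masker), amplitude-contour control stimuli,
two-interval detection trials, and the automated masker-level search that
finds the quietest masker whose cochleagram is essentially unchanged by adding
the inducer.

Levels are rms-referenced dB (0 dB = rms 1.0); the sound-pressure calibration
of a playback system is outside the scope of waveform construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert, resample_poly

from .frontend import (
    AudioSignal,
    TextureModel,
    DEFAULT_MODEL,
    _antialias_fir,
)

DEFAULT_CROSSFADE_MS = 20.0
DEFAULT_GAP_MS = 200.0

CONTOUR_SHAPES = ("continuous", "fade-out", "dip", "glimpse", "fade-in", "absent")


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of an inducer/masker trial.

    ``snr_db`` is the inducer level minus the masker level.  In the main
    conditions the masker physically replaces the inducer; ``superimpose``
    (with ``control=True``) builds control trials where the inducer remains
    physically present during the masker.
    """

    snr_db: float = -10.0
    inducer_level_db: float = 0.0
    crossfade_ms: float = DEFAULT_CROSSFADE_MS
    gap_before: bool = False
    gap_after: bool = False
    gap_ms: float = DEFAULT_GAP_MS
    pre_duration: float = 2.0
    masker_duration: float = 2.0
    post_duration: float = 1.0
    control: bool = False
    superimpose: bool = False
    control_snr_db: float = 6.0
    contour: str | None = None


@dataclass(frozen=True)
class ContourShape:
    """One of the six response contours, as a raised-cosine amplitude envelope."""

    name: str

    def __post_init__(self):
        if self.name not in CONTOUR_SHAPES:
            raise ValueError(
                f"unknown contour {self.name!r}; expected one of {CONTOUR_SHAPES}"
            )

    def envelope(self, n: int) -> np.ndarray:
        """Amplitude envelope in [0, 1]: a raised cosine whose phase/period
        yields the requested shape over the window."""
        t = np.arange(n) / max(n - 1, 1)
        if self.name == "continuous":
            return np.ones(n)
        if self.name == "absent":
            return np.zeros(n)
        if self.name == "fade-out":
            return 0.5 * (1.0 + np.cos(np.pi * t))
        if self.name == "fade-in":
            return 0.5 * (1.0 - np.cos(np.pi * t))
        if self.name == "dip":
            return 0.5 * (1.0 + np.cos(2.0 * np.pi * t))
        # glimpse: complement of dip
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def set_level(signal: AudioSignal, level_db: float) -> AudioSignal:
    """Scale a waveform to an rms of 10^(level_db/20) (0 dB -> rms 1)."""
    rms = signal.rms()
    if rms == 0:
        raise ValueError("cannot set the level of a silent signal")
    target = 10.0 ** (level_db / 20.0)
    return AudioSignal(samples=signal.samples * (target / rms), rate=signal.rate)


def _ramp(n: int) -> np.ndarray:
    """Raised-cosine fade-in of n samples; its complement is the fade-out.

    Sample phase is centred so fade_in + fade_out = 1 everywhere and the
    crossfade midpoint falls exactly between samples n/2-1 and n/2.
    """
    i = np.arange(n) + 0.5
    return 0.5 * (1.0 - np.cos(np.pi * i / n))


def crossfade_concat(segments, ramp_ms: float = DEFAULT_CROSSFADE_MS) -> AudioSignal:
    """Concatenate segments with raised-cosine crossfades at each junction.

    Adjacent segments overlap by the ramp; the output length is the sum of the
    segment lengths minus (n-1) ramps, and each junction's crossfade midpoint
    sits at the nominal boundary.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    rate = segments[0].rate
    for s in segments[1:]:
        if abs(s.rate - rate) > 1e-9:
            raise ValueError("all segments must share a sampling rate")
    if len(segments) == 1:
        return segments[0]
    ramp = int(round(ramp_ms / 1000.0 * rate))
    for s in segments:
        if s.n_samples <= ramp:
            raise ValueError(
                f"segment of {s.n_samples} samples is shorter than the "
                f"{ramp}-sample crossfade ramp"
            )
    fade_in = _ramp(ramp)
    fade_out = 1.0 - fade_in
    total = sum(s.n_samples for s in segments) - (len(segments) - 1) * ramp
    out = np.zeros(total)
    pos = 0
    for idx, s in enumerate(segments):
        x = s.samples.copy()
        if idx > 0:
            x[:ramp] *= fade_in
        if idx < len(segments) - 1:
            x[-ramp:] *= fade_out
        out[pos:pos + len(x)] += x
        pos += len(x) - ramp
    return AudioSignal(samples=out, rate=rate)


def _insert_gaps(masker: np.ndarray, rate: float, spec: StimulusSpec) -> np.ndarray:
    """Replace the masker's first and/or last gap_ms with silence (ramped edges)."""
    gap = int(round(spec.gap_ms / 1000.0 * rate))
    edge = int(round(spec.crossfade_ms / 1000.0 * rate))
    out = masker.copy()
    if spec.gap_before:
        out[:gap] = 0.0
        out[gap:gap + edge] *= _ramp(edge)
    if spec.gap_after:
        out[-gap:] = 0.0
        out[-gap - edge:-gap] *= 1.0 - _ramp(edge)
    return out


def build_interrupted_stimulus(inducer: AudioSignal, masker: AudioSignal,
                               spec: StimulusSpec) -> AudioSignal:
    """Inducer--masker--inducer sequence with crossfades.

    The pre segment is the first ``pre_duration`` (plus half a crossfade on
    each junction side) of the inducer; the post segment is the tail of the
    nominal ``pre + masker + post`` excerpt, so the masker physically replaces
    the middle of the inducer.  Optional 200 ms silent gaps replace the
    masker's first/last samples.  In control builds the inducer's middle is
    superimposed on the masker at ``control_snr_db``.
    """
    if spec.superimpose and not spec.control:
        raise ValueError(
            "superimposing inducer and masker is only supported in control builds"
        )
    rate = inducer.rate
    ramp = spec.crossfade_ms / 1000.0
    pre_len = int(round((spec.pre_duration + ramp / 2) * rate))
    mask_len = int(round((spec.masker_duration + ramp) * rate))
    post_len = int(round((spec.post_duration + ramp / 2) * rate))
    total_nominal = int(round(
        (spec.pre_duration + spec.masker_duration + spec.post_duration) * rate))
    if inducer.n_samples < total_nominal:
        raise ValueError(
            f"inducer of {inducer.duration:.2f} s is too short for the requested "
            f"{total_nominal / rate:.2f} s geometry"
        )
    if masker.n_samples < mask_len:
        raise ValueError("masker is too short for the requested geometry")

    ind = set_level(inducer, spec.inducer_level_db)
    pre = AudioSignal(ind.samples[:pre_len], rate)
    post = AudioSignal(ind.samples[total_nominal - post_len:total_nominal], rate)
    mask = set_level(AudioSignal(masker.samples[:mask_len], rate),
                     spec.inducer_level_db - spec.snr_db).samples
    if spec.control and spec.superimpose:
        mid_start = pre_len - int(round(ramp * rate))
        middle = ind.samples[mid_start:mid_start + mask_len].copy()
        # control convention: inducer sits control_snr_db above the masker
        masker_level_db = spec.inducer_level_db - spec.control_snr_db
        mask = set_level(AudioSignal(masker.samples[:mask_len], rate),
                         masker_level_db).samples
        if spec.contour is not None:
            middle *= ContourShape(spec.contour).envelope(mask_len)
        mask = mask + middle
    mask = _insert_gaps(mask, rate, spec)
    return crossfade_concat(
        [pre, AudioSignal(mask, rate), post], spec.crossfade_ms
    )


def apply_contour(texture: AudioSignal, contour: ContourShape | str,
                  masker: AudioSignal) -> AudioSignal:
    """Multiply the texture by a contour envelope and add the masker."""
    if isinstance(contour, str):
        contour = ContourShape(contour)
    if texture.n_samples != masker.n_samples or abs(texture.rate - masker.rate) > 1e-9:
        raise ValueError("texture and masker must cover the same window")
    env = contour.envelope(texture.n_samples)
    return AudioSignal(samples=texture.samples * env + masker.samples,
                       rate=texture.rate)


def build_2afc_detection_trial(texture: AudioSignal, snr_db: float, seed: int,
                               duration: float = 2.0, noise_level_db: float = 0.0):
    """Two-interval detection trial: noise vs noise + texture at ``snr_db``.

    Both intervals use fresh seeded Gaussian noise; the interval order is
    randomised by the seed.  Returns ``(interval_1, interval_2, answer)`` where
    ``answer`` is the 0-based index of the target interval.
    """
    rng = np.random.default_rng(seed)
    rate = texture.rate
    n = int(round(duration * rate))
    if texture.n_samples < n:
        raise ValueError(f"texture must be at least {duration} s long")
    noise_a = rng.standard_normal(n)
    noise_b = rng.standard_normal(n)
    noise_a *= 10.0 ** (noise_level_db / 20.0) / np.sqrt(np.mean(noise_a**2))
    noise_b *= 10.0 ** (noise_level_db / 20.0) / np.sqrt(np.mean(noise_b**2))
    tex = set_level(AudioSignal(texture.samples[:n], rate),
                    noise_level_db + snr_db)
    target = AudioSignal(noise_a + tex.samples, rate)
    foil = AudioSignal(noise_b, rate)
    answer = int(rng.integers(2))
    intervals = (target, foil) if answer == 0 else (foil, target)
    return intervals[0], intervals[1], answer


@dataclass(frozen=True)
class MaskerLevelResult:
    snr_db: float
    diff_db: float
    degenerate: bool = False

    def __float__(self):
        return self.snr_db


def masker_difference_curve(inducer: AudioSignal, masker: AudioSignal,
                            snr_grid_db: np.ndarray,
                            model: TextureModel | None = None) -> np.ndarray:
    """Mean |dB cochleagram difference| between masker and masker+inducer.

    The inducer is held at 0 dB rms and the masker is scaled to -SNR for each
    grid value.  Cochlear filtering is linear, so the analytic subbands of the
    two sources are computed once and recombined per level; only the
    (nonlinear) envelope stages are recomputed.
    """
    model = model or DEFAULT_MODEL
    ind = model.prepare_signal(set_level(inducer, 0.0))
    msk = model.prepare_signal(set_level(masker, 0.0))
    n = min(ind.n_samples, msk.n_samples)
    a_i = hilbert(model.decompose(AudioSignal(ind.samples[:n], model.rate)).bandpass,
                  axis=1)
    a_m = hilbert(model.decompose(AudioSignal(msk.samples[:n], model.rate)).bandpass,
                  axis=1)
    down = int(round(model.rate / model.env_rate))
    h = _antialias_fir(model.rate, model.env_rate)
    c = model.compression

    def cochleagram(analytic_sum):
        env = np.abs(analytic_sum) ** c
        if down > 1:
            env = resample_poly(env, 1, down, axis=1, window=h, padtype="line")
        return np.clip(env, 0.0, None)

    diffs = np.empty(len(snr_grid_db))
    for i, snr in enumerate(snr_grid_db):
        g = 10.0 ** (-snr / 20.0)  # masker gain for inducer at 0 dB
        cg_m = cochleagram(g * a_m)
        cg_mi = cochleagram(g * a_m + a_i)
        floor = 1e-8 * max(cg_mi.max(), 1e-30)
        db_m = 20.0 * np.log10(cg_m + floor)
        db_mi = 20.0 * np.log10(cg_mi + floor)
        diffs[i] = np.mean(np.abs(db_m - db_mi))
    return diffs


def find_masker_level(inducer: AudioSignal, masker: AudioSignal,
                      criterion_db: float = 3.0,
                      snr_min_db: float = -30.0, snr_max_db: float = 30.0,
                      step_db: float = 0.5,
                      model: TextureModel | None = None) -> MaskerLevelResult:
    """Quietest masker (highest SNR) whose cochleagram the inducer barely alters.

    Searches a half-dB SNR grid for the highest SNR at which the mean absolute
    dB-cochleagram difference between the masker and masker+inducer is at most
    ``criterion_db``.  The difference is monotonically non-increasing in masker
    level, so a bisection over the grid suffices.
    """
    if inducer.rms() == 0:
        return MaskerLevelResult(snr_db=snr_max_db, diff_db=0.0, degenerate=True)
    grid = np.round(np.arange(snr_min_db, snr_max_db + step_db / 2, step_db), 6)
    lo, hi = 0, len(grid) - 1
    diff_at = {}

    def diff(i):
        if i not in diff_at:
            diff_at[i] = masker_difference_curve(inducer, masker, grid[[i]], model)[0]
        return diff_at[i]

    if diff(lo) > criterion_db:
        raise ValueError(
            f"criterion {criterion_db} dB unreachable even at the loudest masker "
            f"(SNR {grid[lo]} dB gives {diff(lo):.2f} dB)"
        )
    if diff(hi) <= criterion_db:
        return MaskerLevelResult(snr_db=float(grid[hi]), diff_db=diff(hi))
    # invariant: diff(lo) <= criterion < diff(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if diff(mid) <= criterion_db:
            lo = mid
        else:
            hi = mid
    return MaskerLevelResult(snr_db=float(grid[lo]), diff_db=diff(lo))
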