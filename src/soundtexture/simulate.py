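"""Synthetic sound corpora and simulated observers.

Generators for the sound classes the metrics are designed to separate —
stationary Gaussian noise, filtered noise, periodically amplitude-modulated
noise (rates 2-8 Hz), sparse event-like nonstationary sounds, and
texture-like comodulated noise (a broadband modulator shared across the
spectrum) — plus Bernoulli observers whose response probability follows a
logistic function of a stimulus variable, and a full simulated
step-discrimination experiment over the 10-position morph grid.  Every
generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frontend import AudioSignal, DEFAULT_RATE
from .psychometrics import make_trial_table
from .stats import MORPH_GRID

SOUND_CLASSES = ("stationary_noise", "filtered_noise", "am_periodic",
                 "event_sparse", "comod_noise")

DEFAULT_SOUND_RMS = 0.1


@dataclass(frozen=True)
class SoundClassSpec:
    """Specification of one synthetic sound.

    ``am_rate`` must stay within 2-8 Hz for the periodic class (the range the
    periodicity metric targets); ``depth`` is the modulation depth in [0, 1].
    """

    sound_class: str
    duration: float = 5.0
    seed: int = 0
    rate: float = DEFAULT_RATE
    am_rate: float = 4.0
    depth: float = 1.0
    am_waveform: str = "sine"  # or "square" (50% duty gate)
    band: tuple = (500.0, 4000.0)  # filtered_noise passband, Hz
    event_rate: float = 2.0  # Hz, Poisson rate of bursts
    burst_ms: float = 50.0
    floor_db: float = -40.0  # near-silence floor between events
    mod_cutoff: float = 45.0  # comod_noise: lowpass cutoff of the shared modulator, Hz

    def __post_init__(self):
        if self.sound_class not in SOUND_CLASSES:
            raise ValueError(
                f"unknown sound class {self.sound_class!r}; expected one of "
                f"{SOUND_CLASSES}"
            )
        if self.sound_class == "am_periodic" and not 2.0 <= self.am_rate <= 8.0:
            raise ValueError("am_rate must lie in 2-8 Hz")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")


def _normalise(x: np.ndarray, rms: float = DEFAULT_SOUND_RMS) -> np.ndarray:
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def gen_sound(spec: SoundClassSpec) -> AudioSignal:
    """Generate one labelled synthetic sound, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    noise = rng.standard_normal(n)
    if spec.sound_class == "stationary_noise":
        x = noise
    elif spec.sound_class == "filtered_noise":
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, spec.band, btype="bandpass", fs=spec.rate, output="sos")
        x = sosfiltfilt(sos, noise)
    elif spec.sound_class == "am_periodic":
        carrier = np.sin(2.0 * np.pi * spec.am_rate * t)
        if spec.am_waveform == "square":
            gate = 1.0 - spec.depth * (np.sign(carrier) < 0)
        elif spec.am_waveform == "sine":
            gate = 1.0 + spec.depth * carrier
        else:
            raise ValueError(f"unknown am_waveform {spec.am_waveform!r}")
        x = gate * noise
    elif spec.sound_class == "comod_noise":
        # texture-like noise: one broadband lowpass-noise modulator shared
        # across the whole spectrum, the synthetic analogue of the
        # comodulation real textures exhibit
        from scipy.signal import butter, sosfiltfilt

        sos = butter(2, spec.mod_cutoff, btype="lowpass", fs=spec.rate, output="sos")
        mod = sosfiltfilt(sos, rng.standard_normal(n))
        mod /= np.std(mod)
        x = np.maximum(1.0 + spec.depth * mod, 0.0) * noise
    else:  # event_sparse: Poisson-timed raised-cosine noise bursts over near-silence
        burst_len = int(round(spec.burst_ms / 1000.0 * spec.rate))
        env = np.full(n, 10.0 ** (spec.floor_db / 20.0))
        n_events = rng.poisson(spec.event_rate * spec.duration)
        starts = np.sort(rng.integers(0, max(n - burst_len, 1), size=n_events))
        burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(burst_len) / burst_len))
        for s in starts:
            env[s:s + burst_len] = np.maximum(env[s:s + burst_len], burst[: n - s])
        x = env * noise
    return AudioSignal(samples=_normalise(x), rate=spec.rate)


def gen_corpus(class_counts: dict, seed: int = 0, duration: float = 5.0,
               rate: float = DEFAULT_RATE, **class_kwargs):
    """Reproducible labelled corpus: list of (label, AudioSignal).

    Per-sound seeds are spawned deterministically from the master seed, so any
    subset is reproducible and all waveforms are pairwise distinct.
    """
    if not class_counts:
        raise ValueError("class_counts must be nonempty")
    total = sum(class_counts.values())
    if total < 2:
        raise ValueError("a corpus needs at least 2 sounds (metrics use medians)")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(total)
    out = []
    i = 0
    for label in sorted(class_counts):
        for _ in range(class_counts[label]):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            spec = SoundClassSpec(sound_class=label, duration=duration,
                                  seed=child_seed, rate=rate,
                                  **class_kwargs.get(label, {}))
            out.append((label, gen_sound(spec)))
            i += 1
    return out


@dataclass(frozen=True)
class ObserverModel:
    """Bernoulli observer: P(positive response | x) is a range-limited logistic."""

    alpha: float
    beta: float
    floor: float = 0.0
    lapse: float = 0.0
    task: str = "continuity"  # or "2afc_detection"

    @property
    def ceiling(self) -> float:
        return 1.0 - self.lapse

    def prob(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.beta <= 0:
            sig = (x >= self.alpha).astype(float)
        else:
            sig = 1.0 / (1.0 + np.exp(-(x - self.alpha) / self.beta))
        return self.floor + (self.ceiling - self.floor) * sig


def simulate_observer(xs, model: ObserverModel, trials_per_x: int = 1,
                      seed: int = 0, participant: int = 0,
                      condition: str = "main") -> pd.DataFrame:
    """Binomial responses of one observer over the stimulus levels ``xs``."""
    if trials_per_x < 1:
        raise ValueError("trials_per_x must be >= 1")
    rng = np.random.default_rng(seed)
    xs = np.asarray(xs, dtype=float)
    p = model.prob(xs)
    k = rng.binomial(trials_per_x, p)
    return make_trial_table(
        [(participant, condition, float(x), trials_per_x, int(kk))
         for x, kk in zip(xs, k)]
    )


def simulate_step_experiment(true_bias: float = 0.0, n_participants: int = 13,
                             trials_per_cell: int = 4, seed: int = 0,
                             alpha_jitter_sd: float = 0.05, beta: float = 0.1,
                             lapse: float = 0.0,
                             grid=MORPH_GRID) -> pd.DataFrame:
    """Simulated two-direction step experiment over the morph grid.

    Each participant judges, at every morph position, whether the morph is
    more similar to the reference than the step endpoint; their response curve
    is a logistic whose PSE is shifted by +bias/2 for the "up" step direction
    and -bias/2 for "down", around a participant-specific baseline (Gaussian
    jitter on the morph scale).  Returns a trial table with conditions
    ``step_down`` and ``step_up``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    rows = []
    xs = np.asarray(grid, dtype=float)
    for p_id in range(n_participants):
        base = 0.5 + rng.normal(0.0, alpha_jitter_sd)
        for cond, shift in (("step_down", -true_bias / 2.0),
                            ("step_up", +true_bias / 2.0)):
            model = ObserverModel(alpha=base + shift, beta=beta, lapse=lapse)
            prob = model.prob(xs)
            k = rng.binomial(trials_per_cell, prob)
            rows.extend(
                (p_id, cond, float(x), trials_per_cell, int(kk))
                for x, kk in zip(xs, k)
            )
    return make_trial_table(rows)
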