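"""Auditory frontend: cochlear filterbank, envelopes, modulation bands.

The frontend is a two-stage filterbank cascade.  The first stage splits the
waveform into subbands with 4th-order gammatone filters whose center
frequencies are equally spaced on the ERB_N scale (34 channels spanning
50-8097 Hz by default).  Subband envelopes are extracted from the analytic
signal, power-law compressed (exponent 0.3, a standard model of cochlear
nonlinearity), and downsampled to 400 Hz.  The second stage filters each
compressed envelope into 18 half-octave spaced modulation bands (centers
0.5*2^(n/2) Hz, constant Q = 2).

Filtering in both stages is zero-phase and performed in the frequency domain
with analytically evaluated magnitude responses.  With the lowpass/highpass
edge channels enabled, the cochlear bank is pointwise power-normalised so that
the summed squared magnitude response is exactly flat; decomposition and
reconstruction are then exact transposes of one another (a paraunitary bank),
giving perfect reconstruction up to floating-point rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal import firwin, hilbert, resample_poly

DEFAULT_RATE = 48_000
DEFAULT_N_CHANNELS = 34
DEFAULT_FMIN = 50.0
DEFAULT_FMAX = 8097.0
DEFAULT_COMPRESSION = 0.3
DEFAULT_ENV_RATE = 400
DEFAULT_MOD_FMIN = 0.5
DEFAULT_MOD_FMAX = 200.0
DEFAULT_N_MOD_BANDS = 18
DEFAULT_MOD_Q = 2.0
GAMMATONE_ORDER = 4

# Glasberg & Moore ERB_N conventions.
_EARQ_SLOPE = 4.37e-3  # per Hz
_ERB_SCALE = 24.7
_GAMMATONE_B_FACTOR = 1.019  # decay parameter of a 4th-order gammatone per ERB


class InvalidConfigurationError(ValueError):
    """Raised when a filterbank or model configuration is inconsistent."""


class UnsupportedConfigurationError(ValueError):
    """Raised when an operation needs a capability the configuration lacks."""


def erb_bandwidth(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth (Hz) at frequency ``f`` (Hz)."""
    return _ERB_SCALE * (_EARQ_SLOPE * np.asarray(f, dtype=float) + 1.0)


def hz_to_erb_number(f: np.ndarray | float) -> np.ndarray | float:
    """Map frequency in Hz to position on the ERB_N-number scale."""
    return 21.4 * np.log10(_EARQ_SLOPE * np.asarray(f, dtype=float) + 1.0)


def erb_number_to_hz(e: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`hz_to_erb_number`."""
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / _EARQ_SLOPE


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples:
        Real-valued sample sequence (arbitrary units).
    rate:
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(f"expected a mono 1-D waveform, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CochlearFilterbank:
    """Gammatone analysis bank, ERB-spaced, evaluated in the frequency domain.

    ``center_freqs`` holds the 34 (by default) bandpass centers; when
    ``edge_channels`` is on, a lowpass residual below the first center and a
    highpass residual above the last are appended during decomposition and the
    whole bank is power-normalised per frequency bin, which makes the summed
    squared magnitude response exactly flat (the bank is paraunitary).
    """

    center_freqs: np.ndarray
    rate: float
    order: int = GAMMATONE_ORDER
    edge_channels: bool = True
    fmin: float = DEFAULT_FMIN
    fmax: float = DEFAULT_FMAX

    @property
    def n_channels(self) -> int:
        """Number of bandpass (statistics) channels, excluding edge residuals."""
        return len(self.center_freqs)

    @property
    def n_total(self) -> int:
        return self.n_channels + (2 if self.edge_channels else 0)

    @property
    def bandpass_slice(self) -> slice:
        return slice(0, self.n_channels)

    def responses(self, n_samples: int) -> np.ndarray:
        """Magnitude responses on the rfft grid for a signal of given length.

        Returns an array of shape ``(n_total, n_samples // 2 + 1)``.  Bandpass
        channels come first, then (if enabled) the lowpass and highpass edge
        channels.
        """
        return _bank_responses(
            tuple(np.round(self.center_freqs, 9)),
            self.rate,
            self.order,
            self.edge_channels,
            n_samples,
        )


@lru_cache(maxsize=16)
def _bank_responses(centers_key, rate, order, edge_channels, n_samples):
    centers = np.asarray(centers_key, dtype=float)
    freqs = rfftfreq(n_samples, 1.0 / rate)
    b = _GAMMATONE_B_FACTOR * erb_bandwidth(centers)
    # |H(f)| of an n-th order gammatone with decay parameter b (Hz).
    g = (1.0 + ((freqs[None, :] - centers[:, None]) / b[:, None]) ** 2) ** (-order / 2.0)
    if not edge_channels:
        return g
    power = np.sum(g**2, axis=0)
    plateau = power.max()
    deficit = np.maximum(plateau - power, 0.0)
    lo = np.sqrt(np.where(freqs <= centers[0], deficit, 0.0))
    hi = np.sqrt(np.where(freqs >= centers[-1], deficit, 0.0))
    bank = np.vstack([g, lo[None, :], hi[None, :]])
    total = np.sum(bank**2, axis=0)
    # Pointwise power normalisation: sum of squared responses becomes exactly 1.
    bank /= np.sqrt(total)[None, :]
    return bank


def design_cochlear_filterbank(
    n_channels: int = DEFAULT_N_CHANNELS,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    rate: float = DEFAULT_RATE,
    order: int = GAMMATONE_ORDER,
    edge_channels: bool = True,
) -> CochlearFilterbank:
    """Design an ERB-spaced gammatone filterbank.

    Centers are equally spaced on the ERB_N-number scale between ``fmin`` and
    ``fmax`` inclusive.  ``fmax`` must lie below the Nyquist frequency.
    """
    if n_channels < 2:
        raise InvalidConfigurationError("need at least 2 channels")
    if not fmin < fmax:
        raise InvalidConfigurationError(f"fmin ({fmin}) must be below fmax ({fmax})")
    if fmax >= rate / 2:
        raise InvalidConfigurationError(
            f"fmax ({fmax} Hz) must be below the Nyquist frequency ({rate / 2} Hz)"
        )
    erbs = np.linspace(hz_to_erb_number(fmin), hz_to_erb_number(fmax), n_channels)
    centers = np.asarray(erb_number_to_hz(erbs), dtype=float)
    return CochlearFilterbank(
        center_freqs=centers,
        rate=float(rate),
        order=order,
        edge_channels=edge_channels,
        fmin=float(fmin),
        fmax=float(fmax),
    )


@dataclass(frozen=True)
class SubbandSet:
    """Cochlear subbands at the audio rate; rows follow the bank's channel order."""

    subbands: np.ndarray  # (n_total, n_samples)
    rate: float
    bank: CochlearFilterbank

    @property
    def n_samples(self) -> int:
        return self.subbands.shape[1]

    @property
    def bandpass(self) -> np.ndarray:
        return self.subbands[self.bank.bandpass_slice]


@dataclass(frozen=True)
class EnvelopeSet:
    """Compressed cochlear envelopes at the envelope rate (default 400 Hz)."""

    envelopes: np.ndarray  # (n_channels, n_frames), nonnegative
    env_rate: float
    compression_exponent: float = DEFAULT_COMPRESSION

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.envelopes.shape[1]


@dataclass(frozen=True)
class ModulationSet:
    """Modulation bands: each cochlear envelope split into constant-Q bands."""

    bands: np.ndarray  # (n_channels, n_modbands, n_frames)
    mod_center_freqs: np.ndarray
    env_rate: float
    q_factor: float = DEFAULT_MOD_Q

    @property
    def n_modbands(self) -> int:
        return self.bands.shape[1]

    def weighted_means(self, w: np.ndarray) -> np.ndarray:
        """Per-band weighted mean mu_{k,n}; near zero for bandpass bands."""
        return self.bands @ w

    def weighted_stds(self, w: np.ndarray) -> np.ndarray:
        mu = self.weighted_means(w)
        return np.sqrt(((self.bands - mu[..., None]) ** 2) @ w)


@dataclass(frozen=True)
class Cochleagram:
    """Time-frequency representation from the envelopes of the cochlear bank."""

    values: np.ndarray  # (n_channels, n_frames)
    env_rate: float
    scale: str = "linear"  # "linear" or "db"


def cochlear_decompose(signal: AudioSignal, bank: CochlearFilterbank) -> SubbandSet:
    """Split ``signal`` into cochlear subbands by zero-phase gammatone filtering."""
    if abs(signal.rate - bank.rate) > 1e-9:
        raise ValueError(
            f"signal rate ({signal.rate} Hz) does not match the filterbank design "
            f"rate ({bank.rate} Hz)"
        )
    h = bank.responses(signal.n_samples)
    spec = rfft(signal.samples)
    subbands = irfft(spec[None, :] * h, n=signal.n_samples, axis=1)
    return SubbandSet(subbands=subbands, rate=signal.rate, bank=bank)


def reconstruct_waveform(subbands: SubbandSet) -> AudioSignal:
    """Invert a subband decomposition by paraconjugate filtering and summation.

    Because the analysis filters are zero-phase with a power-normalised summed
    response, applying each filter a second time and summing reconstructs the
    waveform exactly (up to rounding).  Requires a bank designed with edge
    channels; other configurations are not invertible.
    """
    bank = subbands.bank
    if not bank.edge_channels:
        raise UnsupportedConfigurationError(
            "reconstruction requires a filterbank designed with edge_channels=True"
        )
    h = bank.responses(subbands.n_samples)
    spec = rfft(subbands.subbands, axis=1)
    out = irfft(np.sum(spec * h, axis=0), n=subbands.n_samples)
    return AudioSignal(samples=out, rate=subbands.rate)


@lru_cache(maxsize=8)
def _antialias_fir(rate: float, env_rate: float) -> np.ndarray:
    """FIR anti-alias lowpass with cutoff at 0.45 * env_rate."""
    down = int(round(rate / env_rate))
    numtaps = 2 * 10 * down + 1
    return firwin(numtaps, 0.45 * env_rate, fs=rate)


def _resample_ratio(rate: float, env_rate: float) -> int:
    down = rate / env_rate
    if abs(down - round(down)) > 1e-9:
        raise InvalidConfigurationError(
            f"audio rate {rate} must be an integer multiple of env_rate {env_rate}"
        )
    return int(round(down))


def extract_envelopes(
    subbands: SubbandSet,
    compression: float = DEFAULT_COMPRESSION,
    env_rate: float = DEFAULT_ENV_RATE,
) -> EnvelopeSet:
    """Compressed Hilbert envelopes of the bandpass subbands at ``env_rate``.

    Per channel: analytic-signal magnitude, power-law compression, FIR
    anti-alias filtering (cutoff 0.45 * env_rate) and polyphase downsampling,
    then clipping of small negative resampling overshoots to zero.  Edge
    (residual) channels are excluded: the statistics are defined on the
    bandpass channels only.
    """
    if compression <= 0:
        raise InvalidConfigurationError(f"compression exponent must be > 0, got {compression}")
    if env_rate > subbands.rate:
        raise InvalidConfigurationError("env_rate cannot exceed the subband rate")
    down = _resample_ratio(subbands.rate, env_rate)
    env = np.abs(hilbert(subbands.bandpass, axis=1)) ** compression
    if down > 1:
        h = _antialias_fir(subbands.rate, env_rate)
        env = resample_poly(env, 1, down, axis=1, window=h, padtype="line")
    env = np.clip(env, 0.0, None)
    return EnvelopeSet(envelopes=env, env_rate=float(env_rate), compression_exponent=compression)


def upsample_envelopes(envs: np.ndarray, env_rate: float, rate: float, n_samples: int) -> np.ndarray:
    """Polyphase-upsample envelope rows from ``env_rate`` back to the audio rate."""
    up = _resample_ratio(rate, env_rate)
    if up == 1:
        out = envs
    else:
        h = _antialias_fir(rate, env_rate)
        out = resample_poly(envs, up, 1, axis=1, window=h, padtype="line")
    out = np.clip(out[:, :n_samples], 0.0, None)
    if out.shape[1] < n_samples:
        out = np.pad(out, ((0, 0), (0, n_samples - out.shape[1])), mode="edge")
    return out


def _mod_q_to_log2_sigma(q: float) -> float:
    # FWHM in octaves of a constant-Q band: solve 2^(w/2) - 2^(-w/2) = 1/Q.
    u = (1.0 / q + np.sqrt(1.0 / q**2 + 4.0)) / 2.0
    fwhm_oct = 2.0 * np.log2(u)
    return fwhm_oct / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@lru_cache(maxsize=16)
def _mod_responses(centers_key, q, env_rate, n_frames):
    centers = np.asarray(centers_key, dtype=float)
    freqs = rfftfreq(n_frames, 1.0 / env_rate)
    sigma = _mod_q_to_log2_sigma(q)
    with np.errstate(divide="ignore"):
        logf = np.log2(np.where(freqs > 0, freqs, np.nan))
    z = (logf[None, :] - np.log2(centers)[:, None]) / sigma
    h = np.exp(-0.5 * z**2)
    h[:, freqs <= 0] = 0.0  # bandpass: no DC
    return h


def modulation_center_freqs(
    fmin: float = DEFAULT_MOD_FMIN, n_bands: int = DEFAULT_N_MOD_BANDS
) -> np.ndarray:
    """Half-octave spaced centers: fmin * 2^(n/2), n = 0..n_bands-1."""
    return fmin * 2.0 ** (np.arange(n_bands) / 2.0)


def modulation_decompose(
    envs: EnvelopeSet,
    q: float = DEFAULT_MOD_Q,
    fmin: float = DEFAULT_MOD_FMIN,
    fmax: float = DEFAULT_MOD_FMAX,
    n_bands: int = DEFAULT_N_MOD_BANDS,
) -> ModulationSet:
    """Filter each envelope into half-octave spaced constant-Q modulation bands.

    Filters are zero-phase with Gaussian magnitude on a log-frequency axis
    (constant Q = 2 by default); the DC bin is zeroed, so a constant envelope
    yields (numerically) zero modulation bands.
    """
    centers = modulation_center_freqs(fmin, n_bands)
    centers = centers[centers <= fmax + 1e-9]
    if centers[-1] > envs.env_rate / 2:
        raise InvalidConfigurationError(
            f"highest modulation center ({centers[-1]:.1f} Hz) exceeds the envelope "
            f"Nyquist frequency ({envs.env_rate / 2:.1f} Hz)"
        )
    n_frames = envs.n_frames
    h = _mod_responses(tuple(np.round(centers, 9)), q, envs.env_rate, n_frames)
    spec = rfft(envs.envelopes, axis=1)  # (K, F)
    bands = irfft(spec[:, None, :] * h[None, :, :], n=n_frames, axis=2)
    return ModulationSet(
        bands=bands, mod_center_freqs=centers, env_rate=envs.env_rate, q_factor=q
    )


def compute_cochleagram(
    signal: AudioSignal,
    scale: str = "linear",
    bank: CochlearFilterbank | None = None,
    compression: float = DEFAULT_COMPRESSION,
    env_rate: float = DEFAULT_ENV_RATE,
    db_floor_rel: float = 1e-8,
) -> Cochleagram:
    """Cochleagram from the first two model stages (subbands -> envelopes).

    ``scale='db'`` maps linear values v to 20*log10(v + floor) with a floor at
    ``db_floor_rel`` times the maximum linear value.
    """
    if bank is None:
        bank = design_cochlear_filterbank(rate=signal.rate)
    envs = extract_envelopes(cochlear_decompose(signal, bank), compression, env_rate)
    values = envs.envelopes
    if scale == "db":
        vmax = values.max()
        floor = db_floor_rel * vmax if vmax > 0 else 1e-12
        values = 20.0 * np.log10(values + floor)
    elif scale != "linear":
        raise ValueError(f"unknown cochleagram scale: {scale!r}")
    return Cochleagram(values=values, env_rate=envs.env_rate, scale=scale)


@dataclass(frozen=True)
class TextureModel:
    """Bundle of the full frontend configuration.

    Owns the cochlear bank and the envelope/modulation parameters so that every
    stage of the analysis (and the synthesizer) shares one configuration.
    """

    rate: float = DEFAULT_RATE
    n_channels: int = DEFAULT_N_CHANNELS
    fmin: float = DEFAULT_FMIN
    fmax: float = DEFAULT_FMAX
    compression: float = DEFAULT_COMPRESSION
    env_rate: float = DEFAULT_ENV_RATE
    mod_fmin: float = DEFAULT_MOD_FMIN
    mod_fmax: float = DEFAULT_MOD_FMAX
    n_mod_bands: int = DEFAULT_N_MOD_BANDS
    mod_q: float = DEFAULT_MOD_Q
    bank: CochlearFilterbank = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        bank = design_cochlear_filterbank(
            self.n_channels, self.fmin, self.fmax, self.rate, edge_channels=True
        )
        object.__setattr__(self, "bank", bank)

    def config_dict(self) -> dict:
        return {
            "rate": self.rate,
            "n_channels": self.n_channels,
            "fmin": self.fmin,
            "fmax": self.fmax,
            "compression": self.compression,
            "env_rate": self.env_rate,
            "mod_fmin": self.mod_fmin,
            "mod_fmax": self.mod_fmax,
            "n_mod_bands": self.n_mod_bands,
            "mod_q": self.mod_q,
        }

    def decompose(self, signal: AudioSignal) -> SubbandSet:
        return cochlear_decompose(signal, self.bank)

    def envelopes(self, source: AudioSignal | SubbandSet) -> EnvelopeSet:
        if isinstance(source, AudioSignal):
            source = self.decompose(source)
        return extract_envelopes(source, self.compression, self.env_rate)

    def modulation(self, envs: EnvelopeSet) -> ModulationSet:
        return modulation_decompose(
            envs, self.mod_q, self.mod_fmin, self.mod_fmax, self.n_mod_bands
        )

    def mod_filter_responses(self, n_frames: int) -> np.ndarray:
        centers = modulation_center_freqs(self.mod_fmin, self.n_mod_bands)
        centers = centers[centers <= self.mod_fmax + 1e-9]
        return _mod_responses(tuple(np.round(centers, 9)), self.mod_q, self.env_rate, n_frames)

    def prepare_signal(self, signal: AudioSignal) -> AudioSignal:
        """Resample to the model rate if needed (with a warning)."""
        if abs(signal.rate - self.rate) <= 1e-9:
            return signal
        warnings.warn(
            f"resampling input from {signal.rate:.0f} Hz to the model rate "
            f"{self.rate:.0f} Hz",
            stacklevel=2,
        )
        from fractions import Fraction

        frac = Fraction(int(round(self.rate)), int(round(signal.rate)))
        out = resample_poly(signal.samples, frac.numerator, frac.denominator)
        return AudioSignal(samples=out, rate=self.rate)


DEFAULT_MODEL = TextureModel()
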