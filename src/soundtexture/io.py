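"""WAV and statistics serialization.

WAV files are mono PCM16 or float32; reads at a rate other than the requested
one are resampled with a logged warning.  Texture statistics round-trip
through JSON (full precision, class partitions, config hash) and through a
labelled CSV of the flattened vector.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .frontend import AudioSignal
from .stats import TextureStatistics

log = logging.getLogger("soundtexture")


def write_wav(path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a mono WAV file (``subtype`` is 'float32' or 'pcm16')."""
    path = Path(path)
    if subtype == "float32":
        data = signal.samples.astype(np.float32)
    elif subtype == "pcm16":
        scaled = np.clip(signal.samples, -1.0, 1.0 - 2.0**-15)
        data = np.round(scaled * 32768.0).astype(np.int16)
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
    wavfile.write(path, int(round(signal.rate)), data)


def read_wav(path, expected_rate: float | None = None) -> AudioSignal:
    """Read a mono WAV file; resample (with a warning) on a rate mismatch."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise OSError(f"could not read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483648.0
    else:
        samples = data.astype(float)
    if expected_rate is not None and abs(rate - expected_rate) > 1e-9:
        msg = (f"{path}: resampling from {rate} Hz to {expected_rate} Hz")
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
        frac = Fraction(int(round(expected_rate)), int(rate))
        samples = resample_poly(samples, frac.numerator, frac.denominator)
        rate = expected_rate
    return AudioSignal(samples=samples, rate=float(rate))


def save_statistics_json(path, stats: TextureStatistics) -> None:
    Path(path).write_text(stats.to_json())


def load_statistics_json(path, expected_config: dict | None = None) -> TextureStatistics:
    return TextureStatistics.from_json(Path(path).read_text(), expected_config)


def save_statistics_csv(path, stats: TextureStatistics) -> None:
    """Flattened vector with (class, j, k, n) labels, full float precision."""
    stats.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_statistics_vector_csv(path) -> np.ndarray:
    """Re-import the flattened vector written by :func:`save_statistics_csv`."""
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")["value"].to_numpy(dtype=float)
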