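"""EMG conditioning, GRF/kinematics filtering, step segmentation.

All filtering is zero-phase (forward-backward Butterworth); the stated
orders are the design order of the underlying one-pass filter, so the
effective order is doubled and the magnitude response squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "StanceWindow",
    "NormalizedEnvelope",
    "process_emg",
    "normalize_emg",
    "lowpass_kinematics",
    "lowpass_grf",
    "segment_steps",
    "stance_mean",
    "resample_stance",
    "apply_emg_delay",
]


@dataclass(frozen=True)
class StanceWindow:
    """One step's stance interval in samples, half-open [onset, offset)."""

    onset: int
    offset: int
    rate: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(
                f"offset ({self.offset}) must exceed onset ({self.onset})"
            )
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def duration(self) -> float:
        """Stance duration in seconds."""
        return (self.offset - self.onset) / self.rate

    @property
    def n_samples(self) -> int:
        return self.offset - self.onset

    def shifted(self, k: int) -> "StanceWindow":
        return StanceWindow(self.onset + k, self.offset + k, self.rate)


@dataclass
class NormalizedEnvelope:
    """EMG envelope as a fraction of MVC (dimensionless, >= 0, not clipped
    at 1: walking may exceed the MVC reference effort)."""

    values: np.ndarray
    muscle: str
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("normalized envelope must be non-negative")


def _sos_filtfilt(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    padlen = min(x.size - 1, 3 * (2 * sos.shape[0]) * 4)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def process_emg(
    raw: np.ndarray,
    rate: float,
    band: tuple[float, float] = (30.0, 500.0),
    band_order: int = 4,
    lowpass_cut: float = 6.0,
    lowpass_order: int = 4,
) -> np.ndarray:
    """Condition raw EMG into a linear envelope.

    Bandpass (zero-phase Butterworth), full-wave rectify, then low-pass
    (zero-phase Butterworth). Output is non-negative, same length as input.

    Raises
    ------
    ValueError
        If the bandpass upper edge is not below Nyquist (lower the upper
        band edge via configuration, or raise the sampling rate), if the
        input contains NaN, or if the signal is too short to filter.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(np.isnan(raw)):
        raise ValueError("raw EMG contains NaN")
    lo, hi = band
    if rate <= 2 * hi:
        raise ValueError(
            f"sampling rate {rate} Hz too low for bandpass upper edge "
            f"{hi} Hz; lower the upper band edge via config or resample"
        )
    sos_bp = sps.butter(band_order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    sos_lp = sps.butter(lowpass_order, lowpass_cut, btype="lowpass", fs=rate, output="sos")
    min_len = 6 * 3 * (2 * (sos_bp.shape[0] + sos_lp.shape[0]))
    if raw.size < min_len:
        raise ValueError(f"signal too short to filter ({raw.size} < {min_len})")
    env = _sos_filtfilt(np.abs(_sos_filtfilt(raw, sos_bp)), sos_lp)
    return np.maximum(env, 0.0)


def normalize_emg(envelope: np.ndarray, mvc_max: float, muscle: str = "",
                  rate: float = 1.0) -> NormalizedEnvelope:
    """Divide an envelope by the muscle's MVC reference (volts)."""
    if mvc_max <= 0:
        raise ValueError(f"mvc_max must be > 0, got {mvc_max}")
    return NormalizedEnvelope(np.asarray(envelope, float) / mvc_max, muscle, rate)


def _lowpass(x: np.ndarray, rate: float, cutoff: float, order: int) -> np.ndarray:
    if rate <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {rate} Hz must exceed twice the {cutoff} Hz cutoff"
        )
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return _sos_filtfilt(np.asarray(x, float), sos)


def lowpass_kinematics(x: np.ndarray, rate: float, cutoff: float = 6.0,
                       order: int = 6) -> np.ndarray:
    """Zero-phase 6 Hz low-pass, 6th-order design, for joint kinematics."""
    return _lowpass(x, rate, cutoff, order)


def lowpass_grf(x: np.ndarray, rate: float, cutoff: float = 6.0,
                order: int = 4) -> np.ndarray:
    """Zero-phase 6 Hz low-pass, 4th-order design, for ground reaction force."""
    return _lowpass(x, rate, cutoff, order)


def segment_steps(
    vgrf: np.ndarray,
    rate: float,
    threshold: float = 20.0,
    min_stance: float = 0.3,
) -> list[StanceWindow]:
    """Detect stance windows as supra-threshold runs of vertical GRF.

    Runs touching either end of the record (incomplete steps) and runs
    shorter than ``min_stance`` seconds are discarded. Returns windows in
    time order; an empty list is valid.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vgrf = np.asarray(vgrf, dtype=float)
    above = vgrf > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    onsets = np.nonzero(edges == 1)[0] + 1
    offsets = np.nonzero(edges == -1)[0] + 1
    if above[0]:  # incomplete leading stance
        offsets = offsets[1:] if offsets.size and (not onsets.size or offsets[0] < onsets[0]) else offsets
    if above[-1] and onsets.size:  # incomplete trailing stance
        onsets = onsets[:-1] if onsets.size > offsets.size else onsets
    n = min(onsets.size, offsets.size)
    min_samples = int(np.ceil(min_stance * rate))
    return [
        StanceWindow(int(a), int(b), rate)
        for a, b in zip(onsets[:n], offsets[:n])
        if b - a >= min_samples
    ]


def stance_mean(values: np.ndarray, w: StanceWindow) -> float:
    """Arithmetic mean of a signal over [onset, offset)."""
    values = np.asarray(values, dtype=float)
    if w.onset < 0 or w.offset > values.size:
        raise ValueError(
            f"window [{w.onset}, {w.offset}) outside signal of length {values.size}"
        )
    return float(values[w.onset : w.offset].mean())


def resample_stance(values: np.ndarray, w: StanceWindow, n: int = 101) -> np.ndarray:
    """Linearly interpolate a window's samples onto an n-point 0–100% stance
    grid; the window's first and last samples are preserved exactly."""
    if n < 2:
        raise ValueError("n must be >= 2")
    values = np.asarray(values, dtype=float)
    if w.onset < 0 or w.offset > values.size:
        raise ValueError("window outside signal bounds")
    seg = values[w.onset : w.offset]
    src = np.arange(seg.size, dtype=float)
    dst = np.linspace(0.0, seg.size - 1.0, n)
    return np.interp(dst, src, seg)


def apply_emg_delay(values: np.ndarray, rate: float, delay: float = 0.040) -> np.ndarray:
    """Shift a signal later by ``round(delay*rate)`` samples (electromechanical
    delay); the leading gap holds the first value to avoid onset transients."""
    if delay < 0:
        raise ValueError("delay must be >= 0")
    values = np.asarray(values, dtype=float)
    k = int(round(delay * rate))
    if k == 0 or values.size == 0:
        return values.copy()
    k = min(k, values.size)
    out = np.empty_like(values)
    out[:k] = values[0]
    out[k:] = values[: values.size - k]
    return out
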