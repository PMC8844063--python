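"""Measurement of frog-call parameters from single-call audio.

Six parameters characterise a species' advertisement call: three spectral
(5% frequency, 95% frequency, dominant frequency, all stored as log10 Hz)
and three temporal (90% energy duration, relative peak time, note rate).
Spectra are averaged Hann-windowed periodograms (window 512, 50% overlap),
matching the default selection spectrum of interactive bioacoustics tools
at the 44.1 kHz sampling rate the recordings use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

logger = logging.getLogger(__name__)

#: Default analysis window (samples); at 44.1 kHz gives 86.13 Hz bins.
DEFAULT_WINDOW_LEN = 512
#: Reference sampling rate of the recordings (Hz).
REFERENCE_SAMPLE_RATE = 44100
#: Spectral bin width at the reference rate / default window (Hz).
BIN_WIDTH_HZ = REFERENCE_SAMPLE_RATE / DEFAULT_WINDOW_LEN

#: Envelope smoothing window (ms).
DEFAULT_SMOOTH_MS = 5.0
#: Note-segmentation silence threshold, as a fraction of the peak envelope.
DEFAULT_SILENCE_FRAC = 0.10
#: Gaps shorter than this (s) do not split notes.
DEFAULT_MIN_GAP_S = 0.010


class NoEnergyError(ValueError):
    """Raised when a waveform, spectrum or envelope carries no energy."""


class TooShortError(ValueError):
    """Raised when a waveform is shorter than the analysis window."""


class MeasurementInconsistencyError(ValueError):
    """Raised when the six measured parameters violate their mutual invariants."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitudes, 1-D.
    sample_rate : int
        Sampling rate in Hz, positive.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.sample_rate

    def scaled(self, c: float) -> "Waveform":
        return Waveform(self.samples * c, self.sample_rate)


@dataclass(frozen=True)
class PowerSpectrum:
    """Per-frequency energy of a call: bin centre frequencies (Hz) and
    non-negative powers, averaged over analysis windows."""

    freqs: np.ndarray
    power: np.ndarray

    @property
    def total(self) -> float:
        return float(np.sum(self.power))


@dataclass(frozen=True)
class CallParams:
    """One species' six call parameters.

    Frequencies are log10 Hz; ``dur90`` is seconds; ``peak_time_rel`` is a
    fraction in [0, 1]; ``note_rate`` is notes per second.
    """

    species_id: str
    freq5: float
    freq95: float
    dom_freq: float
    dur90: float
    peak_time_rel: float
    note_rate: float

    def validate(self) -> None:
        problems = []
        if not self.freq5 <= self.freq95:
            problems.append(f"freq5 ({self.freq5:.4f}) > freq95 ({self.freq95:.4f})")
        if not (self.freq5 <= self.dom_freq <= self.freq95):
            problems.append(
                f"dom_freq ({self.dom_freq:.4f}) outside "
                f"[{self.freq5:.4f}, {self.freq95:.4f}]"
            )
        if not self.dur90 > 0:
            problems.append(f"dur90 ({self.dur90}) not positive")
        if not 0.0 <= self.peak_time_rel <= 1.0:
            problems.append(f"peak_time_rel ({self.peak_time_rel}) outside [0, 1]")
        if not self.note_rate > 0:
            problems.append(f"note_rate ({self.note_rate}) not positive")
        if problems:
            raise MeasurementInconsistencyError(
                f"inconsistent call parameters for {self.species_id}: "
                + "; ".join(problems)
            )


# ---------------------------------------------------------------------------
# Spectral measurements
# ---------------------------------------------------------------------------

def power_spectrum(w: Waveform, window_len: int = DEFAULT_WINDOW_LEN) -> PowerSpectrum:
    """Averaged Hann-windowed power spectrum (Welch, 50% overlap) of a call.

    Raises
    ------
    TooShortError
        If the waveform has fewer samples than ``window_len``.
    NoEnergyError
        If the waveform is silent.
    """
    if len(w.samples) < window_len:
        raise TooShortError(
            f"waveform has {len(w.samples)} samples, need >= {window_len}"
        )
    if not np.any(w.samples):
        raise NoEnergyError("no energy: waveform is silent")
    freqs, power = welch(
        w.samples,
        fs=w.sample_rate,
        window="hann",
        nperseg=window_len,
        noverlap=window_len // 2,
        detrend=False,
        scaling="spectrum",
    )
    return PowerSpectrum(freqs=freqs, power=power)


def dominant_frequency(spectrum: PowerSpectrum) -> float:
    """log10 of the centre frequency of the maximum-energy bin.

    Ties break toward the lower frequency.
    """
    if spectrum.total <= 0:
        raise NoEnergyError("no energy: flat zero spectrum")
    idx = int(np.argmax(spectrum.power))  # argmax takes the first maximum
    f = spectrum.freqs[idx]
    if f <= 0:
        raise MeasurementInconsistencyError("dominant energy at 0 Hz (DC)")
    return float(np.log10(f))


def energy_percentile_frequency(spectrum: PowerSpectrum, q: float) -> float:
    """log10 Hz of the smallest bin centre whose cumulative energy reaches
    ``q`` of the total; right-continuous and monotone non-decreasing in q."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    total = spectrum.total
    if total <= 0:
        raise NoEnergyError("no energy: zero total spectral energy")
    cum = np.cumsum(spectrum.power)
    # tiny relative slack so exact q*total boundaries are included
    idx = int(np.argmax(cum >= q * total * (1.0 - 1e-12)))
    f = spectrum.freqs[idx]
    if f <= 0:
        raise MeasurementInconsistencyError(
            f"{q:.0%} energy frequency falls in the DC bin"
        )
    return float(np.log10(f))


# ---------------------------------------------------------------------------
# Temporal measurements
# ---------------------------------------------------------------------------

def amplitude_envelope(w: Waveform, smooth_ms: float = DEFAULT_SMOOTH_MS) -> np.ndarray:
    """Rectified waveform smoothed with a moving average (default 5 ms).

    Same length as the input; deterministic given the smoothing window.
    """
    if len(w.samples) == 0:
        raise ValueError("empty waveform")
    n = max(1, int(round(w.sample_rate * smooth_ms / 1000.0)))
    kernel = np.ones(n) / n
    return np.convolve(np.abs(w.samples), kernel, mode="same")


def duration90(envelope: np.ndarray, sample_rate: int) -> float:
    """Time between the 5% and 95% cumulative-energy instants of the
    squared envelope (the duration containing 90% of call energy)."""
    energy = np.asarray(envelope, dtype=float) ** 2
    total = energy.sum()
    if total <= 0:
        raise NoEnergyError("no energy: zero envelope")
    cum = np.cumsum(energy)
    i5 = int(np.argmax(cum >= 0.05 * total))
    i95 = int(np.argmax(cum >= 0.95 * total))
    return (i95 - i5) / sample_rate


def peak_time_relative(
    envelope: np.ndarray, call_bounds: tuple[int, int]
) -> float:
    """Relative position (0-1) of the peak amplitude within the call bounds
    (inclusive sample indices). Ties break toward the earliest peak."""
    i0, i1 = call_bounds
    if not (0 <= i0 < i1 < len(envelope)):
        raise ValueError(f"degenerate or out-of-range call bounds {call_bounds}")
    segment = envelope[i0 : i1 + 1]
    peak = int(np.argmax(segment))  # first maximum
    return peak / (i1 - i0)


def segment_notes(
    envelope: np.ndarray,
    sample_rate: int,
    silence_frac: float = DEFAULT_SILENCE_FRAC,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
) -> list[tuple[float, float]]:
    """Intervals (seconds) where the envelope exceeds the silence threshold.

    Notes are subunits of a call separated by silence: maximal supra-threshold
    runs, with gaps shorter than ``min_gap_s`` merged. Returns disjoint,
    ordered intervals of positive duration; silence yields an empty list.
    """
    if silence_frac <= 0:
        raise ValueError("silence_frac must be positive")
    env = np.asarray(envelope, dtype=float)
    peak = env.max(initial=0.0)
    if peak <= 0:
        return []
    mask = env > silence_frac * peak
    if not mask.any():
        return []
    m = mask.astype(np.int8)
    starts = list(np.flatnonzero(np.diff(np.r_[0, m]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[m, 0]) == -1) + 1)
    min_gap = min_gap_s * sample_rate
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s / sample_rate, e / sample_rate) for s, e in merged]


def note_rate(notes: list[tuple[float, float]], call_duration: float) -> float:
    """Number of notes divided by the call duration (notes per second)."""
    if call_duration <= 0:
        raise ValueError("call_duration must be positive")
    return len(notes) / call_duration


# ---------------------------------------------------------------------------
# Full measurement
# ---------------------------------------------------------------------------

def call_bounds_from_envelope(
    envelope: np.ndarray, silence_frac: float = DEFAULT_SILENCE_FRAC
) -> tuple[int, int]:
    """First and last supra-threshold sample of the envelope (the call's
    extent when no explicit bounds are given)."""
    peak = envelope.max(initial=0.0)
    if peak <= 0:
        raise NoEnergyError("no energy: silent envelope")
    above = np.flatnonzero(envelope > silence_frac * peak)
    return int(above[0]), int(above[-1])


def measure_call(
    w: Waveform,
    species_id: str,
    *,
    window_len: int = DEFAULT_WINDOW_LEN,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
    silence_frac: float = DEFAULT_SILENCE_FRAC,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
    bounds: tuple[int, int] | None = None,
) -> CallParams:
    """Measure all six call parameters from an isolated single-call waveform.

    ``bounds`` (inclusive sample indices) overrides automatic boundary
    detection (first to last supra-threshold envelope sample).

    Raises
    ------
    NoEnergyError, TooShortError
        Propagated from the underlying measurements.
    MeasurementInconsistencyError
        If the measured parameters violate the CallParams invariants.
    """
    spectrum = power_spectrum(w, window_len=window_len)
    env = amplitude_envelope(w, smooth_ms=smooth_ms)
    if bounds is None:
        bounds = call_bounds_from_envelope(env, silence_frac=silence_frac)
    i0, i1 = bounds
    call_env = env[i0 : i1 + 1]
    call_duration = (i1 - i0 + 1) / w.sample_rate

    dom = dominant_frequency(spectrum)
    f5 = energy_percentile_frequency(spectrum, 0.05)
    f95 = energy_percentile_frequency(spectrum, 0.95)
    dur = duration90(call_env, w.sample_rate)
    peak = peak_time_relative(env, (i0, i1))
    notes = segment_notes(
        call_env, w.sample_rate, silence_frac=silence_frac, min_gap_s=min_gap_s
    )
    rate = note_rate(notes, call_duration)

    params = CallParams(
        species_id=species_id,
        freq5=f5,
        freq95=f95,
        dom_freq=dom,
        dur90=dur,
        peak_time_rel=peak,
        note_rate=rate,
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# WAV input
# ---------------------------------------------------------------------------

_PCM_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
}


def read_wav(path) -> Waveform:
    """Read a PCM WAV file as a mono float waveform.

    Multi-channel audio is averaged to mono with a warning; a sampling rate
    other than 44.1 kHz triggers a warning (no resampling is applied).
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path}: averaging {data.shape[1]} channels to mono")
        data = data.astype(float).mean(axis=1)
    if data.dtype in _PCM_SCALE:
        data = data.astype(float) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if rate != REFERENCE_SAMPLE_RATE:
        warnings.warn(
            f"{path}: sample rate {rate} Hz differs from the reference "
            f"{REFERENCE_SAMPLE_RATE} Hz; measurements use the file's rate"
        )
    return Waveform(samples=data, sample_rate=int(rate))
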