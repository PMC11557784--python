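"""Windowed-FFT amplitude analysis of venous pressure waveforms.

The analysis follows a fixed recipe: the signal is cut into fixed-length
windows (8192 samples by default, non-overlapping), each window is
mean-subtracted and transformed, the single-sided amplitude spectrum is
scaled so a pure sinusoid of amplitude A at an exact bin frequency reads A,
and the per-window amplitude at the dominant frequency inside a narrow band
around the nominal chest-compression rate is reported as the PIVA value.

Scaling convention: ``amplitude[k] = 2 |X_k| / N`` for ``0 < k < N/2``;
DC and Nyquist bins carry ``|X_k| / N``.  For a zero-mean window this gives
the Parseval identity ``sum(x^2) = N/2 * sum(amplitude[1:nyq]^2)
+ N * (amplitude[0]^2 + amplitude[nyq]^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from .io import Recording

__all__ = [
    "SpectrumWindow",
    "PivaSeries",
    "segment_windows",
    "compute_amplitude_spectrum",
    "find_dominant_frequency",
    "extract_piva",
    "DEFAULT_WINDOW_SAMPLES",
    "DEFAULT_BAND_HALF_WIDTH_HZ",
]

DEFAULT_WINDOW_SAMPLES = 8192  # "8 K" window
DEFAULT_BAND_HALF_WIDTH_HZ = 1.0

Taper = Literal["rect", "hann"]


@dataclass(frozen=True)
class SpectrumWindow:
    """Single-sided amplitude spectrum of one analysis window."""

    window_start: float  # s
    window_length: int  # samples
    frequencies: np.ndarray  # Hz
    amplitudes: np.ndarray  # mmHg

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class PivaSeries:
    """Per-window PIVA amplitude values for one channel.

    ``times`` are window centres in seconds; ``in_cpr`` flags windows that
    overlap the annotated CPR interval (windows entirely outside it are kept
    but flagged False).
    """

    channel: str
    times: np.ndarray  # s, window centres
    values: np.ndarray  # mmHg
    window_length: int  # samples
    hop: int  # samples
    in_cpr: np.ndarray  # bool per window

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.in_cpr = np.asarray(self.in_cpr, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.in_cpr)):
            raise ValueError("times, values and in_cpr must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("window times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("PIVA amplitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


def segment_windows(
    samples: np.ndarray,
    window_length: int = DEFAULT_WINDOW_SAMPLES,
    hop: int | None = None,
) -> list[np.ndarray]:
    """Cut ``samples`` into complete windows of ``window_length`` samples.

    Window ``i`` starts at sample ``i * hop``; the trailing partial window is
    discarded.  ``hop`` defaults to ``window_length`` (no overlap).  A signal
    shorter than one window yields an empty list with a warning, not an
    error.
    """
    samples = np.asarray(samples)
    if window_length < 2:
        raise ValueError(f"window_length must be >= 2 samples, got {window_length}")
    if hop is None:
        hop = window_length
    if not 1 <= hop <= window_length:
        raise ValueError(
            f"hop must be in [1, window_length={window_length}], got {hop}"
        )
    n = len(samples)
    if n < window_length:
        warnings.warn(
            f"signal of {n} samples is shorter than one {window_length}-sample "
            "window; no complete windows",
            stacklevel=2,
        )
        return []
    starts = range(0, n - window_length + 1, hop)
    return [samples[s : s + window_length] for s in starts]


def _window_starts(n: int, window_length: int, hop: int) -> list[int]:
    if n < window_length:
        return []
    return list(range(0, n - window_length + 1, hop))


def compute_amplitude_spectrum(
    window_samples: np.ndarray,
    sampling_rate: float,
    taper: Taper = "rect",
    window_start: float = 0.0,
) -> SpectrumWindow:
    """Single-sided amplitude spectrum of one window.

    The window mean is subtracted before the transform so the baseline
    pressure cannot dominate the spectrum.  With ``taper="hann"`` the
    amplitudes are divided by the Hann coherent gain (0.5) so tone
    amplitudes remain comparable to the rectangular default.
    """
    x = np.asarray(window_samples, dtype=float)
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0, got {sampling_rate}")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("window must be a 1-D array of at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError(
            f"non-finite samples in window starting at {window_start} s"
        )
    n = len(x)
    x = x - x.mean()
    if taper == "hann":
        x = x * np.hanning(n)
        gain = 0.5  # coherent gain of the Hann window
    elif taper == "rect":
        gain = 1.0
    else:
        raise ValueError(f"unknown taper {taper!r}; use 'rect' or 'hann'")

    spectrum = np.fft.rfft(x)
    amplitudes = np.abs(spectrum) / n
    # interior bins carry both halves of the two-sided spectrum
    if n % 2 == 0:
        amplitudes[1:-1] *= 2.0
    else:
        amplitudes[1:] *= 2.0
    amplitudes /= gain
    frequencies = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return SpectrumWindow(
        window_start=window_start,
        window_length=n,
        frequencies=frequencies,
        amplitudes=amplitudes,
    )


def find_dominant_frequency(
    spectrum: SpectrumWindow,
    search_band: tuple[float, float],
) -> float:
    """Frequency of the largest-amplitude bin inside ``search_band``.

    The band is inclusive; the DC bin is always excluded; ties break toward
    the lower frequency.  The restriction to the band is absolute: a larger
    out-of-band peak is never returned.
    """
    lo, hi = search_band
    if not lo < hi:
        raise ValueError(f"search band must satisfy lo < hi, got ({lo}, {hi})")
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    mask[0] = False  # DC excluded from peak searches
    if not mask.any():
        raise ValueError(
            f"search band ({lo}, {hi}) Hz contains no frequency bins "
            f"(bin width {spectrum.bin_width:.4g} Hz)"
        )
    idx = np.nonzero(mask)[0]
    best = idx[np.argmax(spectrum.amplitudes[idx])]  # argmax -> first (lowest f)
    return float(spectrum.frequencies[best])


def _piva_value(
    spectrum: SpectrumWindow, band: tuple[float, float], band_energy: bool
) -> float:
    freq = find_dominant_frequency(spectrum, band)
    k = int(np.searchsorted(spectrum.frequencies, freq))
    if not band_energy:
        return float(spectrum.amplitudes[k])
    lo = max(1, k - 1)
    hi = min(len(spectrum.amplitudes) - 1, k + 1)
    return float(np.sqrt(np.sum(spectrum.amplitudes[lo : hi + 1] ** 2)))


def extract_piva(
    recording: Recording,
    channel: str,
    window_length: int = DEFAULT_WINDOW_SAMPLES,
    hop: int | None = None,
    search_band: tuple[float, float] | None = None,
    taper: Taper = "rect",
    band_energy: bool = False,
) -> PivaSeries:
    """PIVA amplitude series for one channel of a recording.

    One value per complete window: the amplitude at the dominant in-band
    frequency of that window's spectrum.  ``search_band`` defaults to the
    annotated nominal compression frequency +/- 1 Hz.  With
    ``band_energy=True`` the value is the root-sum-square over the dominant
    bin and its two neighbours (leakage-robust variant).
    """
    samples = recording.channel(channel)
    if recording.kind_of(channel) != "venous":
        warnings.warn(
            f"channel {channel!r} has kind {recording.kind_of(channel)!r}, "
            "not 'venous'; PIVA extraction proceeds anyway",
            stacklevel=2,
        )
    if hop is None:
        hop = window_length
    if search_band is None:
        f0 = recording.annotations.nominal_compression_rate / 60.0
        search_band = (f0 - DEFAULT_BAND_HALF_WIDTH_HZ, f0 + DEFAULT_BAND_HALF_WIDTH_HZ)

    fs = recording.sampling_rate
    starts = _window_starts(recording.n_samples, window_length, hop)
    if not starts:
        warnings.warn(
            f"recording of {recording.n_samples} samples shorter than one "
            f"{window_length}-sample window; empty PIVA series",
            stacklevel=2,
        )
        return PivaSeries(
            channel=channel,
            times=np.empty(0),
            values=np.empty(0),
            window_length=window_length,
            hop=hop,
            in_cpr=np.empty(0, dtype=bool),
        )

    cpr_start = recording.annotations.cpr_start
    rosc = recording.annotations.rosc_time
    times = np.empty(len(starts))
    values = np.empty(len(starts))
    in_cpr = np.empty(len(starts), dtype=bool)
    n_straddling = 0
    for i, s in enumerate(starts):
        t0, t1 = s / fs, (s + window_length) / fs
        spec = compute_amplitude_spectrum(
            samples[s : s + window_length], fs, taper=taper, window_start=t0
        )
        times[i] = (t0 + t1) / 2.0
        values[i] = _piva_value(spec, search_band, band_energy)
        in_cpr[i] = (t1 > cpr_start) and (t0 < rosc)
        if in_cpr[i] and (t0 < cpr_start or t1 > rosc):
            n_straddling += 1
    if n_straddling:
        warnings.warn(
            f"{n_straddling} window(s) straddle the CPR interval boundaries; "
            "they are retained and flagged in_cpr=True",
            stacklevel=2,
        )
    return PivaSeries(
        channel=channel,
        times=times,
        values=values,
        window_length=window_length,
        hop=hop,
        in_cpr=in_cpr,
    )
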