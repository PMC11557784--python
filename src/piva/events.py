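"""Event detection and summary statistics over the CPR interval.

Covers: the per-site PIVA peak, the capnography >100%-rise rule, coronary
perfusion pressure, time-domain per-cycle venous amplitudes, per-cycle
arterial metrics, and quarter-segmented means of all of the above.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io import Recording

__all__ = [
    "EventSet",
    "QuarterSummary",
    "detect_piva_peak",
    "detect_etco2_rise",
    "compute_cpp",
    "compute_cycle_amplitudes",
    "derive_arterial_metrics",
    "summarize_quarters",
]

logger = logging.getLogger(__name__)

Etco2Rule = Literal["running_min", "global_min", "local_min"]


@dataclass
class EventSet:
    """Detected event times for one recording, absolute seconds."""

    rosc_time: float
    piva_peak_time: dict[str, float] = field(default_factory=dict)
    piva_peak_value: dict[str, float] = field(default_factory=dict)
    etco2_baseline: float | None = None
    etco2_rise_time: float | None = None  # None when the rule is never met
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rosc_time_s": self.rosc_time,
            "piva_peak_time_s": dict(self.piva_peak_time),
            "piva_peak_value_mmhg": dict(self.piva_peak_value),
            "etco2_baseline_mmhg": self.etco2_baseline,
            "etco2_rise_time_s": self.etco2_rise_time,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EventSet":
        return cls(
            rosc_time=float(d["rosc_time_s"]),
            piva_peak_time={k: float(v) for k, v in d["piva_peak_time_s"].items()},
            piva_peak_value={
                k: float(v) for k, v in d["piva_peak_value_mmhg"].items()
            },
            etco2_baseline=(
                None
                if d.get("etco2_baseline_mmhg") is None
                else float(d["etco2_baseline_mmhg"])
            ),
            etco2_rise_time=(
                None
                if d.get("etco2_rise_time_s") is None
                else float(d["etco2_rise_time_s"])
            ),
            provenance=dict(d.get("provenance", {})),
        )


@dataclass
class QuarterSummary:
    """Per-quarter means of hemodynamic metrics over the CPR interval."""

    boundaries: np.ndarray  # 5 edges partitioning [cpr_start, rosc_time]
    means: dict[str, np.ndarray]  # metric -> 4 quarter means (NaN = absent)
    counts: dict[str, np.ndarray]  # metric -> 4 sample counts

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.boundaries) != 5:
            raise ValueError("boundaries must have 5 edges (4 quarters)")
        for metric, m in self.means.items():
            if len(m) != 4:
                raise ValueError(f"metric {metric!r} must have 4 quarter means")

    def to_frame(self) -> pd.DataFrame:
        """Metrics x quarters table (Table-1 layout)."""
        return pd.DataFrame(
            self.means,
            index=["first_quarter", "second_quarter", "third_quarter", "fourth_quarter"],
        ).T


def detect_piva_peak(
    piva,
    interval: tuple[float, float],
) -> tuple[float, float]:
    """Maximum PIVA value whose window centre lies in ``interval``.

    Returns ``(time, value)``; ties break to the earliest window.
    """
    lo, hi = interval
    mask = (piva.times >= lo) & (piva.times <= hi)
    if not mask.any():
        raise ValueError(
            f"no PIVA windows with centres inside [{lo}, {hi}] s "
            f"(hop {piva.hop} samples); use a smaller hop or a longer recording"
        )
    idx = np.nonzero(mask)[0]
    best = idx[np.argmax(piva.values[idx])]  # argmax -> first = earliest
    return float(piva.times[best]), float(piva.values[best])


def _moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    kernel = np.ones(width_samples) / width_samples
    # reflect-pad so the edges are unbiased
    pad_l = width_samples // 2
    pad_r = width_samples - 1 - pad_l
    padded = np.concatenate([x[pad_l:0:-1], x, x[-2 : -2 - pad_r : -1]])
    return np.convolve(padded, kernel, mode="valid")


def detect_etco2_rise(
    samples: np.ndarray,
    sampling_rate: float,
    interval: tuple[float, float],
    smoothing: float = 1.0,
    rule: Etco2Rule = "running_min",
) -> tuple[float, float | None]:
    """Apply the >100%-of-first-lowest-value rule to a capnography trace.

    Returns ``(baseline, rise_time)`` where ``baseline`` is the reference
    minimum (mmHg) and ``rise_time`` the first instant the (optionally
    smoothed) trace exceeds ``2 * baseline``, or ``None`` if it never does.

    Rule variants for the ambiguous "first lowest value":

    * ``running_min`` (default): scan forward keeping the running minimum;
      the event fires at the first sample exceeding twice the minimum seen
      so far, and the baseline is that running minimum.
    * ``global_min``: baseline is the first global minimum over the whole
      interval; the scan for the doubling starts there.
    * ``local_min``: baseline is the first local minimum of the smoothed
      trace in the interval.
    """
    samples = np.asarray(samples, dtype=float)
    lo, hi = interval
    i0 = int(np.ceil(lo * sampling_rate))
    i1 = int(np.floor(hi * sampling_rate))
    if not 0 <= i0 < i1 <= len(samples):
        raise ValueError(
            f"interval [{lo}, {hi}] s outside the recorded trace "
            f"({len(samples)} samples at {sampling_rate} Hz)"
        )
    width = max(1, int(round(smoothing * sampling_rate)))
    # smooth within the interval only, so samples outside it (e.g. the
    # pre-CPR flat line) cannot bias the running minimum at the edges
    smoothed = _moving_average(samples[i0:i1], width)

    if rule == "running_min":
        running = np.minimum.accumulate(smoothed)
        crossings = np.nonzero(smoothed > 2.0 * running)[0]
        if crossings.size == 0:
            baseline = float(running[-1])
            rise_idx = None
        else:
            rise_idx = int(crossings[0])
            baseline = float(running[rise_idx])
    elif rule == "global_min":
        min_idx = int(np.argmin(smoothed))  # first occurrence
        baseline = float(smoothed[min_idx])
        after = np.nonzero(smoothed[min_idx:] > 2.0 * baseline)[0]
        rise_idx = int(min_idx + after[0]) if after.size else None
    elif rule == "local_min":
        d = np.diff(smoothed)
        local = np.nonzero((d[:-1] <= 0) & (d[1:] > 0))[0] + 1
        min_idx = int(local[0]) if local.size else int(np.argmin(smoothed))
        baseline = float(smoothed[min_idx])
        after = np.nonzero(smoothed[min_idx:] > 2.0 * baseline)[0]
        rise_idx = int(min_idx + after[0]) if after.size else None
    else:
        raise ValueError(
            f"unknown rule {rule!r}; use running_min, global_min or local_min"
        )

    if baseline <= 0:
        raise ValueError(
            f"capnography baseline {baseline:.4g} mmHg is not positive; the "
            ">100% rule is undefined (check units or sensor offset)"
        )
    if rise_idx is None:
        logger.info("no etCO2 criterion met in [%s, %s] s", lo, hi)
        return baseline, None
    return baseline, (i0 + rise_idx) / sampling_rate


def compute_cpp(
    diastolic_times: np.ndarray,
    diastolic_values: np.ndarray,
    cvp_samples: np.ndarray,
    sampling_rate: float,
    interval: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coronary perfusion pressure: diastolic minus the interval-minimum CVP.

    Returns ``(times, cpp_values, interval_mean)``; the CVP minimum is taken
    over ``interval`` and subtracted from every in-interval diastolic value.
    """
    lo, hi = interval
    i0 = int(np.ceil(lo * sampling_rate))
    i1 = int(np.floor(hi * sampling_rate))
    if i1 <= i0:
        raise ValueError(f"empty interval [{lo}, {hi}] s")
    cvp_min = float(np.min(np.asarray(cvp_samples, dtype=float)[i0:i1]))
    diastolic_times = np.asarray(diastolic_times, dtype=float)
    diastolic_values = np.asarray(diastolic_values, dtype=float)
    mask = (diastolic_times >= lo) & (diastolic_times <= hi)
    if not mask.any():
        raise ValueError("no diastolic values inside the interval")
    times = diastolic_times[mask]
    cpp = diastolic_values[mask] - cvp_min
    return times, cpp, float(cpp.mean())


def _cycle_slices(
    sampling_rate: float,
    compression_rate: float,
    interval: tuple[float, float],
    n_samples: int,
) -> list[tuple[int, int]]:
    """Consecutive compression-period sample slices; last partial dropped.

    Boundaries accumulate in float time to avoid drift when the period is a
    non-integer number of samples.
    """
    lo, hi = interval
    period = 60.0 / compression_rate  # s
    slices = []
    k = 0
    while True:
        t0 = lo + k * period
        t1 = lo + (k + 1) * period
        if t1 > hi + 1e-12:
            break
        i0 = int(round(t0 * sampling_rate))
        i1 = int(round(t1 * sampling_rate))
        if i1 > n_samples:
            break
        if i1 > i0:
            slices.append((i0, i1))
        k += 1
    return slices


def compute_cycle_amplitudes(
    samples: np.ndarray,
    sampling_rate: float,
    compression_rate: float,
    interval: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-compression-cycle peak-to-trough amplitudes (clock-segmented).

    The interval is cut into consecutive nominal compression periods
    (``sampling_rate * 60 / compression_rate`` samples); the amplitude of
    each period is ``max - min``.  Returns ``(period_centre_times,
    amplitudes)``; a trailing partial period is dropped.
    """
    if compression_rate <= 0:
        raise ValueError(f"compression_rate must be > 0, got {compression_rate}")
    samples = np.asarray(samples, dtype=float)
    slices = _cycle_slices(sampling_rate, compression_rate, interval, len(samples))
    if not slices:
        warnings.warn(
            "compression period longer than the interval; empty amplitude series",
            stacklevel=2,
        )
        return np.empty(0), np.empty(0)
    times = np.array([(i0 + i1) / 2.0 / sampling_rate for i0, i1 in slices])
    amps = np.array([samples[i0:i1].max() - samples[i0:i1].min() for i0, i1 in slices])
    return times, amps


def derive_arterial_metrics(
    samples: np.ndarray,
    sampling_rate: float,
    compression_rate: float,
    interval: tuple[float, float],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-cycle systole (max), diastole (min) and MAP (cycle time-average).

    Returns ``{"map": (times, values), "systole": ..., "diastole": ...}``
    with one entry per complete compression cycle in ``interval``.
    """
    if compression_rate <= 0:
        raise ValueError(f"compression_rate must be > 0, got {compression_rate}")
    samples = np.asarray(samples, dtype=float)
    slices = _cycle_slices(sampling_rate, compression_rate, interval, len(samples))
    if not slices:
        warnings.warn(
            "compression period longer than the interval; empty metric series",
            stacklevel=2,
        )
        empty = (np.empty(0), np.empty(0))
        return {"map": empty, "systole": empty, "diastole": empty}
    times = np.array([(i0 + i1) / 2.0 / sampling_rate for i0, i1 in slices])
    systole = np.array([samples[i0:i1].max() for i0, i1 in slices])
    diastole = np.array([samples[i0:i1].min() for i0, i1 in slices])
    map_ = np.array([samples[i0:i1].mean() for i0, i1 in slices])
    return {
        "map": (times, map_),
        "systole": (times, systole),
        "diastole": (times, diastole),
    }


def summarize_quarters(
    recording: Recording,
    series: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> QuarterSummary:
    """Average each derived series within 4 equal-duration CPR quarters.

    ``series`` maps metric name to ``(times, values)``.  A quarter with no
    samples for a metric gets a NaN mean and is logged.
    """
    ann = recording.annotations
    edges = np.linspace(ann.cpr_start, ann.rosc_time, 5)
    means: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for metric, (times, values) in series.items():
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        m = np.full(4, np.nan)
        c = np.zeros(4, dtype=int)
        for q in range(4):
            if q < 3:
                mask = (times >= edges[q]) & (times < edges[q + 1])
            else:  # last quarter inclusive of ROSC
                mask = (times >= edges[q]) & (times <= edges[q + 1])
            c[q] = int(mask.sum())
            if c[q]:
                m[q] = float(values[mask].mean())
            else:
                logger.info(
                    "metric %r has no samples in quarter %d; mean reported absent",
                    metric,
                    q + 1,
                )
        means[metric] = m
        counts[metric] = c
    return QuarterSummary(boundaries=edges, means=means, counts=counts)
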