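"""Reading and writing recordings and analysis results.

Canonical interchange is a plain CSV sample matrix (one column per channel,
header row) plus a JSON sidecar carrying the sampling rate, channel kinds and
the CPR annotations.  All timestamps are seconds from the first sample
(t = 0 at sample 0); annotations are stored in seconds, never sample indices,
so files remain valid under resampling.  Units are mmHg throughout.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Annotations",
    "Recording",
    "read_recording",
    "write_recording",
    "write_results",
]

CHANNEL_KINDS = ("venous", "arterial", "etco2", "other")

#: significant digits used when serializing samples (round-trip precision)
DEFAULT_PRECISION = 9


@dataclass(frozen=True)
class Annotations:
    """CPR-epoch annotations, in seconds from recording start."""

    cpr_start: float
    rosc_time: float
    nominal_compression_rate: float  # per minute

    def __post_init__(self) -> None:
        if not 0 <= self.cpr_start < self.rosc_time:
            raise ValueError(
                f"annotations require 0 <= cpr_start < rosc_time, got "
                f"cpr_start={self.cpr_start}, rosc_time={self.rosc_time}"
            )
        if self.nominal_compression_rate <= 0:
            raise ValueError(
                f"nominal_compression_rate must be > 0, got "
                f"{self.nominal_compression_rate}"
            )


@dataclass
class Recording:
    """Uniformly sampled multi-channel pressure/capnography recording.

    Parameters
    ----------
    channel_names
        One identifier per channel; must be unique.
    samples
        Array of shape ``(n_channels, n_samples)``, mmHg.
    sampling_rate
        Hz, > 0.
    annotations
        CPR start / ROSC / nominal compression rate.
    channel_kinds
        Map from channel name to one of ``venous``, ``arterial``,
        ``etco2``, ``other``.
    """

    channel_names: list[str]
    samples: np.ndarray
    sampling_rate: float
    annotations: Annotations
    channel_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.samples.shape[1] == 0:
            raise ValueError("recording has zero samples")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        for name, kind in self.channel_kinds.items():
            if name not in self.channel_names:
                raise ValueError(f"channel_kinds references unknown channel {name!r}")
            if kind not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {kind!r} for {name!r}")
        if self.annotations.rosc_time > self.duration + 0.5 / self.sampling_rate:
            raise ValueError(
                f"rosc_time {self.annotations.rosc_time} s exceeds recording "
                f"duration {self.duration} s"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return the 1-D sample vector for ``name``."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.samples[idx]

    def kind_of(self, name: str) -> str:
        return self.channel_kinds.get(name, "other")

    def channels_of_kind(self, kind: str) -> list[str]:
        return [c for c in self.channel_names if self.kind_of(c) == kind]


def _sidecar_dict(recording: Recording) -> dict:
    return {
        "sampling_rate_hz": recording.sampling_rate,
        "channels": [
            {"name": c, "kind": recording.kind_of(c)}
            for c in recording.channel_names
        ],
        "annotations": {
            "cpr_start_s": recording.annotations.cpr_start,
            "rosc_time_s": recording.annotations.rosc_time,
            "compression_rate_per_min": recording.annotations.nominal_compression_rate,
        },
    }


def write_recording(
    recording: Recording,
    csv_path: str | os.PathLike,
    sidecar_path: str | os.PathLike,
    precision: int = DEFAULT_PRECISION,
) -> None:
    """Write the sample matrix as CSV and the metadata as a JSON sidecar.

    ``read_recording`` inverts this up to ``precision`` significant digits.
    """
    df = pd.DataFrame(
        {name: recording.channel(name) for name in recording.channel_names}
    )
    df.to_csv(csv_path, index=False, float_format=f"%.{precision}g")
    with open(sidecar_path, "w") as fh:
        json.dump(_sidecar_dict(recording), fh, indent=2)
        fh.write("\n")


def read_recording(
    csv_path: str | os.PathLike,
    sidecar_path: str | os.PathLike,
    dialect: str = "csv",
) -> Recording:
    """Read a recording from a CSV matrix + JSON sidecar.

    ``dialect="chart"`` accepts tab-delimited chart-recorder text exports:
    leading metadata lines starting with ``#``, tab separation and comma
    decimal marks are tolerated.  The sidecar is required in either dialect.
    """
    if dialect == "csv":
        df = pd.read_csv(csv_path)
    elif dialect == "chart":
        df = pd.read_csv(
            csv_path, sep="\t", comment="#", decimal=",", engine="python"
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'chart'")

    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("sampling_rate_hz", "channels", "annotations"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing required key {key!r}")
    ann = meta["annotations"]
    for key in ("cpr_start_s", "rosc_time_s", "compression_rate_per_min"):
        if key not in ann:
            raise ValueError(f"sidecar annotations missing required key {key!r}")

    names = [ch["name"] for ch in meta["channels"]]
    kinds = {ch["name"]: ch.get("kind", "other") for ch in meta["channels"]}
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"CSV {csv_path} lacks sidecar channels: {missing}")

    # a time column, if present, must agree with the implied uniform grid
    fs = float(meta["sampling_rate_hz"])
    if "time" in df.columns and "time" not in names:
        t = df["time"].to_numpy(dtype=float)
        implied = np.arange(len(t)) / fs
        if not np.allclose(t, implied, atol=0.5 / fs if fs > 0 else 0):
            raise ValueError(
                "explicit time column conflicts with the uniform grid implied "
                f"by sampling_rate_hz={fs}"
            )

    mat = np.vstack([df[n].to_numpy(dtype=float) for n in names])
    if np.isnan(mat).any():
        bad = [n for n in names if df[n].isna().any()]
        raise ValueError(
            f"channels {bad} contain missing values (ragged channel lengths?)"
        )
    return Recording(
        channel_names=names,
        samples=mat,
        sampling_rate=fs,
        annotations=Annotations(
            cpr_start=float(ann["cpr_start_s"]),
            rosc_time=float(ann["rosc_time_s"]),
            nominal_compression_rate=float(ann["compression_rate_per_min"]),
        ),
        channel_kinds=kinds,
    )


def write_results(
    out_dir: str | os.PathLike,
    event_set=None,
    piva_series: Sequence | None = None,
    quarter_summary=None,
    timing_result: Mapping | None = None,
) -> list[str]:
    """Write analysis outputs to ``out_dir``.

    Events and timing results go to JSON; PIVA series and the quarter summary
    go to tidy CSV (quarter summary laid out metrics x quarters).  Returns the
    list of paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    if event_set is not None:
        path = os.path.join(out_dir, "events.json")
        with open(path, "w") as fh:
            json.dump(event_set.to_dict(), fh, indent=2)
            fh.write("\n")
        written.append(path)

    for series in piva_series or ():
        path = os.path.join(out_dir, f"piva_{series.channel}.csv")
        pd.DataFrame(
            {
                "time_s": series.times,
                "piva_mmhg": series.values,
                "in_cpr": series.in_cpr,
            }
        ).to_csv(path, index=False)
        written.append(path)

    if quarter_summary is not None:
        path = os.path.join(out_dir, "quarters.csv")
        quarter_summary.to_frame().to_csv(path)
        written.append(path)

    if timing_result is not None:
        path = os.path.join(out_dir, "comparisons.json")
        with open(path, "w") as fh:
            json.dump(timing_result, fh, indent=2, default=float)
            fh.write("\n")
        written.append(path)

    return written
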