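"""Synthetic CPR-epoch recording generator with known ground truth.

Builds multi-channel recordings (three venous sites, one arterial channel,
one capnography channel) in which every downstream quantity — compression
frequency, venous amplitude envelope peak times, the capnography doubling
time — is known by construction, so detectors can be tested for parameter
recovery without external data.

Timeline: ``[0, pre_cpr) `` arrest, no compressions; ``[cpr_start,
rosc_time)`` mechanical compressions at ``compression_rate`` per minute with
ventilation resumed; ``[rosc_time, end)`` compressions stopped.
``rosc_time = cpr_start + cpr_duration`` (compressions stop at ROSC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import Annotations, Recording

__all__ = [
    "SiteEnvelope",
    "ArterialParams",
    "Etco2Params",
    "SimConfig",
    "GroundTruth",
    "generate_compression_train",
    "generate_venous_channel",
    "generate_arterial_channel",
    "generate_etco2",
    "generate_recording",
    "default_config",
]

PulseShape = Literal["sinusoid", "rectified_sinusoid", "gaussian_pulse"]
EnvelopeShape = Literal["gaussian", "linear", "constant"]

VENOUS_SITES = ("tail", "femoral", "central")

#: ventilation sinusoid amplitude as a fraction of the site's peak amplitude
VENTILATION_FRACTION = 0.1


@dataclass(frozen=True)
class SiteEnvelope:
    """Rise-peak-fall amplitude envelope for one venous site.

    ``peak_time`` is seconds relative to CPR start.  ``shape``:

    * ``gaussian`` — asymmetric Gaussian bump, width ``rise_width`` before
      the peak and ``fall_width`` after;
    * ``linear`` — piecewise-linear tent with the same half-widths;
    * ``constant`` — flat ``peak_amplitude`` across the whole CPR interval
      (degenerate case used for spectral calibration).
    """

    baseline_pressure: float  # mmHg
    peak_amplitude: float  # mmHg (sinusoid amplitude; peak-to-trough is 2x)
    peak_time: float  # s relative to CPR start
    rise_width: float  # s
    fall_width: float  # s
    shape: EnvelopeShape = "gaussian"

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError(f"peak_amplitude must be >= 0, got {self.peak_amplitude}")
        if self.shape != "constant" and (self.rise_width <= 0 or self.fall_width <= 0):
            raise ValueError("rise_width and fall_width must be > 0")

    def __call__(self, t_rel: np.ndarray) -> np.ndarray:
        """Evaluate the envelope at times relative to CPR start."""
        t_rel = np.asarray(t_rel, dtype=float)
        if self.shape == "constant":
            return np.full_like(t_rel, self.peak_amplitude)
        dt = t_rel - self.peak_time
        width = np.where(dt < 0, self.rise_width, self.fall_width)
        if self.shape == "gaussian":
            return self.peak_amplitude * np.exp(-0.5 * (dt / width) ** 2)
        # linear tent, clipped at zero
        return self.peak_amplitude * np.clip(1.0 - np.abs(dt) / width, 0.0, None)


@dataclass(frozen=True)
class ArterialParams:
    start_map: float = 14.0  # mmHg at CPR start
    end_map: float = 80.0  # mmHg at ROSC
    pulse_amplitude: float = 10.0  # mmHg (half of peak-to-trough)

    def __post_init__(self) -> None:
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")


@dataclass(frozen=True)
class Etco2Params:
    """Capnography trace: descent to a dip early in CPR, then a surge.

    ``surge_time`` is seconds relative to CPR start.  The surge must be able
    to trigger the >100%-of-first-minimum rule, i.e. ``surge_value >
    2 * dip_value``; configs violating that are rejected because the event
    they are meant to produce would be undetectable.
    """

    baseline: float = 15.0  # mmHg at CPR start (post-arrest re-ventilation)
    dip_value: float = 10.0  # mmHg early-CPR plateau
    surge_time: float = 35.0  # s relative to CPR start
    surge_value: float = 45.0  # mmHg
    transition_width: float = 2.0  # s (sigmoid time constant)

    def __post_init__(self) -> None:
        if self.dip_value <= 0:
            raise ValueError("dip_value must be > 0 (the >100% rule needs a positive baseline)")
        if self.surge_value <= 2 * self.dip_value:
            raise ValueError(
                f"surge_value={self.surge_value} must exceed 2 x dip_value="
                f"{2 * self.dip_value}; otherwise the >100% capnography rule "
                "can never fire"
            )
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")


def _default_sites() -> dict[str, SiteEnvelope]:
    # magnitudes are order-of-magnitude placeholders (tail smallest, central
    # largest); peak times staggered tail < femoral < central
    return {
        "tail": SiteEnvelope(13.0, 1.5, 18.0, 8.0, 10.0),
        "femoral": SiteEnvelope(14.0, 5.0, 24.0, 9.0, 11.0),
        "central": SiteEnvelope(13.5, 9.0, 30.0, 10.0, 12.0),
    }


@dataclass(frozen=True)
class SimConfig:
    sampling_rate: float = 1000.0  # Hz
    pre_cpr_duration: float = 10.0  # s
    cpr_duration: float = 55.0  # s
    post_rosc_duration: float = 15.0  # s
    compression_rate: float = 200.0  # per minute
    ventilation_rate: float = 60.0  # per minute
    sites: dict[str, SiteEnvelope] = field(default_factory=_default_sites)
    arterial: ArterialParams = field(default_factory=ArterialParams)
    etco2: Etco2Params = field(default_factory=Etco2Params)
    pulse_shape: PulseShape = "sinusoid"
    noise_sd: float = 0.0  # mmHg
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.pre_cpr_duration < 0 or self.post_rosc_duration < 0:
            raise ValueError("durations must be >= 0")
        if self.cpr_duration <= 0:
            raise ValueError(f"cpr_duration must be > 0, got {self.cpr_duration}")
        if self.compression_rate <= 0 or self.ventilation_rate <= 0:
            raise ValueError("compression_rate and ventilation_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for site, env in self.sites.items():
            if not 0 <= env.peak_time <= self.cpr_duration:
                raise ValueError(
                    f"site {site!r}: peak_time {env.peak_time} s outside "
                    f"[0, {self.cpr_duration}] s CPR interval"
                )
        if not 0 <= self.etco2.surge_time <= self.cpr_duration:
            raise ValueError(
                f"etco2 surge_time {self.etco2.surge_time} s outside "
                f"[0, {self.cpr_duration}] s CPR interval"
            )

    @property
    def cpr_start(self) -> float:
        return self.pre_cpr_duration

    @property
    def rosc_time(self) -> float:
        return self.pre_cpr_duration + self.cpr_duration

    @property
    def total_duration(self) -> float:
        return self.pre_cpr_duration + self.cpr_duration + self.post_rosc_duration

    @property
    def compression_frequency(self) -> float:
        """Hz."""
        return self.compression_rate / 60.0

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """True event times implied by a :class:`SimConfig`, absolute seconds."""

    cpr_start: float
    rosc_time: float
    true_piva_peak_time: dict[str, float]
    true_etco2_rise_time: float
    true_compression_frequency: float

    def __post_init__(self) -> None:
        if not self.cpr_start < self.rosc_time:
            raise ValueError("cpr_start must precede rosc_time")
        for site, t in self.true_piva_peak_time.items():
            if not self.cpr_start <= t <= self.rosc_time:
                raise ValueError(f"{site} peak time {t} outside CPR interval")
        if not self.cpr_start <= self.true_etco2_rise_time <= self.rosc_time:
            raise ValueError("etco2 rise time outside CPR interval")

    def to_dict(self) -> dict:
        return {
            "cpr_start_s": self.cpr_start,
            "rosc_time_s": self.rosc_time,
            "true_piva_peak_time_s": dict(self.true_piva_peak_time),
            "true_etco2_rise_time_s": self.true_etco2_rise_time,
            "true_compression_frequency_hz": self.true_compression_frequency,
        }


def generate_compression_train(
    rate: float,
    duration: float,
    sampling_rate: float,
    pulse_shape: PulseShape = "sinusoid",
) -> np.ndarray:
    """Unit-amplitude periodic compression oscillation.

    Fundamental frequency is ``rate / 60`` Hz; peak-to-trough span is exactly
    2.0 for every shape.  Length is ``round(duration * sampling_rate)``.
    """
    if rate <= 0:
        raise ValueError(f"compression rate must be > 0 per minute, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0 Hz, got {sampling_rate}")
    n = round(duration * sampling_rate)
    t = np.arange(n) / sampling_rate
    f0 = rate / 60.0
    if pulse_shape == "sinusoid":
        return np.sin(2 * math.pi * f0 * t)
    if pulse_shape == "rectified_sinusoid":
        # |sin(pi f0 t)| has period 1/f0; rescale [0, 1] -> [-1, 1]
        return 2.0 * np.abs(np.sin(math.pi * f0 * t)) - 1.0
    if pulse_shape == "gaussian_pulse":
        period = 1.0 / f0
        phase = np.mod(t, period) - period / 2.0  # pulse centred mid-period
        pulse = np.exp(-0.5 * (phase / (period / 8.0)) ** 2)
        lo, hi = pulse.min(), pulse.max()
        return 2.0 * (pulse - lo) / (hi - lo) - 1.0
    raise ValueError(
        f"unknown pulse_shape {pulse_shape!r}; expected sinusoid, "
        "rectified_sinusoid or gaussian_pulse"
    )


def _time_grid(config: SimConfig) -> np.ndarray:
    n = round(config.total_duration * config.sampling_rate)
    return np.arange(n) / config.sampling_rate


def _cpr_mask(config: SimConfig, t: np.ndarray) -> np.ndarray:
    return (t >= config.cpr_start) & (t < config.rosc_time)


def _compression_component(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Unit compression oscillation, zero outside the CPR interval."""
    f0 = config.compression_frequency
    tr = t - config.cpr_start
    if config.pulse_shape == "sinusoid":
        train = np.sin(2 * math.pi * f0 * tr)
    elif config.pulse_shape == "rectified_sinusoid":
        train = 2.0 * np.abs(np.sin(math.pi * f0 * tr)) - 1.0
    elif config.pulse_shape == "gaussian_pulse":
        period = 1.0 / f0
        phase = np.mod(tr, period) - period / 2.0
        pulse = np.exp(-0.5 * (phase / (period / 8.0)) ** 2)
        lo, hi = pulse.min(), pulse.max()
        train = 2.0 * (pulse - lo) / (hi - lo) - 1.0
    else:  # pragma: no cover - rejected in SimConfig
        raise ValueError(f"unknown pulse_shape {config.pulse_shape!r}")
    return np.where(_cpr_mask(config, t), train, 0.0)


def generate_venous_channel(
    config: SimConfig,
    site: str,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Venous pressure samples for ``site`` plus the true envelope-peak time.

    The channel is ``baseline + envelope(t) * compression_train`` during CPR,
    with a small ventilation-frequency sinusoid (10% of the site's peak
    amplitude) from CPR start onward and additive white Gaussian noise.
    Returns ``(samples, true_peak_time)`` with the peak time in absolute
    seconds (``cpr_start + peak_time``).
    """
    if site not in config.sites:
        raise ValueError(
            f"no envelope parameters for site {site!r}; configured sites: "
            f"{sorted(config.sites)}"
        )
    env = config.sites[site]
    t = _time_grid(config)
    cpr = _cpr_mask(config, t)

    samples = np.full(t.shape, env.baseline_pressure)
    envelope = np.where(cpr, env(t - config.cpr_start), 0.0)
    samples = samples + envelope * _compression_component(config, t)

    # ventilation rides on the trace once ventilation resumes at CPR start
    vent_amp = VENTILATION_FRACTION * env.peak_amplitude
    vent = vent_amp * np.sin(
        2 * math.pi * (config.ventilation_rate / 60.0) * (t - config.cpr_start)
    )
    samples = samples + np.where(t >= config.cpr_start, vent, 0.0)

    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)

    return samples, config.cpr_start + env.peak_time


def generate_arterial_channel(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Arterial pressure: mean ramps ``start_map -> end_map`` over CPR with a
    compression-frequency pulsatile component of ``pulse_amplitude``."""
    p = config.arterial
    if p.end_map < p.start_map:
        import logging

        logging.getLogger(__name__).warning(
            "arterial end_map %.3g < start_map %.3g: simulating a falling ramp",
            p.end_map,
            p.start_map,
        )
    t = _time_grid(config)
    cpr = _cpr_mask(config, t)
    frac = np.clip((t - config.cpr_start) / config.cpr_duration, 0.0, 1.0)
    mean_pressure = np.where(
        t < config.cpr_start,
        p.start_map,
        np.where(cpr, p.start_map + (p.end_map - p.start_map) * frac, p.end_map),
    )
    samples = mean_pressure + p.pulse_amplitude * _compression_component(config, t)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)
    return samples


def _noiseless_etco2(config: SimConfig, t: np.ndarray) -> np.ndarray:
    p = config.etco2
    tr = t - config.cpr_start
    descent = p.dip_value + (p.baseline - p.dip_value) * np.exp(
        -np.clip(tr, 0.0, None) / p.transition_width
    )
    # clip the logistic argument so sharp transitions cannot overflow exp
    z = np.clip((tr - p.surge_time) / p.transition_width, -500.0, 500.0)
    surge = (p.surge_value - p.dip_value) / (1.0 + np.exp(-z))
    during = descent + surge
    return np.where(t < config.cpr_start, 0.0, during)


def generate_etco2(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Capnography samples plus the true >100%-rise time (absolute seconds).

    The noiseless trace starts near ``baseline`` at CPR start, decays to
    ``dip_value``, then rises sigmoidally to ``surge_value`` around
    ``surge_time``.  The true rise time is the first sample in the CPR
    interval where the noiseless trace exceeds twice its running minimum.
    """
    t = _time_grid(config)
    clean = _noiseless_etco2(config, t)

    cpr = _cpr_mask(config, t)
    idx = np.nonzero(cpr)[0]
    seg = clean[idx]
    running_min = np.minimum.accumulate(seg)
    crossing = np.nonzero(seg > 2.0 * running_min)[0]
    if crossing.size == 0:  # pragma: no cover - excluded by Etco2Params check
        raise ValueError("etco2 config produced no detectable >100% rise")
    true_rise_time = idx[crossing[0]] / config.sampling_rate

    samples = clean
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)
    return samples, true_rise_time


def generate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Assemble the full five-channel recording and its ground truth.

    Channel order: ``tail_venous, femoral_venous, central_venous, arterial,
    etco2``.  Identical configs (including ``rng_seed``) give bit-identical
    sample matrices.
    """
    rng = np.random.default_rng(config.rng_seed)

    channels: list[np.ndarray] = []
    names: list[str] = []
    kinds: dict[str, str] = {}
    peak_times: dict[str, float] = {}

    for site in VENOUS_SITES:
        if site not in config.sites:
            raise ValueError(f"config lacks envelope parameters for site {site!r}")
        samples, peak = generate_venous_channel(config, site, rng=rng)
        name = f"{site}_venous"
        channels.append(samples)
        names.append(name)
        kinds[name] = "venous"
        peak_times[site] = peak

    channels.append(generate_arterial_channel(config, rng=rng))
    names.append("arterial")
    kinds["arterial"] = "arterial"

    etco2_samples, rise_time = generate_etco2(config, rng=rng)
    channels.append(etco2_samples)
    names.append("etco2")
    kinds["etco2"] = "etco2"

    recording = Recording(
        channel_names=names,
        samples=np.vstack(channels),
        sampling_rate=config.sampling_rate,
        annotations=Annotations(
            cpr_start=config.cpr_start,
            rosc_time=config.rosc_time,
            nominal_compression_rate=config.compression_rate,
        ),
        channel_kinds=kinds,
    )
    truth = GroundTruth(
        cpr_start=config.cpr_start,
        rosc_time=config.rosc_time,
        true_piva_peak_time=peak_times,
        true_etco2_rise_time=rise_time,
        true_compression_frequency=config.compression_frequency,
    )
    return recording, truth


def default_config(**overrides) -> SimConfig:
    """Convenience constructor for the default simulation scenario."""
    return SimConfig(**overrides)
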