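"""Kinetic simulator for chemiluminescence sessions.

Concentration follows the production/decay balance

    dC/dt = P(t) - k * C,

with piecewise-constant production P(t) and pseudo-first-order decay k,
solved analytically on each constant-P interval:

    C(t) = P/k + (C0 - P/k) * exp(-k * dt).

The instrument renders concentration to photomultiplier counts with a linear
response, a reagent baseline, an optional transit delay through the sampling
tubing (pure first-order loss, exp(-k*tau), no dispersion) and additive
Gaussian noise.  An optional SOD event removes the biogenic term from that
instant onward, emulating the specificity check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from oxylume.traces import (
    SEGMENT_LABELS,
    ChemiluminescenceTrace,
    SegmentAnnotation,
    TraceMetadata,
)

__all__ = [
    "SimulationConfig",
    "SessionPhase",
    "StandardRun",
    "time_grid",
    "simulate_concentration",
    "render_trace",
    "simulate_field_session",
    "simulate_standard_run",
    "simulate_blank_series",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic trace.

    Parameters
    ----------
    production_schedule
        ``(start_s, end_s, P)`` triples with P in nM/s; production is zero
        outside the listed intervals, which must not overlap.
    decay_constant_k
        Pseudo-first-order decay constant, 1/s.
    sensitivity
        Instrument response, counts per pM.
    transit_delay_tau
        Travel time through the sampling tubing, s; the rendered signal is
        attenuated by exp(-k*tau) — uncorrected downstream, so measurements
        are conservative.
    sod_event_time
        If set, the biogenic term is zeroed for t >= this time.
    """

    production_schedule: tuple[tuple[float, float, float], ...] = ()
    decay_constant_k: float = 0.01
    initial_concentration: float = 0.0
    sensitivity: float = 0.3
    baseline_counts: float = 100.0
    noise_sd: float = 0.0
    transit_delay_tau: float = 0.0
    sampling_rate: float = 0.5
    duration: float = 600.0
    sod_event_time: float | None = None
    seed: int = 0
    flow_rate_ml_min: float = 2.0
    matrix: str = "AFRW+DTPA"
    temperature_c: float = 27.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "production_schedule",
            tuple(tuple(map(float, seg)) for seg in self.production_schedule),
        )
        if self.decay_constant_k <= 0:
            raise ValueError("decay_constant_k must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.transit_delay_tau < 0:
            raise ValueError("transit_delay_tau must be non-negative")
        if self.initial_concentration < 0:
            raise ValueError("initial_concentration must be non-negative")
        prev_end = -np.inf
        for start, end, rate in sorted(self.production_schedule):
            if rate < 0:
                raise ValueError("production rates must be non-negative")
            if end <= start:
                raise ValueError("schedule interval must have start < end")
            if start < prev_end:
                raise ValueError("production schedule intervals overlap")
            prev_end = end

    def metadata(self, notes: str = "") -> TraceMetadata:
        return TraceMetadata(
            flow_rate_ml_min=self.flow_rate_ml_min,
            matrix=self.matrix,
            temperature_c=self.temperature_c,
            sampling_rate_hz=self.sampling_rate,
            notes=notes,
        )


def time_grid(config: SimulationConfig) -> np.ndarray:
    """Uniform sample grid [0, duration] at ``config.sampling_rate``."""
    n = int(round(config.duration * config.sampling_rate)) + 1
    return np.arange(n, dtype=float) / config.sampling_rate


def _production_segments(
    config: SimulationConfig,
) -> list[tuple[float, float, float]]:
    """Cover [0, duration] with contiguous (start, end, P) segments."""
    events = sorted(
        (max(0.0, s), min(config.duration, e), p)
        for s, e, p in config.production_schedule
        if e > 0 and s < config.duration
    )
    segments: list[tuple[float, float, float]] = []
    cursor = 0.0
    for start, end, rate in events:
        if start > cursor:
            segments.append((cursor, start, 0.0))
        segments.append((start, end, rate))
        cursor = end
    if cursor < config.duration:
        segments.append((cursor, config.duration, 0.0))
    return segments


def simulate_concentration(config: SimulationConfig) -> np.ndarray:
    """Exact concentration (nM) on the trace grid.

    Solves dC/dt = P(t) - k*C piecewise-analytically, so there is no
    integration error at any step size.  Concentrations are floored at zero
    (negative values can arise only after blank subtraction downstream,
    never here).
    """
    times = time_grid(config)
    k = config.decay_constant_k
    conc = np.empty_like(times)
    c0 = config.initial_concentration
    for start, end, rate in _production_segments(config):
        css = rate / k
        mask = (times >= start) & (times <= end)
        conc[mask] = css + (c0 - css) * np.exp(-k * (times[mask] - start))
        c0 = css + (c0 - css) * np.exp(-k * (end - start))
    return np.maximum(conc, 0.0)


def render_trace(
    concentration: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    notes: str = "",
) -> ChemiluminescenceTrace:
    """Convert a concentration series (nM) to photomultiplier counts.

    counts(t) = baseline + s * 1000 * C(t - tau) * exp(-k*tau) + N(0, noise_sd)

    with C treated as zero before t = 0 and the biogenic term zeroed from
    ``sod_event_time`` onward.  The factor 1000 converts nM to pM to match
    the counts-per-pM sensitivity.  Noise is drawn from ``rng`` or, when not
    supplied, from a fresh generator seeded with ``config.seed`` (identical
    config + seed gives a bit-identical trace).
    """
    times = time_grid(config)
    concentration = np.asarray(concentration, dtype=float)
    if concentration.shape != times.shape:
        raise ValueError("concentration series must live on the config time grid")
    tau = config.transit_delay_tau
    delayed = np.interp(times - tau, times, concentration, left=0.0)
    attenuation = np.exp(-config.decay_constant_k * tau)
    biogenic = config.sensitivity * 1000.0 * delayed * attenuation
    if config.sod_event_time is not None:
        biogenic = np.where(times >= config.sod_event_time, 0.0, biogenic)
    counts = config.baseline_counts + biogenic
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        counts = counts + rng.normal(0.0, config.noise_sd, size=counts.shape)
    return ChemiluminescenceTrace(times, counts, config.metadata(notes))


@dataclass(frozen=True)
class SessionPhase:
    """One phase of a field session: where the tubing is and for how long."""

    label: str
    duration: float
    production: float = 0.0  # nM/s while this phase lasts

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(
                f"unknown phase label {self.label!r}; expected one of {SEGMENT_LABELS}"
            )
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.production < 0:
            raise ValueError("phase production must be non-negative")


def simulate_field_session(
    config: SimulationConfig, plan: Sequence[SessionPhase]
) -> tuple[ChemiluminescenceTrace, list[SegmentAnnotation]]:
    """Render one continuous trace following a phase plan.

    The plan's first phase must be ``reagent_blank`` (the session protocol
    starts on the boat with the reagent blank).  Production steps between
    phases per the plan; a ``sod_check`` phase triggers the SOD quench at its
    start.  The config's own ``production_schedule``, ``duration`` and
    ``sod_event_time`` are ignored in favour of the plan.
    """
    if not plan:
        raise ValueError("plan must contain at least one phase")
    if plan[0].label != "reagent_blank":
        raise ValueError("the first phase of a session plan must be 'reagent_blank'")
    schedule: list[tuple[float, float, float]] = []
    annotations: list[SegmentAnnotation] = []
    sod_time: float | None = None
    cursor = 0.0
    for phase in plan:
        start, end = cursor, cursor + phase.duration
        if phase.label == "sod_check" and sod_time is None:
            sod_time = start
        if phase.production > 0:
            schedule.append((start, end, phase.production))
        annotations.append(SegmentAnnotation(phase.label, start, end))
        cursor = end
    session_config = dataclasses.replace(
        config,
        production_schedule=tuple(schedule),
        duration=cursor,
        sod_event_time=sod_time,
    )
    conc = simulate_concentration(session_config)
    trace = render_trace(conc, session_config, notes="simulated field session")
    return trace, annotations


@dataclass(frozen=True)
class StandardRun:
    """A rendered calibration-standard injection and when it happened."""

    trace: ChemiluminescenceTrace
    injection_time: float


def simulate_standard_run(
    c0: float,
    k: float,
    config: SimulationConfig,
    baseline_duration: float = 60.0,
) -> StandardRun:
    """Simulate a secondary-standard injection: a blank baseline phase, then
    an instantaneous step to ``c0`` nM decaying as C0*exp(-k*(t - t_inject)).

    Rendered with zero transit delay (standards are pumped straight into the
    flow cell).
    """
    if c0 <= 0:
        raise ValueError("standard concentration c0 must be positive")
    if k <= 0:
        raise ValueError("decay constant k must be positive")
    if not 0 <= baseline_duration < config.duration:
        raise ValueError("baseline_duration must lie within the trace duration")
    run_config = dataclasses.replace(
        config,
        decay_constant_k=k,
        transit_delay_tau=0.0,
        sod_event_time=None,
        production_schedule=(),
        initial_concentration=0.0,
    )
    times = time_grid(run_config)
    conc = np.where(
        times >= baseline_duration,
        c0 * np.exp(-k * (times - baseline_duration)),
        0.0,
    )
    trace = render_trace(
        conc, run_config, notes=f"standard injection at t={baseline_duration}s"
    )
    return StandardRun(trace=trace, injection_time=baseline_duration)


def simulate_blank_series(n: int, sd: float, seed: int) -> np.ndarray:
    """``n`` replicate blank concentration readings, Gaussian(0, sd) nM.

    At least three replicates are required (a detection limit needs a
    defensible s.d.).
    """
    if n < 3:
        raise ValueError("a blank series needs at least 3 replicates")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return np.random.default_rng(seed).normal(0.0, sd, size=n)
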