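"""Trace containers, CSV I/O, plateau detection and blank correction.

A :class:`ChemiluminescenceTrace` is the unit every pipeline stage consumes
or produces: a uniformly sampled photomultiplier time series plus the
acquisition metadata needed to interpret it (flow rate, matrix, temperature,
sampling rate).

The on-disk format is plain CSV with a ``#key=value`` metadata header::

    #flow_rate_ml_min=2.0
    #matrix=AFRW+DTPA
    #temperature_c=27.0
    #sampling_rate_hz=0.5
    time_s,luminescence_counts
    0.0,101.3
    ...

Segment annotations live in a sidecar CSV with columns
``label,start_s,end_s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "SEGMENT_LABELS",
    "TraceFormatError",
    "SchemeMismatchError",
    "TraceMetadata",
    "ChemiluminescenceTrace",
    "SegmentAnnotation",
    "PlateauConfig",
    "SegmentStats",
    "CorrectedSignal",
    "read_trace",
    "write_trace",
    "read_annotations",
    "write_annotations",
    "detect_plateau",
    "segment_stats",
    "verify_sod_quench",
    "correct_signal",
    "peak_corrected_reading",
]

#: Recognized segment labels, in the order phases typically occur in a session.
SEGMENT_LABELS = (
    "reagent_blank",
    "background_sw_surface",
    "background_sw_depth",
    "coral_surface",
    "sod_check",
    "standard_decay",
)

#: Metadata keys required in the trace CSV header.
_REQUIRED_METADATA = ("flow_rate_ml_min", "matrix", "temperature_c", "sampling_rate_hz")

#: Tolerance for grid-uniformity checks, in seconds.
_GRID_TOL = 1e-9


class TraceFormatError(ValueError):
    """Raised when a trace or annotation file violates the CSV dialect."""


class SchemeMismatchError(ValueError):
    """Raised when a blank-correction scheme is fed the wrong reference segment."""


@dataclass(frozen=True)
class TraceMetadata:
    """Acquisition metadata carried with every trace."""

    flow_rate_ml_min: float
    matrix: str
    temperature_c: float
    sampling_rate_hz: float
    notes: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.flow_rate_ml_min < 0:
            raise ValueError("flow_rate_ml_min must be non-negative")


@dataclass
class ChemiluminescenceTrace:
    """Uniformly sampled photomultiplier counts with acquisition metadata."""

    times: np.ndarray
    luminescence: np.ndarray
    metadata: TraceMetadata

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.luminescence = np.asarray(self.luminescence, dtype=float)
        if self.times.ndim != 1 or self.luminescence.ndim != 1:
            raise ValueError("times and luminescence must be 1-D")
        if self.times.size != self.luminescence.size:
            raise ValueError("times and luminescence must have equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.luminescence)):
            raise ValueError("luminescence contains non-finite values")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        expected = 1.0 / self.metadata.sampling_rate_hz
        if np.any(np.abs(dt - expected) > _GRID_TOL):
            raise ValueError(
                "times are not a uniform grid at "
                f"{self.metadata.sampling_rate_hz} Hz (within {_GRID_TOL} s)"
            )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def window_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of samples with ``start <= t <= end``."""
        return (self.times >= start) & (self.times <= end)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChemiluminescenceTrace):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.luminescence, other.luminescence)
            and self.metadata == other.metadata
        )


@dataclass(frozen=True)
class SegmentAnnotation:
    """Labelled time window within a trace."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(
                f"unknown segment label {self.label!r}; expected one of {SEGMENT_LABELS}"
            )
        if not self.start < self.end:
            raise ValueError("annotation start must precede end")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_trace(trace: ChemiluminescenceTrace, path: str | Path) -> Path:
    """Write a trace to the ``#key=value`` header CSV dialect. Lossless."""
    path = Path(path)
    md = trace.metadata
    lines = [
        f"#flow_rate_ml_min={float(md.flow_rate_ml_min)!r}",
        f"#matrix={md.matrix}",
        f"#temperature_c={float(md.temperature_c)!r}",
        f"#sampling_rate_hz={float(md.sampling_rate_hz)!r}",
    ]
    if md.notes:
        lines.append(f"#notes={md.notes}")
    lines.append("time_s,luminescence_counts")
    for t, lum in zip(trace.times, trace.luminescence):
        lines.append(f"{float(t)!r},{float(lum)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path: str | Path) -> ChemiluminescenceTrace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        On a malformed header, a missing metadata field, non-monotone times
        or non-numeric counts; the message names the offending line or field.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    counts: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise TraceFormatError(
                        f"{path}:{lineno}: metadata after the column header"
                    )
                if "=" not in line:
                    raise TraceFormatError(
                        f"{path}:{lineno}: malformed metadata line {line!r}"
                    )
                key, value = line[1:].split("=", 1)
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "time_s,luminescence_counts":
                    raise TraceFormatError(
                        f"{path}:{lineno}: expected column header "
                        f"'time_s,luminescence_counts', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TraceFormatError(f"{path}:{lineno}: expected two columns")
            try:
                t, lum = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}:{lineno}: non-numeric value: {exc}"
                ) from None
            if times and t <= times[-1]:
                raise TraceFormatError(
                    f"{path}:{lineno}: time {t} is not greater than the previous "
                    f"sample ({times[-1]})"
                )
            times.append(t)
            counts.append(lum)
    for key in _REQUIRED_METADATA:
        if key not in meta:
            raise TraceFormatError(f"{path}: missing metadata field {key!r}")
    try:
        metadata = TraceMetadata(
            flow_rate_ml_min=float(meta["flow_rate_ml_min"]),
            matrix=meta["matrix"],
            temperature_c=float(meta["temperature_c"]),
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            notes=meta.get("notes", ""),
        )
    except ValueError as exc:
        raise TraceFormatError(f"{path}: bad metadata value: {exc}") from None
    if not header_seen or not times:
        raise TraceFormatError(f"{path}: no data rows found")
    try:
        return ChemiluminescenceTrace(np.array(times), np.array(counts), metadata)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


def write_annotations(annotations: Iterable[SegmentAnnotation], path: str | Path) -> Path:
    path = Path(path)
    lines = ["label,start_s,end_s"]
    for ann in annotations:
        lines.append(f"{ann.label},{float(ann.start)!r},{float(ann.end)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_annotations(path: str | Path) -> list[SegmentAnnotation]:
    path = Path(path)
    out: list[SegmentAnnotation] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or lineno == 1 and line.startswith("label"):
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise TraceFormatError(f"{path}:{lineno}: expected three columns")
            try:
                out.append(
                    SegmentAnnotation(parts[0], float(parts[1]), float(parts[2]))
                )
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# Plateau detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateauConfig:
    """Rolling coefficient-of-variation plateau criterion.

    A plateau is a contiguous run of rolling windows of ``window_length``
    seconds whose CV (sd/mean) stays below ``cv_threshold`` and that spans at
    least ``min_duration`` seconds.  The 0.04 default threshold is the <4% CV
    baseline-stability rule; ``min_duration`` defaults to 60 s for biological
    plateaus (use 120 s for reagent blanks).
    """

    window_length: float = 30.0
    cv_threshold: float = 0.04
    min_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 < self.cv_threshold < 1:
            raise ValueError("cv_threshold must lie in (0, 1)")
        if self.min_duration < 0:
            raise ValueError("min_duration must be non-negative")


@dataclass(frozen=True)
class SegmentStats:
    """Mean +/- temporal s.d. of counts over a detected segment."""

    label: str
    mean: float
    sd: float
    n_points: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("segment statistics require at least two points")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def segment_stats(
    trace: ChemiluminescenceTrace, window: SegmentAnnotation | tuple[float, float]
) -> SegmentStats:
    """Mean/sd of all samples inside a window, without any plateau screening."""
    label, start, end = _unpack_window(window)
    mask = trace.window_mask(start, end)
    values = trace.luminescence[mask]
    if values.size < 2:
        raise ValueError("window contains fewer than two samples")
    t = trace.times[mask]
    return SegmentStats(
        label=label,
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        n_points=int(values.size),
        start=float(t[0]),
        end=float(t[-1]),
    )


def _unpack_window(
    window: SegmentAnnotation | tuple[float, float],
) -> tuple[str, float, float]:
    if isinstance(window, SegmentAnnotation):
        return window.label, window.start, window.end
    start, end = window
    return "window", float(start), float(end)


def detect_plateau(
    trace: ChemiluminescenceTrace,
    window: SegmentAnnotation | tuple[float, float],
    config: PlateauConfig | None = None,
) -> SegmentStats | None:
    """Find the latest stable plateau inside an annotated window.

    Rolling windows of ``config.window_length`` seconds are slid across the
    annotated span; a window qualifies when its mean is positive and its CV
    (sample sd / mean) is below ``config.cv_threshold``.  The latest
    contiguous run of qualifying windows covering at least
    ``config.min_duration`` seconds is returned, with mean/sd computed over
    every sample the run covers.  Returns ``None`` when no run qualifies.

    Windows with non-positive mean are ineligible (CV undefined), not an
    error.  The latest run (not the first) is returned because field protocol
    reads the final steady state before the tubing is moved.
    """
    if config is None:
        config = PlateauConfig()
    label, start, end = _unpack_window(window)
    mask = trace.window_mask(start, end)
    values = trace.luminescence[mask]
    times = trace.times[mask]
    fs = trace.metadata.sampling_rate_hz
    w = max(2, int(round(config.window_length * fs)))
    if values.size < w:
        return None

    n_windows = values.size - w + 1
    good = np.zeros(n_windows, dtype=bool)
    for j in range(n_windows):
        chunk = values[j : j + w]
        mean = chunk.mean()
        if mean <= 0:
            continue
        cv = chunk.std(ddof=1) / mean
        good[j] = cv < config.cv_threshold

    best: tuple[int, int] | None = None
    j = 0
    while j < n_windows:
        if not good[j]:
            j += 1
            continue
        j0 = j
        while j < n_windows and good[j]:
            j += 1
        first, last = j0, j - 1 + w - 1  # sample indices covered by the run
        if times[last] - times[first] >= config.min_duration:
            best = (first, last)  # keep scanning: latest qualifying run wins
    if best is None:
        return None
    first, last = best
    run = values[first : last + 1]
    return SegmentStats(
        label=label,
        mean=float(run.mean()),
        sd=float(run.std(ddof=1)),
        n_points=int(run.size),
        start=float(times[first]),
        end=float(times[last]),
    )


# ---------------------------------------------------------------------------
# SOD verification and blank correction
# ---------------------------------------------------------------------------


def verify_sod_quench(
    surface: SegmentStats, post_sod: SegmentStats, reagent_blank: SegmentStats
) -> bool:
    """Check that adding SOD collapsed the signal to (or slightly below) the
    reagent-blank baseline: ``post_sod.mean <= blank.mean + 2*blank.sd`` and
    ``post_sod.mean < surface.mean``."""
    return (
        post_sod.mean <= reagent_blank.mean + 2.0 * reagent_blank.sd
        and post_sod.mean < surface.mean
    )


#: scheme -> set of labels accepted for the reference segment
_SCHEME_REFERENCE_LABELS = {
    "coral_minus_sw": {"background_sw_surface", "background_sw_depth"},
    "raw_minus_reagent_blank": {"reagent_blank"},
}


@dataclass(frozen=True)
class CorrectedSignal:
    """Blank-corrected counts with the scheme and segments that produced it.

    ``value`` may be negative (a surface dimmer than its background is a
    real, reportable outcome) and is never clipped.  ``sd`` carries the
    temporal s.d. of the target segment for downstream propagation.
    """

    value: float
    scheme: str
    provenance: tuple[str, ...]
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEME_REFERENCE_LABELS:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; expected one of "
                f"{sorted(_SCHEME_REFERENCE_LABELS)}"
            )
        if not self.provenance:
            raise ValueError("provenance must record the segments used")


def correct_signal(
    target: SegmentStats, reference: SegmentStats, scheme: str
) -> CorrectedSignal:
    """Subtract a reference segment from a target segment.

    ``coral_minus_sw`` removes both the seawater and reagent blanks in one
    subtraction (reference must be a background-seawater segment);
    ``raw_minus_reagent_blank`` subtracts the reagent blank only.
    """
    if scheme not in _SCHEME_REFERENCE_LABELS:
        raise SchemeMismatchError(
            f"unknown scheme {scheme!r}; expected one of "
            f"{sorted(_SCHEME_REFERENCE_LABELS)}"
        )
    allowed = _SCHEME_REFERENCE_LABELS[scheme]
    if reference.label not in allowed:
        raise SchemeMismatchError(
            f"scheme {scheme!r} requires a reference labelled "
            f"{sorted(allowed)}, got {reference.label!r}"
        )
    return CorrectedSignal(
        value=target.mean - reference.mean,
        scheme=scheme,
        provenance=(target.label, reference.label),
        sd=target.sd,
    )


def peak_corrected_reading(
    trace: ChemiluminescenceTrace,
    window: SegmentAnnotation | tuple[float, float],
    reference: SegmentStats,
) -> float:
    """Maximum single reference-subtracted reading within a window.

    Convention-dependent: how per-specimen "peak" levels were selected is not
    specified by the protocol, so the maximum single corrected sample is
    reported and callers should flag it as such.
    """
    _, start, end = _unpack_window(window)
    values = trace.luminescence[trace.window_mask(start, end)]
    if values.size == 0:
        raise ValueError("window contains no samples")
    return float(values.max() - reference.mean)
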