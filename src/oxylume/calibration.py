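"""KO2 calibration: primary standards, decay fits, back-extrapolation, curves.

Primary KO2 standards are quantified by the drop in absorbance at 240 nm
after SOD addition (Beer-Lambert, molar absorptivity 2,183 L/mol/cm at
pH 12.5, already corrected for the hydrogen peroxide formed during decay).
Secondary standards decay while being pumped to the flow cell, so the
observed luminescence is fit log-linearly (first-order kinetics) and
extrapolated backwards to the instant the primary standard was quantified.
The calibration curve regresses extrapolated luminescence on concentration;
its inverse slope is the sensitivity in pM per count and the 3-sigma blank
rule gives the detection limit.

Concentrations are handled internally in nM; sensitivity is reported in pM
per count (conversions live in :mod:`oxylume.units`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats as sps

from oxylume.traces import ChemiluminescenceTrace
from oxylume.units import pm_per_count_from_slope

__all__ = [
    "EPSILON_SUPEROXIDE_240NM",
    "InvalidDecayFitError",
    "ExtrapolationSpanWarning",
    "PrimaryStandard",
    "DecayFit",
    "CalibrationPoint",
    "CalibrationCurve",
    "quantify_primary_standard",
    "fit_decay",
    "extrapolate_luminescence",
    "build_calibration",
    "detection_limit",
    "half_life",
]

#: Molar absorptivity of superoxide at 240 nm, pH 12.5, L/(mol cm);
#: treated as already corrected for H2O2 absorbance.
EPSILON_SUPEROXIDE_240NM = 2183.0

#: Default floor on the calibration correlation coefficient.
DEFAULT_R_FLOOR = 0.93

#: Default cap on back-extrapolation span, seconds.
DEFAULT_SPAN_CAP = 120.0


class InvalidDecayFitError(ValueError):
    """Raised when a decay window cannot support a first-order fit."""


class ExtrapolationSpanWarning(UserWarning):
    """Emitted when back-extrapolation exceeds the configured span cap."""


@dataclass(frozen=True)
class PrimaryStandard:
    """A240 readings bracketing SOD addition, for Beer-Lambert quantification."""

    a240_before: float
    a240_after_sod: float
    path_length_cm: float = 1.0
    epsilon: float = EPSILON_SUPEROXIDE_240NM

    def __post_init__(self) -> None:
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not self.a240_before > self.a240_after_sod:
            raise ValueError(
                "a240_before must exceed a240_after_sod (SOD removes superoxide "
                "absorbance)"
            )


def quantify_primary_standard(std: PrimaryStandard) -> float:
    """Superoxide concentration of a primary standard, mol/L.

    C = (A_before - A_after) / (epsilon * path_length).
    """
    delta = std.a240_before - std.a240_after_sod
    return delta / (std.epsilon * std.path_length_cm)


@dataclass(frozen=True)
class DecayFit:
    """Log-linear first-order decay fit: ln(counts - baseline) = a - k t."""

    k: float
    log_intercept: float
    r_squared: float
    fit_window: tuple[float, float]
    baseline_used: float
    n_points: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("a valid decay fit requires k > 0")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def half_life(self) -> float:
        return half_life(self.k)

    def predict(self, t: float | np.ndarray) -> np.ndarray:
        """Baseline-subtracted luminescence predicted at time t."""
        return np.exp(self.log_intercept - self.k * np.asarray(t, dtype=float))


def fit_decay(
    trace: ChemiluminescenceTrace,
    window: tuple[float, float],
    baseline: float,
) -> DecayFit:
    """Ordinary least squares on ln(luminescence - baseline) versus time.

    Samples whose baseline-subtracted signal is non-positive are dropped
    (and counted in ``n_dropped``); at least 5 usable points are required.
    A non-positive fitted k signals non-decaying input and raises
    :class:`InvalidDecayFitError`.
    """
    start, end = window
    mask = trace.window_mask(start, end)
    t = trace.times[mask]
    signal = trace.luminescence[mask] - baseline
    usable = signal > 0
    n_dropped = int(np.sum(~usable))
    t, signal = t[usable], signal[usable]
    if t.size < 5:
        raise InvalidDecayFitError(
            f"decay fit needs >= 5 points above baseline, got {t.size} "
            f"({n_dropped} dropped)"
        )
    result = sps.linregress(t, np.log(signal))
    k = -result.slope
    if k <= 0:
        raise InvalidDecayFitError(
            f"fitted rate constant {k:.3g} /s is not positive; input does not decay"
        )
    r_squared = 0.0 if math.isnan(result.rvalue) else float(result.rvalue**2)
    return DecayFit(
        k=float(k),
        log_intercept=float(result.intercept),
        r_squared=r_squared,
        fit_window=(float(start), float(end)),
        baseline_used=float(baseline),
        n_points=int(t.size),
        n_dropped=n_dropped,
    )


def extrapolate_luminescence(
    fit: DecayFit,
    quant_time: float,
    read_time: float,
    span_cap: float = DEFAULT_SPAN_CAP,
) -> float:
    """Baseline-subtracted luminescence extrapolated back to ``quant_time``.

    Under the fitted model, L0 = exp(log_intercept - k * quant_time), which
    equals the observed level at ``read_time`` multiplied by
    exp(k * (read_time - quant_time)).  Spans beyond ``span_cap`` produce an
    :class:`ExtrapolationSpanWarning` rather than a silent result.
    """
    if read_time < quant_time:
        raise ValueError("read_time must not precede quant_time")
    span = read_time - quant_time
    if span > span_cap:
        warnings.warn(
            f"extrapolation span {span:.1f} s exceeds the {span_cap:.0f} s cap; "
            "result amplifies fit error accordingly",
            ExtrapolationSpanWarning,
            stacklevel=2,
        )
    return float(np.exp(fit.log_intercept - fit.k * quant_time))


@dataclass(frozen=True)
class CalibrationPoint:
    """One standard: known concentration vs back-extrapolated luminescence."""

    concentration_nm: float
    extrapolated_luminescence: float
    extrapolation_time: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_nm <= 0:
            raise ValueError("concentration_nm must be positive")
        if self.extrapolation_time < 0:
            raise ValueError("extrapolation_time must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration with sensitivity, detection limit and matrix decay.

    ``slope`` is in counts per nM, ``sensitivity`` its inverse expressed in
    pM per count (sensitivity * slope == 1000).  ``acceptable`` is False when
    the correlation fell below the configured floor; quantification refuses
    flagged curves unless overridden.
    """

    slope: float
    intercept: float
    correlation_r: float
    sensitivity: float
    detection_limit: float
    matrix_half_life: float
    n_points: int
    acceptable: bool = True
    curve_id: str = "curve-0"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a calibration curve needs >= 3 points")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be non-negative")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationCurve":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def detection_limit(blanks: Sequence[float]) -> float:
    """Method detection limit: 3 x sample s.d. (ddof=1) of replicate blanks."""
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 3:
        raise ValueError("detection limit needs >= 3 blank replicates")
    return float(3.0 * np.std(blanks, ddof=1))


def build_calibration(
    points: Sequence[CalibrationPoint],
    blanks: Sequence[float],
    matrix_k: float,
    r_floor: float = DEFAULT_R_FLOOR,
    curve_id: str = "curve-0",
) -> CalibrationCurve:
    """OLS of extrapolated luminescence on concentration, with a free intercept.

    Requires >= 3 points spanning at least a factor of 2 in concentration.
    The intercept is kept free and reported so blank-correction failures are
    visible.  A Pearson r below ``r_floor`` yields a curve flagged
    ``acceptable=False`` rather than an exception.
    """
    if len(points) < 3:
        raise ValueError(f"calibration needs >= 3 points, got {len(points)}")
    conc = np.array([p.concentration_nm for p in points], dtype=float)
    lum = np.array([p.extrapolated_luminescence for p in points], dtype=float)
    if conc.max() / conc.min() < 2.0:
        raise ValueError(
            "calibration standards must span at least a factor of 2 in concentration"
        )
    if matrix_k <= 0:
        raise ValueError("matrix_k must be positive")
    result = sps.linregress(conc, lum)
    slope = float(result.slope)
    if slope <= 0:
        raise ValueError(f"calibration slope {slope:.3g} counts/nM is not positive")
    r = float(result.rvalue)
    return CalibrationCurve(
        slope=slope,
        intercept=float(result.intercept),
        correlation_r=r,
        sensitivity=pm_per_count_from_slope(slope),
        detection_limit=detection_limit(blanks),
        matrix_half_life=half_life(matrix_k),
        n_points=len(points),
        acceptable=r >= r_floor,
        curve_id=curve_id,
    )


def half_life(k: float) -> float:
    """First-order half-life ln(2)/k; k must be positive (units follow k)."""
    if k <= 0:
        raise ValueError("half-life requires k > 0")
    return math.log(2.0) / k
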