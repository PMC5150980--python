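"""Signals to concentrations, seawater normalization, production rates.

Blank-corrected counts become concentrations through a calibration curve.
For the ``coral_minus_sw`` scheme the curve intercept cancels in the
subtraction, so only the slope is applied; for ``raw_minus_reagent_blank``
the intercept is subtracted first.  Negative concentrations are passed
through unchanged.  No transit-decay correction is applied — quantified
values are deliberately conservative.

Net production rate is steady-state concentration times carrier flow rate,
converted to mol/h and optionally normalized per organism on the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from oxylume.calibration import CalibrationCurve
from oxylume.traces import CorrectedSignal
from oxylume.units import choose_amount_unit, nm_flow_to_mol_per_hour

__all__ = [
    "SuperoxideMeasurement",
    "ProductionRate",
    "signal_to_concentration",
    "measurement_from_signal",
    "seawater_normalize",
    "net_production_rate",
    "per_organism_rate",
    "production_rate",
]


@dataclass(frozen=True)
class SuperoxideMeasurement:
    """Steady-state concentration with temporal s.d. and provenance."""

    concentration: float  # nM
    temporal_sd: float  # nM, s.d. of the temporal signal
    scheme: str
    curve_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temporal_sd < 0:
            raise ValueError("temporal_sd must be non-negative")


@dataclass(frozen=True)
class ProductionRate:
    """Total and per-organism net superoxide production."""

    steady_state_concentration: float  # nM
    flow_rate: float  # ml/min
    n_organisms: int
    rate_total: float  # mol/h
    rate_per_organism: float  # mol/organism/h

    @property
    def per_organism_display(self) -> tuple[float, str]:
        """Per-organism rate in the customary unit (fmol or amol) per hour."""
        return choose_amount_unit(self.rate_per_organism)


def signal_to_concentration(
    corrected: CorrectedSignal,
    curve: CalibrationCurve,
    allow_flagged: bool = False,
) -> float:
    """Convert blank-corrected counts to nM via the calibration curve.

    The curve intercept is applied only for the ``raw_minus_reagent_blank``
    scheme; a coral-minus-seawater difference cancels it.  Negative corrected
    values yield negative concentrations, which are real results and
    propagate unchanged.
    """
    if not curve.acceptable and not allow_flagged:
        raise ValueError(
            f"calibration {curve.curve_id!r} is failure-flagged "
            f"(r={curve.correlation_r:.3f}); pass allow_flagged=True to override"
        )
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    adjustment = curve.intercept if corrected.scheme == "raw_minus_reagent_blank" else 0.0
    return (corrected.value - adjustment) / curve.slope


def measurement_from_signal(
    corrected: CorrectedSignal,
    curve: CalibrationCurve,
    allow_flagged: bool = False,
    **metadata: object,
) -> SuperoxideMeasurement:
    """Full measurement record: concentration plus temporal s.d. in nM.

    The temporal s.d. of the counts is divided by |slope|; calibration-fit
    uncertainty is not folded in.
    """
    concentration = signal_to_concentration(corrected, curve, allow_flagged)
    return SuperoxideMeasurement(
        concentration=concentration,
        temporal_sd=corrected.sd / abs(curve.slope),
        scheme=corrected.scheme,
        curve_id=curve.curve_id,
        metadata=dict(metadata),
    )


def seawater_normalize(
    coral: SuperoxideMeasurement, background: SuperoxideMeasurement
) -> SuperoxideMeasurement:
    """Subtract the background-seawater concentration from the coral value.

    Both measurements must come from the same calibration curve; the
    temporal s.d. values combine in quadrature.
    """
    if coral.curve_id != background.curve_id:
        raise ValueError(
            f"curve mismatch: coral used {coral.curve_id!r}, "
            f"background used {background.curve_id!r}"
        )
    combined_sd = (coral.temporal_sd**2 + background.temporal_sd**2) ** 0.5
    return SuperoxideMeasurement(
        concentration=coral.concentration - background.concentration,
        temporal_sd=combined_sd,
        scheme="coral_minus_sw",
        curve_id=coral.curve_id,
        metadata={**background.metadata, **coral.metadata},
    )


def net_production_rate(css_nm: float, flow_rate_ml_min: float) -> float:
    """Net production, mol/h: steady-state concentration times flow rate."""
    if flow_rate_ml_min <= 0:
        raise ValueError("flow_rate_ml_min must be positive")
    return nm_flow_to_mol_per_hour(css_nm, flow_rate_ml_min)


def per_organism_rate(rate_total_mol_per_h: float, n_organisms: int) -> float:
    """Rate divided across the organisms loaded on the filter, mol/organism/h."""
    if n_organisms < 1:
        raise ValueError("n_organisms must be at least 1")
    return rate_total_mol_per_h / n_organisms


def production_rate(
    css_nm: float, flow_rate_ml_min: float, n_organisms: int
) -> ProductionRate:
    """Convenience constructor combining the two rate operations."""
    total = net_production_rate(css_nm, flow_rate_ml_min)
    return ProductionRate(
        steady_state_concentration=css_nm,
        flow_rate=flow_rate_ml_min,
        n_organisms=n_organisms,
        rate_total=total,
        rate_per_organism=per_organism_rate(total, n_organisms),
    )
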