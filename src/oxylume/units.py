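"""Centralized unit conversions (concentration and amount-rate scales)."""

from __future__ import annotations

__all__ = [
    "PM_PER_NM",
    "MOL_PER_FMOL",
    "MOL_PER_AMOL",
    "pm_per_count_from_slope",
    "nm_flow_to_mol_per_hour",
    "choose_amount_unit",
]

PM_PER_NM = 1000.0  # picomolar per nanomolar
MOL_PER_FMOL = 1e-15
MOL_PER_AMOL = 1e-18


def pm_per_count_from_slope(slope_counts_per_nm: float) -> float:
    """Sensitivity in pM per count from a calibration slope in counts per nM."""
    if slope_counts_per_nm <= 0:
        raise ValueError("slope must be positive")
    return PM_PER_NM / slope_counts_per_nm


def nm_flow_to_mol_per_hour(concentration_nm: float, flow_rate_ml_min: float) -> float:
    """mol/h delivered by a concentration (nM) at a carrier flow (ml/min)."""
    return concentration_nm * 1e-9 * flow_rate_ml_min * 1e-3 * 60.0


def choose_amount_unit(rate_mol_per_hour: float) -> tuple[float, str]:
    """Express a molar rate in the customary reporting unit.

    Rates >= 1 fmol/h (typical for larvae) are reported in fmol, smaller
    ones (typical for single cells) in amol.
    """
    magnitude = abs(rate_mol_per_hour)
    if magnitude >= MOL_PER_FMOL:
        return rate_mol_per_hour / MOL_PER_FMOL, "fmol"
    return rate_mol_per_hour / MOL_PER_AMOL, "amol"
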