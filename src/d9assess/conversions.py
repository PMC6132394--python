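"""Basis and matrix conversions for biota concentrations.

All operations are linear in the concentration argument and keep stored
values unrounded; presentation rounding (e.g. breathing-water factors shown
to one decimal) is applied only when formatting reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError


@dataclass(frozen=True)
class BasisContext:
    """Matrix composition of a sample or site.

    water_fraction w: water share of the tissue wet weight, in [0, 1);
    breathing_water_fraction b: share of the pooled wet weight contributed
    by retained respiration water (mussel soft-body pools), in [0, 1);
    lipid_fraction l: lipid share of wet weight, in (0, 1).
    The dry-mass fraction is d = 1 - w.
    """

    water_fraction: Optional[float] = None
    breathing_water_fraction: Optional[float] = None
    lipid_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        w, b, l = self.water_fraction, self.breathing_water_fraction, self.lipid_fraction
        if w is not None and not (0 <= w < 1):
            raise ValidationError(f"water_fraction {w} outside [0, 1)")
        if b is not None and not (0 <= b < 1):
            raise ValidationError(f"breathing_water_fraction {b} outside [0, 1)")
        if l is not None and not (0 < l < 1):
            raise ValidationError(f"lipid_fraction {l} outside (0, 1)")

    @property
    def dry_mass_fraction(self) -> Optional[float]:
        return None if self.water_fraction is None else 1.0 - self.water_fraction


def breathing_water_factor(b: float) -> float:
    """Dilution-correction factor 1/(1-b) for breathing-water share b.

    Mussel soft-body pools retain respiration water, diluting tissue
    concentrations; multiplying by this factor restores a tissue-only
    wet-weight concentration. Returned unrounded (e.g. b=0.58 -> 2.381,
    presented as 2.4 in reports).
    """
    if not (0 <= b < 1):
        raise ValidationError(f"breathing_water_fraction {b} outside [0, 1)")
    return 1.0 / (1.0 - b)


def apply_matrix_correction(value: float, factor: float) -> float:
    """Multiply a measured concentration by a matrix-correction factor >= 1."""
    if factor < 1:
        raise ValidationError(f"matrix correction factor {factor} < 1")
    return value * factor


def threshold_dw_to_ww(threshold_dw: float, w: float) -> float:
    """Convert a dry-weight reference value to wet weight: value x (1-w).

    Used e.g. to express the OSPAR dry-weight EAC for TBT in bivalves on
    the wet-weight scale of the monitoring data, given the site's mean
    tissue water content w.
    """
    if not (0 <= w < 1):
        raise ValidationError(f"water fraction {w} outside [0, 1)")
    return threshold_dw * (1.0 - w)


def wet_to_dry(c_ww: float, w: float) -> float:
    """Convert a wet-weight concentration to dry weight: value / (1-w)."""
    if not (0 <= w < 1):
        raise ValidationError(f"water fraction {w} outside [0, 1)")
    return c_ww / (1.0 - w)


def lipid_normalize(c_ww: float, l: float) -> float:
    """Express a wet-weight concentration per unit lipid mass: value / l."""
    if not (0 < l < 1):
        raise ValidationError(f"lipid_fraction {l} outside (0, 1)")
    return c_ww / l


def round_factor_for_report(factor: float) -> float:
    """Presentation rounding for breathing-water factors.

    Factors are reported to one decimal, with trailing .0 collapsing to an
    integer-valued float (3.03 -> 3.0, 2.381 -> 2.4).  Never applied to
    stored values.
    """
    return round(factor, 1)
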