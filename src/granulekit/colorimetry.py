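"""Iodine-colorimetry amylose calibration and starch-content arithmetic.

Amylose–iodine complexes absorb maximally near 620 nm and
amylopectin–iodine complexes near 535 nm, so the 620/535 absorbance
ratio tracks the amylose fraction of a dispersed starch sample.  The
apparent amylose content (%) is an empirical exponential calibration of
that ratio:

    amylose% = 1.4935 * exp(2.7029 * (A620 / A535))

The calibration constants are fixed empirical values; outputs outside
[0, 100] are returned as-is with a warning, since clamping would hide
assay problems.

Starch content is quantified enzymatically as glucose released per
sample mass (glucose equivalents); an optional anhydro-glucose
correction (162/180) converts released glucose to starch mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .io import ValidationError

__all__ = [
    "AMYLOSE_COEF",
    "AMYLOSE_EXPONENT",
    "ANHYDRO_GLUCOSE_FACTOR",
    "AbsorbancePair",
    "StarchAssay",
    "apparent_amylose",
    "starch_percent",
]

AMYLOSE_COEF = 1.4935
AMYLOSE_EXPONENT = 2.7029
# mass of an anhydro-glucose unit in starch relative to free glucose
ANHYDRO_GLUCOSE_FACTOR = 162.0 / 180.0


@dataclass(frozen=True)
class AbsorbancePair:
    """Absorbances of an iodine-stained starch dispersion."""

    a535: float
    a620: float

    def __post_init__(self) -> None:
        if self.a535 < 0 or self.a620 < 0:
            raise ValidationError("absorbances must be >= 0")


@dataclass(frozen=True)
class StarchAssay:
    """Glucose released (mg glucose equivalents) from a weighed sample (mg)."""

    glucose_released: float
    sample_mass: float

    def __post_init__(self) -> None:
        if self.glucose_released < 0:
            raise ValidationError("glucose_released must be >= 0")
        if self.sample_mass <= 0:
            raise ValidationError("sample_mass must be > 0")


def apparent_amylose(abs_pair: AbsorbancePair) -> float:
    """Apparent amylose content (%) from a 535/620 nm absorbance pair.

    Strictly increasing in the 620/535 ratio and scale-invariant in the
    pair (only the ratio matters).
    """
    if abs_pair.a535 == 0:
        raise ZeroDivisionError("A535 must be positive to form the absorbance ratio")
    value = AMYLOSE_COEF * math.exp(AMYLOSE_EXPONENT * (abs_pair.a620 / abs_pair.a535))
    if not 0.0 <= value <= 100.0:
        warnings.warn(
            f"apparent amylose {value:.2f}% outside [0, 100]; the calibration "
            "is empirical — check the assay",
            UserWarning,
            stacklevel=2,
        )
    return value


def starch_percent(assay: StarchAssay, anhydro_correction: bool = False) -> float:
    """Starch content (%) of a sample on a glucose-equivalent basis.

    With ``anhydro_correction`` the released glucose is scaled by 162/180
    to report polymeric starch mass instead of glucose equivalents.
    """
    factor = ANHYDRO_GLUCOSE_FACTOR if anhydro_correction else 1.0
    return 100.0 * assay.glucose_released * factor / assay.sample_mass
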