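"""Sign rules for induced circular dichroism (ICD) of included chromophores.

An achiral chromophore held by a chiral cyclodextrin host shows ICD whose
sign depends on where the chromophore sits and how its electric transition
dipole is oriented relative to the host's symmetry axis. For a chromophore
*inside* the cavity the band is positive when the transition moment is
parallel to the axis and negative when perpendicular; moving the
chromophore *outside* the cavity reverses both signs. The crossover occurs
at the magic angle, arccos(1/sqrt(3)) = 54.7 deg, where the band
intensity passes through zero. A configurable tolerance band around the
magic angle expresses the experimentally "almost zero" region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = ["MAGIC_ANGLE_DEG", "TransitionGeometry", "icd_sign"]

MAGIC_ANGLE_DEG = 54.7

_LOCATIONS = ("inside", "outside")


@dataclass(frozen=True)
class TransitionGeometry:
    """Location and orientation of one electronic transition moment."""

    location: str  # "inside" or "outside" the host cavity
    angle_to_axis_deg: float  # angle to the host axis, [0, 90]
    label: str = ""  # e.g. "1Bb", "1La", "1Lb"

    def __post_init__(self):
        if self.location not in _LOCATIONS:
            raise InvalidInputError(
                f"location must be one of {_LOCATIONS}, got {self.location!r}")
        if not 0.0 <= self.angle_to_axis_deg <= 90.0:
            raise InvalidInputError("angle must lie in [0, 90] degrees")


def icd_sign(geometry: TransitionGeometry, tolerance_deg: float = 3.0) -> str:
    """Predict the ICD band sign: "positive", "negative" or "near-zero".

    Inside the cavity: positive below the magic angle, negative above it.
    Outside: both reversed. Angles within ``tolerance_deg`` of 54.7 deg
    return "near-zero".
    """
    if tolerance_deg < 0:
        raise InvalidInputError("tolerance must be non-negative")
    theta = geometry.angle_to_axis_deg
    if abs(theta - MAGIC_ANGLE_DEG) <= tolerance_deg:
        return "near-zero"
    sign = "positive" if theta < MAGIC_ANGLE_DEG else "negative"
    if geometry.location == "outside":
        sign = "negative" if sign == "positive" else "positive"
    return sign
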