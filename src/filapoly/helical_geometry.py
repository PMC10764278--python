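"""Twist / rise / crossover conversions for helical amyloid filaments.

A cross-β filament is a helical stack of β-rungs spaced ~4.7 Å along the
axis.  Successive rungs are related by a screw operation: a rotation
(*twist*, degrees; negative = left-handed) plus a translation (*rise*, Å).
The *crossover distance* is the axial length over which the filament
rotates by 180°:

    crossover = 180 · rise / |twist|

Filaments built from two alternating, nearly identical subunits per rung
pair have pseudo-2₁ symmetry: the subunit-level operator is half the rung
rise combined with the half rung twist offset by 180°, so applying it twice
reproduces the rung operator.

All angles are degrees, all lengths Å.  The default rise used in worked
examples is 4.7 Å, the β-sheet rung spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RISE_PER_RUNG_DEFAULT",
    "HelicalParams",
    "crossover_from_twist",
    "twist_from_crossover",
    "pseudo21_subunit_params",
]

RISE_PER_RUNG_DEFAULT = 4.7  # Å, cross-β rung spacing


def crossover_from_twist(twist_per_rung: float, rise_per_rung: float) -> float:
    """Crossover distance (Å) from twist (deg/rung) and rise (Å/rung).

    >>> round(crossover_from_twist(-6.3, 4.7), 1)
    134.3
    """
    if rise_per_rung <= 0:
        raise ValueError("rise must be positive")
    if twist_per_rung == 0:
        raise ValueError("untwisted filament has infinite crossover distance")
    return 180.0 * rise_per_rung / abs(twist_per_rung)


def twist_from_crossover(
    crossover: float, rise_per_rung: float, left_handed: bool = True
) -> float:
    """Twist (deg/rung) from crossover distance (Å) and rise (Å/rung).

    Exact inverse of :func:`crossover_from_twist`; the handedness flag sets
    the sign (left-handed = negative).
    """
    if crossover <= 0 or rise_per_rung <= 0:
        raise ValueError("crossover and rise must be positive")
    mag = 180.0 * rise_per_rung / crossover
    return -mag if left_handed else mag


def _wrap_angle(deg: float) -> float:
    """Map an angle into (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def pseudo21_subunit_params(
    twist_per_rung: float, rise_per_rung: float
) -> tuple[float, float]:
    """Subunit-level screw parameters of a pseudo-2₁ filament.

    Two alternating subunits per rung pair: the subunit operator applied
    twice must reproduce the rung operator, so the subunit twist is
    ``twist/2 + 180`` (wrapped into (-180, 180]) and the subunit rise is
    half the rung rise.

    >>> pseudo21_subunit_params(-6.3, 4.7)
    (176.85, 2.35)
    """
    if rise_per_rung <= 0:
        raise ValueError("rise must be positive")
    return _wrap_angle(twist_per_rung / 2.0 + 180.0), rise_per_rung / 2.0


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry of a filament, per β-rung.

    twist_per_rung  degrees; negative = left-handed
    rise_per_rung   Å; must be positive
    pseudo_21       whether the filament has pseudo-2₁ symmetry
    """

    twist_per_rung: float
    rise_per_rung: float = RISE_PER_RUNG_DEFAULT
    pseudo_21: bool = False

    def __post_init__(self) -> None:
        if self.rise_per_rung <= 0:
            raise ValueError("rise must be positive")
        if self.twist_per_rung == 0:
            raise ValueError("twist must be nonzero for a finite crossover")

    @property
    def left_handed(self) -> bool:
        return self.twist_per_rung < 0

    @property
    def crossover(self) -> float:
        """Crossover distance in Å."""
        return crossover_from_twist(self.twist_per_rung, self.rise_per_rung)

    @property
    def crossover_nm(self) -> float:
        return self.crossover / 10.0

    def subunit_params(self) -> tuple[float, float]:
        """(twist, rise) per subunit; requires pseudo-2₁ symmetry."""
        if not self.pseudo_21:
            raise ValueError("subunit parameters require pseudo-2_1 symmetry")
        return pseudo21_subunit_params(self.twist_per_rung, self.rise_per_rung)
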