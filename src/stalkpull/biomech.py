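"""Static force and moment balance of a maize plant.

A standing plant is modelled as a rigid lever hinged at the stem base
``O``.  Two load cases matter for lodging:

* a horizontal wind force ``P·S`` (pressure times windward area) acting
  at arm ``L1``, together with the stalk weight ``m1·g`` at arm ``L2``
  and the ear weight ``m2·g`` at arm ``L3``;
* the pull of an in-situ tester, a force ``F_theta`` applied at clamp
  height ``L`` with the instrument shaft inclined ``theta`` degrees from
  vertical, so the horizontal component is ``F_theta·cos(theta)``.

Both cases resolve to the root reactions ``(Fox, Foy)`` and the
resistance moment ``Mo`` at the base.  Equating the pull moment
``F_theta·L`` with the wind moment ``P·S·L1`` converts a measured pull
force into the equivalent steady wind pressure the plant can resist.

Moment arms are supplied as data; no geometric plant model is implied.
Angles are degrees at the interface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PlantBody",
    "WindLoad",
    "PullState",
    "ForceBalance",
    "wind_equilibrium",
    "pull_equilibrium",
    "equivalent_wind_pressure",
]

G_DEFAULT = 9.81  # m/s^2


def _require_nonnegative(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class PlantBody:
    """Mass distribution of a plant split into stalk and ear sections.

    Parameters
    ----------
    m1, m2:
        Stalk and ear-section masses (kg).
    L2, L3:
        Moment arms of the stalk and ear weights about the stem base (m).
    g:
        Gravitational acceleration (m/s^2).
    """

    m1: float
    m2: float
    L2: float
    L3: float
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        _require_nonnegative(m1=self.m1, m2=self.m2, L2=self.L2, L3=self.L3)
        if not (math.isfinite(self.g) and self.g > 0):
            raise ValueError(f"g must be > 0, got {self.g!r}")

    @property
    def weight_moment(self) -> float:
        """Gravity moment m1*g*L2 + m2*g*L3 about the stem base (N m)."""
        return self.m1 * self.g * self.L2 + self.m2 * self.g * self.L3


@dataclass(frozen=True)
class WindLoad:
    """Horizontal wind load: pressure ``P`` (Pa) over area ``S`` (m^2) at arm ``L1`` (m)."""

    P: float
    S: float
    L1: float

    def __post_init__(self) -> None:
        _require_nonnegative(P=self.P, S=self.S, L1=self.L1)


@dataclass(frozen=True)
class PullState:
    """Tester pull: force ``F_theta`` (N) at shaft inclination ``theta`` (deg), arm ``L`` (m)."""

    theta: float
    F_theta: float
    L: float

    def __post_init__(self) -> None:
        _require_nonnegative(F_theta=self.F_theta)
        if not (math.isfinite(self.theta) and 0.0 <= self.theta <= 90.0):
            raise ValueError(f"theta must lie in [0, 90] degrees, got {self.theta!r}")
        if not (math.isfinite(self.L) and self.L > 0):
            raise ValueError(f"L must be > 0, got {self.L!r}")


@dataclass(frozen=True)
class ForceBalance:
    """Root reactions and base resistance moment of a plant in equilibrium."""

    Fox: float  # horizontal root reaction, N
    Foy: float  # vertical root reaction, N
    Mo: float   # resistance moment at the stem base, N m


def wind_equilibrium(plant: PlantBody, wind: WindLoad) -> ForceBalance:
    """Equilibrium of a plant loaded by horizontal wind.

    Force balance gives ``Fox = P·S`` and ``Foy = (m1 + m2)·g``; the
    moment balance about the base gives
    ``Mo = P·S·L1 + m1·g·L2 + m2·g·L3``.
    """
    ps = wind.P * wind.S
    return ForceBalance(
        Fox=ps,
        Foy=(plant.m1 + plant.m2) * plant.g,
        Mo=ps * wind.L1 + plant.weight_moment,
    )


def pull_equilibrium(plant: PlantBody, pull: PullState) -> ForceBalance:
    """Equilibrium of a plant pulled by the tester at inclination ``theta``.

    The horizontal component of the pull is ``F_theta·cos(theta)`` and its
    vertical component loads the root, so
    ``Fox = F_theta·cos(theta)``,
    ``Foy = F_theta·sin(theta) + (m1 + m2)·g`` and
    ``Mo = F_theta·L + m1·g·L2 + m2·g·L3``.
    """
    rad = math.radians(pull.theta)
    return ForceBalance(
        Fox=pull.F_theta * math.cos(rad),
        Foy=pull.F_theta * math.sin(rad) + (plant.m1 + plant.m2) * plant.g,
        Mo=pull.F_theta * pull.L + plant.weight_moment,
    )


def equivalent_wind_pressure(pull: PullState, wind_area: float, L1: float) -> float:
    """Wind pressure whose overturning moment equals the pull moment.

    Setting ``P·S·L1 = F_theta·L`` gives ``P = F_theta·L / (S·L1)`` — the
    steady wind pressure the measured pull force is equivalent to.
    """
    if not (math.isfinite(wind_area) and wind_area > 0):
        raise ValueError(f"wind_area must be > 0, got {wind_area!r}")
    if not (math.isfinite(L1) and L1 > 0):
        raise ValueError(f"L1 must be > 0, got {L1!r}")
    return pull.F_theta * pull.L / (wind_area * L1)
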