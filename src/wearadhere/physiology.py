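"""Closed-form exercise-prescription physiology.

Three quantities anchor the intervention design for older adults:

* age-predicted maximal heart rate for sedentary people (Tanaka:
  ``HRmax = 211 - 0.8 * age``),
* a target heart-rate zone from the heart-rate-reserve (Karvonen) method,
  ``HR = HRrest + frac * (HRmax - HRrest)``, by default the 50-80% HRR band
  used for moderate exercise prescription, and
* cardiorespiratory fitness (estimated VO2max) from the six-minute walk
  test via the Kervio regression equation.

All formulas are linear and applied unguarded; physiologically implausible
outputs are flagged, never clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "CardioParams",
    "HrZone",
    "SixMwtInputs",
    "CrfEstimate",
    "InvalidPhysiologyError",
    "tanaka_hrmax",
    "hrr_zone",
    "kervio_crf",
]

#: study-population age band; ages outside it trigger a warning, not an error
_STUDY_AGE_BAND = (60.0, 90.0)
_COMPUTABLE_AGE_BAND = (18.0, 110.0)


class InvalidPhysiologyError(ValueError):
    """Raised when inputs violate basic physiological ordering constraints."""


def _require_finite_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")
    return value


def tanaka_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate for sedentary adults (beats/min).

    Uses the sedentary-population regression ``211 - 0.8 * age``; strictly
    decreasing in age at 0.8 beats/min per year.

    Parameters
    ----------
    age : float
        Age in years, strictly positive.
    """
    age = _require_finite_positive("age", age)
    lo, hi = _STUDY_AGE_BAND
    if not (_COMPUTABLE_AGE_BAND[0] <= age <= _COMPUTABLE_AGE_BAND[1]):
        raise ValueError(
            f"age {age} outside computable band {_COMPUTABLE_AGE_BAND}"
        )
    if not (lo <= age <= hi):
        warnings.warn(
            f"age {age} outside the {lo:.0f}-{hi:.0f} yr band the defaults target",
            stacklevel=2,
        )
    return 211.0 - 0.8 * age


@dataclass(frozen=True)
class CardioParams:
    """Resting and maximal heart rate for one participant.

    ``hr_max`` defaults to the Tanaka estimate from ``age`` when omitted.
    """

    age: float
    hr_rest: float
    hr_max: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _require_finite_positive("hr_rest", self.hr_rest)
        if self.hr_max is None:
            object.__setattr__(self, "hr_max", tanaka_hrmax(self.age))
        else:
            _require_finite_positive("age", self.age)
        if self.hr_max <= self.hr_rest:
            raise InvalidPhysiologyError(
                f"hr_max ({self.hr_max}) must exceed hr_rest ({self.hr_rest})"
            )

    @property
    def hr_reserve(self) -> float:
        """Heart-rate reserve HRmax - HRrest (beats/min)."""
        return self.hr_max - self.hr_rest


@dataclass(frozen=True)
class HrZone:
    """A target heart-rate band expressed in beats/min plus the HRR fractions used."""

    lower: float
    upper: float
    lower_frac: float
    upper_frac: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise InvalidPhysiologyError(
                f"zone lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    def contains(self, hr: float) -> bool:
        """Closed-interval membership test for a minute-mean heart rate."""
        return self.lower <= hr <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hrr_zone(
    hr_rest: float,
    hr_max: float,
    lower_frac: float = 0.50,
    upper_frac: float = 0.80,
) -> HrZone:
    """Karvonen target zone: ``bound = HRrest + frac * (HRmax - HRrest)``.

    The defaults reproduce the moderate-intensity 50-80% HRR prescription
    band. Fractions must satisfy ``0 <= lower_frac < upper_frac <= 1``;
    ``(0, 1)`` returns the full reserve ``(HRrest, HRmax)``.

    Raises
    ------
    InvalidPhysiologyError
        If ``hr_max <= hr_rest``.
    """
    hr_rest = _require_finite_positive("hr_rest", hr_rest)
    hr_max = _require_finite_positive("hr_max", hr_max)
    if hr_max <= hr_rest:
        raise InvalidPhysiologyError(
            f"hr_max ({hr_max}) must exceed hr_rest ({hr_rest})"
        )
    if not (0.0 <= lower_frac < upper_frac <= 1.0):
        raise ValueError(
            f"need 0 <= lower_frac < upper_frac <= 1, got ({lower_frac}, {upper_frac})"
        )
    reserve = hr_max - hr_rest
    return HrZone(
        lower=hr_rest + lower_frac * reserve,
        upper=hr_rest + upper_frac * reserve,
        lower_frac=lower_frac,
        upper_frac=upper_frac,
    )


# Kervio six-minute-walk-test regression coefficients (absolute VO2max, mL/min)
_KERVIO_INTERCEPT = 2830.6
_KERVIO_AGE = -45.2      # per year
_KERVIO_MASS = 4.70      # per kg
_KERVIO_HEIGHT = 12.3    # per cm
_KERVIO_DISTANCE = 1.75  # per m walked in 6 min
_KERVIO_VO2 = 0.309      # per mL/min seated-rest oxygen uptake
_KERVIO_HR = -12.4       # per beat/min


@dataclass(frozen=True)
class SixMwtInputs:
    """Inputs to the six-minute-walk-test fitness regression.

    ``vo2_rest`` and ``hr_test`` are interpreted as the seated-rest
    measurements taken alongside the walk test (the protocol's 5-min quiet
    sitting); pass the end-of-walk heart rate instead if that is the
    convention in use — the equation is applied as given either way.
    """

    age: float
    body_mass: float          # kg
    height: float             # cm
    distance: float           # m covered in six minutes
    vo2_rest: float           # mL/min, seated rest
    hr_test: float            # beats/min

    def __post_init__(self) -> None:
        for name in ("age", "body_mass", "height", "distance", "vo2_rest", "hr_test"):
            _require_finite_positive(name, getattr(self, name))
        if self.distance > 1000:
            raise ValueError(
                f"distance {self.distance} m is not plausible for a six-minute walk"
            )


@dataclass(frozen=True)
class CrfEstimate:
    """Estimated cardiorespiratory fitness from the 6-MWT regression."""

    vo2max_abs: float         # mL/min
    vo2max_rel: float         # mL/kg/min, absolute value divided by body mass
    implausible: bool = field(default=False)

    def __float__(self) -> float:
        return self.vo2max_abs


def kervio_crf(inputs: SixMwtInputs) -> CrfEstimate:
    """Estimate VO2max (mL/min) from six-minute-walk-test data.

    Linear regression: ``2830.6 - 45.2*age + 4.70*BW + 12.3*height
    + 1.75*distance + 0.309*VO2rest - 12.4*HR``. The relative value is the
    absolute estimate divided by current body mass. A non-positive estimate
    sets the ``implausible`` flag; the value itself is never altered.
    """
    absolute = (
        _KERVIO_INTERCEPT
        + _KERVIO_AGE * inputs.age
        + _KERVIO_MASS * inputs.body_mass
        + _KERVIO_HEIGHT * inputs.height
        + _KERVIO_DISTANCE * inputs.distance
        + _KERVIO_VO2 * inputs.vo2_rest
        + _KERVIO_HR * inputs.hr_test
    )
    return CrfEstimate(
        vo2max_abs=absolute,
        vo2max_rel=absolute / inputs.body_mass,
        implausible=absolute <= 0,
    )
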