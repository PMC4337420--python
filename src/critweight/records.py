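"""Typed per-observation records for every pipeline input.

All times are hours after ecdysis to the third larval instar (hr AL3E),
masses are mg, hormone titres pg/mg.  Units are fixed; converting other
units is the caller's job.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import InvariantError

__all__ = [
    "StarvationRecord",
    "GrowthRecord",
    "CtRecord",
    "TimecourseSample",
]


def _finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvariantError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True, eq=False)
class StarvationRecord:
    """One larva's starvation response: the unit of resampling.

    ``age_at_starvation`` is the age (hr AL3E) at which the larva was moved
    to non-nutritive agar; ``time_to_pupariation`` is measured from the
    onset of starvation.  Larvae that died before pupariating carry
    ``pupariated=False`` and an undefined (NaN) time; they are retained by
    the readers but excluded from all fits.
    """

    larva_id: str
    group: str
    age_at_starvation: float
    time_to_pupariation: float
    pupariated: bool = True

    def __post_init__(self):
        age = _finite("age_at_starvation", self.age_at_starvation)
        if age < 0:
            raise InvariantError(f"age_at_starvation must be >= 0, got {age}")
        object.__setattr__(self, "age_at_starvation", age)
        if self.pupariated:
            ttp = _finite("time_to_pupariation", self.time_to_pupariation)
            if ttp <= 0:
                raise InvariantError(
                    f"time_to_pupariation must be > 0 when pupariated, got {ttp}"
                )
            object.__setattr__(self, "time_to_pupariation", ttp)
        else:
            object.__setattr__(self, "time_to_pupariation", float("nan"))

    def _key(self):
        ttp = self.time_to_pupariation if self.pupariated else None
        return (self.larva_id, self.group, self.age_at_starvation, ttp,
                self.pupariated)

    def __eq__(self, other):
        if not isinstance(other, StarvationRecord):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self):
        return hash(self._key())


@dataclass(frozen=True)
class GrowthRecord:
    """One larva's wet mass (mg) at a known age (hr AL3E) during feeding."""

    larva_id: str
    group: str
    age: float
    mass: float

    def __post_init__(self):
        age = _finite("age", self.age)
        mass = _finite("mass", self.mass)
        if age < 0:
            raise InvariantError(f"age must be >= 0, got {age}")
        if mass <= 0:
            raise InvariantError(f"mass must be > 0, got {mass}")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "mass", mass)


@dataclass(frozen=True)
class CtRecord:
    """A qPCR threshold-cycle pair: target gene and internal control.

    The internal control is the reference gene run on the same sample
    (RpL3 in the original design).  Ct values outside the 5-40 cycle range
    are flagged with a warning, not rejected.
    """

    gene: str
    group: str
    time: float
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        ct_t = _finite("ct_target", self.ct_target)
        ct_r = _finite("ct_reference", self.ct_reference)
        for name, ct in (("ct_target", ct_t), ("ct_reference", ct_r)):
            if not (5.0 <= ct <= 40.0):
                warnings.warn(
                    f"{name}={ct} outside the typical 5-40 cycle range "
                    f"(gene={self.gene}, time={self.time}, rep={self.replicate})",
                    UserWarning,
                    stacklevel=3,
                )
        object.__setattr__(self, "ct_target", ct_t)
        object.__setattr__(self, "ct_reference", ct_r)
        object.__setattr__(self, "time", _finite("time", self.time))
        object.__setattr__(self, "replicate", int(self.replicate))


@dataclass(frozen=True)
class TimecourseSample:
    """One replicate measurement in a time course.

    ``value`` is a non-negative quantity: a 20E titre in pg/mg or a relative
    expression fold change.
    """

    group: str
    time: float
    replicate: int
    value: float

    def __post_init__(self):
        value = _finite("value", self.value)
        if value < 0:
            raise InvariantError(f"value must be >= 0, got {value}")
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "time", _finite("time", self.time))
        object.__setattr__(self, "replicate", int(self.replicate))
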