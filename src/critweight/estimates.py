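"""Result containers for critical-weight inference."""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

from .exceptions import InvariantError, EstimateWarning

__all__ = ["CriticalWeightEstimate", "PermutationResult"]


@dataclass(frozen=True)
class CriticalWeightEstimate:
    """Point estimate and percentile bootstrap CI for age and mass at critical weight.

    Ages are hr AL3E, masses mg.  ``n_boot`` counts the bootstrap replicates
    requested, ``n_failed_boot`` the ones whose refit failed and were
    excluded from the percentile computation.
    """

    group: str
    age: float
    age_ci_low: float
    age_ci_high: float
    mass: float
    mass_ci_low: float
    mass_ci_high: float
    n_boot: int
    n_failed_boot: int
    seed: int
    level: float = 0.95

    def __post_init__(self):
        for lo, hi, what in (
            (self.age_ci_low, self.age_ci_high, "age"),
            (self.mass_ci_low, self.mass_ci_high, "mass"),
        ):
            if lo > hi:
                raise InvariantError(
                    f"reversed {what} CI: low={lo} > high={hi}"
                )
        if self.n_failed_boot > self.n_boot:
            raise InvariantError("n_failed_boot exceeds n_boot")
        # Percentile intervals are not guaranteed to bracket the plug-in
        # estimate; surface it but do not abort a long simulation run.
        if not (self.age_ci_low <= self.age <= self.age_ci_high):
            warnings.warn(
                f"age point estimate {self.age} outside its CI "
                f"[{self.age_ci_low}, {self.age_ci_high}]",
                EstimateWarning,
                stacklevel=3,
            )

    def is_finite(self) -> bool:
        return all(
            math.isfinite(v)
            for v in (
                self.age,
                self.age_ci_low,
                self.age_ci_high,
                self.mass,
                self.mass_ci_low,
                self.mass_ci_high,
            )
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PermutationResult:
    """Two-sided permutation test on a derived statistic (age or mass difference).

    ``p_value`` always follows the add-one rule
    ``(n_as_extreme + 1) / (n_perm + 1)`` and is therefore never zero.
    """

    observed_diff: float
    n_perm: int
    n_as_extreme: int
    p_value: float
    seed: int
    statistic: str = "age"
    n_failed_perm: int = 0
    group_a: str = ""
    group_b: str = ""

    def __post_init__(self):
        expected = (self.n_as_extreme + 1) / (self.n_perm + 1)
        if not math.isclose(self.p_value, expected, rel_tol=0, abs_tol=1e-12):
            raise InvariantError(
                f"p_value {self.p_value} violates the add-one rule "
                f"({self.n_as_extreme}+1)/({self.n_perm}+1)={expected}"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise InvariantError(f"p_value out of (0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return asdict(self)
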