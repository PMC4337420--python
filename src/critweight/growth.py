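"""Linear larval growth curve: mass (mg) as a function of age (hr AL3E).

During the feeding period of the final instar, larval wet mass grows
approximately linearly with age, so an ordinary least-squares line converts
an estimated age at critical weight into a mass at critical weight.  Each
genotype/treatment has its own growth curve; conversion across groups is
refused unless explicitly overridden.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import DegenerateDesignError, ExtrapolationWarning, InvariantError
from .records import GrowthRecord

__all__ = ["GrowthFit", "fit_growth_curve", "age_to_mass"]


@dataclass(frozen=True)
class GrowthFit:
    """An OLS line mass = intercept + slope * age, with residual scatter.

    ``residual_sd`` is the root mean squared residual with n-2 degrees of
    freedom; ``slope_se`` the standard error of the slope.
    """

    group: str
    intercept: float
    slope: float
    residual_sd: float
    slope_se: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise InvariantError(f"growth fit needs n >= 3, got {self.n}")
        if self.residual_sd < 0:
            raise InvariantError("residual_sd must be >= 0")

    def predict(self, age):
        """Vectorized alias of :func:`age_to_mass` without the group check."""
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def fit_growth_curve(records: Iterable[GrowthRecord]) -> GrowthFit:
    """OLS fit of mass on age over one group's growth measurements.

    Requires at least three larvae spanning at least two distinct ages.
    Raises :class:`DegenerateDesignError` when all ages coincide.
    """
    records = list(records)
    if len(records) < 3:
        raise InvariantError(f"need >= 3 growth records, got {len(records)}")
    groups = {r.group for r in records}
    if len(groups) > 1:
        raise InvariantError(f"growth records mix groups: {sorted(groups)}")
    age = np.array([r.age for r in records], dtype=float)
    mass = np.array([r.mass for r in records], dtype=float)
    if np.unique(age).size < 2:
        raise DegenerateDesignError("all growth ages identical; slope not estimable")
    res = sm.OLS(mass, sm.add_constant(age)).fit()
    return GrowthFit(
        group=groups.pop(),
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.sqrt(res.mse_resid)),
        slope_se=float(res.bse[1]),
        n=len(records),
    )


def age_to_mass(
    fit: GrowthFit,
    age: float | Sequence[float],
    *,
    group: str | None = None,
    allow_cross_group: bool = False,
):
    """Convert age(s) at critical weight to mass(es) through the growth line.

    ``group``, when given, must match the fit's group unless
    ``allow_cross_group`` is set — each genotype is converted through its
    own growth curve.  A negative predicted mass signals extrapolation
    outside the feeding period and is returned with a warning.
    """
    if group is not None and group != fit.group and not allow_cross_group:
        raise InvariantError(
            f"growth fit is for group {fit.group!r}, not {group!r}; "
            "pass allow_cross_group=True to override"
        )
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0):
        raise InvariantError("age must be >= 0")
    mass = fit.intercept + fit.slope * arr
    if np.any(mass < 0):
        warnings.warn(
            "negative predicted mass: age outside the feeding period",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(mass) if np.isscalar(age) else mass
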