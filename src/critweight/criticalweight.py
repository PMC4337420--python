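"""End-to-end critical-weight estimation: hinge fit + growth conversion + bootstrap.

`CriticalWeightModel` bundles one cohort's starvation-response records with
its growth measurements; `fit()` estimates the age at critical weight (the
hinge breakpoint), converts it to a mass through the cohort's growth line,
and attaches percentile bootstrap confidence intervals to both.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .bisegmental import (
    DEFAULT_GRID_STEP,
    DEFAULT_REFINE_TOL,
    BisegmentalResults,
)
from .estimates import CriticalWeightEstimate
from .exceptions import InvariantError
from .growth import GrowthFit, fit_growth_curve
from .records import GrowthRecord, StarvationRecord
from .resampling import bootstrap_critical_weight, percentile_interval

__all__ = ["CriticalWeightModel", "CriticalWeightResults"]


class CriticalWeightModel:
    """One cohort's critical-weight analysis.

    Parameters
    ----------
    starvation_records
        Per-larva (age at starvation, time to pupariation) observations.
        Non-pupariating larvae are excluded from fits and counted.
    growth_records, growth_fit
        Either raw growth measurements (the line is fitted here) or an
        already-fitted :class:`GrowthFit` for the same group.
    group
        Cohort label; when given, records of other groups are filtered out.

    Examples
    --------
    >>> model = CriticalWeightModel(starv, growth_records=growth, group="w1118")
    >>> res = model.fit(n_boot=1000, seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        starvation_records: Iterable[StarvationRecord],
        growth_records: Iterable[GrowthRecord] | None = None,
        growth_fit: GrowthFit | None = None,
        group: str | None = None,
    ):
        records = list(starvation_records)
        if group is not None:
            records = [r for r in records if r.group == group]
        if not records:
            raise InvariantError(f"no starvation records for group {group!r}")
        self.starvation_records = records
        self.group = group if group is not None else records[0].group
        if (growth_records is None) == (growth_fit is None):
            raise InvariantError(
                "pass exactly one of growth_records or growth_fit"
            )
        if growth_records is not None:
            growth_records = [
                g for g in growth_records if group is None or g.group == group
            ]
            growth_fit = fit_growth_curve(growth_records)
        if growth_fit.group != self.group:
            raise InvariantError(
                f"growth fit is for {growth_fit.group!r}, cohort is {self.group!r}"
            )
        self.growth_records = growth_records
        self.growth_fit = growth_fit

    @classmethod
    def from_dataframes(cls, starvation_df, growth_df, group: str, **kwargs):
        from .records import GrowthRecord, StarvationRecord

        starv = [
            StarvationRecord(str(i), row["group"], row["age_at_starvation"],
                             row["time_to_pupariation"])
            for i, row in starvation_df.iterrows()
        ]
        growth = [
            GrowthRecord(str(i), row["group"], row["age"], row["mass"])
            for i, row in growth_df.iterrows()
        ]
        return cls(starv, growth_records=growth, group=group, **kwargs)

    def fit(
        self,
        n_boot: int = 1000,
        level: float = 0.95,
        seed: int = 0,
        *,
        grid_step: float = DEFAULT_GRID_STEP,
        refine_tol: float = DEFAULT_REFINE_TOL,
        stratified: bool = True,
        resample_growth: bool = False,
    ) -> "CriticalWeightResults":
        estimate, diag = bootstrap_critical_weight(
            self.starvation_records,
            self.growth_fit,
            n_boot=n_boot,
            level=level,
            seed=seed,
            stratified=stratified,
            grid_step=grid_step,
            refine_tol=refine_tol,
            growth_records=self.growth_records,
            resample_growth=resample_growth,
            group=self.group,
            full_output=True,
        )
        return CriticalWeightResults(
            model=self,
            breakpoint=diag["point_fit"],
            growth=self.growth_fit,
            estimate=estimate,
            boot_ages=diag["boot_ages"],
            boot_masses=diag["boot_masses"],
        )


@dataclass(frozen=True)
class CriticalWeightResults:
    """Estimates, bootstrap draws and diagnostics for one cohort."""

    model: CriticalWeightModel = field(repr=False)
    breakpoint: BisegmentalResults
    growth: GrowthFit
    estimate: CriticalWeightEstimate
    boot_ages: np.ndarray = field(repr=False)
    boot_masses: np.ndarray = field(repr=False)

    def conf_int(self, level: float | None = None, which: str = "age"):
        """Percentile interval at any level from the stored bootstrap draws."""
        level = self.estimate.level if level is None else level
        draws = self.boot_ages if which == "age" else self.boot_masses
        return percentile_interval(draws, level)

    def summary(self) -> str:
        e = self.estimate
        pct = 100 * e.level
        lines = [
            "Critical weight estimate",
            "========================",
            f"group                    {e.group}",
            f"n larvae (fit)           {self.breakpoint.n}"
            f"  (excluded: {self.breakpoint.n_excluded})",
            f"age at critical weight   {e.age:8.2f} hr AL3E"
            f"   {pct:.0f}% CI [{e.age_ci_low:.2f}, {e.age_ci_high:.2f}]",
            f"mass at critical weight  {e.mass:8.3f} mg"
            f"      {pct:.0f}% CI [{e.mass_ci_low:.3f}, {e.mass_ci_high:.3f}]",
            f"pre-break slope          {self.breakpoint.beta1:8.2f} hr/hr",
            f"post-break slope         {self.breakpoint.post_slope:8.2f} hr/hr",
            f"growth line              mass = {self.growth.intercept:.3f}"
            f" + {self.growth.slope:.4f} * age  (sd {self.growth.residual_sd:.3f} mg)",
            f"bootstrap                {e.n_boot} replicates, {e.n_failed_boot}"
            f" failed, seed {e.seed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Starvation response with the fitted hinge and the CI band on tau."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.breakpoint.plot(self.model.starvation_records, ax=ax)
        ax.axvspan(self.estimate.age_ci_low, self.estimate.age_ci_high,
                   alpha=0.15, color="grey")
        return ax
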