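"""Case-bootstrap confidence intervals and permutation tests for critical weight.

Ages at starvation are fixed by the experimental design (larvae are pulled
to non-nutritive agar on a 2-hr schedule), so the default resampling unit
is the larva *within its age class*: bootstrap replicates redraw larvae
with replacement inside each class, and the permutation null re-assigns
group labels among the larvae of matched age classes.  Both schemes keep
every replicate dataset on the original age design, which makes the hinge
refit cheap (the candidate-grid normal matrices depend only on the ages
and are computed once) and keeps the breakpoint identifiable in every
replicate.  Unstratified variants are available behind flags.

Confidence intervals are percentile intervals on the bootstrap
distribution of the breakpoint age; the mass interval maps every bootstrap
age through the (fixed, by default) growth line.  P-values use the add-one
rule (n_as_extreme + 1) / (n_perm + 1) and are therefore never zero.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .bisegmental import (
    DEFAULT_GRID_STEP,
    DEFAULT_REFINE_TOL,
    BisegmentalRegression,
    _HingeFitter,
    fit_bisegmental,
)
from .estimates import CriticalWeightEstimate, PermutationResult
from .exceptions import (
    CritweightError,
    InvariantError,
    UnstableEstimateError,
)
from .growth import GrowthFit, age_to_mass, fit_growth_curve
from .records import GrowthRecord, StarvationRecord

__all__ = [
    "bootstrap_critical_weight",
    "permute_critical_weight",
    "percentile_interval",
]

_MAX_FAIL_FRACTION = 0.2


def percentile_interval(values: Sequence[float], level: float) -> tuple[float, float]:
    """Equal-tailed percentile interval at the given coverage level."""
    if not 0 < level < 1:
        raise InvariantError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(values, dtype=float), [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _arrays(records: Iterable[StarvationRecord], group: str | None):
    model = BisegmentalRegression.from_records(records, group=group)
    return model.age, model.time, model.group


def _class_slices(x: np.ndarray):
    """Positions of each age class in the (fixed-order) age vector."""
    return [np.flatnonzero(x == a) for a in np.unique(x)]


def bootstrap_critical_weight(
    records: Iterable[StarvationRecord],
    growth_fit: GrowthFit,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    *,
    stratified: bool = True,
    grid_step: float = DEFAULT_GRID_STEP,
    refine_tol: float = DEFAULT_REFINE_TOL,
    growth_records: Iterable[GrowthRecord] | None = None,
    resample_growth: bool = False,
    allow_cross_group: bool = False,
    group: str | None = None,
    full_output: bool = False,
):
    """Case-bootstrap estimate of age and mass at critical weight.

    The point fit must succeed (its error propagates).  Each of ``n_boot``
    replicates resamples larvae with replacement — within age classes by
    default — and refits the hinge; replicates whose refit fails are
    counted in ``n_failed_boot`` and excluded.  More than 20 % failures
    raises :class:`UnstableEstimateError`.  ``resample_growth=True``
    additionally case-resamples the growth table and refits the growth
    line per replicate (requires ``growth_records``); by default the
    growth line is held fixed and only breakpoint ages vary.

    With ``full_output=True`` returns ``(estimate, diagnostics)`` where
    diagnostics carries the bootstrap age and mass draws.
    """
    records = list(records)
    point = fit_bisegmental(records, grid_step=grid_step, refine_tol=refine_tol,
                            group=group)
    x, y, label = _arrays(records, group)
    mass_point = age_to_mass(growth_fit, point.tau, group=label or None,
                             allow_cross_group=allow_cross_group)

    if resample_growth:
        if growth_records is None:
            raise InvariantError("resample_growth=True requires growth_records")
        growth_records = list(growth_records)

    rng = np.random.default_rng(seed)
    boot_ages = np.empty(n_boot)
    boot_masses = np.empty(n_boot)
    n_failed = 0
    kept = 0

    if stratified:
        fitter = _HingeFitter(x, grid_step=grid_step, refine_tol=refine_tol)
        slices = _class_slices(x)
        y_star = np.empty_like(y)
        for _ in range(n_boot):
            for idx in slices:
                y_star[idx] = y[idx][rng.integers(0, idx.size, idx.size)]
            try:
                _, tau_b, _, _ = fitter.fit(y_star)
            except CritweightError:
                n_failed += 1
                continue
            boot_ages[kept] = tau_b
            boot_masses[kept] = _boot_mass(tau_b, growth_fit, growth_records,
                                           resample_growth, rng)
            kept += 1
    else:
        n = x.size
        for _ in range(n_boot):
            take = rng.integers(0, n, n)
            try:
                res = BisegmentalRegression(x[take], y[take], group=label).fit(
                    grid_step=grid_step, refine_tol=refine_tol
                )
            except CritweightError:
                n_failed += 1
                continue
            boot_ages[kept] = res.tau
            boot_masses[kept] = _boot_mass(res.tau, growth_fit, growth_records,
                                           resample_growth, rng)
            kept += 1

    if n_failed > _MAX_FAIL_FRACTION * n_boot:
        raise UnstableEstimateError(
            f"{n_failed}/{n_boot} bootstrap refits failed (> 20 %)"
        )
    boot_ages, boot_masses = boot_ages[:kept], boot_masses[:kept]
    age_lo, age_hi = percentile_interval(boot_ages, level)
    mass_lo, mass_hi = percentile_interval(boot_masses, level)
    estimate = CriticalWeightEstimate(
        group=label, age=point.tau, age_ci_low=age_lo, age_ci_high=age_hi,
        mass=mass_point, mass_ci_low=mass_lo, mass_ci_high=mass_hi,
        n_boot=n_boot, n_failed_boot=n_failed, seed=int(seed), level=level,
    )
    if full_output:
        return estimate, {"boot_ages": boot_ages, "boot_masses": boot_masses,
                          "point_fit": point}
    return estimate


def _boot_mass(tau_b, growth_fit, growth_records, resample_growth, rng):
    if not resample_growth:
        return growth_fit.predict(tau_b)
    take = rng.integers(0, len(growth_records), len(growth_records))
    gfit = fit_growth_curve([growth_records[i] for i in take])
    return gfit.predict(tau_b)


def permute_critical_weight(
    records_a: Iterable[StarvationRecord],
    records_b: Iterable[StarvationRecord],
    statistic: str = "age",
    n_perm: int = 1000,
    seed: int = 0,
    growth_fits: Mapping[str, GrowthFit] | None = None,
    *,
    stratified: bool = True,
    grid_step: float = DEFAULT_GRID_STEP,
    refine_tol: float = DEFAULT_REFINE_TOL,
) -> PermutationResult:
    """Two-sided permutation test for a group difference in critical weight.

    The observed statistic is ``statistic(a) - statistic(b)`` where the
    statistic is the breakpoint age (``"age"``) or the mass it maps to
    through each group's own growth line (``"mass"``, requires
    ``growth_fits`` keyed by group label; the growth lines stay fixed
    under permutation).  The null pools the larvae of both groups and
    re-assigns group labels — within matched age classes by default —
    preserving each group's per-class sample sizes, then refits both
    hinges.  Permutations whose refit fails are discarded and counted;
    more than 20 % discards raises :class:`UnstableEstimateError`.
    """
    if statistic not in ("age", "mass"):
        raise InvariantError(f"statistic must be 'age' or 'mass', got {statistic!r}")
    xa, ya, label_a = _arrays(records_a, None)
    xb, yb, label_b = _arrays(records_b, None)

    def stat_from_tau(tau: float, label: str) -> float:
        if statistic == "age":
            return tau
        if growth_fits is None or label not in growth_fits:
            raise InvariantError(f"statistic='mass' needs a growth fit for {label!r}")
        return age_to_mass(growth_fits[label], tau, group=label)

    fit_a = BisegmentalRegression(xa, ya, group=label_a).fit(
        grid_step=grid_step, refine_tol=refine_tol)
    fit_b = BisegmentalRegression(xb, yb, group=label_b).fit(
        grid_step=grid_step, refine_tol=refine_tol)
    observed = stat_from_tau(fit_a.tau, label_a) - stat_from_tau(fit_b.tau, label_b)

    rng = np.random.default_rng(seed)
    n_extreme = 0
    n_failed = 0

    if stratified:
        fitter_a = _HingeFitter(xa, grid_step=grid_step, refine_tol=refine_tol)
        fitter_b = _HingeFitter(xb, grid_step=grid_step, refine_tol=refine_tol)
        slices_a = _class_slices(xa)
        slices_b = _class_slices(xb)
        ages_a, ages_b = np.unique(xa), np.unique(xb)
        # pooled responses per age class; classes present in one group only
        # cannot exchange members and stay put
        pools, assign_a, assign_b = [], [], []
        for age in np.unique(np.concatenate([ages_a, ages_b])):
            ia = slices_a[np.searchsorted(ages_a, age)] if age in ages_a else np.empty(0, int)
            ib = slices_b[np.searchsorted(ages_b, age)] if age in ages_b else np.empty(0, int)
            pools.append(np.concatenate([ya[ia], yb[ib]]))
            assign_a.append(ia)
            assign_b.append(ib)
        ya_star, yb_star = np.empty_like(ya), np.empty_like(yb)
        for _ in range(n_perm):
            for pool, ia, ib in zip(pools, assign_a, assign_b):
                perm = rng.permutation(pool.size)
                ya_star[ia] = pool[perm[: ia.size]]
                yb_star[ib] = pool[perm[ia.size:]]
            try:
                _, tau_a, _, _ = fitter_a.fit(ya_star)
                _, tau_b, _, _ = fitter_b.fit(yb_star)
            except CritweightError:
                n_failed += 1
                continue
            diff = stat_from_tau(tau_a, label_a) - stat_from_tau(tau_b, label_b)
            if abs(diff) >= abs(observed):
                n_extreme += 1
    else:
        x_pool = np.concatenate([xa, xb])
        y_pool = np.concatenate([ya, yb])
        na = xa.size
        for _ in range(n_perm):
            perm = rng.permutation(x_pool.size)
            try:
                ra = BisegmentalRegression(x_pool[perm[:na]], y_pool[perm[:na]],
                                           group=label_a).fit(
                    grid_step=grid_step, refine_tol=refine_tol)
                rb = BisegmentalRegression(x_pool[perm[na:]], y_pool[perm[na:]],
                                           group=label_b).fit(
                    grid_step=grid_step, refine_tol=refine_tol)
            except CritweightError:
                n_failed += 1
                continue
            diff = stat_from_tau(ra.tau, label_a) - stat_from_tau(rb.tau, label_b)
            if abs(diff) >= abs(observed):
                n_extreme += 1

    n_done = n_perm - n_failed
    if n_failed > _MAX_FAIL_FRACTION * n_perm:
        raise UnstableEstimateError(
            f"{n_failed}/{n_perm} permutation refits failed (> 20 %)"
        )
    return PermutationResult(
        observed_diff=float(observed), n_perm=n_done, n_as_extreme=n_extreme,
        p_value=(n_extreme + 1) / (n_done + 1), seed=int(seed),
        statistic=statistic, n_failed_perm=n_failed,
        group_a=label_a, group_b=label_b,
    )
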