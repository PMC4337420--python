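"""Bi-segmental (breakpoint) regression of time-to-pupariation on age at starvation.

The starvation response of a final-instar larva changes qualitatively at
the critical-weight checkpoint: starving a larva *before* it delays
pupariation, and the delay shrinks the closer the larva is to the
checkpoint, whereas starving it *after* leaves the timing on a flat (or
even declining) plateau.  The model is therefore a continuous hinge

    y = beta0 + beta1 * x + beta2 * max(0, x - tau)

where ``x`` is the age at starvation (hr AL3E), ``y`` the time to
pupariation from starvation onset (hr), and the join ``tau`` — the
inflection point of the fitted relationship — estimates the age at
critical weight.  Neither slope is sign-constrained: larvae starved past
the checkpoint may pupariate *earlier*, so ``beta1 + beta2`` may be
negative.

Estimation is exact profile least squares: for each candidate ``tau`` on a
grid the remaining coefficients have a closed-form OLS solution, and the
candidate minimizing the residual sum of squares wins.  The default grid
places candidates every 0.5 hr between the second-smallest and
second-largest observed age (observations sit on a 2-hr collection grid,
so sub-grid resolution is required); the winner is then refined by a dense
0.01-hr scan over the intervals bracketing every coarse local minimum of
the RSS profile.  Equal-RSS minima are broken to the smallest ``tau``, with
a warning when the coarse profile itself is flat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    DegenerateDesignError,
    DegenerateFitWarning,
    InvariantError,
    NoBreakpointError,
)
from .records import StarvationRecord

__all__ = [
    "BisegmentalRegression",
    "BisegmentalResults",
    "fit_bisegmental",
    "profile_rss",
    "default_grid",
]

DEFAULT_GRID_STEP = 0.5
DEFAULT_REFINE_TOL = 0.01


def default_grid(ages: np.ndarray, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Candidate breakpoints every ``step`` hr between the 2nd-smallest and
    2nd-largest distinct observed ages."""
    distinct = np.unique(ages)
    if distinct.size < 4:
        raise NoBreakpointError(
            f"need >= 4 distinct ages for an interior breakpoint, got {distinct.size}"
        )
    lo, hi = distinct[1], distinct[-2]
    n_steps = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n_steps + 1)


def _valid_mask(distinct_ages: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """A candidate is interior when >= 2 distinct ages lie on each side."""
    left = np.searchsorted(distinct_ages, taus, side="right")  # ages <= tau
    right = distinct_ages.size - left                          # ages >  tau
    return (left >= 2) & (right >= 2)


class _HingeFitter:
    """Profile-least-squares engine over a fixed age vector ``x``.

    Precomputes, for every coarse candidate, the 3x3 normal-equation matrix
    of the design [1, x, (x - tau)+] and its inverse, so that refitting a
    new response vector (a bootstrap or permutation replicate over the same
    ages) costs only one matrix-vector sweep.  Candidates are guaranteed
    full rank by the interior-validity rule, ages being fixed.
    """

    def __init__(self, x: np.ndarray, taus: np.ndarray | None = None,
                 grid_step: float = DEFAULT_GRID_STEP,
                 refine_tol: float = DEFAULT_REFINE_TOL):
        self.x = np.asarray(x, dtype=float)
        if self.x.size < 6:
            raise InvariantError(f"need >= 6 records, got {self.x.size}")
        self.distinct = np.unique(self.x)
        if self.distinct.size < 2:
            raise DegenerateDesignError("all ages identical")
        if taus is None:
            taus = default_grid(self.x, grid_step)
        taus = np.asarray(taus, dtype=float)
        taus = taus[_valid_mask(self.distinct, taus)]
        if taus.size == 0:
            raise NoBreakpointError(
                "no interior candidate has >= 2 distinct ages on each side"
            )
        self.taus = np.sort(taus)
        self.refine_tol = float(refine_tol)
        self._A_inv, self._H = self._normal_inverses(self.taus)

    # -- batched linear algebra over candidates ---------------------------
    def _normal_inverses(self, taus):
        x = self.x
        H = np.maximum(0.0, x[None, :] - taus[:, None])  # (T, n)
        n = float(x.size)
        Sx, Sxx = x.sum(), x @ x
        Sh = H.sum(axis=1)
        Shh = np.einsum("tn,tn->t", H, H)
        Sxh = H @ x
        T = taus.size
        A = np.empty((T, 3, 3))
        A[:, 0, 0] = n
        A[:, 0, 1] = A[:, 1, 0] = Sx
        A[:, 0, 2] = A[:, 2, 0] = Sh
        A[:, 1, 1] = Sxx
        A[:, 1, 2] = A[:, 2, 1] = Sxh
        A[:, 2, 2] = Shh
        return np.linalg.inv(A), H

    def _solve(self, y, A_inv, H):
        rhs = np.empty((A_inv.shape[0], 3))
        rhs[:, 0] = y.sum()
        rhs[:, 1] = self.x @ y
        rhs[:, 2] = H @ y
        beta = np.einsum("tij,tj->ti", A_inv, rhs)
        rss = np.maximum(y @ y - np.einsum("ti,ti->t", beta, rhs), 0.0)
        return beta, rss

    # -- the fit ----------------------------------------------------------
    def fit(self, y: np.ndarray):
        """Return (beta, tau, rss, flat_profile) for response ``y``."""
        y = np.asarray(y, dtype=float)
        beta_c, rss_c = self._solve(y, self._A_inv, self._H)
        scale = float(y @ y)
        flat = self.taus.size > 1 and bool(
            np.all(rss_c <= rss_c.min() + 1e-9 * (scale + 1e-9))
        )

        # dense refinement around every coarse local minimum
        refine = self._refine_taus(rss_c)
        if refine.size:
            A_inv_r, H_r = self._normal_inverses(refine)
            beta_r, rss_r = self._solve(y, A_inv_r, H_r)
            taus = np.concatenate([self.taus, refine])
            beta = np.concatenate([beta_c, beta_r])
            rss = np.concatenate([rss_c, rss_r])
            order = np.argsort(taus, kind="stable")
            taus, beta, rss = taus[order], beta[order], rss[order]
        else:
            taus, beta, rss = self.taus, beta_c, rss_c

        if flat:
            # float jitter breaks exact ties arbitrarily; pick the smallest
            # tau whose RSS is within numerical noise of the minimum
            best = int(np.flatnonzero(
                rss <= rss.min() + 1e-9 * (scale + 1e-9))[0])
        else:
            best = int(np.argmin(rss))  # first minimum = smallest tau on ties
        return beta[best], float(taus[best]), float(rss[best]), flat

    def _refine_taus(self, rss_c):
        taus = self.taus
        if taus.size < 2 or self.refine_tol <= 0:
            return np.empty(0)
        lower = np.r_[np.inf, rss_c[:-1]]
        upper = np.r_[rss_c[1:], np.inf]
        minima = np.flatnonzero((rss_c <= lower) & (rss_c <= upper))
        spans = []
        for i in minima:
            # boundary minima extend to the edges of the valid tau region
            lo = taus[i - 1] if i > 0 else self.distinct[1]
            hi = taus[i + 1] if i < taus.size - 1 else self.distinct[-2]
            k = int(np.floor((hi - lo) / self.refine_tol + 1e-9))
            spans.append(lo + self.refine_tol * np.arange(k + 1))
        dense = np.unique(np.concatenate(spans))
        dense = dense[_valid_mask(self.distinct, dense)]
        return np.setdiff1d(dense, taus)

    def profile(self, y: np.ndarray, taus: np.ndarray):
        """RSS at arbitrary candidate breakpoints (diagnostic; allows any tau
        inside the validity region)."""
        taus = np.asarray(taus, dtype=float)
        ok = _valid_mask(self.distinct, taus)
        if not ok.all():
            raise NoBreakpointError(
                f"candidate(s) {taus[~ok].tolist()} lack >= 2 distinct ages on a side"
            )
        A_inv, H = self._normal_inverses(taus)
        _, rss = self._solve(np.asarray(y, dtype=float), A_inv, H)
        return rss


@dataclass(frozen=True)
class BisegmentalResults:
    """Fitted hinge: parameters, breakpoint, goodness of fit.

    ``beta1 + beta2`` is the post-breakpoint slope.  ``rss`` is the minimum
    residual sum of squares over the candidate grid plus refinement.
    """

    group: str
    beta0: float
    beta1: float
    beta2: float
    tau: float
    rss: float
    n: int
    grid: np.ndarray = field(repr=False, default=None)
    n_excluded: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.tau])

    @property
    def post_slope(self) -> float:
        return self.beta1 + self.beta2

    def predict(self, age):
        a = np.asarray(age, dtype=float)
        return self.beta0 + self.beta1 * a + self.beta2 * np.maximum(0.0, a - self.tau)

    def summary(self) -> str:
        lines = [
            "Bi-segmental starvation-response fit",
            "====================================",
            f"group                 {self.group}",
            f"n larvae              {self.n}  (excluded: {self.n_excluded})",
            f"breakpoint age tau    {self.tau:10.3f} hr AL3E",
            f"intercept beta0       {self.beta0:10.3f} hr",
            f"pre-break slope       {self.beta1:10.3f} hr/hr",
            f"slope change beta2    {self.beta2:10.3f} hr/hr",
            f"post-break slope      {self.post_slope:10.3f} hr/hr",
            f"residual SS           {self.rss:10.4f} hr^2",
        ]
        return "\n".join(lines)

    def plot(self, records: Sequence[StarvationRecord] | None = None, ax=None):
        """Data (optional) and the fitted two-segment line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if records:
            xs = [r.age_at_starvation for r in records if r.pupariated]
            ys = [r.time_to_pupariation for r in records if r.pupariated]
            ax.plot(xs, ys, "o", alpha=0.4, label="larvae")
        grid = np.linspace(0, max(self.tau * 2, self.tau + 10), 200)
        ax.plot(grid, self.predict(grid), "-", label="hinge fit")
        ax.axvline(self.tau, ls="--", color="grey", label=f"tau = {self.tau:.2f} hr")
        ax.set_xlabel("age at starvation (hr AL3E)")
        ax.set_ylabel("time to pupariation (hr)")
        ax.legend()
        return ax


class BisegmentalRegression:
    """Hinge-regression model of time-to-pupariation on age at starvation.

    Parameters
    ----------
    age, time : array-like
        Per-larva age at starvation (hr AL3E) and time to pupariation (hr).
    group : str
        Cohort label carried into the results.

    Use :meth:`from_records` to build from validated
    :class:`~critweight.records.StarvationRecord` collections (non-pupariating
    larvae are excluded and counted).
    """

    def __init__(self, age, time, group: str = ""):
        self.age = np.asarray(age, dtype=float)
        self.time = np.asarray(time, dtype=float)
        if self.age.shape != self.time.shape or self.age.ndim != 1:
            raise InvariantError("age and time must be equal-length 1-d arrays")
        self.group = group
        self.n_excluded = 0

    @classmethod
    def from_records(cls, records: Iterable[StarvationRecord], group: str | None = None):
        records = list(records)
        if group is not None:
            records = [r for r in records if r.group == group]
        kept = [r for r in records if r.pupariated]
        labels = {r.group for r in kept}
        if group is None and len(labels) > 1:
            raise InvariantError(f"records mix groups {sorted(labels)}; pass group=")
        model = cls(
            [r.age_at_starvation for r in kept],
            [r.time_to_pupariation for r in kept],
            group=group or (labels.pop() if labels else ""),
        )
        model.n_excluded = len(records) - len(kept)
        return model

    @classmethod
    def from_dataframe(cls, df, age_col="age_at_starvation",
                       time_col="time_to_pupariation", group: str = ""):
        return cls(df[age_col].to_numpy(), df[time_col].to_numpy(), group=group)

    def fit(self, grid: Sequence[float] | None = None,
            grid_step: float = DEFAULT_GRID_STEP,
            refine_tol: float = DEFAULT_REFINE_TOL,
            continuous: bool = True) -> BisegmentalResults:
        """Profile-least-squares fit; deterministic given data and grid.

        ``continuous=False`` fits two unjoined lines instead of the hinge
        (sensitivity analysis); the reported breakpoint is then the
        boundary between the two pieces and ``beta2`` the slope difference.
        """
        if not continuous:
            return self._fit_disjoint(grid, grid_step)
        fitter = _HingeFitter(self.age, taus=grid, grid_step=grid_step,
                              refine_tol=refine_tol)
        beta, tau, rss, flat = fitter.fit(self.time)
        if flat:
            warnings.warn(
                "flat RSS profile: breakpoint is weakly identified; "
                "tie broken to the smallest candidate age",
                DegenerateFitWarning,
                stacklevel=2,
            )
        return BisegmentalResults(
            group=self.group, beta0=float(beta[0]), beta1=float(beta[1]),
            beta2=float(beta[2]), tau=tau, rss=rss, n=self.age.size,
            grid=fitter.taus, n_excluded=self.n_excluded,
        )

    def _fit_disjoint(self, grid, grid_step):
        x, y = self.age, self.time
        fitter = _HingeFitter(x, taus=grid, grid_step=grid_step, refine_tol=0)
        best = None
        for tau in fitter.taus:
            left, right = x <= tau, x > tau
            rss = 0.0
            coefs = []
            for mask in (left, right):
                X = np.column_stack([np.ones(mask.sum()), x[mask]])
                c, res, rank, _ = np.linalg.lstsq(X, y[mask], rcond=None)
                if rank < 2:
                    break
                coefs.append(c)
                r = y[mask] - X @ c
                rss += float(r @ r)
            else:
                if best is None or rss < best[0]:
                    best = (rss, tau, coefs)
        if best is None:
            raise DegenerateDesignError("no candidate admits two full-rank lines")
        rss, tau, (cl, cr) = best
        return BisegmentalResults(
            group=self.group, beta0=float(cl[0]), beta1=float(cl[1]),
            beta2=float(cr[1] - cl[1]), tau=float(tau), rss=rss,
            n=x.size, grid=fitter.taus, n_excluded=self.n_excluded,
        )

    def profile_rss(self, taus: Sequence[float]) -> list[tuple[float, float]]:
        fitter = _HingeFitter(self.age, taus=np.asarray(taus, dtype=float),
                              refine_tol=0)
        rss = fitter.profile(self.time, np.asarray(taus, dtype=float))
        return list(zip((float(t) for t in taus), (float(r) for r in rss)))


def fit_bisegmental(records: Iterable[StarvationRecord], *,
                    grid: Sequence[float] | None = None,
                    grid_step: float = DEFAULT_GRID_STEP,
                    refine_tol: float = DEFAULT_REFINE_TOL,
                    continuous: bool = True,
                    group: str | None = None) -> BisegmentalResults:
    """Functional entry point: fit the hinge model to a cohort."""
    model = BisegmentalRegression.from_records(records, group=group)
    return model.fit(grid=grid, grid_step=grid_step, refine_tol=refine_tol,
                     continuous=continuous)


def profile_rss(records: Iterable[StarvationRecord],
                taus: Sequence[float]) -> list[tuple[float, float]]:
    """RSS of the hinge fit at each candidate breakpoint (diagnostic)."""
    return BisegmentalRegression.from_records(records).profile_rss(taus)
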