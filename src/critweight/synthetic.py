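"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design: larvae collected on a 2-hr
schedule after the molt to the final instar, starved at defined ages, and
scored for time to pupariation every 2 hr.  The generative model is

* starvation response: mean time to pupariation piecewise linear in age
  at starvation with a hinge at the true critical-weight age (delay
  declining before the hinge, ~flat plateau after), Gaussian noise
  truncated at zero;
* growth: wet mass linear in age with Gaussian noise truncated at zero;
* qPCR: a stable reference-gene Ct and a target Ct offset by a baseline
  ΔCt minus log2 of a time-varying fold profile;
* hormone titre: a unimodal Gaussian-shaped pulse sampled in 2-hr
  classes.

Defaults place the hinge at 9 hr AL3E with a ~33.8 hr plateau and a
0.07 mg/hr growth line — illustrative values with the anatomy of real
wild-type cohorts, not calibrated to any particular dataset.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigError
from .records import CtRecord, GrowthRecord, StarvationRecord, TimecourseSample

__all__ = [
    "QpcrConfig",
    "HormoneConfig",
    "SyntheticConfig",
    "simulate_starvation_cohort",
    "simulate_growth",
    "simulate_qpcr",
    "simulate_hormone_pulse",
]

_DEFAULT_AGE_GRID = tuple(float(a) for a in range(0, 26, 2))


@dataclass(frozen=True)
class QpcrConfig:
    """Per-gene qPCR generative block.

    ``fold_profile`` maps sampling time (hr) to the true fold change of the
    target relative to its value at the calibrator time; ``baseline_dct``
    is the target-minus-reference Ct difference when the fold change is 1.
    """

    reference_ct: float = 18.0
    reference_sd: float = 0.15
    baseline_dct: float = 7.0
    fold_profile: Mapping[float, float] = field(
        default_factory=lambda: {t: 1.0 for t in _DEFAULT_AGE_GRID}
    )
    replicate_sd: float = 0.25
    n_replicates: int = 3


@dataclass(frozen=True)
class HormoneConfig:
    """Unimodal hormone pulse: baseline + amplitude * exp(-(t-peak)^2 / 2w^2)."""

    baseline: float = 5.0
    amplitude: float = 30.0
    peak_time: float = 8.0
    width: float = 2.0
    noise_sd: float = 3.0
    n_replicates: int = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generative model.

    Starvation response: mean time to pupariation at age ``x`` is
    ``intercept_true + pre_slope * x + (post_slope - pre_slope) * max(0, x - tau_true)``
    with N(0, noise_sd) noise truncated at zero.  ``n_per_age`` larvae are
    starved at each age of ``age_grid``.  All units hr / mg.
    """

    tau_true: float = 9.0
    intercept_true: float = 50.0
    pre_slope: float = -1.8
    post_slope: float = 0.0
    noise_sd: float = 2.0
    age_grid: Sequence[float] = _DEFAULT_AGE_GRID
    n_per_age: int = 25
    growth_intercept: float = 0.25
    growth_slope: float = 0.07
    growth_noise_sd: float = 0.05
    lognormal_noise: bool = False
    qpcr: QpcrConfig | None = None
    hormone: HormoneConfig | None = None
    seed: int = 0

    def __post_init__(self):
        grid = tuple(float(a) for a in self.age_grid)
        object.__setattr__(self, "age_grid", grid)
        if self.noise_sd < 0 or self.growth_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.n_per_age < 1:
            raise ConfigError("n_per_age must be >= 1")
        if not grid or not (min(grid) <= self.tau_true <= max(grid)):
            raise ConfigError(
                f"tau_true={self.tau_true} outside the age grid span {grid[:1]}..{grid[-1:]}"
            )
        bad = [x for x in grid if self.mean_time(x) <= 0]
        if bad:
            raise ConfigError(
                f"mean time to pupariation <= 0 at age(s) {bad}: biologically impossible"
            )

    def mean_time(self, age: float) -> float:
        return (
            self.intercept_true
            + self.pre_slope * age
            + (self.post_slope - self.pre_slope) * max(0.0, age - self.tau_true)
        )

    # -- flat JSON round-trip --------------------------------------------
    def to_json(self, path) -> None:
        payload = asdict(self)
        if self.qpcr is not None:
            payload["qpcr"]["fold_profile"] = {
                str(k): v for k, v in self.qpcr.fold_profile.items()
            }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("qpcr") is not None:
            qp = payload["qpcr"]
            qp["fold_profile"] = {float(k): v for k, v in qp["fold_profile"].items()}
            payload["qpcr"] = QpcrConfig(**qp)
        if payload.get("hormone") is not None:
            payload["hormone"] = HormoneConfig(**payload["hormone"])
        return cls(**payload)


def _positive_noise(rng: np.random.Generator, mean: np.ndarray, sd: float,
                    lognormal: bool) -> np.ndarray:
    """Draws with the given mean/sd, support restricted to (0, inf)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return mean.copy()
    if lognormal:
        # lognormal with matched mean and sd (skew-sensitivity mode)
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2))
    a = (0.0 - mean) / sd  # standardized truncation bound
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)


def simulate_starvation_cohort(
    config: SyntheticConfig, group: str = "synthetic", rng=None
) -> list[StarvationRecord]:
    """One cohort of ``n_per_age`` larvae per age class; reproducible by seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records = []
    k = 0
    for age in config.age_grid:
        mu = np.full(config.n_per_age, config.mean_time(age))
        times = _positive_noise(rng, mu, config.noise_sd, config.lognormal_noise)
        for t in times:
            records.append(
                StarvationRecord(
                    larva_id=f"{group}-{k}", group=group,
                    age_at_starvation=age, time_to_pupariation=float(t),
                )
            )
            k += 1
    return records


def simulate_growth(
    config: SyntheticConfig, group: str = "synthetic", rng=None
) -> list[GrowthRecord]:
    """Larval masses on the age grid around the linear growth line."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records = []
    k = 0
    for age in config.age_grid:
        mu = np.full(
            config.n_per_age, config.growth_intercept + config.growth_slope * age
        )
        masses = _positive_noise(rng, mu, config.growth_noise_sd,
                                 config.lognormal_noise)
        for m in masses:
            records.append(
                GrowthRecord(larva_id=f"{group}-g{k}", group=group,
                             age=age, mass=float(m))
            )
            k += 1
    return records


def simulate_qpcr(
    config: SyntheticConfig, genes: Sequence[str], group: str = "synthetic",
    rng=None,
) -> list[CtRecord]:
    """Ct pairs: stable reference gene, target offset by -log2(fold(t))."""
    qp = config.qpcr if config.qpcr is not None else QpcrConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records = []
    for gene in genes:
        for time, fold in sorted(qp.fold_profile.items()):
            if fold <= 0:
                raise ConfigError(f"fold change must be > 0, got {fold} at t={time}")
            for rep in range(qp.n_replicates):
                ct_ref = rng.normal(qp.reference_ct, qp.reference_sd)
                ct_tgt = (
                    ct_ref + qp.baseline_dct - math.log2(fold)
                    + rng.normal(0.0, qp.replicate_sd)
                )
                records.append(
                    CtRecord(gene=gene, group=group, time=float(time),
                             replicate=rep, ct_target=float(ct_tgt),
                             ct_reference=float(ct_ref))
                )
    return records


def simulate_hormone_pulse(
    config: SyntheticConfig, group: str = "synthetic", rng=None,
    times: Sequence[float] | None = None,
) -> list[TimecourseSample]:
    """A unimodal titre pulse sampled in 2-hr classes (pg/mg)."""
    hc = config.hormone if config.hormone is not None else HormoneConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    times = config.age_grid if times is None else times
    samples = []
    for t in times:
        mu = hc.baseline + hc.amplitude * math.exp(
            -((t - hc.peak_time) ** 2) / (2 * hc.width**2)
        )
        vals = _positive_noise(rng, np.full(hc.n_replicates, mu), hc.noise_sd, False)
        for rep, v in enumerate(vals):
            samples.append(
                TimecourseSample(group=group, time=float(t), replicate=rep,
                                 value=float(v))
            )
    return samples
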