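"""Relative qPCR quantification and sliding-window letter comparisons.

Two conventions used to present developmental time courses:

* **ΔΔCt relative expression.**  Each replicate's target Ct is normalized
  to the internal control gene run on the same sample (ΔCt = Ct_target −
  Ct_reference), then to a calibrator condition (a (group, time) cell,
  e.g. the control genotype at 0 hr) whose mean ΔCt maps to a fold change
  of exactly 1.  Amplification efficiency is taken as perfect doubling, so
  fold change = 2^−ΔΔCt.  With the calibrator's *arithmetic mean* ΔCt as
  the reference level, the calibrator's *geometric* mean fold change is
  exactly 1.

* **Windowed compact letter display.**  Mean values at sampling times
  within ±``window`` hr of each other (and across groups at matched
  times) are compared pairwise by Welch's t test; letters are then
  assigned by the insert-and-absorb algorithm so that any two compared
  cells share a letter iff they were not significantly different.  Pairs
  further apart than the window are not compared and impose no
  constraint.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InvariantError
from .records import CtRecord, TimecourseSample

__all__ = [
    "RelativeExpression",
    "LetterAssignment",
    "relative_expression",
    "windowed_letter_groups",
    "insert_absorb_letters",
]


@dataclass(frozen=True)
class RelativeExpression:
    """One replicate's fold change relative to the calibrator condition."""

    gene: str
    group: str
    time: float
    replicate: int
    value: float

    def __post_init__(self):
        if not (self.value > 0 and math.isfinite(self.value)):
            raise InvariantError(f"fold change must be finite and > 0, got {self.value}")


def relative_expression(
    ct: Iterable[CtRecord], calibrator: tuple[str, float]
) -> list[RelativeExpression]:
    """ΔΔCt fold changes, per gene, against one calibrator (group, time) cell.

    For each replicate, ΔCt = ct_target − ct_reference and
    value = 2^−(ΔCt − mean ΔCt of the gene's calibrator replicates).
    Normalizing by the reference gene makes the result invariant to any
    per-sample shift applied to both channels.
    """
    ct = list(ct)
    cal_group, cal_time = calibrator
    out: list[RelativeExpression] = []
    for gene in sorted({r.gene for r in ct}):
        gene_recs = [r for r in ct if r.gene == gene]
        cal = [r for r in gene_recs if r.group == cal_group and r.time == cal_time]
        if not cal:
            raise ConfigError(
                f"calibrator ({cal_group!r}, {cal_time}) absent for gene {gene!r}"
            )
        cal_mean_dct = float(np.mean([r.ct_target - r.ct_reference for r in cal]))
        for r in gene_recs:
            ddct = (r.ct_target - r.ct_reference) - cal_mean_dct
            out.append(
                RelativeExpression(
                    gene=gene, group=r.group, time=r.time,
                    replicate=r.replicate, value=float(2.0 ** (-ddct)),
                )
            )
    return out


@dataclass(frozen=True)
class LetterAssignment:
    """Letters per (group, time) cell plus the pairwise decision matrix.

    ``decisions`` maps a frozenset of two cells to True (significantly
    different) or False (compared, not significant); uncompared pairs are
    absent.  ``letters`` maps every retained cell to a non-empty,
    alphabetically sorted letter string.
    """

    letters: Mapping[tuple[str, float], str]
    decisions: Mapping[frozenset, bool]
    p_values: Mapping[frozenset, float] = field(default_factory=dict)
    alpha: float = 0.05
    excluded: tuple = ()

    def verify(self) -> None:
        """Assert the letter/decision consistency invariant; raises otherwise."""
        for pair, significant in self.decisions.items():
            a, b = sorted(pair)
            shared = set(self.letters[a]) & set(self.letters[b])
            if significant and shared:
                raise InvariantError(f"significant pair {a}, {b} share letter(s) {shared}")
            if not significant and not shared:
                raise InvariantError(f"non-significant pair {a}, {b} share no letter")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "time": t, "letters": s}
            for (g, t), s in sorted(self.letters.items())
        ]
        return pd.DataFrame(rows, columns=["group", "time", "letters"])


def _letter(i: int) -> str:
    # a..z, then aa, ab, ... for pathological matrices
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s


def insert_absorb_letters(cells: list, significant_pairs: Iterable[frozenset]):
    """Compact letter display by insert-and-absorb.

    Starts with all cells in one letter column; each significantly
    different pair splits every column containing both; columns that
    become subsets of another are absorbed.  Any pair never split stays
    together in some column, so compared-but-not-different cells always
    share a letter, and split pairs never do.
    """
    columns: list[set] = [set(cells)]
    for pair in significant_pairs:
        a, b = sorted(pair)
        hit = [c for c in columns if a in c and b in c]
        for col in hit:
            columns.remove(col)
            columns.append(col - {b})
            columns.append(col - {a})
        # absorb subsets (keeps the display minimal and duplicate-free)
        keep = []
        for i, c in enumerate(columns):
            if c and not any(
                c < d or (c == d and j < i) for j, d in enumerate(columns) if j != i
            ):
                keep.append(c)
        columns = keep
    order = {cell: k for k, cell in enumerate(cells)}
    columns.sort(key=lambda c: min(order[m] for m in c))
    letters = {cell: "" for cell in cells}
    for k, col in enumerate(columns):
        for cell in col:
            letters[cell] += _letter(k)
    return {cell: "".join(sorted(s)) for cell, s in letters.items()}


def _welch_decision(va: np.ndarray, vb: np.ndarray, alpha: float):
    """(significant, p) under Welch's t; zero-variance pairs decided by means."""
    if np.ptp(va) == 0 and np.ptp(vb) == 0:
        same = va[0] == vb[0]
        return (not same), (1.0 if same else 0.0)
    p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
    if math.isnan(p):
        p = 1.0
    return p < alpha, p


def windowed_letter_groups(
    samples: Iterable[TimecourseSample],
    window: float = 2.0,
    alpha: float = 0.05,
    *,
    all_pairs: bool = False,
    holm: bool = False,
) -> LetterAssignment:
    """Letter groups over a (group, time) grid of replicate measurements.

    Cells are compared within the same group when their times differ by at
    most ``window`` hr, and across groups at identical times — matching
    how time-course figures annotate "the mean at the time ±window hr".
    ``all_pairs=True`` compares every pair instead; ``holm=True`` applies
    a Holm step-down correction over the tested pairs.  Cells with fewer
    than two replicates are excluded with a warning.
    """
    grouped: dict[tuple[str, float], list[float]] = {}
    for s in samples:
        grouped.setdefault((s.group, s.time), []).append(s.value)
    excluded = tuple(sorted(k for k, v in grouped.items() if len(v) < 2))
    for k in excluded:
        warnings.warn(f"cell {k} has < 2 replicates; excluded", UserWarning,
                      stacklevel=2)
    cells = sorted(k for k, v in grouped.items() if len(v) >= 2)
    if len(cells) < 2:
        raise InvariantError("need >= 2 cells with >= 2 replicates each")

    tested: list[frozenset] = []
    p_values: dict[frozenset, float] = {}
    for a, b in itertools.combinations(cells, 2):
        (ga, ta), (gb, tb) = a, b
        comparable = all_pairs or (
            (ga == gb and abs(ta - tb) <= window) or (ga != gb and ta == tb)
        )
        if not comparable:
            continue
        pair = frozenset((a, b))
        _, p = _welch_decision(np.asarray(grouped[a]), np.asarray(grouped[b]), alpha)
        tested.append(pair)
        p_values[pair] = p

    if holm and tested:
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([p_values[q] for q in tested], alpha=alpha,
                                 method="holm")[1]
        p_values = dict(zip(tested, (float(p) for p in adjusted)))

    decisions = {pair: p_values[pair] < alpha for pair in tested}
    significant = [pair for pair in tested if decisions[pair]]
    letters = insert_absorb_letters(cells, significant)
    assignment = LetterAssignment(
        letters=letters, decisions=decisions, p_values=p_values,
        alpha=alpha, excluded=excluded,
    )
    assignment.verify()
    return assignment
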