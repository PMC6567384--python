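"""Goodness-of-fit of the time-dependent CJS model on live-only histories.

Because no omnibus test exists for the full multievent model, adequacy is
assessed on the live resightings alone (optical collars, ear tags, inactive
GPS collars — certain GPS detections and dead recoveries are excluded) by
the classical contingency-table decomposition of the Cormack–Jolly–Seber
model:

* ``TEST3.SR`` — do newly marked and previously marked animals seen at an
  occasion have the same probability of ever being seen again? (transience)
* ``TEST3.SM`` — among those seen again, does the occasion of next
  sighting depend on whether they were newly marked?
* ``TEST2.CT`` — among animals known alive at an occasion (seen before and
  after), does being seen at that occasion change the timing of the next
  sighting (at the next occasion vs later)? (trap-dependence)
* ``TEST2.CL`` — among those next seen two or more occasions later, does
  the exact timing depend on being seen at the occasion?

Each component sums per-occasion Pearson chi-square statistics.  Sparse
tables are pooled by merging outermost columns inward until every expected
count reaches 2; tables that remain deficient are skipped and contribute no
degrees of freedom.  Components are computed per group (sex) and summed
into one pooled statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .events import EncounterHistory, to_live_only_binary

COMPONENT_NAMES = ("TEST3.SR", "TEST3.SM", "TEST2.CT", "TEST2.CL")

#: minimum expected cell count before pooling stops
MIN_EXPECTED = 2.0


@dataclass
class MArray:
    """Releases and first-recapture counts (the CJS sufficient statistic)."""

    releases: np.ndarray  # R_i, animals released at occasion i
    m: np.ndarray  # m[i, j], first recaptured at j of those released at i

    @property
    def never_seen(self) -> np.ndarray:
        return self.releases - self.m.sum(axis=1)


def build_m_array(binary: np.ndarray) -> MArray:
    """Reduced m-array; every detection is a release (no losses on capture)."""
    binary = np.asarray(binary, dtype=int)
    T = binary.shape[1]
    R = np.zeros(T, dtype=int)
    m = np.zeros((T, T), dtype=int)
    for row in binary:
        occ = np.flatnonzero(row)
        for a, b in zip(occ, occ[1:]):
            R[a] += 1
            m[a, b] += 1
        if occ.size:
            R[occ[-1]] += 1
    # the final release cohort can never be recaptured; it still counts
    return MArray(releases=R, m=m)


def pooled_chi2(table: np.ndarray, min_expected: float = MIN_EXPECTED) -> tuple[float, int] | None:
    """Pearson chi-square of a 2 x C table after directional pooling.

    Zero columns are removed first; then the outermost column on the side
    with the smaller marginal total is merged inward until all expected
    counts reach ``min_expected`` or only two columns remain.  Returns
    (chi2, df) or None when the table stays deficient (a zero row margin,
    fewer than two informative columns, or a deficient 2 x 2).
    """
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or np.any(t.sum(axis=1) == 0):
        return None
    while t.shape[1] > 2:
        n = t.sum()
        E = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        if (E >= min_expected).all():
            break
        if t[:, 0].sum() <= t[:, -1].sum():
            t = np.column_stack([t[:, 0] + t[:, 1], t[:, 2:]])
        else:
            t = np.column_stack([t[:, :-2], t[:, -2] + t[:, -1]])
    n = t.sum()
    E = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (E < min_expected).any():
        return None
    chi2 = float(((t - E) ** 2 / E).sum())
    df = t.shape[1] - 1
    return chi2, df


@dataclass
class GofComponent:
    name: str
    group: str
    chi2: float
    df: int
    n_tables: int


@dataclass
class GofResult:
    components: list[GofComponent]
    total_chi2: float
    total_df: int
    p_value: float

    def by_group(self, group: str) -> list[GofComponent]:
        return [c for c in self.components if c.group == group]


def _first_detection(binary: np.ndarray) -> np.ndarray:
    return np.argmax(binary > 0, axis=1)


def component_tests(binary: np.ndarray, group: str = "") -> list[GofComponent]:
    """U-CARE-style component tests on one group of binary histories."""
    binary = np.asarray(binary, dtype=int)
    if binary.shape[1] < 3:
        raise ValueError("need at least 3 occasions for component tests")
    T = binary.shape[1]
    first = _first_detection(binary)
    seen_after = np.zeros((binary.shape[0], T), dtype=bool)
    for t in range(T - 1):
        seen_after[:, t] = binary[:, t + 1 :].any(axis=1)
    # occasion of first detection strictly after t (T means never)
    next_det = np.full((binary.shape[0], T), T, dtype=int)
    for i, row in enumerate(binary):
        occ = np.flatnonzero(row)
        for t in range(T):
            later = occ[occ > t]
            if later.size:
                next_det[i, t] = later[0]

    out: list[GofComponent] = []

    # TEST3.SR
    chi, df, ntab = 0.0, 0, 0
    for t in range(1, T - 1):
        at = binary[:, t] > 0
        new = at & (first == t)
        old = at & (first < t)
        tab = np.array(
            [
                [np.sum(new & seen_after[:, t]), np.sum(new & ~seen_after[:, t])],
                [np.sum(old & seen_after[:, t]), np.sum(old & ~seen_after[:, t])],
            ]
        )
        res = pooled_chi2(tab)
        if res:
            chi += res[0]
            df += res[1]
            ntab += 1
    out.append(GofComponent("TEST3.SR", group, chi, df, ntab))

    # TEST3.SM
    chi, df, ntab = 0.0, 0, 0
    for t in range(1, T - 1):
        at = (binary[:, t] > 0) & seen_after[:, t]
        if not at.any():
            continue
        new = at & (first == t)
        old = at & (first < t)
        cols = range(t + 1, T)
        tab = np.array(
            [
                [np.sum(new & (next_det[:, t] == j)) for j in cols],
                [np.sum(old & (next_det[:, t] == j)) for j in cols],
            ]
        )
        res = pooled_chi2(tab)
        if res:
            chi += res[0]
            df += res[1]
            ntab += 1
    out.append(GofComponent("TEST3.SM", group, chi, df, ntab))

    # TEST2.CT: known alive at t (seen before and after), seen at t or not,
    # next detection at t+1 vs later
    chi, df, ntab = 0.0, 0, 0
    for t in range(1, T - 1):
        known = (first < t) & seen_after[:, t]
        if not known.any():
            continue
        at = known & (binary[:, t] > 0)
        miss = known & (binary[:, t] == 0)
        tab = np.array(
            [
                [np.sum(at & (next_det[:, t] == t + 1)), np.sum(at & (next_det[:, t] > t + 1))],
                [np.sum(miss & (next_det[:, t] == t + 1)), np.sum(miss & (next_det[:, t] > t + 1))],
            ]
        )
        res = pooled_chi2(tab)
        if res:
            chi += res[0]
            df += res[1]
            ntab += 1
    out.append(GofComponent("TEST2.CT", group, chi, df, ntab))

    # TEST2.CL: among known-alive animals next seen at t+2 or later, the
    # exact occasion of next detection
    chi, df, ntab = 0.0, 0, 0
    for t in range(1, T - 2):
        known = (first < t) & seen_after[:, t] & (next_det[:, t] >= t + 2)
        if not known.any():
            continue
        at = known & (binary[:, t] > 0)
        miss = known & (binary[:, t] == 0)
        cols = range(t + 2, T)
        tab = np.array(
            [
                [np.sum(at & (next_det[:, t] == j)) for j in cols],
                [np.sum(miss & (next_det[:, t] == j)) for j in cols],
            ]
        )
        res = pooled_chi2(tab)
        if res:
            chi += res[0]
            df += res[1]
            ntab += 1
    out.append(GofComponent("TEST2.CL", group, chi, df, ntab))
    return out


def overall_gof(
    histories: Sequence[EncounterHistory],
    group_by_sex: bool = True,
) -> GofResult:
    """Pooled CJS goodness-of-fit over groups (sexes by default)."""
    comps: list[GofComponent] = []
    if group_by_sex:
        groups = sorted({h.sex for h in histories})
        for g in groups:
            binary, kept = to_live_only_binary([h for h in histories if h.sex == g])
            if len(kept) == 0:
                continue
            comps += component_tests(binary, group=g)
    else:
        binary, kept = to_live_only_binary(list(histories))
        comps += component_tests(binary, group="all")
    total_chi2 = float(sum(c.chi2 for c in comps))
    total_df = int(sum(c.df for c in comps))
    p = float(chi2_dist.sf(total_chi2, total_df)) if total_df > 0 else float("nan")
    return GofResult(comps, total_chi2, total_df, p)


def gof_from_stats(total_chi2: float, total_df: int) -> GofResult:
    """Assemble a GofResult from an externally computed pooled statistic."""
    return GofResult([], float(total_chi2), int(total_df), float(chi2_dist.sf(total_chi2, total_df)))
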