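"""Jonckheere-Terpstra ordered-alternative trend test and the step-down
search for the thermoneutral zone (TNZ).

The JT statistic counts concordant cross-group value pairs (ties half) over
groups ordered by ambient temperature. p-values come either from exhaustive
enumeration of all multinomial reassignments (small samples) or from a
seeded Monte-Carlo permutation null with the add-one estimator
p = (1 + #{J* >= J}) / (n_perm + 1), so p is never exactly zero.

The step-down procedure locates the upper and then the lower critical
temperature by repeatedly testing for a trend and trimming the extreme
temperature until no trend remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 10_000
DEFAULT_SEED = 20170922
DEFAULT_MIN_GROUP_N = 5


class NoTnzDetectedError(RuntimeError):
    """A step-down loop stayed significant until fewer than two groups
    remained; no critical temperature could be identified."""

    def __init__(self, message: str, steps: list["StepRecord"]):
        super().__init__(message)
        self.steps = steps


@dataclass
class TemperatureGroups:
    """msRMR values grouped by strictly increasing ambient temperature.

    Values within each group are stored sorted, which makes every
    permutation-based p-value invariant to the input record order.
    """

    groups: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        cleaned = []
        for ta, values in self.groups:
            v = np.sort(np.asarray(values, dtype=float))
            if v.size == 0:
                raise ValueError(f"group at {ta} has no values")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group at {ta} contains non-finite values")
            cleaned.append((float(ta), v))
        cleaned.sort(key=lambda g: g[0])
        temps = [ta for ta, _ in cleaned]
        if len(set(temps)) != len(temps):
            raise ValueError("duplicate group temperatures")
        self.groups = cleaned

    @classmethod
    def from_table(cls, table: pd.DataFrame, temp_col: str = "ta_c",
                   value_col: str = "msrmr") -> "TemperatureGroups":
        groups = [
            (float(ta), sub[value_col].to_numpy())
            for ta, sub in table.groupby(temp_col, sort=True)
        ]
        return cls(groups)

    @property
    def temps(self) -> list[float]:
        return [ta for ta, _ in self.groups]

    @property
    def sizes(self) -> list[int]:
        return [len(v) for _, v in self.groups]

    def subset(self, temps) -> "TemperatureGroups":
        keep = set(float(t) for t in temps)
        return TemperatureGroups([g for g in self.groups if g[0] in keep])

    def filter_min_n(self, min_group_n: int) -> "TemperatureGroups":
        kept = [g for g in self.groups if len(g[1]) >= min_group_n]
        if not kept:
            raise ValueError("no group meets the minimum sample size")
        return TemperatureGroups(kept)


@dataclass
class JtResult:
    statistic: float
    p_value: float
    method: str                   # "exact" | "permutation"
    alternative: str              # "increasing" | "decreasing"
    n_perm: int = 0
    seed: int | None = None


@dataclass
class StepRecord:
    """One step of the step-down trail (mirrors one row of a step table)."""

    side: str                     # "upper" | "lower"
    temps: list[float]
    result: JtResult


@dataclass
class TnzEstimate:
    lct_c: float
    uct_c: float
    lct_flag: str                 # "interior" | "boundary-of-design"
    uct_flag: str
    steps: list[StepRecord]
    min_group_n: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "lct_c": self.lct_c,
            "uct_c": self.uct_c,
            "lct_flag": self.lct_flag,
            "uct_flag": self.uct_flag,
            "alpha": self.alpha,
            "min_group_n": self.min_group_n,
            "steps": [
                {
                    "side": s.side,
                    "temps": s.temps,
                    "statistic": s.result.statistic,
                    "p_value": s.result.p_value,
                    "method": s.result.method,
                    "alternative": s.result.alternative,
                    "n_perm": s.result.n_perm,
                }
                for s in self.steps
            ],
        }


def _as_groups(groups) -> TemperatureGroups:
    if isinstance(groups, TemperatureGroups):
        return groups
    if isinstance(groups, pd.DataFrame):
        return TemperatureGroups.from_table(groups)
    return TemperatureGroups(list(groups))


def _ordered_values(tg: TemperatureGroups, alternative: str) -> list[np.ndarray]:
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    vals = [v for _, v in tg.groups]
    return vals[::-1] if alternative == "decreasing" else vals


def _jt_from_arrays(vals: list[np.ndarray]) -> float:
    j = 0.0
    for a, b in combinations(vals, 2):
        j += float(np.sum(b[None, :] > a[:, None]))
        j += 0.5 * float(np.sum(b[None, :] == a[:, None]))
    return j


def jt_statistic(groups, alternative: str = "increasing") -> float:
    """JT statistic: over all group pairs i<j in temperature order, count
    value pairs with the later-group value larger (ties count 1/2). The
    decreasing alternative reverses the group order."""
    tg = _as_groups(groups)
    if len(tg.groups) < 2:
        raise ValueError("need at least two groups")
    return _jt_from_arrays(_ordered_values(tg, alternative))


def max_pair_count(groups) -> float:
    """Upper bound of the JT statistic: sum over i<j of n_i * n_j."""
    sizes = _as_groups(groups).sizes
    total = sum(sizes)
    return (total * total - sum(s * s for s in sizes)) / 2


def jt_exact_p(groups, alternative: str = "increasing",
               max_arrangements: int = 2_000_000) -> JtResult:
    """Exact one-sided p by exhaustive enumeration of every reassignment of
    the pooled values to the observed group sizes (index-combination
    recursion; each of the multinomially many splits is equally likely under
    exchangeability, which handles ties with correct multiplicity)."""
    tg = _as_groups(groups)
    if len(tg.groups) < 2:
        raise ValueError("need at least two groups")
    sizes = tg.sizes
    n = sum(sizes)
    n_arr = math.factorial(n)
    for s in sizes:
        n_arr //= math.factorial(s)
    if n_arr > max_arrangements:
        raise ValueError(
            f"{n_arr} arrangements exceed the cap ({max_arrangements}); "
            "use jt_permutation_p"
        )
    vals = _ordered_values(tg, alternative)
    pooled = np.concatenate(vals)
    sizes_o = [len(v) for v in vals]
    # pairwise score between pooled positions, computed once
    score = (pooled[None, :] > pooled[:, None]).astype(float)
    score += 0.5 * (pooled[None, :] == pooled[:, None])
    observed = _jt_from_arrays(vals)

    n_ge = 0
    n_total = 0

    def recurse(remaining: tuple[int, ...], gi: int, chosen: list[np.ndarray], acc: float):
        nonlocal n_ge, n_total
        if gi == len(sizes_o) - 1:
            last = np.fromiter(remaining, dtype=int)
            j = acc + sum(score[np.ix_(g, last)].sum() for g in chosen)
            n_total += 1
            if j >= observed - 1e-9:
                n_ge += 1
            return
        for combo in combinations(remaining, sizes_o[gi]):
            g = np.fromiter(combo, dtype=int)
            extra = sum(score[np.ix_(prev, g)].sum() for prev in chosen)
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, gi + 1, chosen + [g], acc + extra)

    recurse(tuple(range(n)), 0, [], 0.0)
    assert n_total == n_arr
    return JtResult(
        statistic=observed,
        p_value=n_ge / n_total,
        method="exact",
        alternative=alternative,
    )


def _jt_permuted(vals: list[np.ndarray], n_perm: int, rng: np.random.Generator,
                 chunk: int = 2000) -> np.ndarray:
    """JT statistic for n_perm random reassignments, vectorized over
    permutations in chunks (memory per group pair stays small)."""
    pooled = np.concatenate(vals)
    sizes = [len(v) for v in vals]
    bounds = np.cumsum([0] + sizes)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        mat = rng.permuted(np.broadcast_to(pooled, (p, pooled.size)).copy(), axis=1)
        j = np.zeros(p)
        for gi in range(len(sizes)):
            a = mat[:, bounds[gi]:bounds[gi + 1]]
            for gj in range(gi + 1, len(sizes)):
                b = mat[:, bounds[gj]:bounds[gj + 1]]
                gt = b[:, None, :] > a[:, :, None]
                eq = b[:, None, :] == a[:, :, None]
                j += gt.sum(axis=(1, 2)) + 0.5 * eq.sum(axis=(1, 2))
        out[done:done + p] = j
        done += p
    return out


def jt_permutation_p(groups, alternative: str = "increasing",
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = DEFAULT_SEED,
                     rng: np.random.Generator | None = None) -> JtResult:
    """Monte-Carlo permutation p: pooled values are reshuffled across groups
    holding the group sizes fixed. Reproducible for a given seed (or pass an
    explicit generator, e.g. from a pipeline seed stream)."""
    tg = _as_groups(groups)
    if len(tg.groups) < 2:
        raise ValueError("need at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = _ordered_values(tg, alternative)
    observed = _jt_from_arrays(vals)
    perm = _jt_permuted(vals, n_perm, rng)
    p = (1.0 + np.sum(perm >= observed - 1e-9)) / (n_perm + 1.0)
    return JtResult(
        statistic=observed,
        p_value=float(p),
        method="permutation",
        alternative=alternative,
        n_perm=n_perm,
        seed=seed,
    )


def step_down_tnz(groups, alpha: float = 0.05,
                  min_group_n: int = DEFAULT_MIN_GROUP_N,
                  n_perm: int = DEFAULT_N_PERM,
                  seed: int | None = DEFAULT_SEED,
                  rng: np.random.Generator | None = None) -> TnzEstimate:
    """Step-down permutation JT search for the TNZ boundaries.

    1. Drop temperatures with fewer than ``min_group_n`` values.
    2. T* = qualifying temperature with the lowest mean msRMR (ties break to
       the lowest temperature).
    3. Upper side: on temperatures >= T*, test for an increasing trend;
       while significant, drop the highest temperature and retest. The UCT
       is the highest temperature of the first non-significant set.
    4. Lower side: on temperatures from the design minimum up to the UCT,
       test for a decreasing trend (msRMR falls as temperature rises toward
       the TNZ); while significant, drop the lowest temperature and retest.
       The LCT is the lowest temperature of the first non-significant set.

    A boundary is flagged ``boundary-of-design`` when it coincides with the
    extreme qualifying temperature, i.e. the design did not bracket it. When
    a side starts with fewer than two groups no trend is testable and the
    boundary estimate is that single temperature, flagged. A side whose loop
    stays significant down to fewer than two groups raises
    :class:`NoTnzDetectedError` with the trail attached.
    """
    tg = _as_groups(groups).filter_min_n(min_group_n)
    if len(tg.groups) < 3:
        raise ValueError("need at least three qualifying temperature groups")
    if rng is None:
        rng = np.random.default_rng(seed)
    temps = tg.temps
    means = np.array([v.mean() for _, v in tg.groups])
    t_star = temps[int(np.argmin(means))]
    steps: list[StepRecord] = []

    def run_side(side: str, current: TemperatureGroups) -> float:
        """Trim `current` from its extreme end until the trend vanishes."""
        alternative = "increasing" if side == "upper" else "decreasing"
        while True:
            res = jt_permutation_p(current, alternative, n_perm=n_perm,
                                   seed=None, rng=rng)
            steps.append(StepRecord(side, current.temps, res))
            if res.p_value >= alpha:
                return max(current.temps) if side == "upper" else min(current.temps)
            drop = max(current.temps) if side == "upper" else min(current.temps)
            keep = [t for t in current.temps if t != drop]
            if len(keep) < 2:
                raise NoTnzDetectedError(
                    f"{side} step-down stayed significant to the last pair; "
                    "no critical temperature inside the design", steps
                )
            current = current.subset(keep)

    upper_set = tg.subset([t for t in temps if t >= t_star])
    if len(upper_set.groups) < 2:
        uct = max(upper_set.temps)
    else:
        uct = run_side("upper", upper_set)
    uct_flag = "boundary-of-design" if uct == max(temps) else "interior"

    lower_set = tg.subset([t for t in temps if t <= uct])
    if len(lower_set.groups) < 2:
        lct = min(lower_set.temps)
    else:
        lct = run_side("lower", lower_set)
    lct_flag = "boundary-of-design" if lct == min(temps) else "interior"

    return TnzEstimate(lct_c=lct, uct_c=uct, lct_flag=lct_flag,
                       uct_flag=uct_flag, steps=steps,
                       min_group_n=min_group_n, alpha=alpha)


def steps_table(steps: list[StepRecord]) -> pd.DataFrame:
    """Step trail as a tidy table (one row per trend test)."""
    return pd.DataFrame(
        {
            "side": [s.side for s in steps],
            "range": [f"{min(s.temps):g}...{max(s.temps):g}" for s in steps],
            "alternative": [s.result.alternative for s in steps],
            "jt": [s.result.statistic for s in steps],
            "p": [s.result.p_value for s in steps],
            "n_perm": [s.result.n_perm for s in steps],
        }
    )
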