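"""Small-sample two-group inference: Hedges' g, exact randomisation tests,
and stratified BCa bootstrap intervals.

Designed for comparisons at n = 4 per group, where parametric t/Welch
inference is fragile. The conventions throughout: group ``x`` is the case
(epic) group, group ``y`` the control group, and every "difference" is
x minus y (epic minus control), so looser gating in cases shows up as a
negative estimate.

* Hedges' g: pooled-SD standardized mean difference times the small-sample
  correction J = 1 - 3 / (4 N - 9).
* Exact randomisation test: enumerate every distinct assignment of the
  pooled values into groups of the observed sizes — C(8, 4) = 70 at
  n = 4/4 — and count assignments whose statistic is at least as extreme
  as the observed one (observed assignment included, so p >= 1/70).
* BCa bootstrap: resampling stratified by group (each group resampled
  independently with replacement); bias correction z0 from the proportion
  of bootstrap statistics below the observed value, acceleration from
  grouped delete-one jackknife influence values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .exceptions import DegenerateSampleError, InvalidConfigError

__all__ = [
    "TwoGroupSample",
    "StatResult",
    "group_mean_difference",
    "hedges_g",
    "exact_randomisation_test",
    "monte_carlo_randomisation_test",
    "bca_bootstrap_ci",
    "two_group_report",
]

Statistic = Callable[[np.ndarray, np.ndarray], float]


@dataclass(frozen=True)
class TwoGroupSample:
    """Finite observations for the case group ``x`` and control group ``y``."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        for name, arr in (("x", self.x), ("y", self.y)):
            if arr.ndim != 1 or arr.size < 2:
                raise InvalidConfigError(f"group {name} needs >= 2 values")
            if not np.all(np.isfinite(arr)):
                raise InvalidConfigError(f"group {name} contains non-finite values")


@dataclass
class StatResult:
    """One estimate with its uncertainty summaries."""

    estimate: float
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")
    p_perm: Optional[float] = None
    n_permutations: int = 0
    n_resamples: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isnan(self.ci_lo) and not np.isnan(self.ci_hi) and self.ci_lo > self.ci_hi:
            raise InvalidConfigError("ci_lo must be <= ci_hi")


def _coerce(x, y=None) -> TwoGroupSample:
    if isinstance(x, TwoGroupSample):
        return x
    return TwoGroupSample(x, y)


def group_mean_difference(x, y=None) -> float:
    """mean(x) - mean(y), case-minus-control orientation."""
    s = _coerce(x, y)
    return float(s.x.mean() - s.y.mean())


def hedges_g(x, y=None) -> float:
    """Small-sample-corrected standardized mean difference.

    d = (mean x - mean y) / s_pooled with the n1 + n2 - 2 denominator;
    g = J * d with J = 1 - 3 / (4 (n1 + n2) - 9).
    """
    s = _coerce(x, y)
    n1, n2 = s.x.size, s.y.size
    sp2 = ((n1 - 1) * s.x.var(ddof=1) + (n2 - 1) * s.y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise DegenerateSampleError("pooled SD is zero; g undefined")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (s.x.mean() - s.y.mean()) / np.sqrt(sp2))


def _p_value(stats_all: np.ndarray, observed: float, alternative: str) -> float:
    tol = 1e-12 * (1.0 + abs(observed))
    if alternative == "two-sided":
        count = int(np.sum(np.abs(stats_all) >= abs(observed) - tol))
    elif alternative == "greater":
        count = int(np.sum(stats_all >= observed - tol))
    elif alternative == "less":
        count = int(np.sum(stats_all <= observed + tol))
    else:
        raise InvalidConfigError("alternative must be two-sided, greater or less")
    return count / stats_all.size


def exact_randomisation_test(
    x,
    y=None,
    statistic: Statistic | None = None,
    alternative: str = "two-sided",
    cap: int = 10**6,
) -> StatResult:
    """Complete enumeration randomisation test.

    Every distinct split of the pooled values into groups of sizes
    (n1, n2) is evaluated once; the two-sided p is the proportion of splits
    with |statistic| >= |observed| (observed split included in the count).
    Raises when C(n1+n2, n1) exceeds ``cap`` — use
    :func:`monte_carlo_randomisation_test` for larger designs.
    """
    s = _coerce(x, y)
    stat = statistic or group_mean_difference
    n1, n = s.x.size, s.x.size + s.y.size
    n_perm = comb(n, n1)
    if n_perm > cap:
        raise InvalidConfigError(
            f"C({n}, {n1}) = {n_perm} exceeds cap {cap}; "
            "use monte_carlo_randomisation_test instead"
        )
    pooled = np.concatenate([s.x, s.y])
    observed = float(stat(s.x, s.y))
    all_idx = frozenset(range(n))
    stats_all = np.empty(n_perm)
    for i, idx in enumerate(combinations(range(n), n1)):
        rest = sorted(all_idx.difference(idx))
        stats_all[i] = stat(pooled[list(idx)], pooled[rest])
    return StatResult(
        estimate=observed,
        p_perm=_p_value(stats_all, observed, alternative),
        n_permutations=n_perm,
    )


def monte_carlo_randomisation_test(
    x,
    y=None,
    statistic: Statistic | None = None,
    alternative: str = "two-sided",
    n_draws: int = 10_000,
    seed: int | None = None,
) -> StatResult:
    """Monte-Carlo approximation of the randomisation test p-value.

    Uses the add-one estimator p = (b + 1) / (n_draws + 1), where b counts
    random relabellings at least as extreme as the observed one.
    """
    s = _coerce(x, y)
    stat = statistic or group_mean_difference
    rng = np.random.default_rng(seed)
    n1, n = s.x.size, s.x.size + s.y.size
    pooled = np.concatenate([s.x, s.y])
    observed = float(stat(s.x, s.y))
    draws = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(n)
        draws[i] = stat(pooled[perm[:n1]], pooled[perm[n1:]])
    count = _p_value(draws, observed, alternative) * n_draws
    return StatResult(
        estimate=observed,
        p_perm=(count + 1.0) / (n_draws + 1.0),
        n_permutations=n_draws,
        seed=seed,
    )


def _adjusted_quantiles(
    thetas: np.ndarray, z0: float, a: float, level: float
) -> tuple[float, float]:
    """BCa endpoint percentiles. With z0 = 0 and a = 0 this reduces to the
    plain percentile interval."""
    out = []
    for q in ((1 - level) / 2, 1 - (1 - level) / 2):
        z = ndtri(q)
        denom = 1.0 - a * (z0 + z)
        adj = ndtr(z0 + (z0 + z) / denom) if denom > 0 else 1.0
        out.append(float(np.quantile(thetas, np.clip(adj, 0.0, 1.0))))
    return min(out), max(out)


def bca_bootstrap_ci(
    x,
    y=None,
    statistic: Statistic | None = None,
    n_resamples: int = 20_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified bias-corrected and accelerated bootstrap interval.

    Groups are resampled independently with replacement (stratified by
    group); z0 comes from the proportion of bootstrap statistics below the
    observed value (ties counted half) and the acceleration from the
    skewness of grouped delete-one jackknife influence values. Reproducible
    given ``seed``.
    """
    s = _coerce(x, y)
    stat = statistic or group_mean_difference
    if not 0 < level < 1:
        raise InvalidConfigError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n1, n2 = s.x.size, s.y.size
    idx1 = rng.integers(0, n1, size=(n_resamples, n1))
    idx2 = rng.integers(0, n2, size=(n_resamples, n2))
    thetas = np.empty(n_resamples)
    for b in range(n_resamples):
        thetas[b] = stat(s.x[idx1[b]], s.y[idx2[b]])
    observed = float(stat(s.x, s.y))
    if np.ptp(thetas) == 0:
        warnings.warn("all bootstrap statistics identical; degenerate interval", stacklevel=2)
        return float(thetas[0]), float(thetas[0])
    prop = (np.sum(thetas < observed) + 0.5 * np.sum(thetas == observed)) / n_resamples
    prop = float(np.clip(prop, 0.5 / n_resamples, 1.0 - 0.5 / n_resamples))
    z0 = float(ndtri(prop))
    jack = np.array(
        [stat(np.delete(s.x, i), s.y) for i in range(n1)]
        + [stat(s.x, np.delete(s.y, j)) for j in range(n2)]
    )
    u = jack.mean() - jack
    denom = np.sum(u**2) ** 1.5
    a = float(np.sum(u**3) / (6.0 * denom)) if denom > 0 else 0.0
    return _adjusted_quantiles(thetas, z0, a, level)


def two_group_report(
    x,
    y=None,
    n_resamples: int = 20_000,
    level: float = 0.95,
    seed: int | None = None,
    decimals: int | None = 3,
) -> dict:
    """The full descriptive report for one metric: Hedges' g, the mean
    difference (case - control) with its stratified BCa interval, and the
    exact randomisation p on the mean-difference statistic.

    ``decimals`` rounds the reported effect sizes (None = full precision).
    """
    s = _coerce(x, y)
    g = hedges_g(s)
    md = group_mean_difference(s)
    lo, hi = bca_bootstrap_ci(s, n_resamples=n_resamples, level=level, seed=seed)
    perm = exact_randomisation_test(s)
    rnd = (lambda v: v) if decimals is None else (lambda v: round(float(v), decimals))
    return {
        "hedges_g": rnd(g),
        "mean_difference": rnd(md),
        "ci_lo": rnd(lo),
        "ci_hi": rnd(hi),
        "ci_level": level,
        "p_perm": perm.p_perm,
        "n_permutations": perm.n_permutations,
        "n_resamples": n_resamples,
        "seed": seed,
        "n_x": int(s.x.size),
        "n_y": int(s.y.size),
    }
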