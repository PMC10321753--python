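"""Rank-based statistics kernel.

Every screening stage in this package reduces to a handful of nonparametric
primitives: average ranks, rank percentiles, Spearman correlation, the
two-sample Wilcoxon rank-sum test, Benjamini-Hochberg FDR control, the
Kaplan-Meier product-limit estimator, and the two-group log-rank
(Mantel-Cox) test.  They are implemented here from first principles so that
tie handling and p-value conventions are explicit and identical across
stages.  SciPy is used only for distribution tail probabilities, never for
the statistics themselves.

Conventions
-----------
* Ties always receive average ranks (the mean of the integer ranks the tied
  block spans).  This choice propagates into rank percentiles, Spearman
  correlation, and the rank-sum test.
* All p-values are two-sided unless stated otherwise.
* At tied survival times, deaths are processed before censorings: a subject
  censored at an event time is still in the risk set at that time.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _dists

from .exceptions import DegenerateStatisticsWarning

__all__ = [
    "average_ranks",
    "rank_percentile",
    "spearman",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "km_curve",
    "logrank",
    "KMCurve",
    "LogRankResult",
]

_TIE_EPS = 1e-12  # float guard when counting permutations at least as extreme


def _as_1d_finite(values, name: str = "values") -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def average_ranks(values) -> np.ndarray:
    """Ranks 1..n with ties averaged.

    The sum of the returned ranks is always n(n+1)/2.
    """
    a = _as_1d_finite(values)
    n = a.size
    order = np.argsort(a, kind="mergesort")
    sa = a[order]
    new_block = np.r_[True, sa[1:] != sa[:-1]]
    block_id = np.cumsum(new_block) - 1
    starts = np.flatnonzero(new_block)          # 0-based first index of each tie block
    ends = np.r_[starts[1:], n]                 # exclusive end of each block
    block_avg = (starts + ends + 1) / 2.0       # mean of 1-based ranks start+1 .. end
    ranks = np.empty(n)
    ranks[order] = block_avg[block_id]
    return ranks


def rank_percentile(values) -> np.ndarray:
    """Average rank divided by n; values lie in (0, 1].

    Invariant under any strictly increasing transform of the input, since it
    depends on the data only through the ordering (with ties preserved).
    """
    a = _as_1d_finite(values)
    return average_ranks(a) / a.size


def spearman(x, y, p_method: str = "t_approx", exact_cap: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of the two average-rank vectors.
    ``p_method``:

    * ``"t_approx"`` -- t = rho * sqrt((n-2)/(1-rho^2)) referred to a
      t-distribution with n-2 degrees of freedom (the usual large-sample
      approximation).
    * ``"exact_permutation"`` -- enumerate all n! pairings of y against x and
      count those with |rho| at least as large as observed.  Refused for
      n > ``exact_cap`` (factorial blow-up).
    """
    xa = _as_1d_finite(x, "x")
    ya = _as_1d_finite(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(xa).size < 2 or np.unique(ya).size < 2:
        raise ValueError("constant input: correlation undefined")

    cx = average_ranks(xa)
    cy = average_ranks(ya)
    cx -= cx.mean()
    cy -= cy.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    dot = float(cx @ cy)
    rho = float(np.clip(dot / denom, -1.0, 1.0))

    if p_method == "t_approx":
        if 1.0 - rho * rho <= 0.0:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(_dists.t.sf(abs(t), n - 2))
    elif p_method == "exact_permutation":
        if n > exact_cap:
            raise ValueError(
                f"exact permutation p refused for n={n} > cap={exact_cap}"
            )
        perms = np.array(list(itertools.permutations(range(n))))
        dots = cy[perms] @ cx  # one rank-dot-product per pairing
        hits = int(np.sum(np.abs(dots) >= abs(dot) - _TIE_EPS))
        p = hits / math.factorial(n)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return rho, min(p, 1.0)


def wilcoxon_rank_sum(a, b, exact_limit: int = 12) -> tuple[float, float]:
    """Unpaired two-sample Wilcoxon rank-sum test (Mann-Whitney form).

    Returns (W, p) where W is the sum of pooled average ranks in ``a``.
    For pooled sizes n_a + n_b <= ``exact_limit`` the two-sided p is computed
    by exact enumeration of all C(N, n_a) group assignments (with the
    observed tie pattern); otherwise a normal approximation with tie
    correction is used (no continuity correction).
    """
    aa = _as_1d_finite(a, "a")
    bb = _as_1d_finite(b, "b")
    na, nb = aa.size, bb.size
    N = na + nb
    pooled = np.concatenate([aa, bb])
    r = average_ranks(pooled)
    W = float(r[:na].sum())
    mu = na * (N + 1) / 2.0

    if N <= exact_limit:
        dev = abs(W - mu) - _TIE_EPS
        hits = total = 0
        for combo in itertools.combinations(range(N), na):
            total += 1
            if abs(r[list(combo)].sum() - mu) >= dev:
                hits += 1
        p = hits / total
    else:
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts)) / (N * (N - 1))
        var = na * nb / 12.0 * ((N + 1) - tie_term)
        if var <= 0.0:
            warnings.warn(
                "all pooled observations tied; rank-sum p set to 1",
                DegenerateStatisticsWarning,
                stacklevel=2,
            )
            return W, 1.0
        z = (W - mu) / math.sqrt(var)
        p = 2.0 * float(_dists.norm.sf(abs(z)))
    return W, min(p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Output is in the original order; along the sorted raw order the adjusted
    values are monotone nondecreasing and never smaller than the raw values.
    """
    pa = np.asarray(p, dtype=float).ravel()
    if pa.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(pa)) or np.any(pa < 0.0) or np.any(pa > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    m = pa.size
    order = np.argsort(pa, kind="mergesort")
    scaled = pa[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    # p*m/rank can round a hair below p at the top rank; the adjustment is
    # mathematically never smaller than the raw value
    return np.maximum(out, pa)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""

    event_times: np.ndarray  # ordered distinct times with >= 1 death
    survival: np.ndarray     # S(t) immediately after each event time
    at_risk: np.ndarray      # risk-set size at each event time
    events: np.ndarray       # deaths at each event time

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, or NaN if never reached."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.event_times[below[0]]) if below.size else math.nan

    def restricted_mean(self, tau: float) -> float:
        """Area under the step function S on [0, tau]."""
        area = 0.0
        prev_t, prev_s = 0.0, 1.0
        for t, s in zip(self.event_times, self.survival):
            if t >= tau:
                break
            area += prev_s * (t - prev_t)
            prev_t, prev_s = float(t), float(s)
        area += prev_s * (tau - prev_t)
        return area


def _validate_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = _as_1d_finite(time, "time")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    e = np.asarray(event).ravel()
    if e.size != t.size:
        raise ValueError("time and event must have equal length")
    ef = e.astype(float)
    if not np.all(np.isin(ef, (0.0, 1.0))):
        raise ValueError("event flags must be 0 or 1")
    return t, ef.astype(int)


def km_curve(time, event) -> KMCurve:
    """Product-limit survival estimate.

    Subjects censored at an event time remain in the risk set at that time
    (deaths precede censorings at ties).  With no censoring the estimate
    equals 1 minus the empirical CDF of the times.
    """
    t, e = _validate_time_event(time, event)
    etimes = np.unique(t[e == 1])
    surv = np.empty(etimes.size)
    at_risk = np.empty(etimes.size, dtype=int)
    deaths = np.empty(etimes.size, dtype=int)
    s = 1.0
    for i, te in enumerate(etimes):
        n = int(np.sum(t >= te))
        d = int(np.sum((t == te) & (e == 1)))
        s *= 1.0 - d / n
        surv[i] = s
        at_risk[i] = n
        deaths[i] = d
    return KMCurve(event_times=etimes, survival=surv, at_risk=at_risk, events=deaths)


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank (Mantel-Cox) test.

    ``observed``/``expected`` refer to deaths in the reference group (the
    first group label in sorted order); ``direction`` names the group with
    the survival deficit (more deaths than expected), or None when O = E.
    """

    observed: float
    expected: float
    variance: float
    chi2: float
    p: float
    direction: object
    reference: object


def logrank(time, event, group) -> LogRankResult:
    """Log-rank test from per-event-time hypergeometric contributions.

    At each distinct event time the expectation and variance of
    reference-group deaths are accumulated; chi2 = (O - E)^2 / V with a
    1-df chi-square reference.  Zero total variance (no informative event
    time) yields chi2 = 0 and p = 1 with a `DegenerateStatisticsWarning`.
    """
    t, e = _validate_time_event(time, event)
    g = np.asarray(group).ravel()
    if g.size != t.size:
        raise ValueError("group labels must match time/event length")
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"exactly two groups required, got {labels.size}")
    ref = labels[0]
    in_ref = g == ref
    if e.sum() == 0:
        raise ValueError("at least one event is required")

    O = E = V = 0.0
    for te in np.unique(t[e == 1]):
        at_risk = t >= te
        n = int(at_risk.sum())
        n1 = int((at_risk & in_ref).sum())
        d = int(np.sum((t == te) & (e == 1)))
        d1 = int(np.sum((t == te) & (e == 1) & in_ref))
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)

    if V <= 0.0:
        warnings.warn(
            "log-rank variance is zero (no informative event time); p set to 1",
            DegenerateStatisticsWarning,
            stacklevel=2,
        )
        return LogRankResult(O, E, V, 0.0, 1.0, None, ref)

    chi2 = (O - E) ** 2 / V
    p = float(_dists.chi2.sf(chi2, 1))
    p = min(max(p, 5e-324), 1.0)  # keep p in (0, 1]
    if O > E:
        direction = ref
    elif O < E:
        direction = labels[1]
    else:
        direction = None
    return LogRankResult(O, E, V, chi2, p, direction, ref)
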