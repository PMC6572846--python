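"""Skyline reconstruction of historical effective population size.

Given a timed genealogy, the coalescent likelihood of a piecewise-constant
size history over the inter-coalescent intervals (k lineages, length w) is

    L = prod_groups N_g^-m_g * exp(-A_g / N_g),
    A_g = sum_{j in g} k_j (k_j - 1) w_j / 2,

with m_g coalescences per group.  Three estimators share this skeleton:

* ``classical_skyline`` — one group per interval, N-hat = k(k-1)w/2, the
  method-of-moments estimator under E[w] = 2N/(k(k-1)).
* ``generalized_skyline`` — adjacent intervals pooled by a length threshold
  epsilon (small, noisy intervals merge with their successors); epsilon is
  chosen by small-sample AIC over a grid, counting both the group sizes and
  the group boundaries as parameters.
* ``bayesian_skyline`` — fixed-genealogy MCMC over contiguous interval
  groupings and per-group sizes (uniform prior on log N and on boundary
  compositions), with Metropolis-within-Gibbs updates, posterior median and
  95% HPD bands, and an effective-sample-size convergence requirement.

When the genealogy is calibrated in years the size unit is Ne x generation
time (years); the detection rule uses only relative changes, so units
cancel there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genealogy import CoalescentInterval, Genealogy

__all__ = [
    "ClockModel",
    "clock_rate",
    "calibrate_tree",
    "coalescent_intervals",
    "SkylineEstimate",
    "classical_skyline",
    "generalized_skyline",
    "bayesian_skyline",
    "MCMCTrace",
    "ess",
    "DetectionRule",
    "detect_change",
    "constant_size_mle",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when an MCMC chain fails its ESS target."""


# ---------------------------------------------------------------------------
# clock calibration
# ---------------------------------------------------------------------------


def clock_rate(mu: float, reliable_sites: float, n_snps: int) -> float:
    """Per-SNP-column substitution rate per year.

    A per-site rate ``mu`` over ``reliable_sites`` callable bases implies
    ``mu * reliable_sites`` substitutions per year genome-wide; dividing by
    the number of observed SNP columns converts to the per-column rate that
    calibrates p-distance trees built on SNPs only.
    """
    if mu <= 0 or reliable_sites <= 0:
        raise ValueError("mu and reliable_sites must be positive")
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    return mu * reliable_sites / n_snps


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock for SNP-column trees."""

    mu: float = 0.74e-9
    reliable_sites: float = 14_494_268
    n_snps: int = 28_254

    @property
    def per_column_rate(self) -> float:
        return clock_rate(self.mu, self.reliable_sites, self.n_snps)


def calibrate_tree(tree: Genealogy, clock: ClockModel | float) -> Genealogy:
    """Rescale an ultrametric tree with heights in p-distance to years.

    ``clock`` is a :class:`ClockModel` or a per-column rate per year; node
    time in years is height divided by the rate.
    """
    rate = clock.per_column_rate if isinstance(clock, ClockModel) else float(clock)
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    if tree.tmrca <= 0:
        raise ValueError("degenerate zero-height tree cannot be calibrated")
    return tree.scale_times(1.0 / rate)


def coalescent_intervals(gen: Genealogy) -> list[CoalescentInterval]:
    """Inter-coalescent intervals (k, w) from n lineages down to 2."""
    return gen.coalescent_intervals()


# ---------------------------------------------------------------------------
# skyline estimates
# ---------------------------------------------------------------------------


@dataclass
class SkylineEstimate:
    """Stepwise size trajectory: ``point[i]`` applies on
    ``(times[i], times[i+1])``; optional lower/upper credible bands."""

    times: np.ndarray  # length m+1, starting at 0
    point: np.ndarray  # length m
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    estimator: str = ""
    n_groups: int | None = None

    @property
    def span(self) -> float:
        return float(self.times[-1])

    def at(self, t: float) -> float:
        if not 0 <= t <= self.span:
            raise ValueError("time outside the estimate's span")
        i = int(np.clip(np.searchsorted(self.times, t, side="right") - 1, 0,
                        len(self.point) - 1))
        return float(self.point[i])

    def window_mean(self, lo: float, hi: float) -> float:
        """Time-weighted mean of the point estimate over [lo, hi].

        Zero-length steps carry no weight, so flagged degenerate intervals
        are excluded automatically.
        """
        if lo < 0 or hi > self.span or hi <= lo:
            raise ValueError(
                f"window [{lo}, {hi}] outside the estimate's span [0, {self.span}]"
            )
        total = 0.0
        weight = 0.0
        for i, n_hat in enumerate(self.point):
            a, b = self.times[i], self.times[i + 1]
            o = min(b, hi) - max(a, lo)
            if o > 0:
                total += o * n_hat
                weight += o
        if weight <= 0:
            raise ValueError("window has zero overlap with the estimate")
        return total / weight

    def to_frame(self):
        import pandas as pd

        d = {"time_start": self.times[:-1], "time_end": self.times[1:],
             "point": self.point}
        if self.lower is not None:
            d["lower"] = self.lower
            d["upper"] = self.upper
        return pd.DataFrame(d)


def _interval_arrays(
    intervals: list[CoalescentInterval],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ks = np.array([iv.k for iv in intervals], dtype=float)
    ws = np.array([iv.length for iv in intervals], dtype=float)
    if (ws < 0).any():
        raise ValueError("negative interval length")
    a = ks * (ks - 1.0) / 2.0 * ws
    return ks, ws, a


def classical_skyline(intervals: list[CoalescentInterval]) -> SkylineEstimate:
    """Per-interval moment estimator N-hat = k(k-1) w / 2.

    Zero-length intervals get N-hat = 0 (flagged degenerate; they carry no
    weight in window means).
    """
    if not intervals:
        raise ValueError("need at least one interval")
    ks, ws, a = _interval_arrays(intervals)
    times = np.concatenate([[0.0], np.cumsum(ws)])
    return SkylineEstimate(times, a.copy(), estimator="classical",
                           n_groups=len(intervals))


def constant_size_mle(intervals: list[CoalescentInterval]) -> float:
    """Maximum-likelihood constant size: sum k(k-1)w/2 over coalescences."""
    _, _, a = _interval_arrays(intervals)
    return float(a.sum() / len(a))


def _epsilon_groups(ws: np.ndarray, eps: float) -> list[tuple[int, int]]:
    """Contiguous groups: accumulate intervals until the pooled length
    reaches eps; a trailing remainder joins the last group."""
    segs: list[tuple[int, int]] = []
    start, acc = 0, 0.0
    for j, w in enumerate(ws):
        acc += w
        if acc >= eps:
            segs.append((start, j + 1))
            start, acc = j + 1, 0.0
    if start < len(ws):
        if segs:
            s, _ = segs.pop()
            segs.append((s, len(ws)))
        else:
            segs.append((0, len(ws)))
    return segs


def _group_loglik(cum_a: np.ndarray, a: int, b: int) -> float:
    A = cum_a[b] - cum_a[a]
    m = b - a
    if A <= 0:
        return -np.inf
    return -m * np.log(A / m) - m


def generalized_skyline(
    intervals: list[CoalescentInterval],
    n_eps: int = 60,
    max_groups: int | None = None,
) -> SkylineEstimate:
    """Epsilon-pooled skyline with AICc model selection.

    Candidate epsilons span a log grid from the shortest interval to the
    TMRCA (plus 0, the classical limit); for each, adjacent intervals are
    pooled and the piecewise-constant coalescent AICc computed with
    ``p = 2g - 1`` parameters (g sizes + g-1 boundaries).  The minimal-AICc
    grouping wins.
    """
    if len(intervals) < 2:
        raise ValueError("need at least two intervals")
    ks, ws, a = _interval_arrays(intervals)
    n_int = len(ws)
    cum_a = np.concatenate([[0.0], np.cumsum(a)])
    positive = ws[ws > 0]
    if positive.size == 0:
        raise ValueError("all intervals have zero length")
    total = ws.sum()
    grid = np.geomspace(max(positive.min(), total * 1e-6), total, n_eps)
    candidates = np.unique(np.concatenate([[0.0], grid]))
    best = (np.inf, None)
    for eps in candidates:
        segs = _epsilon_groups(ws, eps)
        g = len(segs)
        if max_groups is not None and g > max_groups:
            continue
        p = 2 * g - 1
        if n_int - p - 1 <= 0:
            continue
        ll = sum(_group_loglik(cum_a, s, e) for s, e in segs)
        if not np.isfinite(ll):
            continue
        aicc = 2 * p - 2 * ll + 2 * p * (p + 1) / (n_int - p - 1)
        if aicc < best[0]:
            best = (aicc, segs)
    if best[1] is None:
        raise ValueError("no admissible grouping found")
    segs = best[1]
    bounds = np.concatenate([[0.0], np.cumsum(ws)])
    times = [0.0]
    point = []
    for s, e in segs:
        A = cum_a[e] - cum_a[s]
        point.append(A / (e - s))
        times.append(bounds[e])
    return SkylineEstimate(
        np.array(times), np.array(point), estimator="generalized",
        n_groups=len(segs),
    )


# ---------------------------------------------------------------------------
# effective sample size
# ---------------------------------------------------------------------------


def ess(values: np.ndarray) -> float:
    """Effective sample size ``n / (1 + 2 sum rho_t)`` with Geyer's
    initial-positive-sequence truncation of the autocorrelations.

    A constant trace has undefined autocorrelation and returns 0 with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        warnings.warn("constant trace: ESS undefined, reporting 0",
                      ConvergenceWarning, stacklevel=2)
        return 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    rho = acf / acf[0]
    # Geyer: sum consecutive pairs, truncate at the first negative pair sum
    tau = 0.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma < 0:
            break
        tau += 2.0 * gamma
        m += 1
    tau -= 1.0  # rho_0 counted twice in the pair sums
    tau = max(tau, 1.0)
    return float(n / tau)


# ---------------------------------------------------------------------------
# Bayesian skyline (fixed genealogy)
# ---------------------------------------------------------------------------


@dataclass
class MCMCTrace:
    """Retained MCMC samples for the fixed-genealogy skyline."""

    sizes: np.ndarray  # (n_kept, n_groups)
    boundaries: np.ndarray  # (n_kept, n_groups - 1) interval split points
    loglik: np.ndarray
    ess_per_parameter: np.ndarray
    converged: bool
    chain_length: int
    burn_in: int
    thin: int
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def min_ess(self) -> float:
        return float(self.ess_per_parameter.min())


def _skyline_loglik(m: np.ndarray, A: np.ndarray, N: np.ndarray) -> float:
    return float(np.sum(-m * np.log(N) - A / N))


def _merge_zero_intervals(
    ks: np.ndarray, ws: np.ndarray, a: np.ndarray, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse zero-length intervals (tied coalescence times) into the
    preceding positive interval, which then ends in several coalescences.

    Returns ``(m_j, w_j, A_j)`` with every ``w_j > 0`` and ``sum m_j = n-1``,
    so any contiguous group has positive likelihood weight ``A``.
    """
    thresh = tol * ws.sum()
    m_out: list[int] = []
    w_out: list[float] = []
    a_out: list[float] = []
    for j in range(len(ws)):
        if w_out and ws[j] <= thresh:
            m_out[-1] += 1
            w_out[-1] += ws[j]
            a_out[-1] += a[j]
        else:
            m_out.append(1)
            w_out.append(ws[j])
            a_out.append(a[j])
    # a leading zero-length run merges forward into the first positive one
    while len(w_out) > 1 and w_out[0] <= thresh:
        m_out[1] += m_out[0]
        w_out[1] += w_out[0]
        a_out[1] += a_out[0]
        del m_out[0], w_out[0], a_out[0]
    return (np.array(m_out, dtype=float), np.array(w_out), np.array(a_out))


def bayesian_skyline(
    gen: Genealogy,
    n_groups: int = 10,
    chain_length: int = 30_000,
    burn_in: float = 0.1,
    seed: int = 0,
    target_ess: float = 200.0,
    max_doublings: int = 4,
    thin: int = 10,
    n_grid: int = 100,
) -> tuple[SkylineEstimate, MCMCTrace]:
    """MCMC skyline on a fixed timed genealogy.

    The n-1 coalescent intervals are partitioned into ``n_groups``
    contiguous, non-empty groups; each group has one size parameter with a
    uniform prior on log N, and the boundary composition has a uniform
    prior.  Updates alternate random-walk proposals on each log N (scale
    adapted to 20-40% acceptance during burn-in) with +/-1 boundary shifts.
    The chain doubles in length until the minimum parameter ESS reaches
    ``target_ess`` or ``max_doublings`` is exhausted; failure to converge
    sets ``trace.converged = False`` and emits a :class:`ConvergenceWarning`.

    Returns the estimate (posterior median and 95% HPD per time-grid cell)
    and the trace.
    """
    intervals = gen.coalescent_intervals()
    if n_groups < 1 or n_groups > len(intervals):
        raise ValueError("need 1 <= n_groups <= n - 1")
    ks, ws, a = _interval_arrays(intervals)
    # tied coalescence times (zero-length intervals) are merged into
    # multi-coalescence events so every group has positive weight A
    m_arr, w_arr, a_arr = _merge_zero_intervals(ks, ws, a, tol=1e-12)
    n_int = len(w_arr)
    n_groups = min(n_groups, n_int)
    cum_a = np.concatenate([[0.0], np.cumsum(a_arr)])
    cum_m = np.concatenate([[0.0], np.cumsum(m_arr)])
    bounds_t = np.concatenate([[0.0], np.cumsum(w_arr)])
    rng = np.random.default_rng(seed)

    # state: edges[0]=0 < edges[1] < ... < edges[g]=n_int; logN per group
    edges = np.round(np.linspace(0, n_int, n_groups + 1)).astype(int)
    edges = np.unique(edges)
    while edges.size < n_groups + 1:  # degenerate rounding at tiny n_int
        for i in range(1, edges.size):
            if edges[i] - edges[i - 1] > 1:
                edges = np.sort(np.append(edges, edges[i - 1] + 1))
                break
    group_m = cum_m[edges[1:]] - cum_m[edges[:-1]]
    group_A = cum_a[edges[1:]] - cum_a[edges[:-1]]
    logN = np.log(group_A / group_m)
    # proper (very wide) uniform prior on log N, centred on the data scale
    centre = np.log(cum_a[-1] / cum_m[-1])
    log_lo, log_hi = centre - 40.0, centre + 40.0
    step = np.full(n_groups, 0.8)

    def total_ll() -> float:
        return _skyline_loglik(group_m, group_A, np.exp(logN))

    ll = total_ll()
    kept_sizes: list[np.ndarray] = []
    kept_edges: list[np.ndarray] = []
    kept_ll: list[float] = []
    acc_size = np.zeros(n_groups)
    prop_size = np.zeros(n_groups)
    acc_edge = 0
    prop_edge = 0

    n_burn = int(burn_in * chain_length)
    total_iter = 0
    target_iter = chain_length
    doublings = 0
    while True:
        while total_iter < target_iter:
            total_iter += 1
            adapting = total_iter <= n_burn
            # size updates
            for gidx in range(n_groups):
                prop_size[gidx] += 1
                new = logN[gidx] + step[gidx] * rng.normal()
                if not log_lo <= new <= log_hi:
                    continue  # outside the prior's support
                Ng = np.exp(logN[gidx])
                Nn = np.exp(new)
                dll = (-group_m[gidx] * (new - logN[gidx])
                       - group_A[gidx] / Nn + group_A[gidx] / Ng)
                if np.log(rng.random()) < dll:
                    logN[gidx] = new
                    ll += dll
                    acc_size[gidx] += 1
                if adapting and prop_size[gidx] % 50 == 0:
                    rate = acc_size[gidx] / prop_size[gidx]
                    if rate < 0.20:
                        step[gidx] *= 0.8
                    elif rate > 0.40:
                        step[gidx] *= 1.25
            # boundary updates: reposition each internal boundary
            # uniformly between its neighbours (symmetric proposal)
            for bidx in (range(1, n_groups) if n_groups > 1 else ()):
                prop_edge += 1
                new_edge = int(rng.integers(edges[bidx - 1] + 1,
                                            edges[bidx + 1]))
                if new_edge != edges[bidx]:
                    mL_new = cum_m[new_edge] - cum_m[edges[bidx - 1]]
                    mR_new = cum_m[edges[bidx + 1]] - cum_m[new_edge]
                    AL_new = cum_a[new_edge] - cum_a[edges[bidx - 1]]
                    AR_new = cum_a[edges[bidx + 1]] - cum_a[new_edge]
                    NL, NR = np.exp(logN[bidx - 1]), np.exp(logN[bidx])
                    ll_old = (-group_m[bidx - 1] * logN[bidx - 1]
                              - group_A[bidx - 1] / NL
                              - group_m[bidx] * logN[bidx]
                              - group_A[bidx] / NR)
                    ll_new = (-mL_new * logN[bidx - 1] - AL_new / NL
                              - mR_new * logN[bidx] - AR_new / NR)
                    if np.log(rng.random()) < ll_new - ll_old:
                        edges[bidx] = new_edge
                        group_m[bidx - 1], group_m[bidx] = mL_new, mR_new
                        group_A[bidx - 1], group_A[bidx] = AL_new, AR_new
                        ll += ll_new - ll_old
                        acc_edge += 1
            if total_iter > n_burn and total_iter % thin == 0:
                kept_sizes.append(np.exp(logN.copy()))
                kept_edges.append(edges[1:-1].copy())
                kept_ll.append(ll)
        sizes_arr = np.asarray(kept_sizes)
        ess_vals = np.array([ess(sizes_arr[:, g]) for g in range(n_groups)])
        if ess_vals.min() >= target_ess or doublings >= max_doublings:
            break
        doublings += 1
        target_iter *= 2
    converged = bool(ess_vals.min() >= target_ess)
    if not converged:
        warnings.warn(
            f"minimum ESS {ess_vals.min():.1f} below target {target_ess} "
            f"after {total_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    edges_arr = np.asarray(kept_edges).reshape(len(kept_sizes), -1)
    trace = MCMCTrace(
        sizes=sizes_arr,
        boundaries=edges_arr,
        loglik=np.asarray(kept_ll),
        ess_per_parameter=ess_vals,
        converged=converged,
        chain_length=total_iter,
        burn_in=n_burn,
        thin=thin,
        acceptance={
            "size": float(acc_size.sum() / max(prop_size.sum(), 1)),
            "boundary": float(acc_edge / max(prop_edge, 1)),
        },
    )
    # summarise on a regular time grid
    grid = np.linspace(0.0, bounds_t[-1], n_grid + 1)
    mids = (grid[:-1] + grid[1:]) / 2.0
    # interval index per grid midpoint
    iv_idx = np.clip(np.searchsorted(bounds_t, mids, side="right") - 1, 0,
                     n_int - 1)
    point = np.empty(n_grid)
    lower = np.empty(n_grid)
    upper = np.empty(n_grid)
    full_edges = np.empty((len(kept_sizes), n_groups + 1), dtype=int)
    full_edges[:, 0] = 0
    full_edges[:, -1] = n_int
    if n_groups > 1:
        full_edges[:, 1:-1] = edges_arr
    for j in range(n_grid):
        gidx = (full_edges[:, 1:] <= iv_idx[j]).sum(axis=1)
        gidx = np.clip(gidx, 0, n_groups - 1)
        vals = sizes_arr[np.arange(len(kept_sizes)), gidx]
        point[j] = np.median(vals)
        lower[j], upper[j] = _hpd(vals, 0.95)
    est = SkylineEstimate(grid, point, lower, upper, estimator="bayesian",
                          n_groups=n_groups)
    return est, trace


def _hpd(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sorted samples."""
    x = np.sort(samples)
    n = x.size
    m = max(int(np.ceil(mass * n)), 2)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# detection rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionRule:
    """Decrease-then-recovery test on a skyline trajectory.

    Windows are (lo, hi) in the trajectory's time unit (years before
    present here), ordered post < bottleneck < pre going back in time; the
    rule fires when the bottleneck-window mean is below the pre-window mean
    by at least a factor ``fold`` AND the post-window mean is above the
    bottleneck mean by at least ``fold``.  Defaults bracket a bottleneck at
    3,000 YBP followed by recovery at 2,000 YBP, with guard gaps.
    """

    post: tuple[float, float] = (0.0, 1_800.0)
    bottleneck: tuple[float, float] = (2_100.0, 2_900.0)
    pre: tuple[float, float] = (3_500.0, 10_000.0)
    fold: float = 2.0

    def __post_init__(self) -> None:
        if self.fold <= 1.0:
            raise ValueError("fold threshold must exceed 1")
        windows = [self.post, self.bottleneck, self.pre]
        for lo, hi in windows:
            if hi <= lo or lo < 0:
                raise ValueError("each window needs 0 <= lo < hi")
        if not (self.post[1] <= self.bottleneck[0]
                and self.bottleneck[1] <= self.pre[0]):
            raise ValueError("windows must be disjoint and ordered")


def detect_change(est: SkylineEstimate, rule: DetectionRule) -> bool:
    """Apply ``rule`` to ``est``; windows must lie within the estimate."""
    pre = est.window_mean(*rule.pre)
    bottleneck = est.window_mean(*rule.bottleneck)
    post = est.window_mean(*rule.post)
    return bool(bottleneck < pre / rule.fold and post > bottleneck * rule.fold)
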