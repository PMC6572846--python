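"""Monte Carlo estimation of ancestral clade frequencies under two-way
admixture.

The model: the modern mainland Japanese population is an admixture of an
indigenous source (the Jomon, unknown clade frequencies ``x``) and a
continental source (the Yayoi immigrants, proxied by observed Korean
frequencies ``z``), with admixture proportion ``alpha`` on the indigenous
side, so the admixed frequencies are ``w = alpha*x + (1-alpha)*z``.  Candidate
``x`` vectors are drawn by normalising seven iid Uniform(0,1) numbers —
note: this is the normalised-uniform scheme, *not* a flat Dirichlet — and
scored against the observed mainland Japanese frequencies ``y`` with the
similarity index

    SI = sum_i |w_i - y_i| / (w_i + y_i),

smaller being more similar.  Out of ``n_iter`` draws the ``top_k`` smallest
SI vectors are retained and averaged per clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "AdmixtureConfig",
    "MCResult",
    "draw_jomon_freqs",
    "admix",
    "similarity_index",
    "run_mc",
    "min_si_search",
    "si_independent_lower_bound",
]

DEFAULT_ALPHA = 0.12


@dataclass(frozen=True)
class AdmixtureConfig:
    """Settings for :func:`run_mc`."""

    alpha: float = DEFAULT_ALPHA
    n_iter: int = 10**8
    top_k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.top_k < 1 or self.n_iter < self.top_k:
            raise ValueError("need n_iter >= top_k >= 1")


@dataclass
class MCResult:
    """Retained low-SI candidate vectors and their summary.

    ``top_freqs`` has shape ``(top_k, 7)`` sorted by ascending SI (ties
    broken by earlier iteration index); ``si_threshold`` is the SI of the
    last retained set.
    """

    top_freqs: np.ndarray
    si_values: np.ndarray
    iteration_index: np.ndarray
    mean_freqs: np.ndarray = field(init=False)
    si_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_freqs = self.top_freqs.mean(axis=0)
        self.si_threshold = float(self.si_values[-1])

    def to_dict(self) -> dict:
        return {
            "mean_freqs": self.mean_freqs.tolist(),
            "si_threshold": self.si_threshold,
            "si_values": self.si_values.tolist(),
            "iteration_index": self.iteration_index.tolist(),
            "top_freqs": self.top_freqs.tolist(),
        }


def draw_jomon_freqs(rng: np.random.Generator) -> np.ndarray:
    """One candidate frequency vector: seven iid Uniform(0,1) normalised to
    sum 1.  (A zero sum has probability zero; guarded by redraw.)"""
    while True:
        r = rng.random(7)
        s = r.sum()
        if s > 0:
            return r / s


def admix(x: np.ndarray, z: np.ndarray, alpha: float) -> np.ndarray:
    """Admixed frequencies ``w = alpha*x + (1-alpha)*z`` (elementwise)."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("frequency vectors must have matching length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * x + (1.0 - alpha) * z


def similarity_index(w: np.ndarray, y: np.ndarray) -> float:
    """``SI = sum |w_i - y_i|/(w_i + y_i)``; a 0/0 term contributes 0."""
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    if w.shape != y.shape:
        raise ValueError("frequency vectors must have matching length")
    if (w < 0).any() or (y < 0).any():
        raise ValueError("frequencies must be non-negative")
    denom = w + y
    terms = np.zeros_like(denom)
    nz = denom > 0
    terms[nz] = np.abs(w[nz] - y[nz]) / denom[nz]
    return float(terms.sum())


def _si_block(X: np.ndarray, y: np.ndarray, z: np.ndarray, alpha: float) -> np.ndarray:
    W = alpha * X + (1.0 - alpha) * z
    denom = W + y
    with np.errstate(invalid="ignore"):
        T = np.abs(W - y) / denom
    T[denom == 0] = 0.0
    return T.sum(axis=1)


def run_mc(
    y: np.ndarray,
    z: np.ndarray,
    config: AdmixtureConfig,
    chunk_size: int = 2_000_000,
) -> MCResult:
    """Stream ``n_iter`` candidate draws, keeping the ``top_k`` smallest-SI.

    Draws are generated in chunks but consumed from the RNG stream in
    iteration order, so the result is invariant to ``chunk_size`` for a
    fixed seed.  Memory is bounded by the chunk size.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    k = config.top_k
    rng = np.random.default_rng(config.seed)
    top_si = np.empty(0)
    top_idx = np.empty(0, dtype=np.int64)
    top_x = np.empty((0, 7))
    done = 0
    while done < config.n_iter:
        m = int(min(chunk_size, config.n_iter - done))
        R = rng.random((m, 7))
        sums = R.sum(axis=1)
        zero = sums == 0.0
        while zero.any():  # probability ~0, kept for totality
            R[zero] = rng.random((int(zero.sum()), 7))
            sums = R.sum(axis=1)
            zero = sums == 0.0
        X = R / sums[:, None]
        si = _si_block(X, y, z, config.alpha)
        if m > k:
            # keep every chunk element tied with the k-th smallest so the
            # global lexicographic (SI, iteration) order is exact
            kth = np.partition(si, k - 1)[k - 1]
            sel = np.flatnonzero(si <= kth)
        else:
            sel = np.arange(m)
        si_all = np.concatenate([top_si, si[sel]])
        idx_all = np.concatenate([top_idx, done + sel])
        x_all = np.concatenate([top_x, X[sel]])
        order = np.lexsort((idx_all, si_all))[:k]
        top_si, top_idx, top_x = si_all[order], idx_all[order], x_all[order]
        done += m
    return MCResult(top_x, top_si, top_idx)


def si_independent_lower_bound(y: np.ndarray, z: np.ndarray, alpha: float) -> float:
    """Sum of per-clade SI minima, relaxing the simplex constraint.

    Each term is minimised independently over ``x_i`` in [0, 1]; since each
    term is monotone in ``w_i`` on either side of ``y_i``, the minimum is 0
    when ``y_i`` is attainable and is otherwise met at the nearest endpoint
    of the attainable interval.  This is a certified lower bound for the SI
    of any frequency vector.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    lo = (1.0 - alpha) * z  # w at x_i = 0
    hi = alpha + (1.0 - alpha) * z  # w at x_i = 1
    total = 0.0
    for yi, a, b in zip(y, lo, hi):
        if a <= yi <= b:
            continue
        w = b if yi > b else a
        if w + yi > 0:
            total += abs(w - yi) / (w + yi)
    return total


def min_si_search(
    y: np.ndarray,
    z: np.ndarray,
    alpha: float,
    n_starts: int = 40,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Numerically minimise SI over the 7-simplex.

    Multi-start SLSQP on the simplex (the objective is piecewise-smooth)
    followed by Nelder-Mead refinement in a softmax parameterisation.
    Returns ``(minimum, argmin)``.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)

    def f(x: np.ndarray) -> float:
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if s <= 0:
            return np.inf
        return similarity_index(admix(x / s, z, alpha), y)

    rng = np.random.default_rng(seed)
    starts = [np.full(7, 1 / 7), y / y.sum(), z / z.sum() if z.sum() > 0 else y]
    starts += list(rng.dirichlet(np.ones(7), size=n_starts))
    best_val, best_x = np.inf, None
    cons = {"type": "eq", "fun": lambda x: x.sum() - 1.0}
    for x0 in starts:
        res = optimize.minimize(
            f,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * 7,
            constraints=[cons],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.clip(res.x, 0, None)

    # softmax refinement escapes SLSQP's kink stalls
    def g(u: np.ndarray) -> float:
        e = np.exp(u - u.max())
        return f(e / e.sum())

    u0 = np.log(np.clip(best_x / best_x.sum(), 1e-12, None))
    res = optimize.minimize(g, u0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
    if res.fun < best_val:
        e = np.exp(res.x - res.x.max())
        best_val, best_x = float(res.fun), e / e.sum()
    best_x = best_x / best_x.sum()
    return best_val, best_x
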