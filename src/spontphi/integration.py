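"""Gaussian-approximation measures of integrated information.

A multichannel signal is summarized by a lagged Gaussian model: the joint
normal distribution of the state X at time t-tau ("past") and t ("present").
On that model the module computes, in nats:

* MI   - multi-information (total correlation) of the equal-time covariance,
* MII  - whole-minus-parts predictive mutual information across the lag,
* SI   - stochastic interaction (excess conditional entropy of the parts),
* Phi* - decoder-based integrated information (mismatched-decoding loss,
  maximized over the scalar decoding parameter beta),
* Phi^G - geometric integrated information (minimum KL divergence to the
  manifold of models with no causal influence across the partition).

The minimum information partition (MIP) is found with Queyranne's
symmetric-function minimization over bipartitions, and informational cores
("complexes") with a recursive hierarchical partitioning search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "LaggedGaussianModel",
    "PhiResult",
    "fit_lagged_gaussian",
    "submodel",
    "gaussian_entropy",
    "mutual_info_past_present",
    "multi_information",
    "mii",
    "stochastic_interaction",
    "phi_star",
    "phi_g",
    "MEASURES",
    "evaluate_measure",
    "mip_search",
    "complex_search",
]

RIDGE_LADDER = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)


@dataclass
class LaggedGaussianModel:
    """Equal-time and time-lagged covariances of a stationary Gaussian process.

    cov_x : covariance of the past state X_{t-tau}
    cov_xy : cross covariance, ``cov_xy[i, j] = Cov(X_i(t-tau), X_j(t))``
    cov_y : covariance of the present state X_t
    """

    cov_x: np.ndarray
    cov_xy: np.ndarray
    cov_y: np.ndarray
    tau: int = 1
    ridge: float = 0.0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cov_x = np.asarray(self.cov_x, dtype=float)
        self.cov_xy = np.asarray(self.cov_xy, dtype=float)
        self.cov_y = np.asarray(self.cov_y, dtype=float)
        n = self.cov_x.shape[0]
        for m in (self.cov_x, self.cov_xy, self.cov_y):
            if m.shape != (n, n):
                raise ValueError("covariance blocks must be square and consistent")
        if not np.allclose(self.cov_x, self.cov_x.T):
            raise ValueError("cov_x must be symmetric")

    @property
    def n(self) -> int:
        return self.cov_x.shape[0]

    @property
    def joint(self) -> np.ndarray:
        """Stacked 2n x 2n covariance of (X_{t-tau}, X_t)."""
        return np.block([[self.cov_x, self.cov_xy],
                         [self.cov_xy.T, self.cov_y]])


@dataclass
class PhiResult:
    measure: str
    value: float
    partition: tuple[tuple[int, ...], ...]
    subset: tuple[int, ...] | None = None


def _is_posdef(m: np.ndarray) -> bool:
    try:
        linalg.cholesky(m, lower=True)
        return True
    except linalg.LinAlgError:
        return False


def fit_lagged_gaussian(data: np.ndarray, tau: int = 1,
                        ridge_ladder=RIDGE_LADDER) -> LaggedGaussianModel:
    """Fit the lagged Gaussian model to a (channels x samples) array.

    Uses unbiased sample covariances of the lag-paired segments. If the
    stacked joint covariance is not positive definite, a ridge from
    ``ridge_ladder`` is added to the diagonal (recorded on the model).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n, t = data.shape
    if t - tau < 10 * n:
        raise ValueError("need at least 10 x channels lag-paired samples")
    x = data[:, :-tau]
    y = data[:, tau:]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    m = x.shape[1] - 1
    cov_x = xc @ xc.T / m
    cov_y = yc @ yc.T / m
    cov_xy = xc @ yc.T / m
    for eps in ridge_ladder:
        joint = np.block([[cov_x + eps * np.eye(n), cov_xy],
                          [cov_xy.T, cov_y + eps * np.eye(n)]])
        if _is_posdef(joint):
            if eps > 0:
                logger.info("fit_lagged_gaussian: ridge %.1e applied", eps)
            return LaggedGaussianModel(cov_x + eps * np.eye(n), cov_xy,
                                       cov_y + eps * np.eye(n), tau=tau, ridge=eps)
    raise linalg.LinAlgError("joint covariance rank-deficient even after max ridge")


def submodel(model: LaggedGaussianModel, subset) -> LaggedGaussianModel:
    """Restrict the model to a channel subset."""
    idx = np.asarray(sorted(subset), dtype=int)
    ix = np.ix_(idx, idx)
    return LaggedGaussianModel(model.cov_x[ix], model.cov_xy[ix], model.cov_y[ix],
                               tau=model.tau, ridge=model.ridge)


def _check_partition(n: int, partition) -> tuple[tuple[int, ...], ...]:
    blocks = tuple(tuple(sorted(int(i) for i in b)) for b in partition)
    flat = sorted(i for b in blocks for i in b)
    if flat != list(range(n)):
        raise ValueError("partition must exactly cover the channel indices")
    if len(blocks) < 2 or any(len(b) == 0 for b in blocks):
        raise ValueError("need at least 2 non-empty blocks")
    return blocks


def _logdet(m: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0:
        raise linalg.LinAlgError("matrix not positive definite")
    return float(ld)


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy 0.5 * ln((2 pi e)^k det(cov)), in nats."""
    cov = np.atleast_2d(cov)
    k = cov.shape[0]
    return 0.5 * (k * np.log(2 * np.pi * np.e) + _logdet(cov))


def _regression(model: LaggedGaussianModel):
    """Full lagged regression A (present on past) and innovation covariance."""
    a = linalg.solve(model.cov_x, model.cov_xy, assume_a="pos").T
    cond = model.cov_y - a @ model.cov_xy
    cond = 0.5 * (cond + cond.T)
    return a, cond


def mutual_info_past_present(model: LaggedGaussianModel) -> float:
    """I(X_{t-tau}; X_t) in nats."""
    _, cond = _regression(model)
    return 0.5 * (_logdet(model.cov_y) - _logdet(cond))


def multi_information(model: LaggedGaussianModel) -> float:
    """Total correlation of the equal-time covariance: sum_i h(X_i) - h(X)."""
    var = np.diag(model.cov_x)
    if np.any(var <= 0):
        raise ValueError("non-positive channel variance")
    return float(0.5 * (np.sum(np.log(var)) - _logdet(model.cov_x)))


def mii(model: LaggedGaussianModel, partition) -> float:
    """Whole-minus-parts lagged mutual information; may be negative."""
    blocks = _check_partition(model.n, partition)
    total = mutual_info_past_present(model)
    return total - sum(mutual_info_past_present(submodel(model, b)) for b in blocks)


def stochastic_interaction(model: LaggedGaussianModel, partition) -> float:
    """sum_k H(M_k,t | M_k,t-tau) - H(X_t | X_{t-tau}); non-negative."""
    blocks = _check_partition(model.n, partition)
    _, cond = _regression(model)
    h_whole = gaussian_entropy(cond)
    h_parts = 0.0
    for b in blocks:
        _, cond_b = _regression(submodel(model, b))
        h_parts += gaussian_entropy(cond_b)
    return float(h_parts - h_whole)


def _block_decoder(model: LaggedGaussianModel, blocks):
    """Part-factorized decoder: block-diagonal regression and noise covariance."""
    n = model.n
    a_d = np.zeros((n, n))
    s_d = np.zeros((n, n))
    for b in blocks:
        ix = np.ix_(b, b)
        sub = submodel(model, b)
        a_b, cond_b = _regression(sub)
        a_d[ix] = a_b
        s_d[ix] = cond_b
    return a_d, s_d


def _mismatched_information(model: LaggedGaussianModel, a_d, s_d, beta: float) -> float:
    """Mismatched-decoding information I~(beta) for decoder q(y|x)=N(A'x, S')."""
    sx, sy, sxy = model.cov_x, model.cov_y, model.cov_xy
    s_inv = linalg.inv(s_d)
    # residual second moment of the decoder's prediction under the true model
    r = sy - a_d @ sxy - sxy.T @ a_d.T + a_d @ sx @ a_d.T
    lam = linalg.inv(sx) + beta * a_d.T @ s_inv @ a_d
    g = s_inv @ a_d  # S'^-1 A'
    quad = g.T @ sy @ g  # A'^T S'^-1 Sy S'^-1 A'
    return float(
        -0.5 * beta * np.trace(s_inv @ r)
        + 0.5 * _logdet(lam) + 0.5 * _logdet(sx)
        + 0.5 * beta * np.trace(s_inv @ sy)
        - 0.5 * beta ** 2 * np.trace(linalg.solve(lam, quad))
    )


def phi_star(model: LaggedGaussianModel, partition,
             beta_bounds: tuple[float, float] = (1e-9, 100.0),
             xatol: float = 1e-10, return_beta: bool = False):
    """Decoder-based integrated information Phi* (nats).

    Phi* = I(X_{t-tau}; X_t) minus the mismatched-decoding information of the
    part-factorized decoder, maximized over the scalar decoding parameter
    beta by bounded 1-D optimization. Satisfies 0 <= Phi* <= I.
    """
    blocks = _check_partition(model.n, partition)
    a_d, s_d = _block_decoder(model, blocks)
    total = mutual_info_past_present(model)

    def neg(beta):
        return -_mismatched_information(model, a_d, s_d, beta)

    res = optimize.minimize_scalar(neg, bounds=beta_bounds, method="bounded",
                                   options={"xatol": xatol})
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"beta optimization failed: {res.message}; "
                           f"bracket={beta_bounds}, last beta={res.x}")
    i_star = max(-res.fun, _mismatched_information(model, a_d, s_d, 1.0))
    phi = float(np.clip(total - i_star, 0.0, total))
    if return_beta:
        return phi, float(res.x)
    return phi


def _block_mask(n: int, blocks) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    for b in blocks:
        mask[np.ix_(b, b)] = True
    return mask


def phi_g(model: LaggedGaussianModel, partition, restarts: int = 1,
          gtol: float = 1e-8, rng: np.random.Generator | int | None = None) -> float:
    """Geometric integrated information Phi^G (nats).

    Minimum KL divergence from the full lagged Gaussian to the manifold of
    models whose lagged regression has no cross-block coefficients (the
    equal-time and innovation covariance structure is unconstrained). With
    D = A - A' and C the full innovation covariance, the optimal constrained
    noise covariance is C + D Sx D^T, so the objective reduces to

        Phi^G(A') = 0.5 * [logdet(C + D Sx D^T) - logdet C]

    minimized over block-diagonal A' by quasi-Newton (L-BFGS-B) with the
    analytic gradient, warm-started at the block-masked full regression.
    Zero iff the full model already lies on the manifold.
    """
    blocks = _check_partition(model.n, partition)
    n = model.n
    a_full, c = _regression(model)
    # guard: make C safely positive definite for the logdet
    c = c + max(model.ridge, 1e-13) * np.eye(n)
    sx = model.cov_x
    mask = _block_mask(n, blocks)
    logdet_c = _logdet(c)

    def fun_grad(vec):
        a_p = np.zeros((n, n))
        a_p[mask] = vec
        d = a_full - a_p
        m = c + d @ sx @ d.T
        try:
            cf = linalg.cho_factor(m, lower=True)
        except linalg.LinAlgError:  # pragma: no cover - m is PD by construction
            return np.inf, np.zeros_like(vec)
        f = 2.0 * np.sum(np.log(np.diag(cf[0])))
        grad = -2.0 * linalg.cho_solve(cf, d) @ sx
        return f, grad[mask]

    rng = np.random.default_rng(rng)
    x_starts = [a_full[mask]]
    for _ in range(max(0, restarts - 1)):
        x_starts.append(a_full[mask] + rng.normal(scale=0.5, size=int(mask.sum())))
    best = np.inf
    last = None
    for x0 in x_starts:
        res = optimize.minimize(fun_grad, x0, jac=True, method="L-BFGS-B",
                                options={"gtol": gtol, "maxiter": 500})
        last = res
        if res.fun < best:
            best = res.fun
    if not np.isfinite(best):  # pragma: no cover
        raise RuntimeError(f"Phi^G optimization failed after restarts: {last.message}")
    return float(max(0.0, 0.5 * (best - logdet_c)))


MEASURES = {
    "mi": lambda model, partition: multi_information(model),
    "mii": mii,
    "si": stochastic_interaction,
    "phi_star": phi_star,
    "phi_g": phi_g,
}


def evaluate_measure(name: str, model: LaggedGaussianModel, partition) -> float:
    try:
        fn = MEASURES[name]
    except KeyError:
        raise ValueError(f"unknown measure {name!r}; choose from {sorted(MEASURES)}")
    return float(fn(model, partition))


def _queyranne_min_cut(n: int, f) -> tuple[float, frozenset]:
    """Queyranne's pendant-pair minimization of a symmetric set function.

    ``f`` maps a frozenset S (proper non-empty subset of range(n)) to the
    value of the cut (S, complement). Exact for symmetric submodular f;
    the standard heuristic otherwise.
    """
    groups: list[frozenset] = [frozenset([i]) for i in range(n)]
    cache: dict[frozenset, float] = {}

    def fc(s: frozenset) -> float:
        key = s if len(s) <= n - len(s) else frozenset(range(n)) - s
        if key not in cache:
            cache[key] = f(key)
        return cache[key]

    best_val, best_set = np.inf, None
    while len(groups) > 1:
        order = [0]
        remaining = list(range(1, len(groups)))
        w = groups[0]
        while remaining:
            if len(remaining) == 1:
                j = remaining[0]
            else:
                j = min(remaining, key=lambda r: fc(w | groups[r]) - fc(groups[r]))
            order.append(j)
            w = w | groups[j]
            remaining.remove(j)
        t, u = order[-2], order[-1]
        val = fc(groups[u])
        if val < best_val:
            best_val, best_set = val, groups[u]
        groups[t] = groups[t] | groups[u]
        groups.pop(u)
    return float(best_val), best_set


def mip_search(model: LaggedGaussianModel, measure: str = "phi_g",
               **measure_kwargs) -> PhiResult:
    """Minimum information partition over bipartitions via Queyranne's algorithm."""
    n = model.n
    if n < 2:
        raise ValueError("MIP search needs at least 2 channels")
    fn = MEASURES[measure]

    def f(subset: frozenset) -> float:
        block = tuple(sorted(subset))
        rest = tuple(i for i in range(n) if i not in subset)
        return float(fn(model, (block, rest), **measure_kwargs))

    if n == 2:
        val = f(frozenset([0]))
        return PhiResult(measure, val, ((0,), (1,)))
    val, subset = _queyranne_min_cut(n, f)
    block = tuple(sorted(subset))
    rest = tuple(i for i in range(n) if i not in subset)
    return PhiResult(measure, val, (block, rest))


def exhaustive_mip(model: LaggedGaussianModel, measure: str = "phi_g",
                   **measure_kwargs) -> PhiResult:
    """Exhaustive bipartition minimum (2^(n-1) - 1 cuts); small n only."""
    n = model.n
    fn = MEASURES[measure]
    best = None
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            if r == n / 2 and 0 not in combo:
                continue  # avoid double-counting complementary halves
            rest = tuple(i for i in range(n) if i not in combo)
            val = float(fn(model, (combo, rest), **measure_kwargs))
            if best is None or val < best.value:
                best = PhiResult(measure, val, (combo, rest))
    return best


def complex_search(model: LaggedGaussianModel, measure: str = "phi_g",
                   **measure_kwargs) -> PhiResult:
    """Channel subset maximizing the measure at its MIP, by recursive
    hierarchical bipartitioning: the full set is split at its MIP, each part
    is split recursively, and the best candidate along the hierarchy wins.
    """
    n = model.n
    if n < 3:
        raise ValueError("complex search needs at least 3 channels")
    best: PhiResult | None = None

    def recurse(subset: tuple[int, ...]) -> None:
        nonlocal best
        if len(subset) < 2:
            return
        sub = submodel(model, subset)
        res = mip_search(sub, measure, **measure_kwargs)
        # map local partition indices back to original channel ids
        partition = tuple(tuple(subset[i] for i in b) for b in res.partition)
        cand = PhiResult(measure, res.value, partition, subset=subset)
        if best is None or cand.value > best.value:
            best = cand
        for block in partition:
            recurse(tuple(sorted(block)))

    recurse(tuple(range(n)))
    return best
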