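"""Directed functional connectivity and graph topology.

MVAR model fitting, the directed transfer function (DTF), band-aggregated
adjacency matrices, mean coherence (mean absolute pairwise correlation),
and the two topology summaries used downstream: global efficiency (network
integration) and directed-weighted Louvain modularity (network segregation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "MVARFit",
    "WeightedDigraph",
    "fit_mvar",
    "select_order",
    "dtf_spectrum",
    "band_adjacency",
    "dtf_adjacency",
    "mean_abs_correlation",
    "global_efficiency",
    "directed_modularity",
]

DEFAULT_FREQS = np.arange(0.0, 40.0 + 1e-9, 0.5)


@dataclass
class MVARFit:
    """Multivariate autoregressive model X_t = sum_k A_k X_{t-k} + e_t."""

    coefs: np.ndarray       # (order, n, n); coefs[k-1] maps X_{t-k} -> X_t
    resid_cov: np.ndarray   # (n, n)
    rate: float
    stable: bool

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n(self) -> int:
        return self.coefs.shape[1]


@dataclass
class WeightedDigraph:
    """Nonnegative directed connectivity with weights in [0, 1], zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def mean_strength(self) -> float:
        """Mean off-diagonal connection strength."""
        w = self.weights
        n = w.shape[0]
        return float((w.sum() / (n * (n - 1))))


def _companion_stable(coefs: np.ndarray) -> bool:
    p, n, _ = coefs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1)


def fit_mvar(series: np.ndarray, order: int = 4, rate: float = 500.0) -> MVARFit:
    """Least-squares MVAR fit of a (channels x samples) series.

    The design stacks the ``order`` lagged state vectors; the solution is the
    multivariate OLS estimate (equivalent to Yule-Walker at large samples).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be channels x samples")
    n, t = x.shape
    if t - order < 10 * n * order:
        raise ValueError("need at least 10 * n * order post-lag samples")
    x = x - x.mean(axis=1, keepdims=True)
    y = x[:, order:].T                                   # (m, n)
    design = np.concatenate([x[:, order - k: t - k].T for k in range(1, order + 1)],
                            axis=1)                      # (m, n*order)
    b, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("ill-conditioned MVAR design matrix")
    coefs = np.stack([b[(k - 1) * n: k * n].T for k in range(1, order + 1)])
    resid = y - design @ b
    dof = max(y.shape[0] - design.shape[1], 1)
    resid_cov = resid.T @ resid / dof
    stable = _companion_stable(coefs)
    if not stable:
        logger.warning("fit_mvar: unstable fit (companion spectral radius >= 1)")
    return MVARFit(coefs=coefs, resid_cov=resid_cov, rate=rate, stable=stable)


def select_order(series: np.ndarray, max_order: int = 10, rate: float = 500.0,
                 criterion: str = "aic") -> int:
    """Order minimizing an information criterion over 1..max_order."""
    n, t = np.asarray(series).shape
    best, best_p = np.inf, 1
    for p in range(1, max_order + 1):
        fit = fit_mvar(series, order=p, rate=rate)
        m = t - p
        sign, ld = np.linalg.slogdet(fit.resid_cov)
        k = p * n * n
        if criterion == "aic":
            score = m * ld + 2 * k
        elif criterion == "bic":
            score = m * ld + k * np.log(m)
        else:
            raise ValueError("criterion must be 'aic' or 'bic'")
        if score < best:
            best, best_p = score, p
    return best_p


def dtf_spectrum(fit: MVARFit, freqs: np.ndarray = DEFAULT_FREQS,
                 rate: float | None = None) -> np.ndarray:
    """Normalized DTF gamma^2_ij(f), shape (n, n, n_freqs).

    H(f) = (I - sum_k A_k exp(-i 2 pi f k / rate))^{-1};
    gamma^2_ij(f) = |H_ij(f)|^2 / sum_m |H_im(f)|^2, so each row sums to 1
    at every frequency. Entry (i, j) is the influence of channel j on i.
    """
    rate = fit.rate if rate is None else rate
    n, p = fit.n, fit.order
    freqs = np.asarray(freqs, dtype=float)
    gamma = np.empty((n, n, freqs.size))
    eye = np.eye(n)
    for fi, f in enumerate(freqs):
        af = eye.astype(complex).copy()
        for k in range(1, p + 1):
            af -= fit.coefs[k - 1] * np.exp(-2j * np.pi * f * k / rate)
        try:
            h = np.linalg.inv(af)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular transfer matrix at {f} Hz") from exc
        h2 = np.abs(h) ** 2
        gamma[:, :, fi] = h2 / h2.sum(axis=1, keepdims=True)
    return gamma


def band_adjacency(gamma: np.ndarray, freqs: np.ndarray = DEFAULT_FREQS,
                   band: tuple[float, float] = (0.0, 40.0)) -> WeightedDigraph:
    """Band-average DTF into a weighted digraph.

    Trapezoidal area under gamma^2_ij(f) over ``band`` divided by the band
    width, so weights stay in [0, 1]; the diagonal is zeroed for graph use.
    """
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError("band must contain at least 2 evaluated frequencies")
    fs = freqs[sel]
    w = np.trapezoid(gamma[:, :, sel], fs, axis=2) / (fs[-1] - fs[0])
    np.fill_diagonal(w, 0.0)
    return WeightedDigraph(weights=np.clip(w, 0.0, 1.0))


def dtf_adjacency(data, order: int = 4, rate: float = 500.0,
                  freqs: np.ndarray = DEFAULT_FREQS,
                  band: tuple[float, float] = (0.0, 40.0)) -> WeightedDigraph:
    """MVAR -> DTF -> band-aggregated adjacency.

    Accepts one (channels x samples) series, or epoched data (EEGEpochs or a
    3-D array), in which case per-epoch fits are averaged at the adjacency
    level.
    """
    arr = np.asarray(getattr(data, "data", data), dtype=float)
    rate = float(getattr(data, "rate", rate))
    if arr.ndim == 2:
        arr = arr[None]
    ws = []
    for ep in arr:
        fit = fit_mvar(ep, order=order, rate=rate)
        ws.append(band_adjacency(dtf_spectrum(fit, freqs), freqs, band).weights)
    return WeightedDigraph(weights=np.mean(ws, axis=0))


def mean_abs_correlation(data) -> float:
    """Mean absolute zero-lag Pearson correlation over unordered channel pairs.

    For epoched input the per-epoch means are averaged.
    """
    arr = np.asarray(getattr(data, "data", data), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    iu = np.triu_indices(arr.shape[1], k=1)
    vals = []
    for ep in arr:
        if np.any(ep.std(axis=1) == 0):
            raise ValueError("constant channel in correlation computation")
        c = np.corrcoef(ep)
        vals.append(float(np.mean(np.abs(c[iu]))))
    return float(np.mean(vals))


def global_efficiency(g: WeightedDigraph, zero_distance: float = 1e-9) -> float:
    """Mean inverse shortest-path distance over ordered node pairs.

    Edge distances are the complement of the weights (1 - w; an absent edge,
    w = 0, has distance exactly 1), shortest paths by Dijkstra. A weight of
    exactly 1 is clamped to distance ``zero_distance`` and logged.
    """
    w = g.weights
    if g.n < 2:
        raise ValueError("need at least 2 nodes")
    dist = 1.0 - w
    if np.any(dist[~np.eye(g.n, dtype=bool)] <= 0):
        logger.warning("global_efficiency: unit weight clamped to distance %g",
                       zero_distance)
        dist = np.where(dist <= 0, zero_distance, dist)
    np.fill_diagonal(dist, 0.0)
    sp = dijkstra(dist, directed=True)
    off = ~np.eye(g.n, dtype=bool)
    return float(np.mean(1.0 / sp[off]))


def directed_modularity(g: WeightedDigraph, seed: int | np.random.Generator = 0,
                        restarts: int = 10) -> tuple[float, list[set]]:
    """Directed-weighted Louvain modularity, best of ``restarts`` runs.

    Q = (1/m) sum_ij [w_ij - s_i^out s_j^in / m] delta(c_i, c_j), optimized
    with the Louvain method on the directed weighted graph.
    """
    w = g.weights
    if w.sum() <= 0:
        raise ValueError("graph has no weight")
    graph = nx.from_numpy_array(w, create_using=nx.DiGraph)
    rng = np.random.default_rng(seed)
    best_q, best_com = -np.inf, None
    for _ in range(restarts):
        com = nx.community.louvain_communities(
            graph, weight="weight", seed=int(rng.integers(2 ** 31)))
        q = nx.community.modularity(graph, com, weight="weight")
        if q > best_q:
            best_q, best_com = q, com
    return float(best_q), [set(c) for c in best_com]
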