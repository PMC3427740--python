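"""Significance testing for key-graph edges and node-strength comparisons.

Edge significance is assessed against surrogate time-varying networks built
by randomly reshuffling edge weights, which preserves each slice's weight
distribution while destroying its topology.  The key-graph estimator is
applied to every surrogate sequence, and each observed key-graph edge gets
an empirical one-sided p-value

    p = (1 + #{null >= observed}) / (1 + n_null),

so p is never exactly zero; with S surrogates the smallest attainable p is
1/(1 + S) per-edge, or 1/(1 + S*d) when the d edge positions of all
surrogate key graphs are pooled into one null (the default -- with S = 2000
per-edge nulls cannot resolve the 0.001 level unless the observed edge beats
every null value).

Node strength across intervals is compared with Welch's unequal-variance
t-test on the node's N-1 edge weights in each interval's key graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .keygraph import DEFAULT_XI, KeyGraph, key_vector, upper_triangle_index, vectorize

__all__ = [
    "SurrogateEnsemble",
    "SignificanceMask",
    "NodeStrengthComparison",
    "make_surrogates",
    "edge_significance",
    "compare_node_strength",
    "min_attainable_p",
]

DEFAULT_N_SURROGATES = 2000
DEFAULT_LEVELS = (0.01, 0.001)


@dataclass
class SurrogateEnsemble:
    """Key-graph edge vectors of an ensemble of reshuffled networks."""

    surrogate_key_edges: np.ndarray  # [n_surrogates x d]
    mode: str
    seed: int
    n_nodes: int

    @property
    def n_surrogates(self) -> int:
        return self.surrogate_key_edges.shape[0]


@dataclass
class SignificanceMask:
    """Per-edge empirical p-values and the two fixed-level masks."""

    p_values: np.ndarray  # length d, in (0, 1]
    mask_01: np.ndarray  # p < 0.01
    mask_001: np.ndarray  # p < 0.001
    pooled: bool = True

    def mask_adjacency(self, n: int, level: str = "01") -> np.ndarray:
        """Boolean N x N adjacency of a significance mask."""
        mask = self.mask_01 if level == "01" else self.mask_001
        r, c = upper_triangle_index(n)
        A = np.zeros((n, n), dtype=bool)
        A[r, c] = mask
        A[c, r] = mask
        return A


@dataclass
class NodeStrengthComparison:
    """Welch's t-test on one node's edge weights across two key graphs."""

    node: int
    interval_a: str
    interval_b: str
    t_statistic: float
    p_value: float
    df: float
    reject_at_05: bool


def min_attainable_p(n_surrogates: int, n_edges: int, pooled: bool) -> float:
    """Smallest empirical p reachable with the plus-one correction."""
    n_null = n_surrogates * n_edges if pooled else n_surrogates
    return 1.0 / (1.0 + n_null)


def make_surrogates(
    interval_graphs,
    n: int = DEFAULT_N_SURROGATES,
    mode: str = "per_slice",
    seed: int = 0,
    xi: float = DEFAULT_XI,
    centered: bool = False,
    permutation_fn=None,
) -> SurrogateEnsemble:
    """Surrogate key-graph ensemble for one event interval.

    Parameters
    ----------
    interval_graphs
        The M graph slices of the interval (list or M x N x N array).
    mode
        ``"per_slice"`` permutes the strict-upper-triangle weight multiset
        independently at every time point; ``"fixed_permutation"`` draws one
        edge-position permutation per surrogate and applies it to all
        slices, preserving each edge's temporal profile.
    seed
        Seeds a deterministic substream per surrogate (derived via
        ``SeedSequence(seed).spawn``), so the ensemble is reproducible and
        independent of evaluation order.
    permutation_fn
        Optional ``f(rng, size) -> permutation`` override (testing hook).

    Every surrogate slice conserves the multiset of edge weights of the
    corresponding original slice.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    if mode not in ("per_slice", "fixed_permutation"):
        raise ValueError(f"unknown surrogate mode {mode!r}")
    A = np.asarray(interval_graphs, dtype=float)
    if A.ndim == 2:
        A = A[None]
    M, N = A.shape[0], A.shape[1]
    Z = np.stack([vectorize(A[i]) for i in range(M)])  # [M x d]
    d = Z.shape[1]
    if permutation_fn is None:
        permutation_fn = lambda rng, size: rng.permutation(size)

    children = np.random.SeedSequence(seed).spawn(n)
    edges = np.empty((n, d))
    for s in range(n):
        rng = np.random.default_rng(children[s])
        if mode == "per_slice":
            Zs = np.stack([Z[i, permutation_fn(rng, d)] for i in range(M)])
        else:
            Zs = Z[:, permutation_fn(rng, d)]
        edges[s] = key_vector(Zs, xi=xi, centered=centered)[0]
    return SurrogateEnsemble(surrogate_key_edges=edges, mode=mode, seed=seed, n_nodes=N)


def edge_significance(
    key: KeyGraph | np.ndarray,
    ensemble: SurrogateEnsemble,
    pooled: bool = True,
    two_sided: bool = False,
    levels: tuple[float, float] = DEFAULT_LEVELS,
) -> SignificanceMask:
    """Empirical per-edge p-values of a key graph against the surrogate null.

    ``pooled=True`` (default) compares every observed edge against the
    pooled null of all surrogate edges at all positions; ``pooled=False``
    uses each edge's own positional null.  One-sided (observed > null) by
    default, since strong connections are the interactions of interest.
    """
    obs = key.edge_vector() if isinstance(key, KeyGraph) else np.asarray(key, float)
    null = ensemble.surrogate_key_edges
    S, d = null.shape
    if obs.size != d:
        raise ValueError("key graph and ensemble edge counts differ")
    if not pooled and min_attainable_p(S, d, pooled=False) > min(levels):
        warnings.warn(
            f"per-edge null with {S} surrogates cannot resolve "
            f"P<{min(levels):g} (minimum attainable p = {1.0/(1+S):.2e}); "
            "consider pooled=True"
        )
    # tolerance so exact ties (e.g. permutation-equivariant surrogates) are
    # counted as ties rather than split by float round-off (anticonservative)
    eps = 1e-9 * max(np.abs(null).max(), np.abs(obs).max(), 1e-300)
    if pooled:
        flat = np.sort(null.ravel())
        n_null = flat.size
        ge = n_null - np.searchsorted(flat, obs - eps, side="left")
        p = (1.0 + ge) / (1.0 + n_null)
        if two_sided:
            le = np.searchsorted(flat, obs + eps, side="right")
            p_lo = (1.0 + le) / (1.0 + n_null)
            p = np.minimum(1.0, 2.0 * np.minimum(p, p_lo))
    else:
        ge = (null >= obs[None, :] - eps).sum(axis=0)
        p = (1.0 + ge) / (1.0 + S)
        if two_sided:
            le = (null <= obs[None, :] + eps).sum(axis=0)
            p_lo = (1.0 + le) / (1.0 + S)
            p = np.minimum(1.0, 2.0 * np.minimum(p, p_lo))
    lev_01, lev_001 = max(levels), min(levels)
    return SignificanceMask(
        p_values=p, mask_01=p < lev_01, mask_001=p < lev_001, pooled=pooled
    )


def compare_node_strength(
    key_a: KeyGraph | np.ndarray,
    key_b: KeyGraph | np.ndarray,
    node: int,
    label_a: str = "a",
    label_b: str = "b",
    alpha: float = 0.05,
) -> NodeStrengthComparison:
    """Welch's t-test on a node's edge weights in two key graphs.

    Compares the node's N-1 connection strengths from each graph with the
    unequal-variance two-sample t statistic and Welch-Satterthwaite degrees
    of freedom, two-sided.
    """
    Aa = key_a.adjacency if isinstance(key_a, KeyGraph) else np.asarray(key_a, float)
    Ab = key_b.adjacency if isinstance(key_b, KeyGraph) else np.asarray(key_b, float)
    if Aa.shape != Ab.shape:
        raise ValueError("key graphs must share the node set")
    N = Aa.shape[0]
    if N < 3:
        raise ValueError("need at least 3 nodes for a node-strength comparison")
    if not 0 <= node < N:
        raise ValueError(f"node {node} out of range")
    others = np.arange(N) != node
    xa, xb = Aa[node, others], Ab[node, others]
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return NodeStrengthComparison(
        node=node,
        interval_a=label_a,
        interval_b=label_b,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        reject_at_05=bool(res.pvalue < alpha),
    )
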