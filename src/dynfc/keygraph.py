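"""Key-graph summarization of an event interval by principal components.

The M graphs of an interval are vectorized (column-major stacking of the
strict upper triangle, d = N(N-1)/2 entries), the sample covariance

    C = 1/(M-1) sum_i (z_i - zbar)(z_i - zbar)^T

is eigendecomposed, and the smallest number L of leading eigenvectors whose
cumulative eigenvalue share reaches the energy threshold xi (default 90%)
spans the summary subspace.  Each vector is projected and reconstructed,

    p_i = V_L^T z_i,   ztilde_i = V_L p_i,

and the key graph is the devectorized mean of the reconstructions,
ztilde_bar = (1/M) sum_i ztilde_i = V_L V_L^T zbar (by linearity), i.e. the
subspace projection of the interval-mean graph.

The projection is applied to the raw, uncentered vectors (the centered
variant is available via ``centered=True`` and is a documented deviation).
Degenerate intervals -- M = 1 or an (almost) zero covariance -- fall back
to the plain interval mean.

Eigenpairs are computed through a thin SVD of the centered M x d data
matrix rather than by forming the d x d covariance (d = 1891 for N = 62
while M may be 13); the dense-covariance route is retained in the test
suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PCASummary",
    "KeyGraph",
    "upper_triangle_index",
    "vectorize",
    "devectorize",
    "fit_pca",
    "key_graph",
    "key_vector",
]

DEFAULT_XI = 90.0

#: Eigenvalues below this multiple of the leading one are clamped to zero.
EIGENVALUE_CLAMP_REL = 1e-12


@dataclass
class PCASummary:
    """Spectral summary of an interval's vectorized graphs."""

    eigenvalues: np.ndarray  # decreasing, zero-clamped, full spectrum length
    eigenvectors: np.ndarray  # [d x r] leading eigenvectors (columns)
    retained: int  # L
    xi: float
    mean_vector: np.ndarray  # zbar
    retained_share: float  # cumulative eigenvalue share of the first L

    @property
    def basis(self) -> np.ndarray:
        """V_L, the retained d x L orthonormal basis."""
        return self.eigenvectors[:, : self.retained]


@dataclass
class KeyGraph:
    """Per-interval summary graph (symmetric, zero diagonal)."""

    adjacency: np.ndarray
    interval: object = None  # events.Interval, if any
    pca: PCASummary | None = None
    projected: np.ndarray | None = None  # p_i, [M x L]
    reconstructed: np.ndarray | None = None  # ztilde_i, [M x d]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_vector(self) -> np.ndarray:
        return vectorize(self.adjacency)


def upper_triangle_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the strict upper triangle in column-major order.

    Order: (0,1), (0,2), (1,2), (0,3), (1,3), (2,3), ... -- i.e. stacking
    the columns of the upper triangular portion.
    """
    rows = np.concatenate([np.arange(j) for j in range(1, n)]) if n > 1 else np.array([], int)
    cols = np.concatenate([np.full(j, j) for j in range(1, n)]) if n > 1 else np.array([], int)
    return rows, cols


def vectorize(G: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Stack the strict upper triangle of a symmetric matrix column-major."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("graph slice must be square")
    if not np.allclose(G, G.T, atol=atol):
        raise ValueError("graph slice is not symmetric within tolerance")
    r, c = upper_triangle_index(G.shape[0])
    return G[r, c]


def devectorize(z: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: symmetric zero-diagonal N x N matrix."""
    z = np.asarray(z, dtype=float)
    if z.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {z.size} does not match n={n}")
    G = np.zeros((n, n))
    r, c = upper_triangle_index(n)
    G[r, c] = z
    G[c, r] = z
    return G


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-magnitude component positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def fit_pca(vectors: np.ndarray, xi: float = DEFAULT_XI) -> PCASummary:
    """PCA of an M x d set of vectorized graphs at energy threshold xi (%).

    L is the smallest count of leading eigenvalues whose cumulative share of
    the total eigenvalue sum reaches xi percent; the denominator includes
    (numerically) zero eigenvalues, and eigenvalues below
    ``EIGENVALUE_CLAMP_REL`` times the largest are clamped to zero.
    """
    Z = np.asarray(vectors, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need an M x d matrix with M >= 2")
    if not 0 < xi <= 100:
        raise ValueError(f"xi must be a percentage in (0, 100], got {xi}")
    M, d = Z.shape
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    # Thin SVD of the centered data; eigenvalues of C are s^2/(M-1).
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    lam = s**2 / (M - 1)
    # round-off residuals of (numerically) identical rows must not masquerade
    # as variance: measure degeneracy against the data's own scale
    scale = max(float(np.mean(Z * Z)), 1e-300)
    if lam.size and lam[0] <= EIGENVALUE_CLAMP_REL * scale:
        lam[:] = 0.0
    if lam.size and lam[0] > 0:
        lam[lam < EIGENVALUE_CLAMP_REL * lam[0]] = 0.0
    total = lam.sum()
    if total == 0:
        # C = 0: no variance direction carries energy; degenerate.
        return PCASummary(
            eigenvalues=lam,
            eigenvectors=np.zeros((d, 0)),
            retained=0,
            xi=xi,
            mean_vector=zbar,
            retained_share=1.0,
        )
    share = np.cumsum(lam) / total
    L = int(np.searchsorted(share * 100.0, xi, side="left") + 1)
    L = min(L, int(np.count_nonzero(lam)))
    V = _fix_signs(Vt.T[:, : max(L, 1)])
    return PCASummary(
        eigenvalues=lam,
        eigenvectors=V,
        retained=L,
        xi=xi,
        mean_vector=zbar,
        retained_share=float(share[L - 1]),
    )


def key_vector(Z: np.ndarray, xi: float = DEFAULT_XI, centered: bool = False) -> tuple[np.ndarray, PCASummary | None, np.ndarray | None, np.ndarray | None]:
    """Key edge vector for an M x d matrix of vectorized interval graphs.

    Returns ``(ztilde_bar, pca, projected, reconstructed)``; the PCA summary
    and per-graph arrays are ``None`` in the degenerate fallback (M = 1 or
    zero covariance), where the key vector is the plain mean.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    M = Z.shape[0]
    if M == 0:
        raise ValueError("empty interval")
    if M == 1:
        return Z[0].copy(), None, None, None
    pca = fit_pca(Z, xi=xi)
    if pca.retained == 0:
        return pca.mean_vector.copy(), None, None, None
    VL = pca.basis
    if centered:
        P = (Z - pca.mean_vector) @ VL
        R = P @ VL.T + pca.mean_vector
    else:
        P = Z @ VL  # Eq.-as-printed: uncentered projection
        R = P @ VL.T
    return R.mean(axis=0), pca, P, R


def key_graph(
    interval_graphs,
    xi: float = DEFAULT_XI,
    centered: bool = False,
    interval=None,
) -> KeyGraph:
    """Key graph summarizing a list (or T x N x N array) of graph slices."""
    A = np.asarray(interval_graphs, dtype=float)
    if A.ndim == 2:
        A = A[None]
    if A.ndim != 3 or A.shape[0] < 1:
        raise ValueError("interval must contain at least one N x N graph")
    n = A.shape[1]
    Z = np.stack([vectorize(A[i]) for i in range(A.shape[0])])
    zkey, pca, P, R = key_vector(Z, xi=xi, centered=centered)
    return KeyGraph(
        adjacency=devectorize(zkey, n),
        interval=interval,
        pca=pca,
        projected=P,
        reconstructed=R,
    )
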