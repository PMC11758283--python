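"""Nonlinear Laplacian spectral analysis of a dense standardized series.

Pipeline (each step is an exported operation):

1. :func:`delay_embed` - lazy delay-coordinate (Hankel) view of the series.
2. :func:`embedded_distances` - kNN graph of squared supervector distances,
   computed with a sliding-window identity instead of materializing the
   embedded matrix.
3. :func:`diffusion_basis` - diffusion-map eigenfunctions and the invariant
   measure of the associated Markov chain (alpha = 1 normalization).
4. :func:`project` - manifold projection ``A = X diag(mu) Phi``.
5. :func:`svd_modes` - thin SVD of A with a deterministic sign convention.
6. :func:`reconstruct_embedded` / :func:`diagonal_average` - truncated
   back-projection and Hankelization back to one vector per time point.

The embedded matrix X (shape D*c x n, n = N - c + 1) is never formed
densely; blocks of X alias columns of the underlying D x N series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .core import MillerIndexSet, VolumeSeries
from .preprocess import DenseSeries

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "EmbeddedMatrix",
    "DistanceGraph",
    "ManifoldBasis",
    "ModeDecomposition",
    "ReconstructedEmbedding",
    "ReconstructedSeries",
    "delay_embed",
    "embedded_distances",
    "markov_matrix",
    "diffusion_basis",
    "project",
    "svd_modes",
    "reconstruct_embedded",
    "diagonal_average",
    "nlsa_run",
]

#: Below this graph size the eigenproblem is solved densely.
_DENSE_EIGEN_LIMIT = 800


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of one NLSA run.

    ``n_basis`` (K) defaults to ``max(2 * n_modes, 16)``; ``knn`` defaults
    to ``min(n - 1, 100)`` where ``n = N - c + 1``.
    """

    c: int
    n_modes: int
    n_basis: int | None = None
    knn: int | None = None
    epsilon_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("concatenation order c must be >= 1")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.n_basis is not None and self.n_modes > self.n_basis:
            raise ValueError(
                f"n_modes={self.n_modes} exceeds basis size n_basis={self.n_basis}"
            )
        if self.epsilon_factor <= 0:
            raise ValueError("epsilon_factor must be positive")

    def resolved(self, n: int) -> tuple[int, int]:
        """(knn, K) after defaulting, for n embedded columns."""
        knn = self.knn if self.knn is not None else min(n - 1, 100)
        K = self.n_basis if self.n_basis is not None else max(2 * self.n_modes, 16)
        K = min(K, n)
        if self.n_modes > K:
            raise ValueError(f"n_modes={self.n_modes} exceeds usable basis size {K}")
        return knn, K


class EmbeddedMatrix:
    """Lazy delay-embedded matrix X of shape (D*c, n), n = N - c + 1.

    Column j is the supervector at original time t = c - 1 + j with blocks
    ordered newest-first: block i of column j equals the series vector at
    time c - 1 + j - i. Blocks alias the underlying dense array.
    """

    def __init__(self, values: np.ndarray, mask: np.ndarray | None, c: int):
        values = np.asarray(values)
        D, N = values.shape
        if not 1 <= c <= N - 1 and not (c == 1 and N >= 1):
            raise ValueError(f"need 1 <= c < N; got c={c}, N={N}")
        self.values = values
        self.mask = mask
        self.c = c
        self.D = D
        self.N = N
        self.n = N - c + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.D * self.c, self.n)

    def block(self, i: int) -> np.ndarray:
        """Rows i*D:(i+1)*D of X as a view into the dense series."""
        if not 0 <= i < self.c:
            raise IndexError(f"block index {i} outside 0..{self.c - 1}")
        start = self.c - 1 - i
        return self.values[:, start : start + self.n]

    def mask_block(self, i: int) -> np.ndarray | None:
        if self.mask is None:
            return None
        start = self.c - 1 - i
        return self.mask[:, start : start + self.n]

    def column(self, j: int) -> np.ndarray:
        """Supervector j, concatenated newest-first (forces a copy)."""
        if not 0 <= j < self.n:
            raise IndexError(f"column {j} outside 0..{self.n - 1}")
        t = self.c - 1 + j
        return np.concatenate([self.values[:, t - i] for i in range(self.c)])

    def dense(self) -> np.ndarray:
        """Materialize X (tests and tiny problems only)."""
        return np.vstack([self.block(i) for i in range(self.c)])


def delay_embed(dense: DenseSeries | np.ndarray, c: int) -> EmbeddedMatrix:
    """Delay-coordinate embedding of a dense series with window c."""
    if isinstance(dense, DenseSeries):
        values, mask = dense.values, dense.mask
    else:
        values, mask = np.asarray(dense, dtype=float), None
    if values.ndim != 2:
        raise ValueError("series must be a 2-d (D x N) array")
    if c >= values.shape[1] + 1 or c < 1:
        raise ValueError(f"need 1 <= c <= N; got c={c}, N={values.shape[1]}")
    if c == values.shape[1]:
        raise ValueError(f"c={c} leaves no embedded columns (need c < N)")
    return EmbeddedMatrix(values, mask, c)


@dataclass
class DistanceGraph:
    """Symmetric kNN graph of squared embedded distances.

    Stored in COO style (``row``, ``col``, ``d2``) so that exact-duplicate
    columns (distance zero) remain first-class edges. ``knn_d2`` holds each
    node's sorted squared distances to its knn nearest neighbours
    (pre-symmetrization), used by the bandwidth rule.
    """

    n: int
    row: np.ndarray
    col: np.ndarray
    d2: np.ndarray
    knn_d2: np.ndarray
    knn: int

    def adjacency(self) -> sp.csr_matrix:
        """Binary structure matrix (for connectivity checks)."""
        return sp.csr_matrix(
            (np.ones(len(self.row)), (self.row, self.col)), shape=(self.n, self.n)
        )

    def to_dense_d2(self) -> np.ndarray:
        """Dense squared-distance matrix with inf on absent edges."""
        out = np.full((self.n, self.n), np.inf)
        out[self.row, self.col] = self.d2
        np.fill_diagonal(out, 0.0)
        return out


def _snapshot_sq_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between series columns."""
    gram = values.T @ values
    nrm = np.diag(gram).copy()
    d2 = nrm[:, None] + nrm[None, :] - 2.0 * gram
    np.clip(d2, 0.0, None, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def _embedded_sq_distances(values: np.ndarray, c: int) -> np.ndarray:
    """Squared supervector distances via the sliding-window identity

        d2_emb(i, j) = sum_{m=0}^{c-1} d2_snap(i + m, j + m)

    (indices in embedded-column coordinates), evaluated per diagonal with
    cumulative sums. Equals the naive concatenated-vector distance.
    """
    d2s = _snapshot_sq_distances(values)
    N = d2s.shape[0]
    n = N - c + 1
    E = np.empty((n, n))
    for k in range(n):
        diag = np.diagonal(d2s, offset=k)
        if c == 1:
            win = diag
        else:
            cs = np.concatenate(([0.0], np.cumsum(diag)))
            win = cs[c:] - cs[:-c]
        idx = np.arange(n - k)
        E[idx, idx + k] = win
        E[idx + k, idx] = win
    np.clip(E, 0.0, None, out=E)
    return E


def embedded_distances(X: EmbeddedMatrix, knn: int) -> DistanceGraph:
    """Symmetric (union) kNN graph over embedded columns.

    Squared distances are plain Euclidean between the imputed standardized
    supervectors, computed with the sliding-window identity rather than by
    concatenation.
    """
    n = X.n
    if knn <= 0:
        raise ValueError("knn must be positive")
    if knn >= n:
        raise ValueError(f"knn={knn} must be smaller than n={n} embedded columns")
    E = _embedded_sq_distances(X.values, X.c)
    work = E.copy()
    np.fill_diagonal(work, np.inf)
    nbr = np.argpartition(work, knn - 1, axis=1)[:, :knn]
    rows = np.repeat(np.arange(n), knn)
    cols = nbr.ravel()
    d2 = work[rows, cols]
    knn_d2 = np.sort(d2.reshape(n, knn), axis=1)
    # Symmetrize by union, deduplicating (i, j) pairs explicitly so that
    # zero-distance edges survive (scipy would silently merge/drop them).
    all_r = np.concatenate([rows, cols])
    all_c = np.concatenate([cols, rows])
    all_d = np.concatenate([d2, d2])
    key = all_r.astype(np.int64) * n + all_c
    _, first = np.unique(key, return_index=True)
    return DistanceGraph(
        n=n, row=all_r[first], col=all_c[first], d2=all_d[first], knn_d2=knn_d2, knn=knn
    )


@dataclass
class ManifoldBasis:
    """Leading diffusion-map eigenfunctions and the invariant measure.

    ``phi`` is (n, K) with the constant eigenfunction first and columns
    mu-orthonormal: ``phi.T @ diag(mu) @ phi = I``. ``mu`` is the stationary
    distribution of the Markov kernel (positive, sums to one).
    """

    phi: np.ndarray
    mu: np.ndarray
    eigenvalues: np.ndarray
    epsilon: float

    @property
    def n_basis(self) -> int:
        return self.phi.shape[1]


def _bandwidth(graph: DistanceGraph, epsilon_factor: float) -> float:
    """Self-tuning bandwidth: square of the median distance to the
    ceil(knn/2)-th neighbour, times epsilon_factor."""
    k_half = max(1, int(np.ceil(graph.knn / 2)))
    d = np.sqrt(graph.knn_d2[:, k_half - 1])
    eps = epsilon_factor * float(np.median(d)) ** 2
    if eps <= 0:
        # All pairwise distances vanish (constant series); any bandwidth
        # yields the same uniform kernel.
        eps = 1.0
    return eps


def markov_matrix(
    graph: DistanceGraph, epsilon: float
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Row-stochastic diffusion kernel P and its stationary distribution mu.

    Gaussian kernel on graph edges with alpha = 1 density normalization
    (W -> D^-1 W D^-1) before row normalization, which removes the leading
    sampling-density bias (Laplace-Beltrami limit).
    """
    n = graph.n
    w = np.exp(-graph.d2 / epsilon)
    rows = np.concatenate([graph.row, np.arange(n)])
    cols = np.concatenate([graph.col, np.arange(n)])
    data = np.concatenate([w, np.ones(n)])  # unit self-affinity
    W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    q = np.asarray(W.sum(axis=1)).ravel()
    Dinv = sp.diags(1.0 / q)
    K = Dinv @ W @ Dinv
    d = np.asarray(K.sum(axis=1)).ravel()
    P = sp.diags(1.0 / d) @ K
    mu = d / d.sum()
    return P.tocsr(), mu


def diffusion_basis(
    graph: DistanceGraph,
    n_basis: int,
    epsilon_factor: float = 1.0,
    seed: int = 0,
) -> ManifoldBasis:
    """Leading right eigenfunctions of the diffusion Markov chain.

    Solved through the symmetric conjugate ``D^-1/2 K D^-1/2`` so the
    spectrum is real; eigenfunctions are returned mu-orthonormal with a
    deterministic sign convention (largest-magnitude entry positive,
    constant mode positive).
    """
    n = graph.n
    if n_basis > n:
        raise ValueError(f"n_basis={n_basis} exceeds n={n} embedded columns")
    adj = graph.adjacency()
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"distance graph has {n_comp} connected components; increase knn"
        )
    eps = _bandwidth(graph, epsilon_factor)
    w = np.exp(-graph.d2 / eps)
    rows = np.concatenate([graph.row, np.arange(n)])
    cols = np.concatenate([graph.col, np.arange(n)])
    data = np.concatenate([w, np.ones(n)])
    W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    q = np.asarray(W.sum(axis=1)).ravel()
    Dinv = sp.diags(1.0 / q)
    K = (Dinv @ W @ Dinv).tocsr()
    d = np.asarray(K.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(d)
    S = sp.diags(d_isqrt) @ K @ sp.diags(d_isqrt)
    if n <= _DENSE_EIGEN_LIMIT or n_basis > n // 2:
        evals, evecs = np.linalg.eigh(S.toarray())
        evals, evecs = evals[::-1][:n_basis], evecs[:, ::-1][:, :n_basis]
    else:
        v0 = np.random.default_rng(seed).standard_normal(n)
        evals, evecs = eigsh(S, k=n_basis, which="LA", v0=v0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    mu = d / d.sum()
    phi = evecs * d_isqrt[:, None] * np.sqrt(d.sum())
    # Deterministic signs: constant mode positive, then largest-|entry|
    # positive per column.
    if phi[:, 0].sum() < 0:
        phi[:, 0] = -phi[:, 0]
    for k in range(1, phi.shape[1]):
        idx = int(np.argmax(np.abs(phi[:, k])))
        if phi[idx, k] < 0:
            phi[:, k] = -phi[:, k]
    return ManifoldBasis(phi=phi, mu=mu, eigenvalues=evals, epsilon=eps)


def project(X: EmbeddedMatrix, basis: ManifoldBasis) -> np.ndarray:
    """Manifold projection A = X diag(mu) Phi, accumulated block-wise so
    the embedded matrix is never materialized."""
    if basis.phi.shape[0] != X.n:
        raise ValueError(
            f"basis has {basis.phi.shape[0]} samples but X has {X.n} columns"
        )
    weighted = basis.mu[:, None] * basis.phi
    A = np.empty((X.D * X.c, basis.n_basis))
    for i in range(X.c):
        A[i * X.D : (i + 1) * X.D] = X.block(i) @ weighted
    return A


@dataclass
class ModeDecomposition:
    """Thin SVD of the projected matrix A = U S V^T.

    ``v`` holds the right singular vectors as columns (K x K); singular
    values are non-increasing.
    """

    u: np.ndarray
    s: np.ndarray
    v: np.ndarray

    @property
    def n_basis(self) -> int:
        return len(self.s)


def svd_modes(A: np.ndarray) -> ModeDecomposition:
    """Thin SVD with the sign of each left singular vector fixed so its
    largest-magnitude entry is positive."""
    A = np.asarray(A)
    if not np.all(np.isfinite(A)):
        raise ValueError("projected matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    for k in range(u.shape[1]):
        idx = int(np.argmax(np.abs(u[:, k])))
        if u[idx, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    return ModeDecomposition(u=u, s=s, v=vt.T)


class ReconstructedEmbedding:
    """Truncated back-projection X~ = U_M S_M V_M^T Phi^T as a block/column
    oracle (never forced dense at scale)."""

    def __init__(self, modes: ModeDecomposition, basis: ManifoldBasis, n_modes: int, c: int):
        K = modes.n_basis
        if n_modes > K:
            raise ValueError(f"n_modes={n_modes} exceeds basis size {K}")
        if n_modes > basis.n_basis:
            raise ValueError("mode count exceeds the manifold basis size")
        if modes.u.shape[0] % c != 0:
            raise ValueError("row count of U is not divisible by c")
        self.u = modes.u
        self.c = c
        self.D = modes.u.shape[0] // c
        self.n = basis.phi.shape[0]
        self.n_modes = n_modes
        # T = diag(S_M) V_M^T Phi^T, shape (M, n)
        self.T = (modes.s[:n_modes, None] * modes.v[:, :n_modes].T) @ basis.phi.T

    @property
    def shape(self) -> tuple[int, int]:
        return (self.D * self.c, self.n)

    def block(self, i: int) -> np.ndarray:
        if not 0 <= i < self.c:
            raise IndexError(f"block index {i} outside 0..{self.c - 1}")
        if self.n_modes == 0:
            return np.zeros((self.D, self.n))
        return self.u[i * self.D : (i + 1) * self.D, : self.n_modes] @ self.T

    def column(self, j: int) -> np.ndarray:
        if self.n_modes == 0:
            return np.zeros(self.D * self.c)
        return self.u[:, : self.n_modes] @ self.T[:, j]

    def dense(self) -> np.ndarray:
        """Materialize X~ (tests and tiny problems only)."""
        if self.n_modes == 0:
            return np.zeros(self.shape)
        return self.u[:, : self.n_modes] @ self.T


def reconstruct_embedded(
    modes: ModeDecomposition, basis: ManifoldBasis, n_modes: int, c: int
) -> ReconstructedEmbedding:
    """Back-project the leading ``n_modes`` SVD modes to the embedded data
    space: X~ = (sum_{m<=M} U_m S_m V_m^T) Phi^T."""
    return ReconstructedEmbedding(modes, basis, n_modes, c)


def diagonal_average(
    x_emb: ReconstructedEmbedding | np.ndarray, c: int | None = None
) -> np.ndarray:
    """Hankelization: average every embedded entry aliasing original time t
    into one value, giving a (D, N) series with N = n + c - 1.

    Accepts either a :class:`ReconstructedEmbedding` or a dense (D*c, n)
    array (``c`` required in that case). Boundary times average over fewer
    terms.
    """
    if isinstance(x_emb, ReconstructedEmbedding):
        c = x_emb.c
        D, n = x_emb.D, x_emb.n
        blocks = (x_emb.block(i) for i in range(c))
    else:
        arr = np.asarray(x_emb, dtype=float)
        if c is None:
            raise ValueError("c is required for a plain array input")
        if arr.shape[0] % c != 0:
            raise ValueError("row count is not divisible by c")
        D, n = arr.shape[0] // c, arr.shape[1]
        blocks = (arr[i * D : (i + 1) * D] for i in range(c))
    N = n + c - 1
    out = np.zeros((D, N))
    cnt = np.zeros(N)
    for i, blk in enumerate(blocks):
        start = c - 1 - i
        out[:, start : start + n] += blk
        cnt[start : start + n] += 1.0
    out /= cnt
    return out


@dataclass
class ReconstructedSeries:
    """Final NLSA output: standardized and de-standardized reconstructions
    for every original time point, plus run diagnostics."""

    standardized: np.ndarray  # (D, N)
    intensities: np.ndarray  # (D, N), de-standardized
    timestamps: np.ndarray
    index_set: MillerIndexSet
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    def as_volume_series(self) -> VolumeSeries:
        """Uniform-grid view (raises if timestamps are not uniform)."""
        return VolumeSeries(self.index_set, self.intensities, self.timestamps)


def nlsa_run(dense: DenseSeries, cfg: EmbeddingConfig) -> ReconstructedSeries:
    """Run the full NLSA chain on a dense standardized series."""
    N = dense.n_frames
    if cfg.c >= N:
        raise ValueError(f"c={cfg.c} must be smaller than the series length N={N}")
    n = N - cfg.c + 1
    knn, K = cfg.resolved(n)
    X = delay_embed(dense, cfg.c)
    graph = embedded_distances(X, knn)
    basis = diffusion_basis(graph, K, cfg.epsilon_factor, cfg.seed)
    logger.info("kernel eigenvalues: %s", np.array2string(basis.eigenvalues, precision=4))
    A = project(X, basis)
    modes = svd_modes(A)
    logger.info("singular values: %s", np.array2string(modes.s, precision=4))
    x_emb = reconstruct_embedded(modes, basis, cfg.n_modes, cfg.c)
    standardized = diagonal_average(x_emb)
    return ReconstructedSeries(
        standardized=standardized,
        intensities=dense.destandardize(standardized),
        timestamps=dense.timestamps,
        index_set=dense.index_set,
        eigenvalues=basis.eigenvalues,
        singular_values=modes.s,
    )
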