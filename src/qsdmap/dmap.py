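"""Diffusion-map generator approximation on point clouds.

Given samples ``{x_1, ..., x_m}`` drawn from a density, the Gaussian kernel

    K_ij = exp(-|x_i - x_j|^2 / (4 eps))

is density-normalised with exponent ``alpha`` (divide by ``q_i^alpha q_j^alpha``
with ``q`` the kernel density estimate, i.e. the row sums of ``K``), row
normalised to a Markov matrix ``P_eps``, and turned into the scaled graph
Laplacian ``L_eps = (P_eps - I)/eps``.  As ``m -> inf`` and ``eps -> 0`` this
matrix converges point-wise to the operator

    L f = Delta f + (2 - 2 alpha) grad f . grad(pi)/pi ,

which for ``alpha = 1/2`` and Boltzmann-distributed samples
(``pi`` proportional to ``exp(-beta V)``) is ``beta`` times the generator of
overdamped Langevin dynamics.  The dominant eigenvectors are the diffusion
coordinates.

The target-measure variant (TMDmap) right-normalises the kernel with known
target-density values ``pi(x_i)`` so that clouds sampled from a *different*
(e.g. biased) distribution still approximate the generator associated with the
target: ``K_pi = K diag(sqrt(pi)/q)``, ``L_pi = (Dtilde^-1 K_pi - I)/eps`` with
``Dtilde`` the row sums of ``K_pi``.

The module exposes both a functional layer (:func:`build_kernel`,
:func:`build_generator`, ...) and a model/results layer
(:class:`DiffusionMap` -> :class:`DiffusionMapResults`) in the style of
statsmodels estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "KernelMatrix",
    "DensityEstimate",
    "GeneratorMatrix",
    "SpectralDecomposition",
    "build_kernel",
    "kernel_density",
    "build_generator",
    "build_tmdmap",
    "spectral_decompose",
    "nystrom_extend",
    "kernel_bandwidth_diagnostic",
    "DiffusionMap",
    "TargetMeasureDiffusionMap",
    "DiffusionMapResults",
]

_DENSE_EIG_MAX = 600  # below this, use a dense full decomposition


@dataclass
class PointCloud:
    """Samples in d dimensions with optional per-point weights and provenance."""

    points: np.ndarray
    weights: Optional[np.ndarray] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a point cloud needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
            if self.weights.shape[0] != self.points.shape[0]:
                raise ValueError("weights length must match number of points")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive")

    @property
    def m(self):
        return self.points.shape[0]

    @property
    def dim(self):
        return self.points.shape[1]


@dataclass
class KernelMatrix:
    values: object  # (m, m) ndarray or scipy.sparse matrix
    epsilon: float
    cutoff: float

    @property
    def is_sparse(self):
        return sp.issparse(self.values)

    @property
    def m(self):
        return self.values.shape[0]


@dataclass
class DensityEstimate:
    q: np.ndarray


@dataclass
class GeneratorMatrix:
    """eps-scaled graph Laplacian (rows sum to zero, off-diagonal >= 0).

    ``row_sums`` holds the row sums of the alpha-normalised kernel (used to
    symmetrise the eigenproblem); ``right_factor`` holds the TMDmap column
    scaling ``sqrt(pi)/q`` (None for the alpha-normalised kind); ``q`` is the
    kernel density estimate, kept for the Nystrom extension.
    """

    values: object
    epsilon: float
    alpha: float
    kind: str  # "alpha_normalized" | "tmdmap"
    row_sums: np.ndarray
    q: np.ndarray
    right_factor: Optional[np.ndarray] = None

    @property
    def m(self):
        return self.values.shape[0]

    @property
    def is_sparse(self):
        return sp.issparse(self.values)


@dataclass
class SpectralDecomposition:
    """Leading eigenpairs of a generator matrix.

    Eigenvalues are sorted decreasingly starting at ``lambda_0 = 0``;
    eigenvectors have unit 2-norm with the sign fixed so the largest-magnitude
    entry is positive.
    """

    eigenvalues: np.ndarray  # (k + 1,)
    eigenvectors: np.ndarray  # (m, k + 1)
    epsilon: float
    alpha: float
    kind: str
    q: np.ndarray
    right_factor: Optional[np.ndarray] = None
    cutoff: float = 0.0

    @property
    def diffusion_coordinates(self):
        """Nontrivial eigenvectors (columns 1..k): the DC embedding at t = 0."""
        return self.eigenvectors[:, 1:]


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # (|a|^2 + |b|^2 - 2 a.b) clipped at 0 for round-off
    d2 = (np.sum(a * a, axis=1)[:, None] + np.sum(b * b, axis=1)[None, :]
          - 2.0 * a @ b.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def build_kernel(cloud: PointCloud, epsilon: float, cutoff: float = 0.0) -> KernelMatrix:
    """Gaussian kernel matrix ``exp(-|x_i - x_j|^2 / (4 eps))``.

    ``cutoff > 0`` switches to a sparse representation: entries below
    ``cutoff`` are stored as zero (applied symmetrically; the unit diagonal is
    always kept).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    x = cloud.points
    m = x.shape[0]
    if cutoff == 0.0:
        d2 = _pairwise_sq_dists(x, x)
        d2 /= -4.0 * epsilon
        K = np.exp(d2, out=d2)
        # exact symmetry (guards against BLAS round-off asymmetry)
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
        return KernelMatrix(K, epsilon=epsilon, cutoff=0.0)
    r = float(np.sqrt(-4.0 * epsilon * np.log(cutoff))) if cutoff < 1 else 0.0
    tree = cKDTree(x)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        d2 = np.sum((x[i] - x[j]) ** 2, axis=1)
        v = np.exp(-d2 / (4.0 * epsilon))
        keep = v >= cutoff
        i, j, v = i[keep], j[keep], v[keep]
    else:
        i = j = np.empty(0, dtype=int)
        v = np.empty(0)
    rows = np.concatenate([i, j, np.arange(m)])
    cols = np.concatenate([j, i, np.arange(m)])
    vals = np.concatenate([v, v, np.ones(m)])
    K = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return KernelMatrix(K, epsilon=epsilon, cutoff=cutoff)


def kernel_density(kernel: KernelMatrix) -> DensityEstimate:
    """Kernel density estimate: row sums of the kernel matrix."""
    if kernel.is_sparse:
        q = np.asarray(kernel.values.sum(axis=1)).reshape(-1)
    else:
        q = kernel.values.sum(axis=1)
    return DensityEstimate(q=q)


def _check_connected(K, context: str):
    if sp.issparse(K):
        ncomp, labels = csgraph.connected_components(K, directed=False)
        if ncomp > 1:
            sizes = np.bincount(labels)
            raise ValueError(
                f"{context}: kernel graph is disconnected after cutoff "
                f"({ncomp} components with sizes {sizes.tolist()}); "
                "increase epsilon or lower the cutoff"
            )


def build_generator(kernel: KernelMatrix, q: DensityEstimate, alpha: float = 0.5) -> GeneratorMatrix:
    """alpha-normalised graph-Laplacian generator ``(P_eps - I)/eps``.

    Two-step construction: ``A_ij = K_ij / (q_i^alpha q_j^alpha)``, then row
    normalisation ``P = diag(A 1)^-1 A``.  Rows of the result sum to zero.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    qv = q.q
    if np.any(qv <= 0):
        bad = int(np.argmin(qv))
        raise ValueError(f"non-positive kernel density at point {bad}")
    eps = kernel.epsilon
    qa = qv**alpha
    if kernel.is_sparse:
        K = kernel.values
        if np.any(K.getnnz(axis=1) <= 1):
            bad = int(np.argmin(K.getnnz(axis=1)))
            raise ValueError(
                f"point {bad} is isolated after cutoff (no neighbours); "
                "increase epsilon or lower the cutoff"
            )
        _check_connected(K, "build_generator")
        inv = 1.0 / qa
        A = sp.diags(inv) @ K @ sp.diags(inv)
        d = np.asarray(A.sum(axis=1)).reshape(-1)
        L = sp.diags(1.0 / d) @ A
        L = (L - sp.identity(L.shape[0], format=L.format)) / eps
        L = L.tocsr()
    else:
        A = kernel.values / qa[:, None]
        A /= qa[None, :]
        d = A.sum(axis=1)
        A /= d[:, None]  # now the Markov matrix P
        idx = np.arange(A.shape[0])
        A[idx, idx] -= 1.0
        A /= eps
        L = A
    return GeneratorMatrix(L, epsilon=eps, alpha=alpha, kind="alpha_normalized",
                           row_sums=d, q=qv)


def build_tmdmap(kernel: KernelMatrix, q: DensityEstimate, target_density: np.ndarray) -> GeneratorMatrix:
    """Target-measure diffusion map generator.

    ``K_pi = K diag(sqrt(pi)/q)``; with ``Dtilde`` the diagonal of row sums of
    ``K_pi``, the generator is ``(Dtilde^-1 K_pi - I)/eps``.  Any positive
    scaling of the (unnormalised) target density leaves the result unchanged.
    """
    pi = np.asarray(target_density, dtype=float).reshape(-1)
    if pi.shape[0] != kernel.m:
        raise ValueError("target_density length must match the cloud size")
    if np.any(pi <= 0) or not np.all(np.isfinite(pi)):
        raise ValueError("target density must be strictly positive and finite")
    qv = q.q
    c = np.sqrt(pi) / qv
    eps = kernel.epsilon
    if kernel.is_sparse:
        _check_connected(kernel.values, "build_tmdmap")
        Kpi = kernel.values @ sp.diags(c)
        dt = np.asarray(Kpi.sum(axis=1)).reshape(-1)
        L = sp.diags(1.0 / dt) @ Kpi
        L = ((L - sp.identity(L.shape[0], format="csr")) / eps).tocsr()
    else:
        Kpi = kernel.values * c[None, :]
        dt = Kpi.sum(axis=1)
        Kpi /= dt[:, None]
        idx = np.arange(Kpi.shape[0])
        Kpi[idx, idx] -= 1.0
        Kpi /= eps
        L = Kpi
    return GeneratorMatrix(L, epsilon=eps, alpha=0.5, kind="tmdmap",
                           row_sums=dt, q=qv, right_factor=c)


def _fix_conventions(vals: np.ndarray, vecs: np.ndarray):
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        v = vecs[:, j]
        n = np.linalg.norm(v)
        if n > 0:
            v /= n
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
        vecs[:, j] = v
    return vals, vecs


def spectral_decompose(generator: GeneratorMatrix, k: int, seed: int = 0) -> SpectralDecomposition:
    """Leading ``k + 1`` eigenpairs of the generator (closest to zero).

    The alpha-normalised generator is similar to a symmetric matrix
    ``S = D^{1/2} P D^{-1/2}`` (``D`` = row sums of the normalised kernel), so
    its eigenpairs are computed with a symmetric solver and mapped back; the
    TMDmap generator goes through the non-symmetric ARPACK path on ``P`` and
    imaginary parts above tolerance raise.  The start vector is deterministic,
    derived from ``seed``.
    """
    m = generator.m
    if not 1 <= k < m:
        raise ValueError(f"need 1 <= k < m, got k={k}, m={m}")
    eps = generator.epsilon
    L = generator.values
    d = generator.row_sums
    if generator.kind == "alpha_normalized":
        sq = np.sqrt(d)
        if generator.is_sparse:
            P = eps * L + sp.identity(m, format="csr")
            S = sp.diags(sq) @ P @ sp.diags(1.0 / sq)
            S = 0.5 * (S + S.T)
            if m <= _DENSE_EIG_MAX:
                s_vals, s_vecs = scipy.linalg.eigh(S.toarray())
                s_vals, s_vecs = s_vals[-(k + 1):], s_vecs[:, -(k + 1):]
            else:
                v0 = np.random.default_rng(seed).standard_normal(m)
                s_vals, s_vecs = spla.eigsh(S, k=k + 1, which="LA", v0=v0,
                                            tol=1e-10)
        else:
            P = eps * L + np.eye(m)
            P *= sq[:, None]
            P /= sq[None, :]
            S = 0.5 * (P + P.T)
            del P
            if m <= _DENSE_EIG_MAX:
                s_vals, s_vecs = scipy.linalg.eigh(S)
                s_vals, s_vecs = s_vals[-(k + 1):], s_vecs[:, -(k + 1):]
            else:
                v0 = np.random.default_rng(seed).standard_normal(m)
                s_vals, s_vecs = spla.eigsh(S, k=k + 1, which="LA", v0=v0,
                                            tol=1e-10)
        vals = (s_vals - 1.0) / eps
        vecs = s_vecs / sq[:, None]
    else:  # tmdmap: non-symmetric
        if generator.is_sparse:
            P = eps * L + sp.identity(m, format="csr")
        else:
            P = eps * L + np.eye(m)
        if m <= _DENSE_EIG_MAX:
            w, V = scipy.linalg.eig(P if not sp.issparse(P) else P.toarray())
            order = np.argsort(w.real)[::-1][: k + 1]
            w, V = w[order], V[:, order]
        else:
            v0 = np.random.default_rng(seed).standard_normal(m)
            w, V = spla.eigs(P, k=k + 1, which="LR", v0=v0, tol=1e-10)
        scale = np.max(np.abs(w.real)) if w.size else 1.0
        if np.max(np.abs(w.imag)) > 1e-8 * max(scale, 1.0):
            raise RuntimeError(
                "TMDmap eigenvalues have non-negligible imaginary parts "
                f"(max |Im| = {np.max(np.abs(w.imag)):.3e}); the kernel graph "
                "may be too sparse or epsilon too small"
            )
        if np.max(np.abs(V.imag)) > 1e-6:
            raise RuntimeError("TMDmap eigenvectors are significantly complex")
        vals = (w.real - 1.0) / eps
        vecs = V.real
    vals, vecs = _fix_conventions(vals, vecs)
    return SpectralDecomposition(
        eigenvalues=vals, eigenvectors=vecs, epsilon=eps,
        alpha=generator.alpha, kind=generator.kind, q=generator.q,
        right_factor=generator.right_factor,
    )


def nystrom_extend(
    decomposition: SpectralDecomposition,
    cloud: PointCloud,
    new_points: np.ndarray,
    j: int,
) -> np.ndarray:
    """Out-of-sample extension of eigenvector ``j`` to arbitrary points.

    The extension divides the re-evaluated, normalised kernel row by the
    Markov-matrix eigenvalue ``1 + eps * lambda_j``, which makes it exact at
    the training points (the eigen-equation itself).
    """
    lam = decomposition.eigenvalues[j]
    mu = 1.0 + decomposition.epsilon * lam
    if abs(mu) < 1e-14:
        raise ZeroDivisionError(
            f"eigenvector {j} has Markov eigenvalue 1 + eps*lambda = 0; "
            "it cannot be Nystrom-extended"
        )
    x = cloud.points
    new = np.atleast_2d(np.asarray(new_points, dtype=float))
    d2 = _pairwise_sq_dists(new, x)
    kx = np.exp(-d2 / (4.0 * decomposition.epsilon))
    if decomposition.kind == "alpha_normalized":
        w = kx / decomposition.q[None, :] ** decomposition.alpha
    else:
        w = kx * decomposition.right_factor[None, :]
    w /= w.sum(axis=1)[:, None]
    return (w @ decomposition.eigenvectors[:, j]) / mu


def kernel_bandwidth_diagnostic(cloud: PointCloud, epsilons: np.ndarray) -> np.ndarray:
    """log-log data (eps, sum_ij K_ij) used to guide the choice of epsilon.

    In the well-scaled regime the log-log slope is about d/2; the returned
    array has columns (epsilon, total kernel mass).
    """
    out = []
    for eps in np.asarray(epsilons, dtype=float):
        K = build_kernel(cloud, float(eps)).values
        out.append((float(eps), float(K.sum())))
    return np.asarray(out)


# --------------------------------------------------------------------------
# Model / results layer
# --------------------------------------------------------------------------


class DiffusionMap:
    """Diffusion-map model for a point cloud.

    Parameters
    ----------
    data : array_like or PointCloud
        (m, d) samples.
    epsilon : float
        Kernel bandwidth (required; no silent default).
    alpha : float
        Density-normalisation exponent in [0, 1]; 1/2 targets the Langevin
        generator when the samples are Boltzmann-distributed.
    cutoff : float
        Kernel sparsity cutoff; 0 keeps the dense path.
    """

    kind = "alpha_normalized"

    def __init__(self, data, epsilon: float, alpha: float = 0.5,
                 cutoff: float = 0.0, metadata: Optional[dict] = None):
        self.cloud = data if isinstance(data, PointCloud) else PointCloud(
            np.asarray(data, dtype=float), metadata=metadata or {})
        self.epsilon = float(epsilon)
        self.alpha = float(alpha)
        self.cutoff = float(cutoff)

    @classmethod
    def from_trajectory(cls, trajectory, epsilon: float, subsample: int = 1,
                        **kw):
        """Build the model from a :class:`~qsdmap.dynamics.Trajectory`."""
        pts = trajectory.points[::subsample]
        meta = {"potential": trajectory.potential_name, "beta": trajectory.beta,
                "dt": trajectory.dt, "seed": trajectory.seed,
                "scheme": trajectory.scheme, "subsample": subsample}
        return cls(pts, epsilon, metadata=meta, **kw)

    def _generator(self) -> GeneratorMatrix:
        kernel = build_kernel(self.cloud, self.epsilon, self.cutoff)
        q = kernel_density(kernel)
        return build_generator(kernel, q, self.alpha)

    def fit(self, k: int = 10, seed: int = 0) -> "DiffusionMapResults":
        """Construct the generator and compute its leading ``k + 1`` eigenpairs."""
        gen = self._generator()
        dec = spectral_decompose(gen, k, seed=seed)
        return DiffusionMapResults(self, gen, dec)


class TargetMeasureDiffusionMap(DiffusionMap):
    """TMDmap model: reweights the kernel towards known target-density values."""

    kind = "tmdmap"

    def __init__(self, data, epsilon: float, target_density,
                 cutoff: float = 0.0, metadata: Optional[dict] = None):
        super().__init__(data, epsilon, alpha=0.5, cutoff=cutoff,
                         metadata=metadata)
        self.target_density = np.asarray(target_density, dtype=float).reshape(-1)

    def _generator(self) -> GeneratorMatrix:
        kernel = build_kernel(self.cloud, self.epsilon, self.cutoff)
        q = kernel_density(kernel)
        return build_tmdmap(kernel, q, self.target_density)


class DiffusionMapResults:
    """Fitted diffusion map: spectrum, embedding and downstream solvers."""

    def __init__(self, model: DiffusionMap, generator: GeneratorMatrix,
                 decomposition: SpectralDecomposition):
        self.model = model
        self.generator = generator
        self.decomposition = decomposition

    @property
    def eigenvalues(self):
        return self.decomposition.eigenvalues

    @property
    def eigenvectors(self):
        return self.decomposition.eigenvectors

    @property
    def diffusion_coordinates(self):
        return self.decomposition.diffusion_coordinates

    def nystrom(self, new_points, j: int) -> np.ndarray:
        return nystrom_extend(self.decomposition, self.model.cloud,
                              new_points, j)

    def committor(self, idxA, idxB):
        from .dirichlet import solve_committor
        return solve_committor(self.generator, idxA, idxB)

    def dirichlet_spectrum(self, domain_idx, k: int):
        from .dirichlet import solve_dirichlet_eigen
        return solve_dirichlet_eigen(self.generator, domain_idx, k)

    def metastable_sets(self, threshold: float, embedding_dim: int = 1):
        from .metastability import identify_metastable_sets
        return identify_metastable_sets(self.decomposition, threshold,
                                        embedding_dim)

    def dc_correlation(self, coordinates=None):
        from .metastability import local_global_dc_correlation
        coords = (self.model.cloud.points if coordinates is None
                  else np.asarray(coordinates, dtype=float))
        return local_global_dc_correlation(self.decomposition, coords)

    def summary(self) -> str:
        m, d = self.model.cloud.points.shape
        lines = [
            "Diffusion map results",
            "=" * 52,
            f"kind            {self.decomposition.kind}",
            f"points          {m}  (dimension {d})",
            f"epsilon         {self.model.epsilon:g}",
            f"alpha           {self.model.alpha:g}",
            f"cutoff          {self.model.cutoff:g}",
            "-" * 52,
            "  j    eigenvalue      spectral gap to previous",
        ]
        ev = self.eigenvalues
        for j, lam in enumerate(ev):
            gap = "" if j == 0 else f"{ev[j - 1] - lam: .6g}"
            lines.append(f"{j:>3d}   {lam: .8g}    {gap}")
        lines.append("=" * 52)
        return "\n".join(lines)
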