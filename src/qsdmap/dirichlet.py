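"""Committor and Dirichlet eigenproblem solvers.

Two discretisations live here:

* point-cloud solvers that act on a diffusion-map generator matrix (the
  committor linear system and the Dirichlet eigenproblem on an index set), and
* a 1-D Chebyshev pseudo-spectral reference solver for the operator
  ``L = -beta V'(x) d/dx + d^2/dx^2`` (the same time-rescaled convention the
  point-cloud generator approximates, so eigenvalues are directly comparable),
  used for quasi-stationary distributions and for validation.

The committor between sets A and B solves ``L q = 0`` off A and B with
``q = 0`` on A and ``q = 1`` on B; on the point cloud this is the linear
system ``L[c,c] q[c] = -L[c,b] 1`` over the free indices ``c``.

The quasi-stationary distribution (QSD) on a domain is
``nu(x) = v(x) e^{-beta V} / int v e^{-beta V}`` with ``v`` the first
Dirichlet eigenfunction of the generator; ``v`` is normalised here so that
its mean against the Boltzmann measure restricted to the domain is one, which
turns "v -> 1 as the domain grows" into a quantitative statement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dmap import GeneratorMatrix
from .potentials import Potential

__all__ = [
    "CommittorField",
    "DirichletSpectrum",
    "QSDResult",
    "solve_committor",
    "solve_dirichlet_eigen",
    "chebyshev_solve_1d",
    "chebyshev_dirichlet",
    "chebyshev_committor",
    "qsd_density",
    "chebyshev_lobatto",
    "clenshaw_curtis_weights",
    "barycentric_interpolate",
]

_DIRECT_SOLVE_MAX = 20_000  # unknowns; above this use preconditioned GMRES


# --------------------------------------------------------------------------
# Point-cloud solvers
# --------------------------------------------------------------------------


@dataclass
class CommittorField:
    """Per-point committor values with the defining index sets.

    ``flagged`` marks points whose value left [-0.05, 1.05] (the discrete
    maximum principle holds only approximately); values are never clamped.
    """

    values: np.ndarray
    idxA: np.ndarray
    idxB: np.ndarray
    flagged: np.ndarray = field(default=None)

    @property
    def n_flagged(self):
        return int(np.sum(self.flagged))


def _as_index_set(idx, m, name):
    idx = np.unique(np.asarray(idx, dtype=int).reshape(-1))
    if idx.size == 0:
        raise ValueError(f"index set {name} is empty")
    if idx.min() < 0 or idx.max() >= m:
        raise ValueError(f"index set {name} out of range for m={m}")
    return idx


def solve_committor(generator: GeneratorMatrix, idxA, idxB) -> CommittorField:
    """Committor of reaching B before A, from the generator linear system."""
    m = generator.m
    a = _as_index_set(idxA, m, "A")
    b = _as_index_set(idxB, m, "B")
    if np.intersect1d(a, b).size:
        raise ValueError("sets A and B must be disjoint")
    mask = np.ones(m, dtype=bool)
    mask[a] = False
    mask[b] = False
    c = np.nonzero(mask)[0]
    if c.size == 0:
        raise ValueError("the free set C = complement(A | B) is empty")
    L = generator.values
    if sp.issparse(L):
        Lcc = L[c][:, c].tocsr()
        rhs = -np.asarray(L[c][:, b].sum(axis=1)).reshape(-1)
        if c.size <= _DIRECT_SOLVE_MAX:
            qc = spla.spsolve(Lcc.tocsc(), rhs)
        else:
            M = spla.LinearOperator(
                (c.size, c.size),
                matvec=lambda v: v / Lcc.diagonal(),
            )
            qc, info = spla.gmres(Lcc, rhs, M=M, rtol=1e-10, atol=0.0)
            if info != 0:
                raise RuntimeError(f"GMRES failed to converge (info={info})")
    else:
        Lcc = L[np.ix_(c, c)]
        rhs = -L[np.ix_(c, b)].sum(axis=1)
        try:
            qc = scipy.linalg.solve(Lcc, rhs)
        except scipy.linalg.LinAlgError as err:
            raise RuntimeError(
                "committor subsystem is singular; the free set C likely "
                "contains a block disconnected from A and B"
            ) from err
    resid = np.linalg.norm(Lcc @ qc - rhs)
    scale = np.linalg.norm(rhs) + 1.0
    if not np.all(np.isfinite(qc)) or resid > 1e-6 * scale:
        raise RuntimeError(
            "committor solve failed (non-finite solution or residual "
            f"{resid:.3e}); the free set C likely contains a block "
            "disconnected from A and B"
        )
    values = np.empty(m)
    values[a] = 0.0
    values[b] = 1.0
    values[c] = qc
    flagged = (values < -0.05) | (values > 1.05)
    return CommittorField(values=values, idxA=a, idxB=b, flagged=flagged)


@dataclass
class DirichletSpectrum:
    """Eigenpairs of the generator restricted to a domain index set.

    Eigenvectors are embedded back into full length with zeros outside the
    domain; eigenvalues are strictly negative, sorted decreasingly, and
    ``first_eigenvalue`` is the (time-rescaled) exit rate ``-lambda_1``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (m, k), zero outside the domain
    domain_idx: np.ndarray

    @property
    def first_eigenvalue(self):
        return float(self.eigenvalues[0])


def solve_dirichlet_eigen(generator: GeneratorMatrix, domain_idx, k: int,
                          seed: int = 0) -> DirichletSpectrum:
    """Leading ``k`` eigenpairs of the principal submatrix ``L[Omega, Omega]``.

    Restricting to the principal submatrix realises homogeneous Dirichlet
    conditions on the point cloud: it gives the same eigenpairs as zeroing the
    exterior rows for vectors supported inside the domain, while keeping the
    matrix well-conditioned.
    """
    m = generator.m
    idx = _as_index_set(domain_idx, m, "Omega")
    if idx.size <= k:
        raise ValueError(f"need |Omega| > k, got |Omega|={idx.size}, k={k}")
    eps = generator.epsilon
    L = generator.values
    if sp.issparse(L):
        sub = L[idx][:, idx].tocsr()
        P = (eps * sub + sp.identity(idx.size, format="csr")).tocsr()
    else:
        P = eps * L[np.ix_(idx, idx)] + np.eye(idx.size)
    if generator.kind == "alpha_normalized":
        sq = np.sqrt(generator.row_sums[idx])
        if sp.issparse(P):
            S = sp.diags(sq) @ P @ sp.diags(1.0 / sq)
            S = 0.5 * (S + S.T)
            if idx.size <= 600:
                s_vals, s_vecs = scipy.linalg.eigh(S.toarray())
                s_vals, s_vecs = s_vals[-k:], s_vecs[:, -k:]
            else:
                v0 = np.random.default_rng(seed).standard_normal(idx.size)
                s_vals, s_vecs = spla.eigsh(S, k=k, which="LA", v0=v0, tol=1e-10)
        else:
            S = P * sq[:, None] / sq[None, :]
            S = 0.5 * (S + S.T)
            if idx.size <= 600:
                s_vals, s_vecs = scipy.linalg.eigh(S)
                s_vals, s_vecs = s_vals[-k:], s_vecs[:, -k:]
            else:
                v0 = np.random.default_rng(seed).standard_normal(idx.size)
                s_vals, s_vecs = spla.eigsh(S, k=k, which="LA", v0=v0, tol=1e-10)
        vals = (s_vals - 1.0) / eps
        vecs = s_vecs / sq[:, None]
    else:
        if idx.size <= 600:
            w, V = scipy.linalg.eig(P.toarray() if sp.issparse(P) else P)
            order = np.argsort(w.real)[::-1][:k]
            w, V = w[order], V[:, order]
        else:
            v0 = np.random.default_rng(seed).standard_normal(idx.size)
            w, V = spla.eigs(P, k=k, which="LR", v0=v0, tol=1e-10)
        if np.max(np.abs(w.imag)) > 1e-8:
            raise RuntimeError("Dirichlet eigenvalues have imaginary parts")
        vals = (w.real - 1.0) / eps
        vecs = V.real
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    full = np.zeros((m, k))
    for j in range(k):
        v = vecs[:, j]
        n = np.linalg.norm(v)
        if n > 0:
            v = v / n
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        full[idx, j] = v
    return DirichletSpectrum(eigenvalues=vals, eigenvectors=full,
                             domain_idx=idx)


# --------------------------------------------------------------------------
# Chebyshev pseudo-spectral reference (1-D)
# --------------------------------------------------------------------------


def chebyshev_lobatto(n: int, a: float = -1.0, b: float = 1.0):
    """Differentiation matrix and Gauss–Lobatto nodes on [a, b].

    Nodes run from ``b`` down to ``a`` (standard cos ordering); returns
    ``(D, x)`` with ``D`` the (n+1)x(n+1) first-derivative matrix.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    j = np.arange(n + 1)
    xi = np.cos(np.pi * j / n)
    c = np.ones(n + 1)
    c[0] = c[n] = 2.0
    c *= (-1.0) ** j
    X = np.tile(xi, (n + 1, 1)).T
    dX = X - X.T
    D = np.outer(c, 1.0 / c) / (dX + np.eye(n + 1))
    D -= np.diag(D.sum(axis=1))
    x = 0.5 * (a + b) + 0.5 * (b - a) * xi
    D *= 2.0 / (b - a)
    return D, x


def clenshaw_curtis_weights(n: int, a: float = -1.0, b: float = 1.0) -> np.ndarray:
    """Clenshaw–Curtis quadrature weights on the Gauss–Lobatto nodes."""
    theta = np.pi * np.arange(n + 1) / n
    w = np.zeros(n + 1)
    v = np.ones(n - 1)
    if n % 2 == 0:
        w[0] = w[n] = 1.0 / (n * n - 1)
        for k in range(1, n // 2):
            v -= 2.0 * np.cos(2 * k * theta[1:n]) / (4 * k * k - 1)
        v -= np.cos(n * theta[1:n]) / (n * n - 1)
    else:
        w[0] = w[n] = 1.0 / (n * n)
        for k in range(1, (n - 1) // 2 + 1):
            v -= 2.0 * np.cos(2 * k * theta[1:n]) / (4 * k * k - 1)
    w[1:n] = 2.0 * v / n
    return 0.5 * (b - a) * w


def barycentric_interpolate(x_nodes: np.ndarray, values: np.ndarray,
                            x_eval) -> np.ndarray:
    """Barycentric interpolation from Chebyshev–Lobatto nodes (stable)."""
    n = x_nodes.size - 1
    wj = (-1.0) ** np.arange(n + 1)
    wj[0] *= 0.5
    wj[n] *= 0.5
    xe = np.atleast_1d(np.asarray(x_eval, dtype=float))
    out = np.empty_like(xe)
    for i, xv in enumerate(xe):
        diff = xv - x_nodes
        hit = np.isclose(diff, 0.0, atol=1e-14)
        if hit.any():
            out[i] = values[np.argmax(hit)]
        else:
            t = wj / diff
            out[i] = np.sum(t * values) / np.sum(t)
    return out if np.ndim(x_eval) else float(out[0])


def _cheb_operator(potential: Potential, beta: float, a: float, b: float,
                   n: int):
    D, x = chebyshev_lobatto(n, a, b)
    D2 = D @ D
    gradV = potential.gradient_many(x[:, None])[:, 0]
    A = D2 - beta * np.diag(gradV) @ D
    return A, x


@dataclass
class QSDResult:
    """Quasi-stationary distribution of a 1-D domain.

    ``v`` is the first Dirichlet eigenfunction on the Chebyshev grid,
    normalised to unit mean against the Boltzmann measure restricted to the
    domain; ``nu`` is the QSD density (integrates to one); ``rate`` is the
    first exit rate ``lambda > 0`` in the time-rescaled (beta L_beta)
    convention.
    """

    grid: np.ndarray
    v: np.ndarray
    nu: np.ndarray
    rate: float
    L: float
    beta: float
    resolution_warning: Optional[str] = None

    def v_at(self, x):
        return barycentric_interpolate(self.grid, self.v, x)

    def nu_at(self, x):
        return barycentric_interpolate(self.grid, self.nu, x)


def chebyshev_dirichlet(potential: Potential, beta: float, a: float, b: float,
                        n: int, k: int = 5):
    """Dirichlet eigenpairs of ``-beta V' d/dx + d^2/dx^2`` on (a, b).

    Returns ``(eigenvalues, eigenfunctions, grid)``; eigenfunctions are grid
    values on all n+1 nodes (zero at the ends), columns sorted by decreasing
    eigenvalue and normalised to unit continuous L2 norm on (a, b).
    """
    if n < 16:
        raise ValueError("n must be >= 16 for a meaningful resolution")
    A, x = _cheb_operator(potential, beta, a, b, n)
    interior = slice(1, n)
    w_full = clenshaw_curtis_weights(n, a, b)
    vals, vecs = scipy.linalg.eig(A[interior, interior])
    if np.max(np.abs(vals.imag)) > 1e-6 * np.max(np.abs(vals.real)):
        # keep only (dominant) real part; pseudo-spectral non-normal round-off
        pass
    order = np.argsort(vals.real)[::-1][:k]
    lam = vals.real[order]
    funcs = np.zeros((n + 1, k))
    for j in range(k):
        f = np.zeros(n + 1)
        f[interior] = vecs[:, order[j]].real
        norm = np.sqrt(np.sum(w_full * f * f))
        f /= norm
        if f[np.argmax(np.abs(f))] < 0:
            f = -f
        funcs[:, j] = f
    return lam, funcs, x


def chebyshev_committor(potential: Potential, beta: float, a: float, b: float,
                        n: int):
    """Committor ``q`` on [a, b] with q(a)=0, q(b)=1; returns (grid, values)."""
    if n < 16:
        raise ValueError("n must be >= 16 for a meaningful resolution")
    A, x = _cheb_operator(potential, beta, a, b, n)
    q = np.empty(n + 1)
    q[0] = 1.0   # node 0 is x = b
    q[n] = 0.0   # node n is x = a
    interior = np.arange(1, n)
    rhs = -A[interior, 0] * 1.0
    q[interior] = scipy.linalg.solve(A[np.ix_(interior, interior)], rhs)
    return x, q


def qsd_density(v_grid, potential: Potential, beta: float, L: float,
                grid: Optional[np.ndarray] = None, rate: float = np.nan,
                warning: Optional[str] = None) -> QSDResult:
    """Normalise a first Dirichlet eigenfunction into a QSD on [-L, L].

    ``v_grid`` may be grid values on the Chebyshev–Lobatto nodes or a callable;
    ``grid`` defaults to the Lobatto nodes inferred from the length of
    ``v_grid``.  Returns the renormalised ``v`` (unit mean against the
    restricted Boltzmann measure) and the QSD density ``nu`` (unit integral).
    """
    if callable(v_grid):
        if grid is None:
            raise ValueError("a grid is required when v is callable")
        v = np.asarray([float(v_grid(x)) for x in grid])
    else:
        v = np.asarray(v_grid, dtype=float)
        if grid is None:
            _, grid = chebyshev_lobatto(v.size - 1, -L, L)
    n = grid.size - 1
    w = clenshaw_curtis_weights(n, float(grid.min()), float(grid.max()))
    interior = v[1:-1]
    if np.any(interior <= 0):
        if np.all(interior < 0):
            v = -v  # overall sign is arbitrary
        elif np.min(interior) > -1e-12 * np.max(np.abs(v)):
            v = np.maximum(v, 0.0)  # boundary-layer round-off
        else:
            raise ValueError(
                "the first eigenfunction must be positive in the interior"
            )
    boltz = np.exp(-beta * potential.value_many(grid[:, None]))
    zb = np.sum(w * boltz)
    mean_v = np.sum(w * v * boltz) / zb
    v = v / mean_v
    weight = v * boltz
    znu = np.sum(w * weight)
    nu = weight / znu
    return QSDResult(grid=grid, v=v, nu=nu, rate=rate, L=L, beta=beta,
                     resolution_warning=warning)


def qsd_generator_spectrum_1d(qsd: "QSDResult", k: int = 3,
                              n_grid: int = 2000) -> np.ndarray:
    """Leading eigenvalues of the QSD-tilted generator ``Delta + grad(ln nu) . grad``.

    This is the operator a diffusion map built on quasi-stationary samples
    approximates (alpha = 1/2).  Discretised in self-adjoint flux form
    ``nu^{-1} d/dx (nu d/dx .)`` on a uniform grid with natural (zero-flux)
    boundaries — the weight ``nu`` itself vanishes at the domain ends, which
    encodes the confinement.  Returns ``k + 1`` eigenvalues sorted
    decreasingly starting at 0.
    """
    a, b = float(qsd.grid.min()), float(qsd.grid.max())
    x = np.linspace(a, b, n_grid)
    h = x[1] - x[0]
    m = np.maximum(qsd.nu_at(x), 0.0)
    floor = 1e-13 * m.max()
    m = m + floor  # keeps the weight matrix positive definite
    mh = 0.5 * (m[1:] + m[:-1])
    A = np.zeros((n_grid, n_grid))
    idx = np.arange(n_grid)
    A[idx[1:], idx[:-1]] = mh / h**2
    A[idx[:-1], idx[1:]] = mh / h**2
    A[idx, idx] = -(np.concatenate([[0.0], mh]) +
                    np.concatenate([mh, [0.0]])) / h**2
    w = scipy.linalg.eigh(A, np.diag(m), eigvals_only=True)
    w = np.sort(w)[::-1]
    return w[: k + 1]


def chebyshev_solve_1d(potential: Potential, beta: float, L: float = None,
                       n: int = 256, problem="dirichlet_eigen",
                       interval: Optional[Sequence[float]] = None,
                       check_resolution: bool = True, max_n: int = 2048):
    """Dispatcher for the 1-D pseudo-spectral solver.

    ``problem`` is either ``"dirichlet_eigen"`` (returns a :class:`QSDResult`
    on [-L, L]) or ``("committor", a, b)`` (returns ``(grid, values)``).

    With ``check_resolution`` (the default) the grid is doubled until both
    the first eigenvalue and the eigenfunction (probed at equispaced interior
    points after Boltzmann normalisation) stop moving — the boundary layer of
    the first Dirichlet eigenfunction becomes exponentially thin on large
    domains, and an under-resolved layer pollutes the whole eigenvector.  If
    the cap ``max_n`` is hit first, a warning is recorded on the result.
    """
    if isinstance(problem, (tuple, list)) and problem[0] == "committor":
        _, a, b = problem
        return chebyshev_committor(potential, beta, float(a), float(b), n)
    if problem != "dirichlet_eigen":
        raise ValueError(f"unknown problem {problem!r}")
    if interval is not None:
        a, b = float(interval[0]), float(interval[1])
    else:
        if L is None:
            raise ValueError("specify L (half-width) or an interval")
        a, b = -float(L), float(L)
    half = 0.5 * (b - a)

    def _solve(nn):
        lam, funcs, x = chebyshev_dirichlet(potential, beta, a, b, nn, k=1)
        return qsd_density(funcs[:, 0], potential, beta, half, grid=x,
                           rate=-lam[0])

    res = None
    while res is None:
        try:
            res = _solve(n)
        except ValueError:
            # sign-indefinite eigenvector: grid too coarse for the boundary
            # layer; refine and retry
            if not check_resolution or 2 * n > max_n:
                raise
            n *= 2
    warning = None
    if check_resolution:
        probes = np.linspace(a, b, 35)[1:-1]
        while True:
            if 2 * n > max_n:
                warning = (f"eigenfunction not converged at the grid cap "
                           f"n={n}; results may be under-resolved")
                warnings.warn(warning, RuntimeWarning, stacklevel=2)
                break
            res2 = _solve(2 * n)
            lam_drift = abs(res.rate - res2.rate)
            v_drift = float(np.max(np.abs(res.v_at(probes) - res2.v_at(probes))))
            res = res2
            n *= 2
            if lam_drift < 1e-8 and v_drift < 1e-6:
                break
    res.resolution_warning = warning
    return res
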