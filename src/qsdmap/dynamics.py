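"""Stochastic samplers: overdamped Langevin, metadynamics, Fleming–Viot.

Conventions
-----------
* Overdamped Langevin: ``dx = -grad V(x) dt + sqrt(2/beta) dW``; the discrete
  noise increment is ``sqrt(2 dt / beta) * xi`` with ``xi ~ N(0, I)``.
  ``beta = inf`` is accepted and gives plain gradient descent (zero noise).
* Integrators: ``"euler"`` is Euler–Maruyama; ``"lm"`` is the
  Leimkuhler–Matthews postprocessed step, which averages successive noise
  increments, ``x_{n+1} = x_n - grad V(x_n) dt + sqrt(2 dt/beta) (xi_n + xi_{n+1})/2``,
  and is second-order accurate for sampling the Boltzmann measure.
* Randomness: each public operation takes an integer ``seed``.  A single
  trajectory uses ``numpy.random.default_rng(seed)``; ensembles derive one
  independent substream per replica via ``numpy.random.SeedSequence(seed).spawn(n)``
  (this derivation is part of the API and is relied on by tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .potentials import Potential

__all__ = [
    "Trajectory",
    "BiasState",
    "ReplicaEnsemble",
    "CollectiveVariable",
    "simulate_overdamped",
    "simulate_metadynamics",
    "evaluate_bias",
    "fleming_viot",
    "replica_seed_sequences",
]

_SCHEMES = ("euler", "lm")
_CHUNK = 16384  # noise draws per block; amortises RNG call overhead


@dataclass
class Trajectory:
    """A discretised sample path: ``points[0]`` is the initial condition."""

    points: np.ndarray  # (n_steps + 1, d)
    dt: float
    beta: float
    seed: int
    scheme: str
    potential_name: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1:
            raise ValueError("trajectory must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise FloatingPointError("trajectory contains non-finite entries")

    def __len__(self):
        return self.points.shape[0]


@dataclass
class BiasState:
    """Accumulated metadynamics bias: Gaussian hills along a scalar CV.

    ``V_bias(z) = sum_k height * exp(-(z - z_k)^2 / (2 width^2))``.
    """

    height: float
    width: float
    stride: int
    centers: List[float] = field(default_factory=list)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("hill width must be positive")
        if self.stride < 1:
            raise ValueError("deposition stride must be >= 1")


def evaluate_bias(bias: BiasState, z: float) -> tuple[float, float]:
    """Bias potential and its derivative at CV value ``z``."""
    if not bias.centers or bias.height == 0.0:
        return 0.0, 0.0
    c = np.asarray(bias.centers, dtype=float)
    u = (z - c) / bias.width
    g = bias.height * np.exp(-0.5 * u * u)
    value = float(np.sum(g))
    deriv = float(np.sum(-g * u / bias.width))
    return value, deriv


@dataclass
class CollectiveVariable:
    """Scalar function of configuration with an (optionally numerical) gradient."""

    name: str
    fn: Callable[[np.ndarray], float]
    grad: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def value(self, x: np.ndarray) -> float:
        return float(self.fn(np.asarray(x, dtype=float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.grad is not None:
            return np.asarray(self.grad(x), dtype=float)
        h = 1e-6
        g = np.empty_like(x)
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (self.fn(x + e) - self.fn(x - e)) / (2 * h)
        return g

    def values(self, xs: np.ndarray) -> np.ndarray:
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        return np.array([self.fn(x) for x in xs])


def _noise_amplitude(beta: float, dt: float) -> float:
    if np.isinf(beta):
        return 0.0
    return float(np.sqrt(2.0 * dt / beta))


def _integrate(
    potential: Potential,
    beta: float,
    dt: float,
    n_steps: int,
    x0: np.ndarray,
    rng: np.random.Generator,
    scheme: str,
    bias: Optional[BiasState] = None,
    cv: Optional[CollectiveVariable] = None,
    record_stride: int = 1,
    static_biases: Sequence[tuple] = (),
) -> np.ndarray:
    """Core integration loop shared by the plain and biased samplers.

    Returns the recorded points, always including the initial condition.  When
    ``bias`` is given, a hill is deposited at the current CV value after every
    ``bias.stride``-th step and the biasing force ``-dV_bias/dz * grad cv`` is
    applied along with ``-grad V``.  ``static_biases`` is a sequence of
    ``(BiasState, CollectiveVariable)`` pairs whose forces act without
    receiving new hills (bias accumulated in earlier iterations of the
    adaptive loop).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    x = np.asarray(x0, dtype=float).reshape(-1)
    if x.shape[0] != potential.dimension:
        raise ValueError(
            f"x0 has dimension {x.shape[0]}, potential expects {potential.dimension}"
        )
    d = x.shape[0]
    amp = _noise_amplitude(beta, dt)
    out = [x.copy()]

    xi_prev = rng.standard_normal(d) if scheme == "lm" else None
    done = 0
    while done < n_steps:
        block = min(_CHUNK, n_steps - done)
        noise = rng.standard_normal((block, d))
        for k in range(block):
            step = done + k + 1
            force = -potential.gradient(x)
            if bias is not None and bias.height != 0.0:
                _, dvb = evaluate_bias(bias, cv.value(x))
                if dvb != 0.0:
                    force = force - dvb * cv.gradient(x)
            for sb, scv in static_biases:
                if sb.height != 0.0 and sb.centers:
                    _, dvb = evaluate_bias(sb, scv.value(x))
                    if dvb != 0.0:
                        force = force - dvb * scv.gradient(x)
            if scheme == "euler":
                x = x + dt * force + amp * noise[k]
            else:  # Leimkuhler–Matthews
                x = x + dt * force + amp * 0.5 * (xi_prev + noise[k])
                xi_prev = noise[k]
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"trajectory diverged (non-finite state) at step {step}"
                )
            if bias is not None and step % bias.stride == 0:
                bias.centers.append(cv.value(x))
            if step % record_stride == 0:
                out.append(x.copy())
        done += block
    return np.asarray(out)


def simulate_overdamped(
    potential: Potential,
    beta: float,
    dt: float,
    n_steps: int,
    x0,
    seed: int,
    scheme: str = "euler",
) -> Trajectory:
    """Sample an overdamped Langevin path; bit-reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    pts = _integrate(potential, beta, dt, n_steps, x0, rng, scheme)
    return Trajectory(pts, dt=dt, beta=beta, seed=seed, scheme=scheme,
                      potential_name=potential.name)


def simulate_metadynamics(
    potential: Potential,
    cv: CollectiveVariable,
    beta: float,
    dt: float,
    n_steps: int,
    hill_height: float,
    hill_width: float,
    stride: int,
    x0,
    seed: int,
    scheme: str = "euler",
    bias: Optional[BiasState] = None,
    static_biases: Sequence[tuple] = (),
) -> tuple[Trajectory, BiasState]:
    """Metadynamics along a scalar CV with standard (non-well-tempered) hills.

    A pre-existing ``bias`` may be passed in to continue accumulating hills
    across iterations (the adaptive loop relies on this); otherwise a fresh
    ``BiasState`` is created.  With ``hill_height = 0`` the trajectory is
    bit-identical to :func:`simulate_overdamped` with the same seed.
    """
    if bias is None:
        bias = BiasState(height=hill_height, width=hill_width, stride=stride)
    rng = np.random.default_rng(seed)
    pts = _integrate(potential, beta, dt, n_steps, x0, rng, scheme,
                     bias=bias, cv=cv, static_biases=static_biases)
    traj = Trajectory(pts, dt=dt, beta=beta, seed=seed, scheme=scheme,
                      potential_name=potential.name)
    return traj, bias


@dataclass
class ReplicaEnsemble:
    """Fleming–Viot replica ensemble confined to a domain indicator."""

    positions: np.ndarray  # (n_replicas, d)
    n_kills: int
    seed: int
    beta: float
    dt: float


def replica_seed_sequences(seed: int, n: int) -> Sequence[np.random.SeedSequence]:
    """The documented substream derivation for per-replica random streams."""
    return np.random.SeedSequence(seed).spawn(n)


def fleming_viot(
    potential: Potential,
    beta: float,
    dt: float,
    domain_indicator: Callable[[np.ndarray], bool],
    n_replicas: int,
    n_steps: int,
    x0,
    seed: int,
    scheme: str = "euler",
    history_stride: int = 0,
) -> ReplicaEnsemble:
    """Kill-and-branch sampler of the quasi-stationary distribution on a domain.

    All replicas start from ``x0`` and evolve by independent overdamped
    Langevin steps; after each full step, any replica that has left the domain
    (indicator false) is restarted from the position of a uniformly chosen
    surviving replica.  Simultaneous exits are processed in replica-index
    order, each restarting from the survivors at that moment.

    With ``history_stride > 0`` the ensemble positions every that-many steps
    are stacked onto the result as ``ensemble.history`` (useful for building
    QSD point clouds).
    """
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if not domain_indicator(x0):
        raise ValueError("x0 must satisfy the domain indicator")
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    seqs = replica_seed_sequences(seed, n_replicas + 1)
    rngs = [np.random.default_rng(s) for s in seqs[:n_replicas]]
    resample_rng = np.random.default_rng(seqs[n_replicas])
    amp = _noise_amplitude(beta, dt)
    d = x0.shape[0]
    pos = np.tile(x0, (n_replicas, 1))
    if scheme == "lm":
        xi_prev = [rng.standard_normal(d) for rng in rngs]
    n_kills = 0
    history = []
    for step in range(1, n_steps + 1):
        forces = -potential.gradient_many(pos)
        for i in range(n_replicas):
            xi = rngs[i].standard_normal(d)
            if scheme == "lm":
                incr = amp * 0.5 * (xi_prev[i] + xi)
                xi_prev[i] = xi
            else:
                incr = amp * xi
            pos[i] = pos[i] + dt * forces[i] + incr
        inside = np.array([bool(domain_indicator(pos[i]))
                           for i in range(n_replicas)])
        if not inside.any():
            raise RuntimeError(
                f"all replicas exited the domain at step {step}; "
                "the domain is too small or dt too large"
            )
        for i in np.nonzero(~inside)[0]:
            survivors = np.nonzero(inside)[0]
            donor = survivors[resample_rng.integers(len(survivors))]
            pos[i] = pos[donor].copy()
            inside[i] = True
            n_kills += 1
        if history_stride and step % history_stride == 0:
            history.append(pos.copy())
    ens = ReplicaEnsemble(positions=pos, n_kills=n_kills, seed=seed,
                          beta=beta, dt=dt)
    if history_stride:
        ens.history = np.concatenate(history, axis=0) if history else np.empty((0, d))
    return ens
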