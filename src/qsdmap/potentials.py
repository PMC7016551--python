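"""Toy potential energy surfaces.

Every potential exposes ``value(x)`` and ``gradient(x)`` with exact analytic
derivatives; the gradient is what the overdamped Langevin and metadynamics
integrators consume.  All potentials operate on ``d``-vectors (1-D systems use
``d = 1``) and support vectorised evaluation on ``(m, d)`` arrays through
``value_many`` / ``gradient_many``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = [
    "Potential",
    "Flat",
    "Quadratic",
    "DoubleWell1D",
    "ShiftedDoubleWell1D",
    "DoubleWell2D",
    "evaluate_potential",
    "make_potential",
]


@dataclass(frozen=True)
class Potential:
    """Base class: a named potential V on R^d with an analytic gradient."""

    name: str = field(init=False, default="potential")
    dimension: int = field(init=False, default=1)

    @property
    def params(self) -> Dict[str, float]:
        return {}

    def value(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # vectorised fallbacks; subclasses override with closed forms where it pays
    def value_many(self, xs: np.ndarray) -> np.ndarray:
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        return np.array([self.value(x) for x in xs])

    def gradient_many(self, xs: np.ndarray) -> np.ndarray:
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        return np.array([self.gradient(x) for x in xs])

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.shape[0] != self.dimension:
            raise ValueError(
                f"potential '{self.name}' is {self.dimension}-dimensional, "
                f"got a point of dimension {x.shape[0]}"
            )
        return x


class Quadratic(Potential):
    """V(x) = |x|^2 / 2 — the Ornstein–Uhlenbeck well."""

    def __init__(self, dimension: int = 1):
        object.__setattr__(self, "name", "quadratic")
        object.__setattr__(self, "dimension", int(dimension))

    def value(self, x):
        x = self._check(x)
        return 0.5 * float(x @ x)

    def gradient(self, x):
        return self._check(x).copy()

    def value_many(self, xs):
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        return 0.5 * np.einsum("ij,ij->i", xs, xs)

    def gradient_many(self, xs):
        return np.atleast_2d(np.asarray(xs, dtype=float)).copy()


class Flat(Potential):
    """V = 0: free diffusion (Brownian motion)."""

    def __init__(self, dimension: int = 1):
        object.__setattr__(self, "name", "flat")
        object.__setattr__(self, "dimension", int(dimension))

    def value(self, x):
        self._check(x)
        return 0.0

    def gradient(self, x):
        return np.zeros_like(self._check(x))

    def value_many(self, xs):
        return np.zeros(np.atleast_2d(np.asarray(xs, dtype=float)).shape[0])

    def gradient_many(self, xs):
        return np.zeros_like(np.atleast_2d(np.asarray(xs, dtype=float)))


class DoubleWell1D(Potential):
    """V(x) = (x^2 - 1)^2, minima at x = +-1, barrier height 1 at x = 0."""

    def __init__(self):
        object.__setattr__(self, "name", "doublewell_1d")
        object.__setattr__(self, "dimension", 1)

    def value(self, x):
        x = self._check(x)[0]
        return float((x * x - 1.0) ** 2)

    def gradient(self, x):
        x = self._check(x)[0]
        return np.array([4.0 * x * (x * x - 1.0)])

    def value_many(self, xs):
        x = np.atleast_2d(np.asarray(xs, dtype=float))[:, 0]
        return (x * x - 1.0) ** 2

    def gradient_many(self, xs):
        x = np.atleast_2d(np.asarray(xs, dtype=float))[:, 0]
        return (4.0 * x * (x * x - 1.0))[:, None]


class ShiftedDoubleWell1D(Potential):
    """V(x) = ((x - 1)^2 - 1)^2, minima at x = 0 and x = 2, barrier at x = 1."""

    def __init__(self):
        object.__setattr__(self, "name", "doublewell_shifted_1d")
        object.__setattr__(self, "dimension", 1)

    def value(self, x):
        x = self._check(x)[0]
        return float(((x - 1.0) ** 2 - 1.0) ** 2)

    def gradient(self, x):
        x = self._check(x)[0]
        return np.array([4.0 * (x - 1.0) * ((x - 1.0) ** 2 - 1.0)])

    def value_many(self, xs):
        x = np.atleast_2d(np.asarray(xs, dtype=float))[:, 0]
        return ((x - 1.0) ** 2 - 1.0) ** 2

    def gradient_many(self, xs):
        x = np.atleast_2d(np.asarray(xs, dtype=float))[:, 0]
        return (4.0 * (x - 1.0) * ((x - 1.0) ** 2 - 1.0))[:, None]


class DoubleWell2D(Potential):
    """Two-dimensional double well

        V(x, y) = (1/6) [ 4 (w - x^2 - y^2)^2 + 2 h (x^2 - 2)^2
                          + ((x + y)^2 - w)^2 + ((x - y)^2 - w)^2 ].

    With h = 2, w = 1 the two wells sit near (+-1.18, 0), separated by saddle
    points near (0, +-1); the intra-well slow direction is y while the inter-well
    transition is a sign change of x.
    """

    def __init__(self, h: float = 2.0, w: float = 1.0):
        object.__setattr__(self, "name", "doublewell_2d")
        object.__setattr__(self, "dimension", 2)
        object.__setattr__(self, "_h", float(h))
        object.__setattr__(self, "_w", float(w))

    @property
    def params(self):
        return {"h": self._h, "w": self._w}

    def value(self, x):
        x = self._check(x)
        return float(self.value_many(x[None, :])[0])

    def gradient(self, x):
        x = self._check(x)
        return self.gradient_many(x[None, :])[0]

    def value_many(self, xs):
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        x, y = xs[:, 0], xs[:, 1]
        h, w = self._h, self._w
        r2 = x * x + y * y
        sp = (x + y) ** 2 - w
        sm = (x - y) ** 2 - w
        return (4.0 * (w - r2) ** 2 + 2.0 * h * (x * x - 2.0) ** 2
                + sp**2 + sm**2) / 6.0

    def gradient_many(self, xs):
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        x, y = xs[:, 0], xs[:, 1]
        h, w = self._h, self._w
        r2 = x * x + y * y
        sp = (x + y) ** 2 - w
        sm = (x - y) ** 2 - w
        gx = (-16.0 * x * (w - r2) + 8.0 * h * x * (x * x - 2.0)
              + 4.0 * (x + y) * sp + 4.0 * (x - y) * sm) / 6.0
        gy = (-16.0 * y * (w - r2) + 4.0 * (x + y) * sp
              - 4.0 * (x - y) * sm) / 6.0
        return np.stack([gx, gy], axis=1)


def evaluate_potential(potential: Potential, x) -> tuple[float, np.ndarray]:
    """Return ``(V(x), grad V(x))``; raises on dimension mismatch."""
    energy = potential.value(x)
    grad = potential.gradient(x)
    if not (np.isfinite(energy) and np.all(np.isfinite(grad))):
        raise FloatingPointError(
            f"non-finite energy/gradient for potential '{potential.name}' at {x!r}"
        )
    return energy, grad


_REGISTRY = {
    "flat": lambda **kw: Flat(int(kw.get("dimension", 1))),
    "quadratic": lambda **kw: Quadratic(int(kw.get("dimension", 1))),
    "doublewell_1d": lambda **kw: DoubleWell1D(),
    "doublewell_shifted_1d": lambda **kw: ShiftedDoubleWell1D(),
    "doublewell_2d": lambda **kw: DoubleWell2D(
        h=float(kw.get("h", 2.0)), w=float(kw.get("w", 1.0))
    ),
}


def make_potential(name: str, **params) -> Potential:
    """Build a registered potential by name (used by the CLI and fixtures)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown potential {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return factory(**params)
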