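"""File formats, fixtures and run configuration.

Formats
-------
* delimited text: whitespace- or comma-separated, ``#`` comments, optional
  header line naming columns; column order is coordinates first, then an
  optional ``weight`` column.
* container: NumPy ``.npz`` (compressed), storing ``points`` (and ``weights``)
  in double precision plus the metadata as a JSON string — bit-exact round
  trips.

Fixtures realise the article-scale toy experiments (Ornstein–Uhlenbeck cloud,
1-D and 2-D double wells, trapped/global 2-D clouds, two Gaussian blobs) as
deterministic functions of a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .dmap import GeneratorMatrix, PointCloud, SpectralDecomposition
from .dynamics import Trajectory, simulate_overdamped
from .potentials import (DoubleWell1D, DoubleWell2D, Quadratic,
                         ShiftedDoubleWell1D)

__all__ = [
    "RunConfig",
    "read_pointcloud",
    "write_pointcloud",
    "write_trajectory",
    "write_generator_coo",
    "write_spectrum",
    "make_fixture",
    "FIXTURE_NAMES",
    "cloud_checksum",
    "log_record",
]


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Flat parameter document for CLI runs; unknown keys are rejected."""

    seed: int = 0
    epsilon: Optional[float] = None
    alpha: float = 0.5
    cutoff: float = 0.0
    k: int = 5
    threshold: Optional[float] = None
    embedding_dim: int = 1
    window_size: int = 1000
    subsample: int = 4
    jump_factor: float = 5.0
    beta: Optional[float] = None
    dt: Optional[float] = None
    n_steps: Optional[int] = None
    potential: Optional[str] = None
    potential_params: Dict = dataclasses.field(default_factory=dict)
    halfwidth: Optional[float] = None
    n_grid: int = 256
    hill_height: Optional[float] = None
    hill_width: Optional[float] = None
    hill_stride: Optional[int] = None
    input_path: Optional[str] = None
    output_path: Optional[str] = None
    format: str = "delimited"

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# Point-cloud / trajectory I/O
# --------------------------------------------------------------------------


def write_pointcloud(cloud: PointCloud, path, format: str = "delimited"):
    path = Path(path)
    if format == "container":
        payload = {"points": cloud.points,
                   "metadata": json.dumps(cloud.metadata, default=str)}
        if cloud.weights is not None:
            payload["weights"] = cloud.weights
        np.savez_compressed(path, **payload)
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    cols = [f"x{i}" for i in range(cloud.dim)]
    data = cloud.points
    if cloud.weights is not None:
        cols.append("weight")
        data = np.column_stack([data, cloud.weights])
    with open(path, "w") as fh:
        if cloud.metadata:
            fh.write(f"# metadata: {json.dumps(cloud.metadata, default=str)}\n")
        fh.write("# " + " ".join(cols) + "\n")
        np.savetxt(fh, data, fmt="%.17g")


def read_pointcloud(path, format: str = "delimited") -> PointCloud:
    path = Path(path)
    if format == "container":
        with np.load(path, allow_pickle=False) as z:
            pts = z["points"]
            weights = z["weights"] if "weights" in z else None
            meta = json.loads(str(z["metadata"])) if "metadata" in z else {}
        return PointCloud(pts, weights=weights, metadata=meta)
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    rows, meta, header = [], {}, None
    ncol = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("metadata:"):
                    try:
                        meta = json.loads(body[len("metadata:"):].strip())
                    except json.JSONDecodeError:
                        pass
                elif header is None and body:
                    header = body.replace(",", " ").split()
                continue
            tokens = line.replace(",", " ").split()
            try:
                vals = [float(t) for t in tokens]
            except ValueError:
                if header is None:
                    header = tokens
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric entry in {tokens!r}"
                ) from None
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncol} columns, "
                    f"got {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    arr = np.asarray(rows)
    weights = None
    if header and header[-1].lower() == "weight":
        weights = arr[:, -1]
        arr = arr[:, :-1]
    return PointCloud(arr, weights=weights, metadata=meta)


def write_trajectory(traj: Trajectory, path, format: str = "delimited"):
    """Trajectory points plus a JSON metadata sidecar (``<path>.meta.json``)."""
    meta = {"potential": traj.potential_name, "beta": traj.beta,
            "dt": traj.dt, "seed": traj.seed, "scheme": traj.scheme}
    cloud = PointCloud(traj.points, metadata=meta)
    write_pointcloud(cloud, path, format=format)
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def write_generator_coo(generator: GeneratorMatrix, path, tol: float = 0.0):
    """Generator matrix in (row, col, value) coordinate text format."""
    import scipy.sparse as sp

    L = generator.values
    coo = (L.tocoo() if sp.issparse(L)
           else sp.coo_matrix(np.where(np.abs(L) > tol, L, 0.0)))
    with open(path, "w") as fh:
        fh.write(f"# generator kind={generator.kind} epsilon={generator.epsilon}"
                 f" alpha={generator.alpha} m={generator.m}\n")
        fh.write("# row col value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.17g}\n")


def write_spectrum(dec: SpectralDecomposition, path):
    """Two-block table: eigenvalues, then eigenvectors by column."""
    with open(path, "w") as fh:
        fh.write("# eigenvalues\n")
        np.savetxt(fh, dec.eigenvalues[None, :], fmt="%.17g")
        fh.write("# eigenvectors (one column per eigenvalue)\n")
        np.savetxt(fh, dec.eigenvectors, fmt="%.17g")


def cloud_checksum(cloud: PointCloud) -> str:
    """sha256 of the double-precision point array (order-sensitive)."""
    h = hashlib.sha256(np.ascontiguousarray(cloud.points).tobytes())
    if cloud.weights is not None:
        h.update(np.ascontiguousarray(cloud.weights).tobytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

FIXTURE_NAMES = ("ou_1d", "doublewell_1d", "doublewell_shifted_1d",
                 "doublewell_2d_trapped", "doublewell_2d_global", "two_blobs")


def make_fixture(name: str, seed: int = 0) -> PointCloud:
    """Deterministic article-scale point clouds.

    ou_1d
        2000 points subsampled from an overdamped trajectory of V = x^2/2 at
        beta = 1 (dt = 0.1, stride 100 — essentially decorrelated samples).
    doublewell_1d
        10^4 points from V = (x^2-1)^2 at beta = 1, dt = 0.1 (10^5 steps,
        stride 10): both wells visited.
    doublewell_shifted_1d
        as above for V = ((x-1)^2-1)^2 (wells at 0 and 2).
    doublewell_2d_trapped
        2-D double well (h = 2, w = 1) at beta = 10: a short trajectory
        started in the right well; the barrier is never crossed, all x > 0.
    doublewell_2d_global
        same potential; two walkers started in opposite wells, pooled —
        covers the whole support.
    two_blobs
        500 + 500 Gaussian points (sigma = 0.1) at separation 10 sigma.
    """
    if name == "ou_1d":
        traj = simulate_overdamped(Quadratic(1), beta=1.0, dt=0.1,
                                   n_steps=200_000, x0=[0.0], seed=seed)
        pts = traj.points[100::100][:2000]
        meta = {"fixture": name, "potential": "quadratic", "beta": 1.0,
                "dt": 0.1, "seed": seed}
        return PointCloud(pts, metadata=meta)
    if name == "doublewell_1d":
        traj = simulate_overdamped(DoubleWell1D(), beta=1.0, dt=0.1,
                                   n_steps=100_000, x0=[-1.0], seed=seed,
                                   scheme="lm")
        pts = traj.points[10::10][:10_000]
        meta = {"fixture": name, "potential": "doublewell_1d", "beta": 1.0,
                "dt": 0.1, "seed": seed}
        return PointCloud(pts, metadata=meta)
    if name == "doublewell_shifted_1d":
        traj = simulate_overdamped(ShiftedDoubleWell1D(), beta=1.0, dt=0.1,
                                   n_steps=100_000, x0=[0.0], seed=seed,
                                   scheme="lm")
        pts = traj.points[10::10][:10_000]
        meta = {"fixture": name, "potential": "doublewell_shifted_1d",
                "beta": 1.0, "dt": 0.1, "seed": seed}
        return PointCloud(pts, metadata=meta)
    if name == "doublewell_2d_trapped":
        pot = DoubleWell2D(h=2.0, w=1.0)
        traj = simulate_overdamped(pot, beta=10.0, dt=0.05, n_steps=20_000,
                                   x0=[1.2, 0.0], seed=seed, scheme="lm")
        pts = traj.points[10::10][:2000]
        meta = {"fixture": name, "potential": "doublewell_2d", "h": 2.0,
                "w": 1.0, "beta": 10.0, "dt": 0.05, "seed": seed}
        return PointCloud(pts, metadata=meta)
    if name == "doublewell_2d_global":
        pot = DoubleWell2D(h=2.0, w=1.0)
        ss = np.random.SeedSequence(seed).spawn(2)
        halves = []
        for x0, s in zip(([1.2, 0.0], [-1.2, 0.0]), ss):
            sub = int(s.generate_state(1)[0] % (2**31))
            traj = simulate_overdamped(pot, beta=10.0, dt=0.05,
                                       n_steps=50_000, x0=x0, seed=sub,
                                       scheme="lm")
            halves.append(traj.points[10::10][:5000])
        pts = np.concatenate(halves, axis=0)
        meta = {"fixture": name, "potential": "doublewell_2d", "h": 2.0,
                "w": 1.0, "beta": 10.0, "dt": 0.05, "seed": seed}
        return PointCloud(pts, metadata=meta)
    if name == "two_blobs":
        rng = np.random.default_rng(seed)
        sigma = 0.1
        a = rng.normal([0.0, 0.0], sigma, size=(500, 2))
        b = rng.normal([10 * sigma, 0.0], sigma, size=(500, 2))
        meta = {"fixture": name, "sigma": sigma, "separation": 10 * sigma,
                "seed": seed}
        return PointCloud(np.concatenate([a, b]), metadata=meta)
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def log_record(operation: str, params: Dict, path=None) -> Dict:
    """One structured log record per operation (JSON line when path given)."""
    rec = {"operation": operation, "params": params,
           "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if path is not None:
        with open(path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
    return rec
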