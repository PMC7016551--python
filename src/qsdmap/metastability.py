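"""Metastable-set identification and spectrum-based exit detection.

Two-centre clustering from the dominant eigenvector: the maximal and minimal
points of the first diffusion coordinate define the centres of sets A and B;
each set grows to all points within a Euclidean threshold of its centre in the
first few diffusion coordinates.  The sign structure of the (mean-centred)
first eigenvector separates the two sets.

Exit detection monitors the convergence of the dominant diffusion-map
eigenvalues along a trajectory: inside a metastable state the samples
equilibrate to the quasi-stationary distribution and the window-to-window
spectrum stabilises; an exit shows up as a jump of the windowed eigenvalue
mean well outside the trailing fluctuation of the converged windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dmap import DiffusionMap, SpectralDecomposition
from .dynamics import Trajectory

__all__ = [
    "MetastablePartition",
    "SpectrumWindowSeries",
    "identify_metastable_sets",
    "spectrum_monitor",
    "detect_spectrum_jump",
    "local_global_dc_correlation",
]


@dataclass
class MetastablePartition:
    center_max: int
    center_min: int
    members_A: np.ndarray
    members_B: np.ndarray
    threshold: float
    embedding_dim: int

    def labels(self, m: int) -> np.ndarray:
        """Per-point labels: 'A', 'B' or 'C' (unassigned transition region)."""
        lab = np.full(m, "C", dtype="<U1")
        lab[self.members_A] = "A"
        lab[self.members_B] = "B"
        return lab


def identify_metastable_sets(decomposition: SpectralDecomposition,
                             threshold: float,
                             embedding_dim: int = 1) -> MetastablePartition:
    """Two-centre metastable sets from the first diffusion coordinate.

    Centres are the argmax and argmin of the first nontrivial eigenvector;
    sets grow to all points within ``threshold`` (Euclidean distance in the
    first ``embedding_dim`` diffusion coordinates, t = 0 weighting) of their
    centre.  A point within the threshold of both centres joins the nearer
    one, ties broken toward A.
    """
    if decomposition.eigenvectors.shape[1] < 2:
        raise ValueError("need at least 2 eigenvectors (one nontrivial)")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    phi1 = decomposition.eigenvectors[:, 1]
    spread = phi1.max() - phi1.min()
    if spread < 1e-12 or spread < 1e-6 * np.max(np.abs(phi1)):
        raise ValueError(
            "the first nontrivial eigenvector is numerically constant "
            "(no spectral gap resolved); gather more data or adjust epsilon"
        )
    emb = decomposition.diffusion_coordinates[:, :embedding_dim]
    i_max = int(np.argmax(phi1))
    i_min = int(np.argmin(phi1))
    dA = np.linalg.norm(emb - emb[i_max], axis=1)
    dB = np.linalg.norm(emb - emb[i_min], axis=1)
    inA = dA < threshold
    inB = dB < threshold
    both = inA & inB
    # nearest centre wins; ties toward A
    inB[both & (dA <= dB)] = False
    inA[both & (dA > dB)] = False
    inA[i_max] = True
    inB[i_min] = True
    inB[i_max] = False
    inA[i_min] = False
    return MetastablePartition(
        center_max=i_max, center_min=i_min,
        members_A=np.nonzero(inA)[0], members_B=np.nonzero(inB)[0],
        threshold=threshold, embedding_dim=embedding_dim,
    )


@dataclass
class SpectrumWindowSeries:
    """Windowed dominant-eigenvalue series along a trajectory.

    ``windows`` holds (start step index, eigenvalue vector) per window;
    ``means`` is the per-window average of the dominant (nonzero)
    eigenvalues; ``maxdiffs[w]`` is the maximal absolute change of the
    corresponding eigenvalues between window ``w`` and window ``w - 1``
    (zero for the first window); ``exit_window`` is the first window flagged
    as a spectrum jump, or None.
    """

    window_starts: np.ndarray
    eigenvalues: np.ndarray  # (n_windows, k)
    means: np.ndarray
    maxdiffs: np.ndarray
    exit_window: Optional[int]
    jump_factor: float

    @property
    def n_windows(self):
        return len(self.window_starts)

    def converged_before_exit(self, rel_tol: float = 0.05,
                              run_length: int = 3) -> bool:
        """True if the means stabilised (relative change < rel_tol over
        ``run_length`` consecutive windows) before any flagged exit."""
        stop = self.exit_window if self.exit_window is not None else self.n_windows
        run = 0
        for i in range(1, stop):
            rel = abs(self.means[i] - self.means[i - 1]) / max(
                abs(self.means[i - 1]), 1e-300)
            run = run + 1 if rel < rel_tol else 0
            if run >= run_length - 1:
                return True
        return False


def detect_spectrum_jump(means, jump_factor: float = 5.0,
                         min_history: int = 3) -> Optional[int]:
    """First window whose mean eigenvalue jumps out of the trailing scatter.

    A window ``i`` is flagged when ``|mean_i - mean_{i-1}|`` exceeds
    ``jump_factor`` times the standard deviation of the preceding (converged)
    window means; at least ``min_history`` previous windows are required.
    """
    means = np.asarray(means, dtype=float)
    for i in range(min_history, len(means)):
        hist = means[:i]
        scatter = float(np.std(hist, ddof=1))
        jump = abs(means[i] - means[i - 1])
        if scatter == 0.0:
            if jump > 0.0:
                return i
            continue
        if jump > jump_factor * scatter:
            return i
    return None


def spectrum_monitor(trajectory: Trajectory, window_size: int,
                     subsample: int, k: int, eps: float,
                     jump_factor: float = 5.0,
                     min_history: int = 3,
                     seed: int = 0) -> SpectrumWindowSeries:
    """Windowed diffusion-map spectra along a trajectory.

    The trajectory is cut into consecutive blocks of ``window_size * subsample``
    steps; each window keeps every ``subsample``-th point (``window_size``
    points), builds an alpha = 1/2 generator with bandwidth ``eps`` and records
    its ``k`` dominant nonzero eigenvalues.  The exit flag applies
    :func:`detect_spectrum_jump` to the per-window means.
    """
    pts = trajectory.points
    block = window_size * subsample
    n_windows = pts.shape[0] // block
    if n_windows < 1:
        raise ValueError(
            f"trajectory too short ({pts.shape[0]} points) for one window of "
            f"{block} steps"
        )
    starts, spectra = [], []
    for w in range(n_windows):
        sel = pts[w * block:(w + 1) * block:subsample][:window_size]
        model = DiffusionMap(sel, epsilon=eps, alpha=0.5)
        res = model.fit(k=k, seed=seed)
        spectra.append(res.eigenvalues[1:k + 1])
        starts.append(w * block)
    spectra = np.asarray(spectra)
    means = spectra.mean(axis=1)
    maxdiffs = np.zeros(n_windows)
    if n_windows > 1:
        maxdiffs[1:] = np.max(np.abs(np.diff(spectra, axis=0)), axis=1)
    exit_w = detect_spectrum_jump(means, jump_factor, min_history)
    return SpectrumWindowSeries(
        window_starts=np.asarray(starts), eigenvalues=spectra, means=means,
        maxdiffs=maxdiffs, exit_window=exit_w, jump_factor=jump_factor,
    )


def local_global_dc_correlation(decomposition: SpectralDecomposition,
                                coordinates: np.ndarray) -> np.ndarray:
    """Pearson correlation of the first diffusion coordinate with each input
    coordinate; zero-variance coordinates give NaN (not an exception)."""
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    phi1 = decomposition.eigenvectors[:, 1]
    if coords.shape[0] != phi1.shape[0]:
        raise ValueError("coordinate rows must match the number of points")
    out = np.empty(coords.shape[1])
    sp_ = phi1 - phi1.mean()
    sphi = np.sqrt(np.mean(sp_**2))
    for j in range(coords.shape[1]):
        c = coords[:, j] - coords[:, j].mean()
        sc = np.sqrt(np.mean(c**2))
        if sc == 0.0 or sphi == 0.0:
            out[j] = np.nan
        else:
            out[j] = float(np.mean(sp_ * c) / (sphi * sc))
    return out
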