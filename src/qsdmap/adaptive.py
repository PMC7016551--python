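"""Adaptive collective-variable learning with metadynamics.

The loop (reconstructed from the narrative description of the published
algorithm, which is available only as a figure in the source article):

1. sample the current metastable state (plain Langevin or Fleming–Viot),
   monitoring the windowed diffusion-map spectrum until the eigenvalue means
   stabilise — at that point the samples follow the local quasi-stationary
   distribution;
2. build an alpha = 1/2 diffusion map on the converged window and compute the
   dominant diffusion coordinates;
3. rank a list of physical candidate CVs by the magnitude of their Pearson
   correlation with the leading diffusion coordinates and pick the best;
4. run metadynamics along the selected CV, keeping all bias accumulated in
   earlier iterations active;
5. watch for exits (spectrum jump / state-label changes), record transitions
   and iterate.

Between iterations the biased samples can be unbiased with the target-measure
diffusion map using the known Boltzmann factors as the target density; the
report carries the first nonzero TMDmap eigenvalue as a reweighting
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .dmap import DiffusionMap, SpectralDecomposition, TargetMeasureDiffusionMap
from .dynamics import (BiasState, CollectiveVariable, Trajectory,
                       fleming_viot, simulate_metadynamics)
from .metastability import spectrum_monitor
from .potentials import Potential

__all__ = [
    "CandidateCVSet",
    "CVSelection",
    "AdaptiveConfig",
    "IterationReport",
    "AdaptiveRunReport",
    "pearson_correlation",
    "select_cvs",
    "run_adaptive_sampling",
    "coordinate_cv",
    "linear_cv",
    "noise_cv",
]


def pearson_correlation(x, y) -> float:
    """Pearson rho = cov(x, y) / (sigma_x sigma_y), population (1/m) moments."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length with m >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc * xc))
    sy = np.sqrt(np.mean(yc * yc))
    if sx == 0.0:
        raise ValueError("first input has zero variance")
    if sy == 0.0:
        raise ValueError("second input has zero variance")
    rho = float(np.mean(xc * yc) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def coordinate_cv(i: int, name: Optional[str] = None) -> CollectiveVariable:
    """CV projecting onto coordinate ``i``."""

    def grad(x, i=i):
        g = np.zeros_like(x)
        g[i] = 1.0
        return g

    return CollectiveVariable(name or f"x{i}", fn=lambda x: float(x[i]),
                              grad=grad)


def linear_cv(coeffs, name: str) -> CollectiveVariable:
    """CV ``c . x`` for a fixed coefficient vector."""
    c = np.asarray(coeffs, dtype=float)
    return CollectiveVariable(name, fn=lambda x: float(c @ x),
                              grad=lambda x: c.copy())


def noise_cv(dimension: int, seed: int, frequency: float = 40.0,
             amplitude: Optional[float] = None,
             name: str = "noise") -> CollectiveVariable:
    """A deterministic rapidly oscillating CV, uncorrelated with any smooth
    coordinate — the 'pure noise' control candidate.

    The default amplitude ``0.01/frequency`` keeps both the CV's range and
    its gradient far below any sensible hill width and force scale, so
    metadynamics along it cannot resolve (or pump energy into) configuration
    space: it models a bias on an uninformative coordinate, which drives no
    transitions.  Pearson correlations are scale-invariant, so the amplitude
    does not affect the CV's ranking.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(dimension)
    a /= np.linalg.norm(a)
    w = float(frequency)
    amp = (0.01 / w) if amplitude is None else float(amplitude)

    def fn(x):
        return amp * float(np.sin(w * (a @ x)))

    def grad(x):
        return amp * w * np.cos(w * (a @ x)) * a

    return CollectiveVariable(name, fn=fn, grad=grad)


@dataclass
class CandidateCVSet:
    """Candidate physical CVs with their values along a sample set."""

    cvs: List[CollectiveVariable]
    values: np.ndarray  # (m, p)

    @classmethod
    def from_cvs(cls, cvs: Sequence[CollectiveVariable], points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        vals = np.column_stack([cv.values(points) for cv in cvs])
        return cls(cvs=list(cvs), values=vals)

    @property
    def names(self):
        return [cv.name for cv in self.cvs]

    @property
    def p(self):
        return self.values.shape[1]


@dataclass
class CVSelection:
    """Ranking of candidates against the leading diffusion coordinates.

    ``ranked`` lists (candidate index, eigenvector index, rho) for every
    candidate and every requested DC, per-DC blocks ordered by decreasing
    |rho| (ties broken toward the lower candidate index); ``chosen`` holds the
    best distinct candidate per eigenvector, in eigenvector order.
    """

    ranked: List[tuple]
    chosen: List[tuple]

    def chosen_names(self, candidates: CandidateCVSet):
        return [candidates.names[i] for i, _, _ in self.chosen]


def select_cvs(decomposition: SpectralDecomposition,
               candidates: CandidateCVSet,
               n_dcs: int = 1, n_select: int = 1) -> CVSelection:
    """Pick the physical candidates most correlated with the leading DCs."""
    if n_dcs < 1:
        raise ValueError("n_dcs must be >= 1")
    if candidates.p < n_select:
        raise ValueError(
            f"need at least {n_select} distinct candidates, have {candidates.p}"
        )
    if decomposition.eigenvectors.shape[1] < n_dcs + 1:
        raise ValueError("decomposition has too few eigenvectors")
    ranked: List[tuple] = []
    per_dc_order: List[List[tuple]] = []
    for dc in range(1, n_dcs + 1):
        phi = decomposition.eigenvectors[:, dc]
        rhos = []
        for j in range(candidates.p):
            rho = pearson_correlation(candidates.values[:, j], phi)
            rhos.append((j, dc, rho))
        # stable sort on candidate index, then by decreasing |rho|
        order = sorted(rhos, key=lambda t: (-abs(t[2]), t[0]))
        ranked.extend(order)
        per_dc_order.append(order)
    chosen: List[tuple] = []
    used = set()
    for order in per_dc_order:
        for cand in order:
            if cand[0] not in used:
                chosen.append(cand)
                used.add(cand[0])
                break
        if len(chosen) >= n_select:
            break
    if len(chosen) < n_select:
        raise ValueError("fewer distinct candidates than n_select")
    return CVSelection(ranked=ranked, chosen=chosen[:n_select])


@dataclass
class AdaptiveConfig:
    """All parameters of the adaptive loop (no silent defaults for the bias)."""

    potential: Potential
    beta: float
    dt: float
    x0: np.ndarray
    candidates: Sequence[CollectiveVariable]
    hill_height: float
    hill_width: float
    hill_stride: int
    seed: int
    n_iterations: int = 1
    sample_steps: int = 20_000
    bias_steps: int = 20_000
    window_size: int = 1000
    subsample: int = 4
    k: int = 4
    eps: float = 0.05
    jump_factor: float = 5.0
    conv_tol: float = 0.05
    conv_windows: int = 3
    n_dcs: int = 1
    scheme: str = "euler"
    sampler: str = "langevin"  # or "fleming_viot"
    domain_indicator: Optional[Callable] = None
    n_replicas: int = 50
    state_fn: Optional[Callable] = None  # configuration -> hashable label
    force_cv_index: Optional[int] = None  # override selection (controls)


@dataclass
class IterationReport:
    iteration: int
    sampling_seed: int
    bias_seed: int
    converged: bool
    inconclusive: bool
    monitor_means: np.ndarray
    selection: CVSelection
    selected_cv: str
    biased_cv: str
    n_hills: int
    transitions: int
    exit_window: Optional[int]
    tmdmap_lambda1: Optional[float]


@dataclass
class AdaptiveRunReport:
    config_seed: int
    iterations: List[IterationReport] = field(default_factory=list)
    seed_ledger: List[dict] = field(default_factory=list)

    @property
    def total_transitions(self):
        return sum(it.transitions for it in self.iterations)


def _count_transitions(points: np.ndarray, state_fn: Callable) -> int:
    """Count changes of the definite state label along a path.

    ``state_fn`` may return None for undecided (transition-region)
    configurations; such points keep the last definite label, so rapid
    recrossings of the barrier top are not double-counted.
    """
    count = 0
    last = None
    for p in points:
        lab = state_fn(p)
        if lab is None:
            continue
        if last is not None and lab != last:
            count += 1
        last = lab
    return count


def _default_state(x, deadband: float = 0.5):
    if x[0] > deadband:
        return 1
    if x[0] < -deadband:
        return -1
    return None


def run_adaptive_sampling(config: AdaptiveConfig) -> AdaptiveRunReport:
    """Run the full adaptive CV-learning loop; reproducible from the seeds."""
    pot = config.potential
    state_fn = config.state_fn or _default_state
    root = np.random.SeedSequence(config.seed)
    report = AdaptiveRunReport(config_seed=config.seed)
    x = np.asarray(config.x0, dtype=float).reshape(-1)
    accumulated: List[tuple] = []  # [(BiasState, CollectiveVariable)]
    for it in range(config.n_iterations):
        ss_sample, ss_bias = root.spawn(2)
        # spawn() advances the root pool, so each iteration gets fresh streams
        seed_sample = int(ss_sample.generate_state(1)[0] % (2**31))
        seed_bias = int(ss_bias.generate_state(1)[0] % (2**31))
        report.seed_ledger.append({"iteration": it,
                                   "sampling_seed": seed_sample,
                                   "bias_seed": seed_bias})
        # 1. local sampling under the accumulated (static) bias
        if config.sampler == "fleming_viot":
            if config.domain_indicator is None:
                raise ValueError("fleming_viot sampler needs a domain_indicator")
            ens = fleming_viot(pot, config.beta, config.dt,
                               config.domain_indicator, config.n_replicas,
                               config.sample_steps // config.n_replicas + 1,
                               x, seed_sample, scheme=config.scheme,
                               history_stride=1)
            sample_points = ens.history
            traj = Trajectory(sample_points, dt=config.dt, beta=config.beta,
                              seed=seed_sample, scheme=config.scheme,
                              potential_name=pot.name)
        else:
            traj, _ = simulate_metadynamics(
                pot, coordinate_cv(0), config.beta, config.dt,
                config.sample_steps, 0.0, 1.0, 10**9, x, seed_sample,
                scheme=config.scheme, static_biases=accumulated)
            x = traj.points[-1]
        monitor = spectrum_monitor(traj, config.window_size, config.subsample,
                                   config.k, config.eps,
                                   jump_factor=config.jump_factor)
        converged = monitor.converged_before_exit(config.conv_tol,
                                                  config.conv_windows)
        # 2. diffusion map on the last window's points
        block = config.window_size * config.subsample
        pts = traj.points[-block::config.subsample][:config.window_size]
        model = DiffusionMap(pts, epsilon=config.eps, alpha=0.5)
        res = model.fit(k=max(config.k, config.n_dcs + 1))
        # 3. CV selection
        cand = CandidateCVSet.from_cvs(config.candidates, pts)
        selection = select_cvs(res.decomposition, cand,
                               n_dcs=config.n_dcs, n_select=1)
        chosen_idx = selection.chosen[0][0]
        bias_idx = (config.force_cv_index
                    if config.force_cv_index is not None else chosen_idx)
        cv = config.candidates[bias_idx]
        # 4. metadynamics along the (possibly overridden) CV
        bias = BiasState(height=config.hill_height, width=config.hill_width,
                         stride=config.hill_stride)
        btraj, bias = simulate_metadynamics(
            pot, cv, config.beta, config.dt, config.bias_steps,
            config.hill_height, config.hill_width, config.hill_stride,
            x, seed_bias, scheme=config.scheme, bias=bias,
            static_biases=accumulated)
        x = btraj.points[-1]
        if config.hill_height != 0.0:
            accumulated.append((bias, cv))
        # 5. transitions and diagnostics
        transitions = _count_transitions(btraj.points, state_fn)
        bexit = None
        if btraj.points.shape[0] >= block:
            bmon = spectrum_monitor(btraj, config.window_size,
                                    config.subsample, config.k, config.eps,
                                    jump_factor=config.jump_factor)
            bexit = bmon.exit_window
        lam1 = None
        if config.hill_height != 0.0:
            sub = btraj.points[::max(1, btraj.points.shape[0] // 1000)]
            target = np.exp(-config.beta * pot.value_many(sub))
            try:
                tm = TargetMeasureDiffusionMap(sub, epsilon=config.eps,
                                               target_density=target)
                lam1 = float(tm.fit(k=2).eigenvalues[1])
            except (RuntimeError, ValueError):
                lam1 = None
        report.iterations.append(IterationReport(
            iteration=it, sampling_seed=seed_sample, bias_seed=seed_bias,
            converged=converged, inconclusive=not converged,
            monitor_means=monitor.means, selection=selection,
            selected_cv=cand.names[chosen_idx], biased_cv=cv.name,
            n_hills=len(bias.centers), transitions=transitions,
            exit_window=bexit, tmdmap_lambda1=lam1,
        ))
    return report
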