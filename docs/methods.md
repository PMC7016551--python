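# Methods

`qsdmap` analyses point clouds sampled by stochastic dynamics with diffusion
maps: it approximates the generator of overdamped Langevin dynamics on the
samples, and uses that matrix to compute committor functions, Dirichlet
(absorbed) spectra, quasi-stationary distributions, metastable partitions and
adaptively learned collective variables. This note records the model, the
numerical choices, and what the synthetic experiments do and do not show.

## Dynamics

The samplers integrate overdamped Langevin dynamics

    dx = -grad V(x) dt + sqrt(2/beta) dW,

whose invariant law is the Boltzmann–Gibbs measure ∝ exp(-beta V). Two
integrators are provided: Euler–Maruyama (`"euler"`) and the
Leimkuhler–Matthews step (`"lm"`), which averages successive noise increments
and samples the invariant measure with O(dt^2) bias; `lm` is the default in
all experiments that quote equilibrium statistics. `beta = inf` is accepted
and yields plain gradient descent (used to test the drift in isolation).
Divergences (non-finite state) raise immediately with the offending step
index; for the quartic 2-D double well this bounds usable time steps at
roughly dt <= 0.05 at beta = 10 and dt <= 0.01 at beta = 2, which is why the
committor experiment below runs at dt = 0.01.

Every stochastic operation takes an integer seed. One trajectory uses
`numpy.random.default_rng(seed)`; ensembles spawn one child stream per
replica from `numpy.random.SeedSequence(seed)` — this derivation is part of
the API and tests rely on it bitwise.

Metadynamics deposits standard (non-well-tempered) Gaussian hills
`V_b(z) = sum_k h exp(-(z - z_k)^2 / 2w^2)` along a scalar collective
variable every `stride` steps; height, width and stride are required
configuration with no defaults. The Fleming–Viot sampler evolves `n`
replicas under independent streams and, after each full step, restarts every
replica that left the domain from a uniformly chosen survivor (replica-index
order for simultaneous exits). The kill/restart rule is the standard
construction; the source article describes this sampler only in footnotes
that are not part of the available text, so this part of the design is a
reconstruction.

## Diffusion maps

From samples {x_i} the Gaussian kernel K_ij = exp(-|x_i - x_j|^2 / 4 eps) is
formed, density-normalised with exponent alpha (divide by q_i^alpha
q_j^alpha, with q the kernel row sums), row-normalised to a Markov matrix
P_eps, and scaled to the generator L_eps = (P_eps - I)/eps. For alpha = 1/2
(the default everywhere) and Boltzmann-distributed samples, L_eps converges
to beta * L_beta with L_beta = -grad V . grad + beta^{-1} Laplacian; all
eigenvalues quoted by the package are therefore on the *time-rescaled* scale
beta * L_beta, and the Chebyshev reference solver uses the same convention so
the two are directly comparable.

A note on the normalisation order: the compressed notation
P = D_alpha^{-1} K with D_alpha = diag(q^{-alpha}) that circulates in the
literature does not, read literally, produce a Markov matrix. The package
implements the standard two-step construction — divide by q_i^alpha
q_j^alpha, then row-normalise — which is the construction with the stated
generator limit.

The target-measure variant (TMDmap) right-normalises the kernel with known
target-density values: K_pi = K diag(sqrt(pi)/q), L = (Dt^{-1} K_pi - I)/eps
with Dt the row sums of K_pi. Any positive rescaling of pi cancels, so
unnormalised Boltzmann factors are valid input. This is the tool used to
unbias metadynamics-biased samples.

Eigenproblems: the alpha-normalised P_eps is similar to the symmetric matrix
D^{1/2} P D^{-1/2} (D = row sums of the normalised kernel), so its spectrum
is computed with a symmetric solver (dense below m = 600, shift-free ARPACK
`LA` above, tolerance 1e-10, deterministic start vector from a seed) and is
exactly real. The TMDmap matrix is not symmetrisable and goes through the
non-symmetric ARPACK path on P; imaginary parts above 1e-8 raise rather than
being silently discarded. Eigenvectors carry a fixed convention: unit
2-norm, largest-magnitude entry positive. Row sums of every generator vanish
to 1e-10 and P_eps is row-stochastic — both are asserted by tests.

The kernel bandwidth eps is required configuration; there is no automatic
tuner. `kernel_bandwidth_diagnostic` returns the (eps, total kernel mass)
log–log table whose slope ~ d/2 identifies the well-scaled regime. The
kernel cutoff defaults to 0 (dense); with a cutoff the matrix is sparse, the
cut is applied symmetrically, and a disconnected kernel graph (or isolated
point) raises with the component sizes.

Nystrom extension: an eigenvector psi_j is evaluated off-sample as the
re-evaluated, normalised kernel row applied to [psi_j], divided by the
*Markov* eigenvalue 1 + eps lambda_j. The source text writes the denominator
as lambda_j without fixing the matrix; the Markov-eigenvalue choice makes
the extension exact at the training points (it is the eigen-equation
itself), which the tests assert at 1e-8.

## Committors, Dirichlet spectra, QSD

The committor between index sets A and B solves
`L[c,c] q[c] = -L[c,b] 1` over the free indices c, with q = 0 on A and
q = 1 on B (A enters only through exclusion). Dense systems are solved by
direct factorisation below 2 * 10^4 unknowns, above that by GMRES with
diagonal preconditioning at residual 1e-10; a singular free block
(disconnected from A and B) raises. Values outside [-0.05, 1.05] are
*flagged*, never clamped — the discrete maximum principle holds only
approximately.

Dirichlet eigenproblems on the cloud use the principal submatrix L[Omega,
Omega] (identical eigenpairs to zeroing exterior rows for vectors supported
in Omega, but better conditioned). Two systematic effects are worth knowing:

* the absorbing boundary is smeared over the kernel width, shifting
  eigenvalues by O(sqrt(eps)); eigenvalue *ratios* cancel the shift. At
  eps = 0.01 the absolute shift on the flat-potential test is 15–19%.
* committor values within a kernel width of the boundary sets are biased
  toward the set value; the sup-norm error against the pseudo-spectral
  reference decays roughly like sqrt(eps) (0.16 at eps = 0.1, 0.05 at
  eps = 0.02 on the 1-D double well). The committor reproduction therefore
  runs at eps = 0.025.

The 1-D reference solver discretises -beta V' d/dx + d^2/dx^2 with Chebyshev
differentiation on Gauss–Lobatto nodes; integrals use Clenshaw–Curtis
weights, off-grid evaluation barycentric interpolation. The first Dirichlet
eigenfunction's boundary layer thins exponentially as the domain grows
(v' ~ e^{beta V} near the boundary), so the solver doubles the grid until
both the eigenvalue and the eigenfunction (probed at 33 interior points)
stop moving, up to n = 2048; hitting the cap records a warning on the
result. The quasi-stationary density is nu = v e^{-beta V} / int v e^{-beta V},
and v is normalised to unit mean against the Boltzmann measure restricted to
the domain — that convention turns "v tends to 1 on compacts as the domain
grows" into a quantitative limit, which the t4 experiment measures at the
minimum x = 1 (deviation 1e-3 at L = 3 and below solver precision, ~1e-12,
from L = 5 on).

`qsd_generator_spectrum_1d` provides an independent oracle for the operator
a diffusion map estimates on quasi-stationary samples
(Laplacian + grad(ln nu) . grad): a Sturm–Liouville flux-form finite
difference scheme weighted by nu, whose vanishing at the domain ends encodes
the confinement. The Fleming–Viot cross-check agrees with it within 20% on
the 1-D double well.

## Metastable sets, exit detection, adaptive loop

Metastable sets are grown from the extrema of the first nontrivial
eigenvector: centres at argmax/argmin of phi_1, members within a Euclidean
threshold of their centre in the first few diffusion coordinates (raw
eigenvector coordinates, i.e. the t = 0 weighting — the threshold is
user-set, so any e^{lambda t} weighting would be absorbed into it). Ambiguous
points join the nearer centre, ties toward A. Note a geometric fact that
matters in practice: with a 1-D embedding, a threshold of half the
inter-centre distance makes the two balls cover the entire embedding and
leaves no transition region; the committor experiments use 0.3x the
inter-centre distance, which keeps the well cores in A/B.

The exit monitor cuts a trajectory into windows of `window_size * subsample`
steps, keeps every `subsample`-th point, builds an alpha = 1/2 map per
window and records its k dominant nonzero eigenvalues, their mean, and the
maximal change of corresponding eigenvalues between consecutive windows. An
exit is flagged when the mean jumps by more than `jump_factor` (default 5)
trailing standard deviations of the preceding window means (at least 3
windows of history); both raw series are exposed so users can apply their
own rule — the source article plots the statistics without fixing a trigger.
On the 2-D double well at beta = 10 with 1000-point windows the unbiased
window means are stable to ~5% and a metadynamics-induced barrier crossing
is flagged at the crossing window itself. A caveat the package documents
rather than hides: a bias *growing during* the monitored windows deforms the
local spectrum continuously, which inflates the trailing deviation; the exit
test therefore equilibrates unbiased first and biases aggressively
afterwards.

The adaptive loop (reconstructed from the narrative description; the
original algorithm listing is available only as a figure) iterates: (1)
sample the current state (plain Langevin or Fleming–Viot) under all
previously accumulated bias, monitoring the windowed spectrum until the
means stabilise (relative change < 5% over 3 windows; an unconverged
iteration is marked inconclusive, not an error); (2) build the alpha = 1/2
map on the last window; (3) rank candidate CVs by |Pearson rho| against the
leading diffusion coordinates and choose the best distinct candidate per
coordinate (population 1/m moments; ties to the lower index); (4) run
metadynamics along the chosen CV, keeping earlier hills active; (5) count
well-to-well transitions (with a +-0.5 hysteresis deadband so barrier-top
recrossings are not double counted) and record a TMDmap reweighting
diagnostic — the biased samples with target Boltzmann factors should
reproduce the unbiased generator, and the report carries the first nonzero
TMDmap eigenvalue.

Candidate CVs for the toy systems are coordinate projections and linear
combinations, plus a "pure noise" control: sin(omega a.x) with a random
direction a and amplitude 0.01/omega. The amplitude matters: Pearson ranking
is scale-invariant, but metadynamics along a unit-amplitude oscillating CV
pumps energy into the system (the accumulated bias derivative random-walks)
and would drive spurious transitions; the small amplitude makes the control
what it is meant to be — a bias that cannot resolve configuration space and
therefore achieves nothing, matching the reported behaviour of
least-correlated CVs.

## Synthetic experiments: sizes and what they show

All acceptance-grade inputs are generated internally. The study conditions:

* OU cloud: V = x^2/2, beta = 1, dt = 0.1 (`lm`), 2 * 10^5 steps subsampled
  at stride 100 to m = 2000 — near-independent samples (correlation time 1).
* 1-D double wells: beta = 1, dt = 0.1, 10^5 steps subsampled to 10^4.
* 2-D double well (h = 2, w = 1): trapped/global clouds at the article's
  beta = 10 (dt = 0.05); the committor experiment at beta = 2, dt = 0.01,
  10^6 steps subsampled to 10^4, eps = 0.1 — at beta = 10 no sampled point
  lies near the barrier, and the experiment's own definition requires a
  temperature at which both wells are visited.
* error-scaling study: N in {250, 500, 1000, 2000, 4000} subsampled points,
  eps = 5e-4, 6 replicate trajectories averaged per N. eps is chosen small
  enough that the deterministic eps-bias sits below the sampling error over
  the whole range; at larger eps the bias floor flattens the curve and the
  asymptotic N^{-1/2} statistical regime is unobservable at these N.
* adaptive loop: 4 * 10^4 sampling steps, 6 * 10^4 biasing steps per
  iteration, hills 0.3 x 0.2 every 250 steps, 1000-point windows, eps = 0.01.

What passing does *not* show: these clouds are low-dimensional, their
densities are smooth and single-scale, and the candidate CV lists are tiny.
Real molecular data adds high ambient dimension (where a single global eps
is often inadequate — variable-bandwidth kernels are out of scope), alignment
ambiguities, and heavy-tailed sampling noise; the package's claims about
convergence rates and CV selection are validated only in the toy regime.

## Known limitations

* The Dirichlet/committor boundary smearing above: absolute exit rates from
  point-cloud Dirichlet spectra carry an O(sqrt(eps)) bias.
* TMDmap eigenpairs use a non-symmetric solver; for very sparse kernels the
  computation can fail with complex-pair warnings rather than degrade
  silently.
* The pseudo-spectral reference is 1-D only; multi-dimensional references
  are out of scope.
* Fleming–Viot uses a fixed replica count with no population-size control;
  it samples the QSD of the *discretised* dynamics, so its law carries the
  integrator's O(dt) (Euler) or O(dt^2) (`lm`) bias.
* Spectrum-based exit detection assumes the monitored windows are
  bias-stationary; a rapidly growing bias degrades the trigger (see above).
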