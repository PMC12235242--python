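# Methods

`chromsol` simulates reversed-phase gradient-elution chromatography of a
ternary mixture with a differentiable mechanistic column model, and trains a
small node-wise neural network that multiplies the adsorption rates inside
every implicit solver step ("solver-in-the-loop" hybrid modeling). This note
records the model, its numerical treatment, the design of the synthetic
benchmark, and the choices made where the design was genuinely open.

## Column model

Mobile phases follow an equilibrium-dispersive transport model on a 1-D
column of length $L$ with total porosity $\varepsilon_t$ and superficial
velocity $u$:

$$\partial_t c_i = -\frac{u}{\varepsilon_t}\,\partial_z c_i
  + D_\text{app}\,\partial_z^2 c_i
  - \frac{1-\varepsilon_t}{\varepsilon_t}\,\partial_t q_i,$$

with the organic modifier $c_m$ (carried in %B units throughout) obeying the
same equation without the adsorption sink. Apparent dispersion lumps all band
broadening via the plate count $N$: $D_\text{app} = uL/(2\varepsilon_t N)$,
recomputed per method step so dispersion follows the step's flow rate.

Adsorption follows a simplified stoichiometric-displacement rate law (SDM):

$$k_{\text{kin},i}\,\partial_t q_i =
  k_{\text{eq},i}\Bigl(\Lambda - \sum_j(\nu_j+\sigma_j)q_j\Bigr)^{\nu_i} c_i
  - q_i\,c_m^{\nu_i},$$

where $\nu$ is the characteristic charge, $\sigma$ the steric shielding
factor and $\Lambda$ the ligand density. The stationary modifier balances
the displaced charge, $\partial_t q_m = -\sum_j \nu_j\,\partial_t q_j$, so
$q_m + \sum_j \nu_j q_j$ is conserved pointwise by construction; the initial
condition sets $q_m(0)=\Lambda$ so this invariant has an interpretable datum.
Danckwerts (flux) inlet and zero-gradient outlet conditions close the system.
Since the modifier appears as $c_m^{\nu}$, all $k_\text{eq}$ values are on
the %B basis.

## Discretization and time integration

Space: nodal discontinuous-Galerkin finite elements on a uniform mesh
(default 7 elements of degree 3), Legendre–Gauss–Lobatto nodes, upwind
convective flux, local-DG (first-order system) diffusion with central
fluxes. The Danckwerts condition is imposed weakly by prescribing the total
inlet flux $v\,c_\text{in}$ ($v=u/\varepsilon_t$), which is its exact flux
form; the outlet carries pure convective outflow. The operator is affine in
the field for fixed boundary data and is assembled once per method step as a
matrix plus an inlet-injection vector. The flux choices are the standard
stable pair for chromatography DG solvers; slope limiters are deliberately
absent (oscillations are controlled by resolution and monitored, not
clamped).

Time: fixed-step BDF of orders 1–5. The step is a fraction of the total
simulated time (default 5‰, i.e. 200 steps); solver steps are aligned with
method-step boundaries so the discontinuous forcing (velocity jumps, feed
switching) is never integrated across, and the order ramps 1→5 from the
start of every method step so the multistep history never spans a
discontinuity. Each implicit step is solved by Newton iteration with an
analytic right-hand-side Jacobian: a chord phase (LU frozen at the
predictor, which reuses the previous step's converged-state factorization
when orders match), one rebuild at the current iterate, and a damped
full-Newton fallback for the rare stiff-wave steps. Newton tolerances are
relative to per-column magnitudes, because the state spans g/L
concentrations and ligand-density units. Power-law bases are clipped far
outside the physical range only to keep non-finite values out of rejected
Newton trial states; accepted states are physicality-checked (surface
overload and non-positive modifier raise errors, negative mobile
concentrations are logged, not clamped).

## Differentiability

Gradients are discretize-then-optimize: the loss cotangent is propagated
backwards through every accepted BDF step using the implicit-function
theorem — one transposed LU solve per step with the factorization stored at
the converged state — accumulating vector-Jacobian products with respect to
the correction-network parameters and, for calibration, the adsorption
parameters $(\nu, k_\text{eq}, \sigma, k_\text{kin})$. All Jacobians and
VJPs are hand-derived and finite-difference-verified in the test suite; the
end-to-end loss gradient matches central differences to ~1e-7 relative on a
small configuration. Double precision is the default: single-precision
finite-difference gradient verification is unreliable, and the conservation
checks resolve drifts at 1e-8.

## Correction network

A fully connected network, shared across mesh nodes, maps the 7 local
features $(c_m, \tilde c_W, \tilde c_P, \tilde c_S, \tilde q_W, \tilde q_P,
\tilde q_S)$ — adsorbates normalized by their feed concentrations, modifier
unscaled, $q_m$ excluded — to 3 strictly positive multipliers applied to the
adsorption rates before each implicit solve. Transport terms are never
corrected, and the stationary-modifier balance and mobile-phase coupling are
recomputed from the corrected rates, so the charge-conservation structure
survives hybridization. ReLU activates the hidden layers (default 2 × 14);
Softplus keeps the outputs positive so the rate signs remain controlled by
the mechanistic operator.

The output layer is initialized at the identity-correction point (zero
weights, bias $\ln(e-1)=\mathrm{softplus}^{-1}(1)$) while hidden layers use
Kaiming initialization. A purely Kaiming-initialized Softplus output would
start near 0.69, visibly perturbing the calibrated model; the identity
initialization makes the fresh hybrid *exactly* the mechanistic model, which
the degeneracy tests check to 1e-10.

## Loss, training, calibration

The loss is a normalized mean-squared error on fraction-averaged
chromatograms, $\lVert\hat C - C\rVert^2 / \lVert C\rVert^2$, pooled over
the adsorbate columns (each normalized by its feed concentration) and
averaged over experiments. By default the modifier column is **excluded**
from the pooling: in this package's synthetic benchmark the modifier outlet
is reproduced exactly by construction (its transport is uncorrected and
decoupled from adsorption), so including it would only dilute the adsorbate
signal ~30-fold; `include_modifier=True` restores the literal all-four-
columns form for data where the modifier carries real misfit.

Training is full-batch Adam (defaults: rate 1e-3, moments 0.9/0.999,
eps 1e-8, 2000 epochs with the best epoch retained) on the network
parameters only; mechanistic parameters are frozen after calibration.
Calibration minimizes the same loss over log-transformed adsorption
parameters (strict positivity for free) with exact adjoint gradients through
the mechanistic simulator via L-BFGS-B, optionally preceded by a coarse
one-at-a-time scan of each free parameter. The hyperparameter grid search
trains every (layers, width, rate) cell for 20 epochs from a shared
initialization seed and reports the full table, the argmin (ties break
toward fewer parameters, then lower rate) and the fraction of cells beating
the mechanistic baseline.

## Synthetic benchmark

Six linear-gradient experiments on a 100 × 4.6 mm column (total porosity
0.54): loads of 7.5/15/22.5 g per litre of packed column crossed with
gradient lengths of 4.6/6.5/8.5 CV in the six standard combinations, split
1:1 into training and test roles so that testing extrapolates in both load
and gradient length. Each run follows the five-step method table
(equilibration 3 CV at 400 cm/h, load at 300, wash 2 CV at 150, 30→100 %B
gradient at 200, strip 2 CV at 150). The feed is 1 g/L total at
W:P:S = 10% : 88.8% : 1.2% — the strongly adsorbed impurity is a trace
component; the load step's duration in CV is load divided by that feed
concentration, and it runs at the 30 %B of its neighbours.

Ground truth = the mechanistic model times a known smooth positive
correction, integrated by the same solver: $g_W \equiv 1$,
$g_P = 1 + 0.3\,\tilde c_P/(0.1+\tilde c_P)$ and
$g_S = 1 + 4\,\tilde q_S/(3+\tilde q_S)$, with features passed through a
smooth positive part (discretization undershoots must not flip the
correction's sign). Outlet concentrations are averaged over 0.5 CV fraction
windows tiling the gradient step only, then perturbed with seeded 2%
relative Gaussian noise truncated at zero.

Parameter magnitudes are fixtures set by forward screening; the orderings
are the physically meaningful content ($\nu_W < \nu_P < \nu_S$, hence
retention ordering W < P < S; $\sigma_S = 0$). Specific choices and why:

- **Charges/shielding** $\nu = (6.0, 7.7, 12.6)$,
  $\sigma = (29.2, 12.5, 0)$, $\Lambda = 4\times10^4$ (model units):
  strong 30 %B retention for full capture at the highest load, elution
  at roughly 65/78/88 %B, and mild capacity saturation at high loads.
- **Kinetics** $k_\text{kin}$ set so adsorption relaxes in ~3 s (W), ~20 s
  (P) and ~80 s (S) at each species' elution composition: W is effectively
  equilibrium-controlled, P and S visibly rate-limited, so multiplicative
  rate corrections leave a clear, learnable fingerprint. A rate correction
  cannot shift an adsorption *equilibrium*, only its approach speed —
  which is also why the truth corrections act on the rate-limited species
  and why corrections on the trace component S (whose occupancy is a
  negligible share of $\Lambda$) do not feed back on the other species
  through the shared free-ligand term.
- **Bounded $g_S$**: $\tilde q_S$ normalizes the trace impurity by its tiny
  feed concentration and reaches several hundred during elution; an
  unbounded linear boost there would produce rate multipliers in the
  hundreds and intractable implicit systems. The saturable form keeps the
  multiplier ≤ 5 while still roughly quadrupling S's kinetics wherever S
  is adsorbed.
- **Plate count** $N = 10$ (apparent, lumping extra-column broadening) and
  **0.5 CV fractions**: chosen so every peak is well resolved even on the
  reduced 4-element quadratic training mesh. Under-resolved peaks ring
  (Gibbs), and zero-truncated noisy observations of a ringing signal
  acquire a rectification bias that no adsorption correction can fit; at
  this smoothness the bias is below the noise floor at both benchmark
  resolutions.

What the generator does *not* emulate: detector characteristics, injection
dead volumes, fraction re-assay error structure, conductivity measurement
and its conversion to %B, temperature effects, buffer chemistry. Passing the
recovery benchmark therefore shows that the training machinery can identify
a kinetic correction from few fractionated, noisy runs when the transport
model is right; it does not certify performance against transport-model
error on real columns.

## Problem sizes and reproducibility

Default simulation resolution is 7 cubic elements with 200 BDF steps;
training and hyperparameter searches run on a reduced mesh of 4 quadratic
elements with 100 steps, which this package treats as its standard few-shot
configuration (the recovery study trains 2 hidden layers × 14 nodes at rate
1e-3 for up to 500 epochs on the three training runs). All randomness —
benchmark noise, network initialization, grid-search initialization — is
driven by explicit integer seeds; two runs with identical seeds produce
identical observations, losses and trained parameters up to the linear-
algebra backend's bitwise behavior.

## Known limitations

- The equilibrium-dispersive model carries no pore/film mass-transfer
  resistances; the SDM omits activity corrections for the organic modifier.
- Fixed-step BDF has no error estimator; accuracy is controlled by the step
  fraction, and solver step boundaries assume the method table's
  discontinuities are the only non-smooth forcing.
- DG fields are not limited: strongly under-resolved settings can produce
  negative concentration undershoots (logged), and the benchmark was
  deliberately smoothed so these stay negligible at the shipped resolutions.
- Mechanistic calibration recovers parameters of the model family that
  generated the data; with structurally misspecified data the log-space
  L-BFGS search only guarantees a loss no worse than its starting point.
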