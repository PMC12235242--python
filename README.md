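# chromsol

Differentiable simulation of reversed-phase gradient-elution chromatography
with a solver-in-the-loop neural correction of the adsorption kinetics.

Preparative chromatography of oligonucleotides (and biologics generally) is
usually modeled mechanistically: an equilibrium-dispersive column model

$$\partial_t c_i = -\tfrac{u}{\varepsilon_t}\partial_z c_i
  + D_\text{app}\partial_z^2 c_i
  - \tfrac{1-\varepsilon_t}{\varepsilon_t}\partial_t q_i$$

coupled to a stoichiometric-displacement adsorption rate law

$$k_{\text{kin},i}\,\partial_t q_i =
  k_{\text{eq},i}\bigl(\Lambda-\textstyle\sum_j(\nu_j+\sigma_j)q_j\bigr)^{\nu_i}c_i
  - q_i c_m^{\nu_i},$$

with Danckwerts inlet conditions and $D_\text{app}=uL/(2\varepsilon_t N)$.
Such models capture retention well but often miss peak shapes, because the
adsorption kinetics of real mixtures are not fully understood. `chromsol`
keeps the transport physics and lets a small fully connected network —
evaluated independently at every mesh node on the normalized local state —
multiply the three adsorption rates *inside every implicit time step*. The
whole simulator (nodal discontinuous-Galerkin space discretization, fixed-
step BDF-1..5 time integration with Newton/LU solves) is differentiable end
to end through a hand-built per-step adjoint, so the network trains by plain
gradient descent on fractionated chromatograms — a few-shot setting with
three training runs. An identity-initialized network reproduces the
calibrated mechanistic model exactly, so hybridization can only start from,
and improve on, the mechanistic baseline.

The package is aimed at downstream-process modelers who want to explore
hybrid mechanistic/learned column models without a deep-learning framework:
everything runs on numpy/scipy.

## What's in the box

| module | contents |
| --- | --- |
| `chromsol.method` | units, `ColumnSpec`, adsorption parameters, multi-step method programs, CV↔time accounting, YAML config I/O |
| `chromsol.dgfem` | nodal DG mesh and convection–dispersion operators (upwind / local-DG, weak Danckwerts inlet) |
| `chromsol.rhs` | the semi-discrete column model, analytic Jacobians and parameter adjoints |
| `chromsol.solver` | fixed-step BDF integration, Newton/LU, reverse (adjoint) sweep |
| `chromsol.network` | the node-wise correction network (ReLU hidden, Softplus output, identity-correction init) |
| `chromsol.training` | loss/R², fraction-averaged simulation, Adam training, hyperparameter grid search |
| `chromsol.calibrate` | gradient-based mechanistic calibration in log-parameter space |
| `chromsol.benchmark` | the six-experiment synthetic benchmark (3 loads × 3 gradient lengths, 1:1 train/test) with a known ground-truth correction |
| `chromsol.cli` | `chromsol generate / simulate / calibrate / train / gridsearch / evaluate` |

## Worked example

Generate the benchmark, train the hybrid model on the three training runs,
and evaluate on the three held-out runs:

```bash
chromsol generate --out bench --seed 1 --resolution 4x2 --steps 100
chromsol train --data bench --out model --epochs 500 --seed 1 \
         --resolution 4x2 --steps 100
chromsol evaluate --data bench --out eval_mech --role test \
         --resolution 4x2 --steps 100
chromsol evaluate --data bench --out eval_hyb --role test \
         --network model/network.json --resolution 4x2 --steps 100
```

The train step prints

```
loss 0.07717 -> best 0.0002877 at epoch 500; wrote model
```

i.e. the identity-initialized hybrid starts at the mechanistic misfit
(normalized MSE ≈ 7.7 × 10⁻², dominated by the kinetics of the two
rate-limited species) and the 500-epoch training drives it to ≈ 2.9 × 10⁻⁴,
essentially the 2% observation-noise floor. The two evaluate steps print
per-experiment loss and R² tables for the held-out runs:

```
         label role     loss  r2_overall     r2_W     r2_P     r2_S
  Load15_GL4p6 test 0.126757    0.814528 0.992071 0.991940 0.588208
Load22p5_GL6p5 test 0.093659    0.860928 0.990767 0.993470 0.619511
Load22p5_GL8p5 test 0.097348    0.860139 0.998961 0.987038 0.593907

         label role     loss  r2_overall     r2_W     r2_P     r2_S
  Load15_GL4p6 test 0.002177    0.996814 0.992846 0.999451 0.998563
Load22p5_GL6p5 test 0.003633    0.994605 0.988970 0.998012 0.998365
Load22p5_GL8p5 test 0.001121    0.998390 0.997896 0.998596 0.998828
```

The mechanistic model (first table) gets the well-behaved species right but
misses the strongly adsorbed trace impurity badly (R² ≈ 0.6); the trained
hybrid (second table) fixes exactly that, and the learned correction
extrapolates to a 50% higher load and a 30% shorter gradient than anything
in the training set.

The same pipeline is available as a library:

```python
from chromsol import (TruthSpec, make_programs, generate_observations,
                      build_mesh, build_models, init_network, NetworkConfig,
                      train, TrainConfig, SolverConfig)

truth = TruthSpec(seed=1)
mesh = build_mesh(4, 2, truth.column.length)
cfg = SolverConfig(step_fraction=0.01)
exps = generate_observations(truth, make_programs(truth), mesh, cfg)
train_set = [e for e in exps if e.role == "train"]
models = build_models(truth.column, truth.components, train_set, mesh)
net = init_network(NetworkConfig(2, 14, 3, init_seed=1))
report = train(models, train_set, net, TrainConfig(1e-3, 500), cfg)
print(report.best_loss, report.best_epoch)
```

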