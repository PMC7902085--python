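# gomsm

Coarse-grained Gō-model simulation and Markov state model (MSM) analysis of
protein–protein association, built around the two-body binding problem of
the barnase–barstar complex.

## The problem

Association and dissociation of a protein complex are rare events: resolving
the equilibrium constant *and* the on/off kinetics from simulation requires
either very long unbiased trajectories or a principled way to combine
unbiased runs with enhanced-sampling data. `gomsm` implements the full
workflow for a residue-level (one bead per residue) Gō model of a two-chain
complex:

- **Simulation** — Langevin dynamics (BAOAB) of a two-chain bead model whose
  inter-chain attraction is a small set of native-contact Lennard-Jones 6-12
  terms in the R_min convention, `U(r) = ε[(R_min/r)¹² − 2(R_min/r)⁶]`, plus
  an intra-chain elastic network, positional tethers on chain A, a
  flat-bottom spherical confinement on the chain-B centre of mass (fixing
  the effective concentration), and harmonic umbrella windows along the
  chain–chain COM distance.
- **Featurization** — COM distance, 1/COM², inter-chain pair distances
  filtered for long-lived contacts, minimum RMSD to the bound pose; TICA
  (`C(τ)U = C(0)UΛ`) for slow-mode extraction; k-means microstates with
  elbow selection.
- **Estimation** — reversible maximum-likelihood MSMs; TRAM multi-ensemble
  reweighting that stitches unbiased and umbrella-biased trajectories into
  one unbiased thermodynamic/kinetic model; PCCA+ metastable assignment.
- **Observables** — stationary distribution π, implied timescales,
  `K_eq = (P_bound/P_unbound)·V` with `V = (4/3)π(r_cavity³ − r_cut³)`,
  `ΔG_b = −k_BT ln(P_bound/P_unbound)`, mean first passage times and
  `k_on = 1/(MFPT_on·C)`, `k_off = 1/MFPT_off`, and the PMF route
  `K_eq = ∫₀^{r_cut} 4πr² e^{−βW(r)} dr`; bootstrap errors over trajectories.
- **Bound-state cutoff** — scans r_cut by maximizing the slow relaxation
  time of a biexponential fit `A₁e^{−t/τ₁} + A₂e^{−t/τ₂}` to the bound-state
  indicator autocorrelation.
- **Sensitivity analysis** — local derivatives `S_ij = ∂π/∂T_ij` of the
  stationary distribution, per-row Dirichlet covariance of the transition
  matrix, first-order Sobol global sensitivities
  `S_global = Σ S·cov[T,T]·S`, and conversion of the most sensitive
  microstates into a focused umbrella-window selection for TRAM.
- **Synthetic systems** — toy two-chain complexes with reachable binding
  statistics, discrete-chain samplers, birth–death chains with closed-form
  Boltzmann distributions and MFPT tables (the estimators' exact oracles),
  and two-basin jump-diffusion COM traces with a known separatrix.

## Worked example

```python
import numpy as np
from gomsm import (ToyComplexSpec, make_toy_complex, LangevinParams,
                   run_langevin, geometry_features, kmeans_cluster,
                   DiscreteTrajectory, count_transitions,
                   estimate_transition_matrix, binding_observables)

cplx, bound_pose = make_toy_complex(ToyComplexSpec(seed=1))
runs = [run_langevin(cplx, LangevinParams(timestep=20.0, n_steps=120_000,
                                          save_stride=25, seed=s))
        for s in range(4)]
com = [geometry_features(r, "com_distance") for r in runs]
X = np.vstack([c.values for c in com])
disc = kmeans_cluster(X, 30, seed=1)
dtrajs, ofs = [], 0
for c in com:
    dtrajs.append(DiscreteTrajectory(disc.assignments[ofs:ofs + c.n_frames],
                                     c.frame_interval))
    ofs += c.n_frames
model = estimate_transition_matrix(count_transitions(dtrajs, lag=40))
state_com = np.array([X[disc.assignments == i, 0].mean() for i in range(30)])
bound = np.where(state_com[model.active_set] <= 12.0)[0]
obs = binding_observables(model, bound, r_cavity=25.0, r_cut=12.0)
print(f"P_bound = {obs.P_bound:.3f}")
print(f"K_eq    = {obs.K_eq:.3g} A^3")
print(f"dG_b    = {obs.dG_b:.3f} kcal/mol")
print(f"k_on    = {obs.k_on:.3g} A^3/s")
print(f"k_off   = {obs.k_off:.3g} 1/s")
```

Output on this configuration:

```
P_bound = 0.283
K_eq    = 2.29e+04 A^3
dG_b    = 0.555 kcal/mol
k_on    = 1.97e+14 A^3/s
k_off   = 1.11e+10 1/s
```

`P_bound` is the stationary weight of microstates whose average COM distance
is within the 12 Å bound-state cutoff; `K_eq` converts the bound/unbound
ratio to a volume-scaled equilibrium constant using the 25 Å confinement
cavity; the slightly positive `ΔG_b` says this shallow toy complex spends
somewhat more time dissociated than bound inside its cavity, and the
MFPT-derived rates give the corresponding association/dissociation
kinetics.

The same pipelines are scriptable from the CLI
(`gomsm make-fixture | simulate | umbrella | featurize | cluster | msm |
rcut-scan | workflow ...`).

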