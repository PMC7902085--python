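# Methods

## The coarse-grained model

Each chain of a two-protein complex is mapped to one bead per residue
(default mass 110 amu).  The inter-chain interaction is a Gō-type potential:
a curated set of native-contact pairs, each a Lennard-Jones 6-12 term in the
R_min convention

    U(r) = ε [ (R_min/r)^12 − 2 (R_min/r)^6 ],

so a tabulated minimum distance is exactly the pair minimum and −ε its
depth.  This convention (rather than the σ form) makes tabulated contact
distances directly usable as parameters.  The remaining terms:

- **Intra-chain elastic network** — harmonic bonds between all intra-chain
  bead pairs within 12 Å of each other in the reference pose
  (k = 10 kcal/mol/Å²), rest length equal to the reference separation.
  This stands in for fold-preserving RMSD-type restraints: same intent
  (rigidify each chain around its native fold), simpler analytic gradient.
- **Chain-A tethers** — per-bead harmonic restraints to the reference
  positions (k = 10 kcal/mol/Å²), pinning chain A at the origin in both
  position and orientation, so the binding coordinate is carried entirely
  by chain B.
- **Flat-bottom confinement** — zero inside radius `r_cavity`, half-harmonic
  (k = 10 kcal/mol/Å²) on the chain-B centre-of-mass radius outside.  The
  cavity fixes the effective concentration C = 1/V of the single free
  chain; C is always computed from the geometry, never assumed.
- **Umbrella bias** — U = (k/2)(d − d₀)² on the mass-weighted COM–COM
  distance d.  The ½ convention is declared here and used consistently
  everywhere a bias energy enters (notably the TRAM bias matrices).

The fold-restraint, wall and tether force constants are not physical
observables of the model; 10 kcal/mol/Å² is stiff relative to k_BT over the
relevant displacements yet soft enough for multi-femtosecond integration.
Units: Å, kcal/mol, amu, fs/ps/ns; k_B = 0.0019872041 kcal/(mol·K), so
k_BT = 0.596 kcal/mol at 300 K.

## Dynamics

Langevin dynamics is integrated with the BAOAB splitting, which has very
small configurational sampling bias at the force constants used here even
at 5–10 fs steps (the stiffest mode, a 10 kcal/mol/Å² spring on a 110 amu
bead, has period ≈ 1 ps).  Defaults: 300 K, friction 1 ps⁻¹.  Every run is
seeded explicitly; umbrella campaigns derive per-window seeds as
`base_seed + window_index`, making campaigns reproducible and
order-independent.  Each umbrella run stores, per saved frame, the reduced
bias energy of that frame in *every* window (the TRAM input matrix); bias
energies exist only at saved-frame resolution.

## Featurization and discretization

Features: chain–chain COM distance (Å), its inverse square (Å⁻²; an
"indirect" reaction coordinate), inter-chain bead pair distances, and the
minimum RMSD to the bound pose (optimal superposition via Kabsch).  Pair
distances are pre-filtered by the long-lived-contact rule: a pair is kept
iff some single trajectory holds it below 12 Å for a contiguous segment of
at least the minimum lifetime (1 ns at production scale); frames exactly at
the cutoff count as unbound, and a lifetime below the frame interval is an
error rather than silently unresolvable.

TICA solves C(τ)U = C(0)UΛ on mean-free data, with both covariances
estimated with 1/(N−τ−1) normalization per trajectory segment (no
cross-trajectory products), the lagged covariance symmetrized — required
for a real spectrum, harmless for reversible dynamics — and C(0) ridge
regularized by 10⁻⁸·tr(C0)/d on the diagonal.  Implied timescales are
−τ·Δt/ln|λ|.  Discretization is k-means (k-means++/Lloyd, deterministic per
seed, nearest-centre assignment with lowest-index tie-break); the number of
clusters can be chosen by the elbow rule, implemented as the point of
maximum perpendicular distance to the chord of the inertia curve, with a
warning on degenerate (linear) curves.

## MSM estimation and observables

Transition counting is sliding-window; the correlation between overlapping
counts is handled by bootstrapping whole trajectories rather than by count
subsampling.  Estimation restricts to the largest strongly connected
component (largest total counts on ties).  The reversible maximum-likelihood
estimate uses the classical symmetric-flux fixed point
x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j), iterated to 10⁻¹² on π; the
detailed-balance residual of the result is below 10⁻⁸.  PCCA+ memberships
come from the m dominant eigenvectors (computed on the π-symmetrized
matrix) via the inner-simplex vertex construction, clipped and renormalized.

Binding observables for the confined two-body system:

    V = (4/3)π(r_cavity³ − r_cut³),  C = 1/V
    K_eq = (P_bound/P_unbound)·V
    ΔG_b = −k_BT ln(P_bound/P_unbound)
    k_on = 1/(MFPT_on·C),  k_off = 1/MFPT_off

Set-to-set MFPTs solve the first-step linear system with the target set
absorbing and average over the source set with the stationary distribution
restricted and renormalized.  A caveat worth knowing: the identity
K_eq = k_on/k_off is exact for two-state models but holds for multistate
chains only when the source/target sets are metastable basin cores.  If a
barrier-top state is lumped into one side's complement, the "off" passage
terminates at the barrier top while the "on" passage crosses it fully, and
the identity degrades even with large timescale separation.  The bound set
may be defined by a COM-distance cutoff on microstate averages or by
two-state PCCA; both are exposed.

The PMF route K_eq = ∫₀^{r_cut} 4πr² e^{−βW(r)} dr uses trapezoidal
quadrature with the endpoint interpolated exactly at r_cut, and warns when
the profile tail is not near zero (the caller owns the offset convention
W(∞) = 0).

## Bound-state cutoff

The indicator h(t) = 1 iff COM distance ≤ r_cut (boundary bound).  Its
autocorrelation is estimated per trajectory (mean-subtracted,
variance-normalized, biased FFT estimator so C(0)=1) and aggregated by
length-weighted averaging — never concatenation, which would fabricate
cross-trajectory correlations.  A constrained biexponential
A₁e^{−t/τ₁} + A₂e^{−t/τ₂} (A_i ≥ 0, τ_i > 0, reported with τ₁ ≤ τ₂) is fit
by bounded least squares, initialized from log-linear fits of the head and
tail of the curve; near-degenerate fits (vanishing amplitude or τ₁ ≈ τ₂)
are flagged rather than rejected.  The cutoff scan maximizes τ₂ — the slow
relaxation, interpreted as the bound-state lifetime; both times peak
together in practice — with ties to the smaller cutoff, and failed fits
recorded per grid point.

## TRAM

The multi-ensemble estimator maximizes the joint likelihood of (i)
reversible transitions within each thermodynamic ensemble k with
equilibrium weights π_i^k ∝ e^{−f_i^k}, and (ii) the observed frames under
the discretization-consistency constraint
e^{−f_i^k} = Σ_{x∈X_i} μ(x)e^{−b^k(x)}, where X_i collects every frame in
microstate i from any ensemble and μ are unbiased sample weights.
Stationarity of the likelihood gives the self-consistent scheme iterated
in log space:

    T^k_ij ∝ (c^k_ij + c^k_ji) e^{f_i^k} / (v_i^k e^{f_i^k} + v_j^k e^{f_j^k})
    v_i^k ← v_i^k Σ_j T^k_ij
    R_i^k = Σ_j (c^k_ij + c^k_ji) v_j^k e^{f_j^k} / (v_i^k e^{f_i^k} + v_j^k e^{f_j^k})
            + N_i^k − col_i^k
    e^{−f_i^k} ← Σ_{x∈X_i} e^{−b^k(x)} / Σ_l R_i^l e^{f_i^l − b^l(x)}

Two limits pin the implementation down: a single unbiased ensemble reduces
exactly to the reversible MSM MLE, and the transition-free limit reduces
exactly to MBAR.  The gauge freedom (μ → cμ, f → f + ln c) is fixed by
normalizing the first ensemble's weights each iteration.  Convergence is
measured on the gauge-fixed free energies only: the Lagrange multipliers
can drift without bound when a within-ensemble transition-matrix MLE sits
on the simplex boundary (entries tending to 0/1), while every reported
quantity converges.  Defaults: tol 10⁻¹⁰ (k_BT), max 10⁵ iterations;
disconnected ensemble graphs raise an error naming the state groups.
The unbiased stationary distribution evaluates the converged μ-weights at
zero bias; per-ensemble transition matrices come from the closed form above
with rows renormalized.

## Sensitivity analysis and window selection

Local sensitivities ∂π_i/∂T_jk use the row-compensation convention (the
diagonal T_jj absorbs the perturbation, keeping rows stochastic) and are
computed analytically: dπ = πEZ with Z = (I − T + 1π)⁻¹, giving
∂π_i/∂T_jk = π_j(Z_ki − Z_ji).  Transition-matrix uncertainty is modelled
as independent per-row Dirichlet posteriors over the counts (+ optional
pseudocount), cov[T_ij, T_il] = T̄_ij(δ_jl − T̄_il)/(c_i + αn + 1), zero
across rows.  The global (first-order Sobol) sensitivity of each π entry
propagates the row blocks through the local derivatives; it is validated
against Dirichlet Monte-Carlo resampling in the well-counted regime.
Microstates are ranked by their π-entry sensitivity (ties to smaller
average COM); the smallest prefix accumulating 90% (default) of the total
selects all umbrella-grid centres within the prefix's average-COM span —
the focused window set for TRAM.

## The synthetic systems, and what passing tests do and do not show

`make_toy_complex` builds two compact random bead blobs (≥ 2.5 Å bead
separation), places them in contact along +x, and turns the closest
inter-chain pairs of that pose into Gō contacts with R_min equal to the
bound-pose distance — so the bound pose is the joint contact minimum by
construction.  Defaults (8+6 beads, 3 contacts, ε = 1.25 kcal/mol, 25 Å
cavity) put the toy in the same regime as the reference system: a
bound/unbound population ratio of order one (measured P_b/P_u ≈ 0.65)
with roughly 10 association/dissociation events per 10⁵ steps, so full
binding statistics are reachable in minutes.  The desk-scale campaign
analyzed in the tests uses 6 unbiased runs of 1.5·10⁵ steps at 10 fs and
20 umbrella windows (5–24 Å at 1 Å, spring 1 kcal/mol/Å² — the production
protocol's spacing and stiffness, scaled to the toy cavity) of 2·10⁴ steps,
30 COM microstates, a 0.02 ns lag, and 10 bootstrap replicates.

The birth–death references are nearest-neighbour Metropolis chains whose
stationary distribution is Boltzmann in the prescribed state energies by
construction and whose MFPT table comes from the classical first-step sum
formula, verified internally against a dense linear solve to 10⁻¹⁰.  The
two-basin jump-diffusion COM trace switches between Ornstein–Uhlenbeck
basins with exponential dwells; its default geometry places both basin
edges 2.5σ from 29 Å, making 29 Å the noise-minimizing separatrix for the
cutoff-scan check.

What these fixtures do not emulate: real side-chain packing, solvent or
hydrodynamics, rugged binding funnels with competing poses, internal
flexibility beyond the elastic network, or the production system's state
count (hundreds of microstates) and timescales (tens of ns).  Tests passing
on them validate estimator correctness, conventions and the qualitative
phenomena (TRAM data efficiency, sensitivity localization at short COM
distances, cutoff-scan behaviour) — not quantitative accuracy on any real
protein complex.

## Numerical choices and known limitations

- Ridge 10⁻⁸·tr(C0)/d on TICA's C(0); rank deficiency beyond that raises
  with the null directions listed.
- Reversible MLE tolerance 10⁻¹² on π; MarkovModel validates row sums to
  10⁻¹², πT = π to 10⁻¹⁰ (also re-checked when a model document is loaded).
- Biexponential fits can be ill-conditioned when τ₂/τ₁ < 3 or an amplitude
  vanishes; such fits carry a degeneracy flag.
- TRAM's bound-state kinetics use the unbiased ensemble's transition
  matrix; when the unbiased data alone do not connect all microstates the
  rates are reported as unavailable rather than extrapolated (K_eq and
  ΔG_b, which need only π, are always reported).
- The bootstrap resamples whole trajectories; for few long runs its error
  bars are themselves noisy (the toy campaign uses 6 runs).
- PCCA+ uses the inner-simplex construction without the subsequent
  constrained optimization refinement; for the well-separated metastable
  structures targeted here the crisp labels agree with the block structure.
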