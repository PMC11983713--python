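# Methods

This note documents the model, its assumptions, every numeric choice that a
maintainer might want to revisit, what the synthetic-label generator does
and does not emulate, and the known limitations.

## 1. The model

The package implements a flexible 3-site water force field whose
electrostatics are *dynamic*: at every energy evaluation the atomic partial
charges and the pairwise intermolecular charge transfer (CT) are predicted
fresh from the instantaneous geometry by small dense neural networks. The
prediction is a direct map — there is no iterative self-consistency loop of
the charge-equilibration family — which keeps the cost per step close to a
fixed-charge model while restoring environment dependence, hydrogen-bond
directionality and out-of-plane polarization through the CT term.

### Descriptors

Each atom's environment is summarized by interaction-classified radial
functions (ICFs),

    f_i^{αβ} = Σ_{j ∈ class β} exp(−k_f · r_ij) · s_c(r_ij),

where the class β of a neighbor is its element (O or H) together with its
intra-/intermolecular relation to the center, and
s_c(r) = ½[cos(π r/r_c) + 1] for r ≤ r_c (0 beyond) smoothly gates
neighbors in and out of range. ICFs are translationally, rotationally and
permutationally invariant and need no angular terms: atomic charges are
scalars, and the element-resolved radial shells carry enough information.

* **Charge features** (24 per atom): for each of three decay constants
  k_f = 0.5, 1.0, 2.0 Å⁻¹ — a geometric ladder spanning first-shell-peaked
  to slowly-decaying profiles; configurable — the atom's intramolecular ICFs
  (classes O, H), its intermolecular ICFs (O, H), and the intermolecular
  ICFs of the two other atoms of its molecule. The cutoff is
  r_c = 4.4 Å, the radius at which ~24 surrounding molecules reproduce the
  charges of a much larger environment.
* **CT features** (36 per molecule pair): for each k_f, ICFs of each atom of
  molecule I restricted to neighbors in J (classes O, H) and vice versa,
  with the CT cutoff 5.5 Å — the O–O distance at which dimer CT has decayed
  to ~1e−5 e. Swapping I and J swaps the two 18-slot halves.

**Hydrogen-mate symmetrization.** The slots that reference "the two other
atoms of the molecule" (and "the two hydrogens of a molecule" in the CT
set) would depend on the arbitrary H1/H2 file order if filled per atom. For
oxygen centers the two hydrogen mates are therefore encoded through the
elementary symmetric polynomials (sum, product) of their ICFs — smooth
functions that are exactly invariant under H relabeling, at unchanged slot
counts. Hydrogen centers order their mates by element (molecule O first),
which is already canonical.

### Networks

One network per element (O, H) plus one for pair CT; each has four hidden
layers (default widths 64-64-64-64 — not dictated by anything except being
comfortably over-parametrized for 24–36 inputs; configurable) and Swish
activation A(x) = x·σ(βx) with β = 3, which stays nearly linear around
x = 0 while remaining smooth everywhere — a requirement, since any kink in
the charge functions would put a kink in the potential-energy surface.
Features and labels are standardized with statistics frozen at training
time and stored in the weight archive.

Pair CT is antisymmetrized by construction,
δq_IJ = ½[g(F_IJ) − g(F_JI)]·S(r_OO): no network can otherwise guarantee
δq_IJ = −δq_JI. S is a quintic C² switch from 1 to 0 over the last 1 Å
below the CT cutoff. The raw network output need not vanish when a pair
leaves CT range (not all feature slots go to zero at the O–O cutoff
crossing), so without the switch the energy would jump; with it, δq and the
CT energy are exactly continuous. Sign convention: positive δq_IJ means
electron flow I → J.

**Neutralization.** The per-atom networks do not constrain the total
charge; the accumulated error (order 1e−4 e) is removed by the uniform
shift Δq = Σ_i q_i/N before any electrostatics. The shift depends on all
coordinates through every charge, and that dependence is propagated in the
forces: the cotangent of each raw charge is ∂U/∂q_i − mean_j(∂U/∂q_j).
Exactness of the total gradient was preferred over fidelity to any
unstated convention, because every conservation test downstream depends on
it.

### Energy functional

    U = Σ_I [ k_b((r_OH1 − r⁰)² + (r_OH2 − r⁰)²) + k_a(θ_I − θ⁰)² ]     intra
      + Σ_{i<j inter} ( A_ij/r_ij⁹ − B_ij/r_ij⁶ )                        vdW
      + k_e Σ_{i<j inter} q_i q_j/r_ij   (Ewald under PBC)               Coulomb
      − k_c Σ_{I<J} δq_IJ²/(δq_IJ² + 3 δq⁰²)                             CT

Conventions and defaults (all configurable through
`ForceFieldParameters`):

| constant | default | unit | note |
|---|---|---|---|
| k_b | 529.581 | kcal/mol/Å² | no-½ convention (= SPC/Fw 1059.162 with ½) |
| k_a | 37.95 | kcal/mol/rad² | no-½ convention |
| r⁰ | 1.012 | Å | SPC/Fw equilibrium bond |
| θ⁰ | 113.24 | deg | SPC/Fw equilibrium angle |
| A_OO, B_OO | 2ε r_min⁹, 3ε r_min⁶ | kcal·Å⁹/mol, kcal·Å⁶/mol | from SPC/Fw ε = 0.15539 kcal/mol, σ = 3.165492 Å, r_min = 2^{1/6}σ |
| k_e | 332.0637 | kcal·Å/(mol·e²) | Coulomb constant |
| k_c | 2.0 | kcal/mol | CT strength (package default) |
| δq⁰ | 0.02 | e | reference CT (package default) |
| r_cut | 5.5 | Å | vdW/real-space cutoff under PBC |

* **Harmonic convention.** All intramolecular terms are written without the
  ½ factor; published SPC/Fw constants (½-convention) are stored as
  published in `SPCFWParameters` and halved internally. The originally
  tuned intramolecular and CT constants of the neural model are not
  publicly tabulated; the defaults above are the package's own documented
  choice (SPC/Fw-like intra terms, CT constants at the physically expected
  scale of ~1 kcal/mol per hydrogen bond and ~0.02 e per contact).
* **9–6 van der Waals.** The softer r⁻⁹ wall (instead of 12–6) compensates
  the extra short-range attraction the CT term introduces. A and B derive
  from standard 12–6 ε/σ by matching well depth and minimum position:
  A = 2ε r_min⁹, B = 3ε r_min⁶ (so A = B = 1 puts the minimum at
  (3/2)^{1/3} ≈ 1.1447 with depth 0.1481).
* **CT functional form.** U_ct = −k_c δq²/(δq² + 3δq⁰²) is symmetric in δq,
  exactly zero at δq = 0, saturates at −k_c per pair (electron migration
  away from equilibrium attenuates the gain), and — because of the factor 3
  — the force magnitude |∂U/∂δq| peaks exactly at δq = δq⁰, which is the
  defining property of the reference CT. The CT term is additive: δq does
  not modify the atomic charges entering the Coulomb sum, since the charge
  networks are trained on CM5-style labels that already reflect
  intermolecular polarization.
* **Truncation.** Under PBC the vdW potential is multiplied by a quintic C²
  switch over the last 1 Å before r_cut. A plain energy-shifted cutoff was
  tried first and rejected: its ~0.03 kcal/mol/Å force discontinuity at the
  cutoff injects a random walk into the NVE total energy that is visible at
  the 1e−4 drift level. Clusters use untruncated sums.
* **Electrostatics.** Clusters: direct sum over intermolecular pairs.
  Periodic: standard Ewald (real + reciprocal + self) with tinfoil boundary
  conditions, orthorhombic cells, intramolecular pairs excluded in real
  space and their erf component removed from reciprocal space. The
  splitting parameter α and the k-space extent derive from one accuracy
  target (default 1e−8 relative): α = erfc⁻¹(acc)/r_cut,
  k_max = 2α√(ln 1/acc); the result is α-independent within the target
  (verified by doubling α). Reciprocal sums use per-axis integer phase
  powers, and the per-site potentials ∂U/∂q_i are returned alongside
  energies and forces for the charge chain rule.

### Forces

dU/dR = ∂U̅/∂R (explicit terms) + (∂U/∂q)·(dq/dF)·(dF/dR) +
(∂U/∂δq)·(dδq/dF_ct)·(dF_ct/dR) + the CT-switch term
(∂U/∂δq)·g·S′(r_OO)·(dr_OO/dR). The descriptor factor is implemented as a
reverse-mode adjoint (χ·dF/dR for an arbitrary cofactor χ) rather than a
materialized Jacobian; dense Jacobians exist for verification. Everything
is checked against central finite differences to < 1e−5 relative on random
clusters and periodic boxes, and the cluster force sums and torques vanish
to < 1e−8.

## 2. MD engine

Velocity Verlet (NVE) and the BAOAB Langevin splitting (NVT; friction
default 1 ps⁻¹ = 0.001 fs⁻¹, seed mandatory). No constraints — the model is
intentionally flexible, and the O–H stretch sets the step: dt = 1 fs is the
protocol default for the fixed-charge model; 0.5 fs is recommended for the
neural backend and used for all conservation tests. Instantaneous
temperature is 2·KE/(3N k_B). Forces beyond 1e4 kcal/mol/Å abort the run
with diagnostics. NVE drift is measured as |linear-fit slope × duration| of
the total energy over the run, relative to max(|mean E|, mean KE), after a
short NVE settling period discarded from the fit (the Langevin equilibrated
state is not on the Verlet shadow-energy manifold, and the first
picosecond of relaxation would otherwise masquerade as drift).

Minimization is L-BFGS with analytic gradients, quasi-Newton restarts, and
a final damped-Newton polish on a finite-difference Hessian of the analytic
gradient (the line searches of quasi-Newton methods lose precision around
1e−6 kcal/mol/Å on the stiff-bond/soft-contact energy landscape; the Newton
polish reaches the 1e−6 force criterion and beyond deterministically).

## 3. SPC/Fw baseline and the dimer benchmark

The fixed-charge counterpart uses the published SPC/Fw constants
(q_O = −0.82 e, q_H = 0.41 e, r⁰ = 1.012 Å, θ⁰ = 113.24°,
k_b = 1059.162 kcal/mol/Å² and k_a = 75.90 kcal/mol/rad² in the
½-convention, ε_OO = 0.15539 kcal/mol, σ_OO = 3.165492 Å). The monomer
dipole is closed-form: |μ| = 2|q_H| r⁰ cos(θ⁰/2) · 4.8032 D/(e·Å) =
2.193 D.

Dimer workflow: a hydrogen-bonded start is minimized to
max|F| < 1e−6 kcal/mol/Å; the report gives r_OO, the acceptor angle θ_A,
the interaction energy and the total dipole. Definitions that matter:

* **θ_A** is the angle between the acceptor molecule's HOH bisector
  (pointing from the acceptor O away from its hydrogens, toward the
  lone-pair side facing the donor) and the O–O axis toward the donor — the
  standard experimental convention. SPC/Fw gives ≈ 22°, far below the
  experimental 58°, because fixed charges have no lone-pair anisotropy.
* **E_int** is the *intermolecular* energy (vdW + Coulomb) at the dimer
  minimum: −7.140 kcal/mol for SPC/Fw. The harmonic strain the monomers
  accept (+0.285 kcal/mol) is reported separately; relative to two relaxed
  monomers (energy exactly 0 by construction) the total is −6.855. The
  intermolecular definition is the one the benchmark table uses — it
  reproduces the printed −7.14 exactly, where the strain-inclusive total
  does not.

## 4. Surrogate labels: what they emulate, what they do not

Real training labels would be CM5 charges from correlated-wavefunction
electron densities; no such data ships with this package. The surrogate
generator supplies labels with the statistical *structure* the learning
pipeline assumes:

    q_H   = 0.41 + a Σ_{O′ inter} exp(−b r)·s_c(r; 4.4 Å)          a = 0.05 e, b = 1.5 Å⁻¹
    q_O   = −(q_H1 + q_H2) + Σ_J δq_IJ
    δq_IJ = c [Σ_{H∈I→O_J} − Σ_{H∈J→O_I}] exp(−λ r)·s_c(r; 5.5 Å)  c = 0.02 e, λ = 2.0 Å⁻¹

plus optional Gaussian noise σ = 0.002 e emulating quantum-chemistry label
scatter. λ = 2.0 Å⁻¹ makes an aligned H···O contact at the CT cutoff decay
to ~1e−5 of the amplitude, matching the physical decay scale of dimer CT.
The labels are deterministic given (parameters, seed), rigid-motion
invariant, local, and antisymmetric in the CT pair — all properties the
real labels have and all verified by tests.

What they do **not** emulate: the magnitude of real polarization response.
Real CM5 water charges spread over ~0.02–0.04 e between gas-like and
bulk-like environments; the closed form above with a = 0.05 e produces
clean-label SDs of only ~0.0012 e, i.e. the default noise is larger than
the signal it corrupts. Consequently a passing learnability test on this
generator demonstrates that the descriptors + networks + training loop can
recover a smooth, local, environment-dependent charge function and transfer
it to larger clusters (with noiseless labels the held-out MAE is 1.5–2% of
the label SD and R² > 0.999) — it does not demonstrate chemical accuracy on
real water, and with the default noise level the noise floor, not the
model, dominates held-out error.

Training configurations are gas-phase NVT (298.15 K, Langevin) cluster
frames from the SPC/Fw backend; frames with an evaporated molecule
(O beyond a radius bound from the center of mass) are discarded and
replaced. The split mirrors the reference protocol: 40% of the pool for
training, a small fixed validation set (50 by default), remainder for
testing. Training is minibatch Adam (lr 1e−3, decay 0.995/epoch, batch
256) on standardized MSE; "early stopping with 200 epochs" is read as a
200-epoch cap with restoration of the best-validation weights — the
ambiguity (patience vs cap) is resolved toward the simpler cap, which the
loss curves justify at these data sizes.

## 5. Observables

* **g(r):** standard histogram estimator against ideal-gas shell counts;
  requires periodic frames and r_max ≤ L/2.
* **Molecular dipoles:** origin at the molecule's nuclear charge center
  (Σ Z_i r_i/Σ Z_i, Z_O = 8, Z_H = 1), the convention that keeps dipoles of
  CT-charged molecules comparable.
* **IR:** Fourier transform of the total-dipole autocorrelation (FFT,
  unbiased normalization, Hann window), multiplied by the harmonic quantum
  correction βħω/(1 − e^{−βħω}) by default (switchable to 'none'; the
  correction convention is not uniquely standard).
* **Self-diffusion:** Einstein relation, least-squares MSD slope over a
  fractional lag window (default 20–80%), unwrapped coordinates required; a
  log-log exponent > 1.5 flags ballistic input.
* **H_vap = −⟨E_int⟩ + RT** (per-molecule liquid interaction energy).
* **Tetrahedral order:** Errington–Debenedetti q over the 4 nearest O
  neighbors; oxygens with fewer than 4 neighbors are excluded and counted.
* **Droplet layers:** instantaneous center of mass per frame; atoms binned
  by distance for VCD (charge / exact spherical-shell volume, e/nm³) and
  PHA; molecules binned by center of mass for charge histograms and
  net-molecular-charge VCD. Shell width defaults to 1 Å. Empty shells are
  NaN, not zero. Whole-droplet PHA is exactly 2/3 for pure water.

## 6. Problem sizes used by the test suite

The correctness suite runs clusters of 2–10 molecules, one periodic
16-molecule box (L = 11.4 Å — the smallest cell satisfying the
L > 2 × 5.5 Å minimum-image bound), 10 ps NVE runs at dt = 0.5 fs, and a
learnability protocol of 500 (H₂O)₂₅ frames with transfer to 10 (H₂O)₆₄
frames. These sizes exercise every code path (all cutoffs are crossed, the
box is genuinely periodic, the transfer clusters are 2.5× the training
size) at workstation scale; liquid-phase condensed observables (density,
H_vap, D, IR bands of bulk water, melting) would need nanosecond
trajectories of thousands of molecules and the originally trained networks,
and are out of scope — the machinery that would compute each is present and
tested on synthetic inputs instead.

## 7. Known limitations

* Orthorhombic cells only; no triclinic support, no barostat (NPT), no
  bond constraints, no MPI parallelism — single-process numpy throughout.
* The shipped force-field constants are documented defaults, not the
  originally tuned set; quantitative liquid properties should not be
  expected from them.
* Ewald uses tinfoil boundary conditions (no surface dipole term), the
  universal choice for liquid simulation but different from a cluster in
  vacuum by 2πk_e|M|²/(3V).
* Charge predictions are unconstrained per molecule; molecular net charges
  carry accumulated error of the same order as the per-atom error.
* The CT energy uses the package's ratio form; any saturating even
  function with a force peak at δq⁰ would fit the same description, and
  retuning k_c/δq⁰ against reference dimer CT curves would be required for
  quantitative work.
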