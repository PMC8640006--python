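# Methods

This note documents the models, numerical choices and limitations of
deltapot, in the spirit of the methods documentation of mature simulation
packages.

## Composite energy

The potential is the strict sum `E_total = E_baseline + E_NN + E_disp`.
The sum is formed once, in that order, so the invariant
`E_total == E_baseline + E_NN + E_disp` holds at floating-point identity
and every component remains individually auditable. Forces are
component-wise analytic; the Hessian is assembled from central finite
differences of the analytic forces (default step 0.005 Å, a compromise
between O(h²) truncation and round-off at Hartree/Å scales) and
symmetrized as (H + Hᵀ)/2.

Internal units are Hartree and Ångström throughout; kcal/mol
(1 Ha = 627.5094740631 kcal/mol) appears only in reports. Molecular charge
is carried as metadata but ignored by the neural correction: two systems
with the same geometry receive the same correction regardless of charge.
Conditioning the networks on charge or spin is out of scope.

## Descriptor

Atomic environment vectors follow the classic two-body/three-body
symmetry-function construction: Gaussian radial shells under a cosine
cutoff `f_c(r) = (cos(πr/R_c)+1)/2`, and an angular term over unordered
neighbor pairs,

```
2^(1−ζ) (1 + cos(θ − θ_s))^ζ · exp(−η((r_ij + r_ik)/2 − R_s)²) · f_c(r_ij) f_c(r_ik),
```

with the mean-distance convention in the radial factor. Defaults:
radial cutoff 5.2 Å with 16 shells (η = 16 Å⁻²), angular cutoff 4.0 Å —
deliberately enlarged for longer-range angular sensitivity — with 4 shells,
8 angle sections and ζ = 32. All hyperparameters are configurable and are
serialized into model checkpoints. Near-collinear angles are stabilized by
clamping cos θ to ±(1 − 10⁻¹²). Geometries with any pair closer than
0.1 Å are rejected as degenerate. The analytic feature Jacobian is
implemented alongside the features and is validated against central finite
differences.

## Networks, centering, ensembles

Each element owns an MLP (default F–160–128–96–1) with GELU activations —
chosen for being infinitely differentiable, which matters for Hessians and
frequencies — and a linear scalar output. Weights use fan-in-scaled normal
initialization with a per-member recorded seed. Labels are centered before
training by the SAE table: per-element offsets obtained by linear least
squares of the reference scalars on molecular composition. The SAE is fit
once on the stage-1 labels and kept fixed through transfer learning; since
stage 2 refits the network weights anyway, re-centering would only shuffle
constants between the offsets and the biases. The ensemble prediction is
the unweighted mean of members (default eight; the desk-scale study uses
two); the member standard deviation is reported as an uncertainty
diagnostic but never folded into the energy.

Backpropagation is implemented directly on numpy. Training on forces
requires the gradient of the input-gradient with respect to the weights;
this second-order pass is a forward-tangent sweep through the network
followed by a reverse sweep over both the primal and tangent graphs (the
GELU second derivative enters here). Both passes are unit-tested against
finite differences.

## Training protocol

Stage 1 (Δ-learning) minimizes `L = √(L_E·L_F)` with
`L_E = mean_records ((Ê − E)/√N_atoms)²` and `L_F` the plain MSE over force
components — the per-record √N scaling keeps large and small molecules
comparable. When a dataset carries no forces the loss reduces to `L_E`.
The dataset is split into nine near-equal parts by seeded permutation: one
test part, and each member validates on a distinct rotated part, training
on the remaining seven. Optimization is Adam (initial LR 10⁻³), with the
learning rate halved after 25 epochs without validation improvement and
training stopped when it falls below 10⁻⁵ or at the epoch cap (default
1000, applied per member); the best-validation weights are restored at the
end. Records whose centered label exceeds 0.01 Ha in magnitude are flagged
for review in the model metadata, never silently dropped.

Stage 2 (transfer learning) splits the high-level set 80/10/10, freezes
the first and third hidden layers — interpreted as 1-based indices over
hidden layers only, configurable — and minimizes `L_E` alone, since
high-level references provide no forces. The frozen weights of the
returned ensemble are bit-identical to stage 1, which the tests check
exactly.

Determinism: all randomness (splits, initialization, batch order, noise)
derives from explicit seeds via seed sequences, so identical configurations
reproduce identical weights and byte-identical pipeline reports on a fixed
thread configuration.

## Dispersion

The two-body term uses rational (Becke–Johnson) damping,
`E₂ = −Σ_{i<j} Σ_{n∈{6,8}} s_n C_n / (r^n + (a1·R0 + a2)^n)`, with
geometric-mean C6 combination, `C8 = 2·C6·R0²`, and a packaged H/C/N/O
coefficient table of literature magnitude (C6 in Hartree·Å⁶). The
three-body Axilrod–Teller–Muto term uses the geometric-mean C9 rule and is
zero-damped by default with an optional BJ-style rational switch; the
angular factor is evaluated through the law of cosines, which makes the
term a rational function of the three pair distances and gives closed-form
gradients. This module is intentionally a generic damped-dispersion
implementation with fixed, geometry-independent coefficients:
charge-scaled or coordination-dependent coefficients and periodic lattice
sums are out of scope, and a production calculation can slot any external
dispersion code in through the EnergyProvider interface.

## Thermochemistry

Frequencies come from the mass-weighted Cartesian Hessian with the six
(five for linear molecules, detected by a principal-moment ratio below
10⁻⁸) rigid-body directions projected out in the Eckart frame. Negative
eigenvalues are reported as negative (imaginary) frequencies. Requesting
frequencies at a non-stationary geometry warns rather than fails — the
numbers are well defined, just not physical. Enthalpies are ideal-gas
HO/RR: `H(T) = E + ZPE + 3/2·RT + RT_rot + Σ R·θ_v/(e^{θ_v/T}−1) + RT`,
with no symmetry number (enthalpy does not need one) and all internal
motions treated as harmonic modes. Imaginary modes are an error unless
explicitly dropped.

Heats of formation use atomization energies with per-element atomic
energies fit by ordinary least squares (ΔHf is linear in each E_A with
coefficient −n_A) against experimental molecular values; experimental
atomic ΔHf at 298 K ship as an editable CSV because different
thermochemistry protocols use slightly different atomic reference values.

## Geometry optimization

Plain Cartesian BFGS (scipy's implementation, which maintains the inverse
Hessian and uses a Wolfe line search); convergence is on the
infinity norm of the force vector, default fmax = 4.5·10⁻⁴ Ha/Å, maximum
500 steps. Exhausting the step budget returns a diagnosed non-converged
result rather than raising. No internal-coordinate transformation and no
symmetry constraints are used — simplicity and testability over speed on
the small systems this package targets.

## Synthetic study system

The generator emulates a two-level reference hierarchy above a cheap
baseline:

* **baseline** — Morse potentials (well depth 0.15 Ha, width 2 Å⁻¹,
  r_e = sum of covalent radii) over pairs closer than 1.6× the
  covalent-radius sum, plus a soft exponential repulsion (1 Ha amplitude,
  0.4 Å decay) over the remaining pairs. Bond classification is geometric
  and re-evaluated per call; near-equilibrium conformers never cross the
  threshold, so the potential is smooth over any sampled dataset.
* **mid level** — baseline plus a planted smooth correction: a Gaussian of
  each pair distance (amplitude 0.005 Ha ≈ 3 kcal/mol, centered at 1.4 Å,
  width 0.7 Å) plus per-element linear offsets that the SAE centering must
  absorb exactly. Energies and analytic forces, mimicking a DFT-level
  reference.
* **high level** — mid plus a second, smaller planted shift (−0.002 Ha,
  center 1.1 Å, width 0.9 Å), energies only, mimicking a coupled-cluster
  reference without gradients.

Conformers are drawn by normal-mode sampling around the baseline-optimized
templates (seven molecules: H₂, H₂O, NH₃, CH₄, C₂H₂, CO₂, H₂CO, covering
H/C/N/O): per-mode amplitudes are zero-mean normal with the
classical-thermal variance kT/λ at 300 K. Label noise defaults to zero so
recovery tests are exact; an optional Gaussian noise of 0.1–1 kcal/mol
exercises robustness.

Because every correction has a recorded closed form, the training loop is
closed: the desk-scale study (2000 records, two members, ≤200 epochs,
reduced descriptor of 8 radial/4 angular shells and 64–56–48 hidden
layers, sized to run in minutes on one CPU) recovers the planted mid-level
correction to well under 5% of its standard deviation, and transfer
learning demonstrably removes the mid-to-high bias with frozen layers
intact. What this does *not* show: performance on real quantum-chemical
data, where labels are noisy, conformational coverage is vastly wider, the
baseline has element-specific pathologies, and millions of records are
needed — the synthetic study validates the machinery, not chemical
accuracy.

## Known limitations

* No periodic systems, no connectivity perception, no SMILES/InChI input.
* The neural correction is charge- and spin-blind.
* Dispersion coefficients are fixed per element pair (no coordination or
  charge dependence).
* Thermochemistry is harmonic only: no hindered rotors, no anharmonicity,
  no conformer averaging, enthalpies only (no entropies or free energies).
* No transition-state searches or constrained optimizations.
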