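# deltapot

A composite machine-learned interatomic potential in the style of modern
Δ-learning quantum-chemistry methods, with the full downstream toolchain:
analytic forces, finite-difference Hessians, harmonic thermochemistry,
heats of formation and BFGS geometry optimization.

The package is for method developers and computational chemists who want a
fully testable, self-contained implementation of the composite-potential
recipe: it ships a synthetic "study system" (an analytic baseline potential
plus planted smooth corrections standing in for DFT- and coupled-cluster-level
references), so every stage of the pipeline — descriptor, networks, both
training stages, thermochemistry, optimization — can be exercised and
verified on a laptop without any external quantum-chemistry program or
dataset.

## The model

The total energy of a molecule is the sum of three parts,

```
E_total = E_baseline + E_NN + E_disp
```

* **E_baseline** — a pluggable low-level method (`EnergyProvider`
  interface). The packaged `ToyBaseline` is an analytic Morse-bond +
  soft-repulsion potential; a real semiempirical backend connects through
  the same interface (e.g. via the external-process adapter pattern).
* **E_NN** — an ensemble of per-element feed-forward networks with GELU
  activations consuming atomic environment vectors (AEVs: Gaussian radial
  shells and modified angular symmetry functions under cosine cutoffs,
  angular cutoff 4 Å). The molecular correction is the sum of atomic
  contributions `E_NN = Σ_A E_A` plus element-wise linear offsets (the SAE
  table, fit by least squares to composition before training).
* **E_disp** — additive dispersion: Becke–Johnson-damped pairwise
  `−Σ s_n C_n / (r^n + (a1·R0 + a2)^n)` for n = 6, 8, plus the
  Axilrod–Teller–Muto three-body term
  `s9 Σ C9 (3 cos θ₁ cos θ₂ cos θ₃ + 1)/(r₁₂ r₂₃ r₃₁)³`
  (zero-damped by default, optional BJ-style switch).

Training is two-stage:

1. **Δ-learning** — networks are fit to SAE-centered differences between a
   mid-level reference and the baseline, minimizing the geometric-mean loss
   `L = √(L_E · L_F)` over energies and forces. The dataset is split into
   nine equal parts; one is held out for testing, and each ensemble member
   validates on a distinct rotated part.
2. **Transfer learning** — the ensemble is refit to a smaller set of
   high-level *energies only* (80/10/10 split), with the first and third
   hidden layers frozen, minimizing `L_E` alone.

Heats of formation use the atomization route
`ΔHf(M) = Σ_A ΔHf_exp(A) − [Σ_A E_A − H_M(298)]`, with per-element atomic
energies `E_A` fit by linear least squares to an experimental reference set
and atomic ΔHf values shipped as an editable table.

## Worked example

`examples/02_delta_then_transfer.py` generates 210 conformers of seven
small CHNO molecules by normal-mode sampling, labels them at two synthetic
levels of theory, and runs both training stages:

```
dataset: 210 mid records (E+F), 210 high records (E only)
stage 1 vs mid labels  (hold-out MAD):  0.282 kcal/mol
stage 1 vs high labels (hold-out MAD):  4.245 kcal/mol
stage 2 vs high labels (hold-out MAD):  0.062 kcal/mol
```

Reading: after Δ-learning the model reproduces its own (mid-level) training
surface to 0.28 kcal/mol on held-out conformers, but is systematically off
the high-level surface by ~4 kcal/mol; transfer learning on high-level
energies removes that bias (0.06 kcal/mol) while the frozen layers preserve
the representation learned from the larger, force-labeled dataset.

`examples/03_thermochemistry.py` optimizes water on the toy baseline and
prints its three harmonic frequencies (389, 2944, 3002 cm⁻¹ for this
potential), the ZPE, and the HO/RR enthalpy at 298.15 K.

The same workflow is scriptable from the shell:

```bash
deltapot run-pipeline --seed 0 --outdir runs/demo
deltapot opt runs/demo/dataset_mid.xyz     # BFGS on the first frame
deltapot freq <xyz> ; deltapot thermo <xyz> ; deltapot disp <xyz>
```

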