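# Methods

## Problem and model

A molecule of fixed configuration may populate one conformation or a
fast-exchanging ensemble in solution. Observed NMR chemical shifts are
then single-conformer values or population-weighted averages. Given
per-conformer GIAO isotropic shieldings and DFT energies, the package
scores candidate explanations of the experimental shifts with the DP4+
probability: errors between (scaled and unscaled) calculated and
experimental shifts are modelled as i.i.d. location-scale Student-t
variates per nucleus, and candidates are compared by their normalized
likelihood under a uniform prior.

A "candidate" is deliberately generic: a single conformer, or a
molar-fraction mixture of cluster representatives. Mixtures are formed
by averaging in shielding space (σ_mix = Σ_k x_k σ_k per site) before
referencing and scaling; since referencing (δ = σ_ref − σ) and the OLS
correction are affine, averaging before or after is equivalent, and one
code path serves both. Every composition of the simplex grid (all
fraction tuples that are integer multiples of the step, enumerated
lexicographically) is one candidate, and grid probabilities are
normalized over the entire grid, so they sum to 1 across compositions.

Assumptions worth stating:

* site assignment is known and fixed (no automatic peak assignment);
* isochronous atoms (e.g. methyl protons) are averaged within a site;
* errors are independent across sites — correlated systematic errors
  beyond the affine term are not modelled;
* the uniform prior ranks candidates by shift agreement alone, on
  purpose: MMFF/DFT energy orderings of conformers are unreliable enough
  that energy enters only through the separately reported Boltzmann
  table;
* exchange is fast on the shift timescale (linear averaging).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| t-parameters (μ, σ, ν) | packaged YAML | ppm, ppm, — | DP4+ error model per nucleus × {scaled, unscaled} |
| σ_ref | packaged YAML | ppm | TMS reference shielding per nucleus |
| grid step | 0.1 | molar fraction | simplex resolution of the mixture scan |
| merge distance | 0.25 | Å | tree-cut height of the RMSD clustering |
| energy window | 12 | kJ/mol | prefilter: drop conformers above E_min + window |
| RMSD cutoff | 1.0 | Å | prefilter: drop near-duplicates of kept conformers |
| temperature | 298.15 | K | Boltzmann populations (room-temperature spectra) |

The t-distribution parameters depend on the level of theory of the GIAO
calculation and are configuration, never constants: two packaged sets
(PCM and gas phase, for mPW1PW91/6-31+G**//B3LYP/6-31G*) are selectable
because published workflows use either, and any YAML with the same
layout overrides them. The packaged values are a best-effort
transcription of the published DP4+ parametrization (Grimblat, Zanardi &
Sarotti, *J. Org. Chem.* 2015, 80, 12526) and should be verified against
that source before production use; none of the package's tests or
reported quantities depend on the specific values, only on the model
family. Energies are read in Hartree and converted once at the I/O
boundary (×2625.4996 kJ/mol); atom indices are 1-based in all files and
converted once at the same boundary.

## Numerical choices

* Likelihoods accumulate as Σ log t-density with max-subtraction before
  exponentiation (softmax); direct products over ~50 sites would
  underflow. A test reproduces direct products on small inputs.
* The OLS scaling is per candidate and per nucleus. Because all
  candidates share the experimental vector, the per-candidate slopes and
  intercepts are computed in closed vector form; a normal-equations
  oracle pins the algebra. With fewer than two sites, or zero variance
  in the experimental shifts, the scaled channel raises an error
  directing the user to the unscaled channel.
* Kabsch superposition uses `scipy.spatial.transform.Rotation.align_vectors`
  (proper rotation enforced); the residual RMSD is recomputed from the
  rotated coordinates because the solver's reported residual loses
  precision near zero. RMSD uses heavy atoms by default; hydrogens or
  named 1-based selections are opt-in.
* Clustering is agglomerative with complete linkage by default (the
  merge distance then bounds within-cluster RMSD, giving compact,
  homogeneous clusters); single/average linkage are selectable. The
  representative of a cluster is its lowest-energy member, falling back
  to the lexicographically first id without energies. Ties in the DP4+
  argmax are reported as a set, never broken silently.
* Sites with a missing experimental shift are dropped from all
  candidates symmetrically, keeping the comparison paired.
* Dihedrals follow the IUPAC sign convention (cis = 0°, range
  (−180°, 180°]); the implementation was cross-checked against an
  independent MD-analysis library on random geometries.
* An optional `outlier_correction` flag halves absolute ¹³C scaled
  errors above 10 ppm (a spreadsheet-style robustness heuristic); it is
  off by default so that CMAE and the likelihoods use plain scaled
  errors.

## The synthetic-data generator

`generate_study` emulates the inputs of a real analysis with a known
ground truth: per-conformer site shieldings are drawn once around
realistic centers (¹H shifts ~0.8–6.8 ppm, ¹³C ~50–180 ppm) with
inter-conformer spreads of 0.3 ppm (¹H) and 3.0 ppm (¹³C) — typical
conformational shift variation; the pseudo-experimental shift of a site
is the ground-truth mixture average, passed through an optional affine
distortion (m, b) that emulates the systematic error of a GIAO
calculation, plus Student-t noise (defaults σ = 0.10 ppm/ν = 10 for ¹H
and σ = 1.5 ppm/ν = 10 for ¹³C, matching the scale of the error model).
Energies are assigned to reproduce target Boltzmann populations (the
ground-truth fractions floored at 1%), and couplings are drawn in the
2–12 Hz ³J range with their ground-truth average as the pseudo
experiment. Geometries are random point clouds (plus a separate
family generator for clustering tests) — sufficient for RMSD machinery,
with no chemical realism.

Because the noise family equals the likelihood family, mixture recovery
is a well-posed self-consistency check: it validates the inference
machinery, not the physics. Passing tests therefore show that the
pipeline recovers known mixtures under its own error model at realistic
noise; they do not show that real GIAO errors are t-distributed, that
real conformer shift differences are as large as the spreads assumed, or
that assignment errors are absent. A Gaussian-noise option probes mild
misspecification; real-data performance ultimately rests on the DP4+
error model's published calibration.

The standard study size — 4 conformers, 20 ¹H + 20 ¹³C sites, grid step
0.1 (286 compositions), 100 recovery replicates — was chosen as
representative of a medium-sized natural product and keeps the whole
pipeline fast; `scripts/acceptance.py` reports each quantity with the
problem size it used.

## Open design points, resolved

* **PCM vs gas-phase parameters**: both packaged and selectable
  (`solvation="pcm"|"gas"`), PCM default since solution NMR is the use
  case; the I/O layer is agnostic to how the shieldings were computed,
  so users must match the parameter set to their calculation.
* **Model shape**: the public API is a fit/results pair
  (`DP4Model`/`MixtureDP4Model` → results with `summary()`), because
  DP4+ is a Bayesian model comparison with a per-candidate fitted
  scaling; the functional core (`dp4_probabilities`, `mixture_dp4_scan`,
  ...) remains importable and the CLI wraps the models.
* **Band queries**: the "probability of a region of composition space"
  is an explicit user-supplied predicate (`band_probability`), not a
  hard-coded band.
* **Couplings**: calculated ³J values are consumed as input; no Karplus
  fallback, which would add an unanchored empirical model.

## Known limitations

* Atom order must be consistent across conformers; no symmetry-aware
  renumbering or graph matching before RMSD.
* No conformational searching, no QM execution, no NOE back-calculation,
  no binary checkpoint formats.
* The log parser targets Gaussian-style text markers ("SCF Done",
  "Isotropic ="); other engines are supported through the plain-CSV
  shielding path.
* The mixture grid is exhaustive, not optimized; above ~6 representatives
  at step 0.1 the grid grows combinatorially (C(1/step + k − 1, k − 1)).
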