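# Methods

This note documents the models, conventions and numerical choices behind
`tsbind`, and what the synthetic study conditions do and do not establish
about real simulation data.

## Free-energy arithmetic

Per frame and species, ΔG = ΔE_gas + ΔG_sol, optionally minus TΔS when an
entropy column is present (`include_entropy=True`; requesting entropy
without the column is a configuration error, never a silent fallback).
The binding free energy follows the standard thermodynamic cycle

    ΔΔG_bind = ΔG_complex − ΔG_receptor − ΔG_ligand,

so lower values mean stronger binding.  An alternative combination with
`+ΔG_ligand` appears in some write-ups of this analysis; it contradicts the
cycle and the "lower is better" interpretation, so the standard form is the
default and the alternative is available as `legacy_sign=True` for
reproduction studies only.  Frames missing one of the three species are
skipped with a logged warning and surfaced in the run report — truncated
MM-GBSA exports are common and must never silently shift a profile.

ΔG_protein is the receptor-only series and doubles as a whole-protein
stability proxy.

## The optimal estimate X̂_k

Frames are partitioned by their interface H-bond count k.  Per bin,
δ²x_k = ⟨x²⟩ − ⟨x⟩² (population variance as the uncertainty measure; the
n−1 variant is available via `variance_ddof=1` for sensitivity checks) and
the inverse-variance ML estimate with a bin-constant weight reduces exactly
to the bin mean — the unit tests assert this against brute-force averaging
at 1e-12 relative error.  Bins below `min_samples` (default 2) are flagged
unreliable and excluded from profile comparisons by default; their spread
estimate carries no information.

Combining runs is genuinely ambiguous when each run supplies (mean, δ², n):

* `mode="inverse_variance"` (default) weights run estimates by 1/δ² — the
  textbook ML combination when δ² is taken as each estimate's uncertainty;
* `mode="pooled"` reconstructs exact sample moments, equal to computing the
  estimate on the concatenated samples (machine-precision identity, tested).

The two agree when runs share their variance and differ otherwise; both are
exposed because the pooled form is the exact answer for same-condition
continuation runs (Run1 + Run2 style), while inverse-variance is appropriate
for heterogeneous blocks.  No autocorrelation correction is applied to δ²x_k;
time-series inefficiency correction is out of scope and noted as a
limitation below.

## Hydrogen bonds

Detection is geometric: donor-heavy-atom to acceptor-heavy-atom distance
≤ 3.0 Å AND D-H···A angle ≥ 135°, both boundaries inclusive for
deterministic behaviour at the cutoff.  The angle is taken at the hydrogen
(the convention of the common trajectory tools); hydrogens farther than
1.5 Å from their nominal donor are rejected with a warning as mislabeled
pairs.  Donor/acceptor assignment defaults to a chemistry table — N/O heavy
atoms with an attached H donate, all N/O accept — and is overridable with
explicit atom-reference lists.  The interface count k keeps one count per
distinct (donor, acceptor) pair per frame, restricted to the eight
interface residues (crystal numbering 120, 241, 248, 273, 276, 277, 280,
283) against the DNA chains.  Occupancy of a specific bond is the percent
of frames in which it is detected, i.e. the mean of its indicator.

## Circular dihedral PCA

φ = C(i−1)–N(i)–CA(i)–C(i) and ψ = N(i)–CA(i)–C(i)–N(i+1), computed with
the praxeolitic torsion formula (matches an established structure library
to float32 precision in tests), degrees on (−180, 180].  Residue
consecutiveness is judged on author numbering; terminal or incomplete
residues are omitted (with a warning when the gap is not a terminus).

PCA operates on the (sin θ, cos θ) embedding with mean-centered columns and
an eigendecomposition of the covariance matrix.  This makes the analysis
exactly invariant under ±360° rewrapping and robust across the branch cut
between cis (~0°) and trans (~180°) populations.  The trade-off, chosen
deliberately: component scores are linear coordinates in the embedded
space, not angles, so scores are comparable across analyses only in their
cluster topology, not numerically against tools that compute geodesic
(torus) principal components.  Each component's dominant mode is
back-projected as atan2(sin-loading, cos-loading) of its strongest residue
for interpretation.  All-constant input (zero total variance) raises a
degenerate-data error.  PCA is fit per dataset, matching per-simulation
landscape plots; cross-fitted comparisons are out of scope.

## Shrake–Rupley SASA

Each atom's sphere is expanded by the probe radius (1.4 Å) and sampled with
a deterministic Fibonacci golden-angle lattice (default 960 points; at
least 32 enforced).  A test point is accessible iff outside every other
atom's expanded sphere; per-atom SASA is 4π(r+p)² times the accessible
fraction.  Neighbour candidates come from a k-d tree.  The lattice is
seed-free, so results are exactly reproducible, and 960 points give
sub-percent discretization error (tested: analytic single-sphere exact;
two-sphere spherical-cap within 2%; brute-force union oracle within 2%;
rigid-motion changes ≤ 0.5%; 1000→4000-point convergence within 1%).

Radii are element-based (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.09 Å),
overridable per atom name.  Slice-based SASA programs use different radii
sets and integration, so absolute Å² values carry systematic offsets of a
few percent between methods; comparisons should stay within one method.

Side-chain SASA sums all atoms except backbone N, CA, C, O, OXT and the
amide/alpha hydrogens; CB is side chain; GLY is defined 0.  Exposure
significance uses the study's own rule: a variant residue changes
significantly when |mean − reference mean| exceeds the variant's
frame-to-frame SD (ddof = 1).

## Stability populations

Relative SASA and Relative ΔG_protein subtract the *mean* of the reference
(wild type, 300 K) window from each variant frame — frame-pairing across
independent simulations is undefined, so a scalar reference is the only
well-posed reading.  Quadrants: (+, +) less stable, both ≤ 0 more stable,
the two mixed quadrants kept separate; exact zeros are assigned away from
the less-stable class (measure-zero for continuous inputs).  Percentages
over the four classes sum to 100 by construction.

## Synthetic study conditions

The generator plants exactly the structure the analysis assumes:

* eight interface bonds drawn i.i.d. Bernoulli per frame;
  ΔΔG | k ~ Normal(β0 + β1·k, σ) with defaults β1 = −2 kcal/mol·bond,
  σ = 3 kcal/mol, 3000 frames (30 ns at 10 ps snapshots);
* species tables decomposed so the combination rule returns the drawn ΔΔG
  exactly (receptor carries the ΔG_protein series; ligand is a fixed
  baseline) — downstream expected values are closed-form in the noiseless
  limit;
* condition presets: at 310 K bond probabilities drop (e.g. WT 0.65 → 0.45
  per bond), β0 rises by 4.5 kcal/mol (within the 2–5 kcal/mol contrast the
  analysis is designed to resolve) and ΔG_protein rises by ~150 kcal/mol;
  the V143A-like preset out-binds WT at 300 K and loses that advantage at
  310 K;
* a toy interface ensemble whose formed bonds are collinear D–H···A at
  2.8 Å (detected by construction) and whose occluder pseudo-atoms approach
  the side chains linearly in `burial_factor` (monotonically lowering
  side-chain SASA);
* wrapped von Mises cis/trans mixtures with one reporter torsion carrying
  the planted cluster assignment.

All draws flow through NumPy's PCG64 with explicit seeds; fixed seed means
bit-identical artifacts on any platform.  What passing tests show: the
estimators are correct, unbiased and discriminating *under these planted
conditions*.  What they do not show: behaviour under autocorrelated frames,
force-field-realistic energy distributions, non-ideal H-bond geometry, or
conformational coupling between bonds — real trajectories have all four,
and the occupancy/population uncertainties quoted here (binomial standard
errors) understate uncertainty for correlated data.

## Pipeline sizes and determinism

The orchestrated `run-all` defaults to 600 energy frames and 60 structural
frames per dataset — structural stages (SASA at 960 lattice points per
atom) dominate cost, and these sizes keep a full two-condition run in the
tens of seconds while every statistical claim above is tested at the full
3000-frame condition.  Tables are written with fixed float formatting and
manifest checksums (SHA-256); identical config + seed reproduces every
output byte-for-byte, and per-dataset seeds are spawned from the master
seed via `SeedSequence` so datasets are independent but reproducible.

## Known limitations

* No statistical-inefficiency or autocorrelation correction in δ²x_k or in
  occupancy standard errors.
* PCA scores are not numerically comparable to geodesic torus-PCA axes.
* Absolute SASA values are method-specific; only within-method comparisons
  are meaningful.
* The PDB dialect is a strict fixed-width subset: no altloc, no insertion
  codes, no mmCIF, no binary trajectory formats.
* Energy tables must be long-format delimited text; native outputs of
  MM-GBSA tools are not parsed (export a frame/species/e_gas/g_sol table).
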