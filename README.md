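# tsbind

Post-simulation analysis for temperature-sensitive (ts) p53 mutants bound to
DNA.  Several hotspot mutations in the p53 DNA-binding domain (e.g. V143A,
R249S, R175H) bind DNA near 298–306 K but lose binding at 310 K.  Given
per-frame MM-GBSA energy-component tables and structural ensembles from
simulations of the p53–DNA complex at two temperatures, `tsbind` computes the
quantities that separate such mutants from wild type:

* **Binding free energy per frame.**  For each species s ∈ {complex,
  receptor, ligand}, ΔG_s = ⟨ΔE_gas⟩ + ⟨ΔG_sol⟩ − T⟨ΔS⟩ (entropy optional),
  and ΔΔG_bind = ΔG_complex − ΔG_receptor − ΔG_ligand; more negative means
  stronger binding.
* **Interface hydrogen bonds.**  Geometric D–H···A detection (donor–acceptor
  distance ≤ 3 Å, D-H···A angle ≥ 135°), the per-frame count k over the eight
  interface residues (LYS 120, SER 241, ARG 248, ARG 273, ALA 276, CYS 277,
  ARG 280, ARG 283) facing the DNA chains, and per-bond occupancy.
* **The optimal estimate X̂_k.**  Frames sharing k interface H-bonds form a
  bin with uncertainty δ²x_k = ⟨x_n²⟩ − ⟨x_n⟩²; the maximum-likelihood
  inverse-variance estimate X̂_k = Σ(x_n/δ²x_k)/Σ(1/δ²x_k) reduces to the bin
  mean within one run and weights runs by 1/δ² when pooling.  The profile
  {(k, X̂_k)} is the headline binding-affinity comparison between conditions.
* **Circular dihedral PCA.**  Backbone φ/ψ torsions embedded as (sin θ,
  cos θ), eigendecomposed, and mapped against whole-protein free energy
  ΔG_protein to expose cis/trans conformational populations.
* **Side-chain SASA.**  A deterministic Shrake–Rupley implementation
  (Fibonacci lattice, probe 1.4 Å) with a mean-vs-SD significance rule for
  interface exposure changes.
* **Stability populations.**  Relative SASA and Relative ΔG_protein versus
  the wild-type 300 K reference mean; the (+, +) quadrant fraction is the
  percent of conformers less stable than native.

Because the original QM-MM trajectories are not publicly deposited, the
package ships a first-class seeded generator (`tsbind.synthetic`) that
emulates the statistical structure of the study — H-bond-coupled binding
energies, temperature-contrasted presets, wrapped cis/trans torsion mixtures,
and a toy interface ensemble — so every stage is testable end to end.

## Worked example

```sh
python examples/01_binding_profile.py
```

prints (abridged):

```
  k    X_300K  d2x_300K    X_310K  d2x_310K
  2     -8.56      8.64     -3.36      8.51
  3    -10.27      8.01     -5.56      8.32
  4    -12.02      8.32     -7.53      9.11
  5    -13.92      8.80     -9.55      8.71

profile slope at 300 K: -1.94 kcal/mol per bond (planted coupling: -2.0)
every shared k has the 310 K estimate above the 300 K one: True
```

Each row is one H-bond count k: X̂_k is the optimal estimate of ΔΔG_bind
(kcal/mol) among frames with that k, and δ²x_k its spread.  More interface
bonds buy roughly −2 kcal/mol each (the planted coupling, recovered by the
profile slope), and at 310 K the whole profile shifts up — the
temperature-sensitive loss of binding.  The other examples cover H-bond
occupancy, dihedral PCA landscapes, interface SASA significance, and the
stability-population quadrants.

The same analyses run from the shell:

```sh
tsbind run-all --seed 1 --outdir out        # all stages, both conditions
tsbind estimate --seed 1 --outdir out_est   # one stage only
```

writing delimited tables plus a `manifest.json` with SHA-256 checksums;
identical config + seed reproduces every table byte-for-byte.

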