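"""Optimal-estimate binding profile: wild type at 300 K vs 310 K.

Generates two synthetic 3000-frame study conditions, bins each frame's
MM-GBSA binding free energy ΔΔG_bind by its interface H-bond count k, and
prints the per-k optimal estimate X̂_k with its uncertainty δ²x_k.  A
profile that sits lower means stronger predicted DNA binding; the 310 K
profile lying above the 300 K one at every shared k is the temperature-
sensitive signature.
"""

from tsbind import synthetic
from tsbind.optimal_estimate import estimate_profile, profile_slope

profiles = {}
for condition in ("T300", "T310"):
    cfg = synthetic.preset("WT", condition, seed=1, n_frames=3000)
    _, truth = synthetic.generate_energy_tables(cfg)
    profiles[condition] = estimate_profile(truth.ddg, truth.k, run_label=condition)

print(f"{'k':>3} {'X_300K':>9} {'d2x_300K':>9} {'X_310K':>9} {'d2x_310K':>9}")
cold = {e.k: e for e in profiles["T300"] if not e.unreliable}
warm = {e.k: e for e in profiles["T310"] if not e.unreliable}
for k in sorted(set(cold) | set(warm)):
    c, w = cold.get(k), warm.get(k)
    print(f"{k:>3} "
          f"{c.estimate if c else float('nan'):>9.2f} {c.uncertainty if c else float('nan'):>9.2f} "
          f"{w.estimate if w else float('nan'):>9.2f} {w.uncertainty if w else float('nan'):>9.2f}")

print(f"\nprofile slope at 300 K: {profile_slope(profiles['T300']):.2f} kcal/mol per bond "
      "(planted coupling: -2.0)")
print("every shared k has the 310 K estimate above the 300 K one:",
      all(warm[k].estimate > cold[k].estimate for k in set(cold) & set(warm)))
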