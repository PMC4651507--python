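"""Side-chain solvent accessibility of the DNA-binding interface residues.

Computes Shrake–Rupley SASA over two small ensembles that differ only in
how buried the interface side chains are, then applies the significance
rule: a residue's exposure change is significant when the variant mean
differs from the reference mean by more than the variant's own SD.
"""

from tsbind import sasa_significance
from tsbind.sasa import sidechain_sasa_series
from tsbind import synthetic

INTERFACE = {r for r, *_ in synthetic.INTERFACE_DONORS}

tables = {}
for label, burial in (("reference", 0.2), ("variant", 0.8)):
    cfg = synthetic.preset("WT", "T300", seed=3, n_frames=10, burial_factor=burial)
    traj = synthetic.generate_interface_frames(cfg)
    tables[label] = sidechain_sasa_series(traj, INTERFACE, n_points=960, chain="A")

ref_means = tables["reference"].groupby("res_id")["sidechain_sasa"].mean()
print(f"{'res':>4} {'ref mean':>9} {'var mean':>9} {'var sd':>7} significant")
for res_id, grp in tables["variant"].groupby("res_id"):
    mean, sd, sig = sasa_significance(grp["sidechain_sasa"].to_numpy(),
                                      float(ref_means[res_id]))
    print(f"{res_id:>4} {ref_means[res_id]:>9.1f} {mean:>9.1f} {sd:>7.2f} {sig}")
print("\nhigher burial lowers every interface side-chain SASA; differences larger")
print("than the variant's own frame-to-frame SD are flagged significant")
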