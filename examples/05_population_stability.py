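"""Relative-stability population map against the wild-type 300 K reference.

Plants 66.9% of 2000 frames in the (+, +) quadrant — larger SASA and
higher ΔG_protein than the native ensemble, i.e. less stable — and
recovers the fraction by quadrant classification, the summary used to
compare each mutant/temperature against wild type at 300 K.
"""

from tsbind import classify_population
from tsbind import synthetic

rel_sasa, rel_dg = synthetic.generate_population_points(2000, 0.669, seed=8)
summary = classify_population(rel_sasa, rel_dg)

for quadrant, pct in sorted(summary.percent_by_quadrant.items()):
    print(f"{quadrant:>16}: {pct:5.1f}%")
print(f"\npercent less stable than the reference: {summary.percent_less_stable:.1f}%"
      " (planted 66.9%)")
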