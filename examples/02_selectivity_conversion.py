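"""Enantiomeric excess vs the free-energy gap of the stereocontrolling TSs.

ΔΔG‡ = RT·ln((1+ee)/(1−ee)) links the selectivity readout of an asymmetric
reaction to the Gibbs free-energy difference between the two diastereomeric
transition states — the quantity all models in this package predict.
"""

from enantiokit import ddg_to_ee, ee_to_ddg

for ee_pct in (50, 68, 74, 90, 99):
    ddg = ee_to_ddg(ee_pct / 100, temperature=298.15)
    print(f"{ee_pct:3d}% e.e.  ->  ΔΔG‡ = {ddg:.2f} kcal/mol")
# note the steep climb: the last percent points of e.e. are the expensive ones

print()
for ddg in (0.5, 1.0, 2.0):
    ee = ddg_to_ee(ddg, temperature=298.15)
    print(f"ΔΔG‡ = {ddg:.1f} kcal/mol  ->  {100 * ee:.1f}% e.e.")
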