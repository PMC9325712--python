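"""Class totals and double-bond (saturation) profiles of a synthetic lipidome.

Simulates the FASN-inhibitor response of KRAS-mutant cells (PUFA-PC up 2x,
SFA/MUFA-PC down 0.5x) and prints the within-class double-bond fractions
of PC under vehicle and treatment.  Mass should visibly shift from 0-1
double bonds toward >= 2.
"""

from lipidkit import SimConfig, class_totals, double_bond_distribution, simulate_lipid_table

cfg = SimConfig(seed=7, groups=("KM",), treatments=("vehicle", "FASNi"),
                samples_per_condition=5).with_effects("fig4_fasni_km")
table, truth = simulate_lipid_table(cfg)

totals = class_totals(table)
print("class totals (first 3 samples):")
print(totals.iloc[:, :3].round(0).to_string())

frac = double_bond_distribution(table, "PC")
vehicle = table.samples_where(treatment="vehicle")
fasni = table.samples_where(treatment="FASNi")
print("\nPC double-bond fractions (mean per arm):")
print(
    frac[vehicle].mean(axis=1).rename("vehicle").to_frame()
    .join(frac[fasni].mean(axis=1).rename("FASNi")).round(3).to_string()
)
# Fractions within each arm sum to 1; the FASNi column concentrates at
# double-bond counts >= 2 (PUFA) relative to vehicle.
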