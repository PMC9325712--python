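"""Per-species differential testing with two-stage adaptive FDR.

Simulates KRAS-mutant tumors vs healthy lung (PC/TAG/SM/PE up, LysoPC
down), runs per-species t-tests on log2 abundances with the two-stage
step-up FDR at q = 0.05, and prints the volcano-style table for the
significant species.
"""

from lipidkit import SimConfig, simulate_lipid_table
from lipidkit.stats import differential_table

cfg = SimConfig(seed=3, groups=("healthy", "KM"),
                samples_per_condition=5).with_effects("fig1_km")
table, truth = simulate_lipid_table(cfg)

km = table.samples_where(group="KM")
healthy = table.samples_where(group="healthy")
diff = differential_table(table.abundances, km, healthy, q=0.05)

hits = diff[diff["significant"]].sort_values("q")
print(f"{len(hits)} of {len(diff)} species significant at q < 0.05")
print(hits[["logFC", "t", "p", "q"]].round(4).to_string())
# logFC ~ +1 for the 2x-up classes (PC, TAG, SM, PE, CE), ~ -1 for
# LysoPC and DAG; unaffected classes (PI, Cer) should be absent.
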