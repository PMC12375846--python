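"""Strategy comparisons and cost-effectiveness: reductions in
screen-initiated biopsies and overdiagnosis (vs annual DRE, and MRI vs no
MRI at the same ages), incremental outcomes vs no screening, and the
efficiency frontier with ICERs.

Reads results/base_case/outcomes.csv; writes results/cea/.
"""

import json
from pathlib import Path

import pandas as pd

from prostasim.outcomes import efficiency_frontier, reduction_vs_reference

OUT = Path("results/cea")
OUT.mkdir(parents=True, exist_ok=True)

table = pd.read_csv("results/base_case/outcomes.csv", index_col="strategy")

rows = []
for name, row in table.iterrows():
    if name in ("no_screening", "dre_45_75"):
        continue
    abs_bx, pct_bx = reduction_vs_reference(
        row["n_biopsies_screen"], table.loc["dre_45_75", "n_biopsies_screen"]
    )
    abs_od, pct_od = reduction_vs_reference(
        row["n_overdiagnosed"], table.loc["dre_45_75", "n_overdiagnosed"]
    )
    rows.append(
        {"strategy": name, "biopsy_reduction_vs_dre": abs_bx,
         "biopsy_reduction_pct": pct_bx, "overdx_reduction_vs_dre": abs_od,
         "overdx_reduction_pct": pct_od}
    )
reductions = pd.DataFrame(rows).set_index("strategy")
reductions.to_csv(OUT / "reductions_vs_dre.csv")
print("reductions vs annual DRE (per 100,000):")
print(reductions.round(0).to_string())

increments = {
    name: (
        row["qaly_disc"] - table.loc["no_screening", "qaly_disc"],
        row["cost_disc_meur"] - table.loc["no_screening", "cost_disc_meur"],
    )
    for name, row in table.iterrows()
}
frontier = efficiency_frontier(increments)
with open(OUT / "frontier.json", "w") as fh:
    json.dump(frontier.to_dict(), fh, indent=2)
print("\nefficiency frontier (incremental QALYs vs incremental M EUR):")
for name, icer in zip(frontier.efficient, frontier.icers):
    label = "first on the frontier" if icer is None else f"{icer * 1e6:,.0f} EUR/QALY"
    print(f"  {name}: {label}")
for name, how in sorted(frontier.dominated.items()):
    print(f"  {name}: {how} dominated")
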