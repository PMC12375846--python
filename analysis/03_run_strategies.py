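"""Run the ten screening strategies on a shared cohort and write the
per-100,000 outcome table, the efficiency frontier and the run manifest.

Writes results/base_case/{outcomes.csv, frontier.json, manifest.json}.
"""

from prostasim.pipeline import RunConfig, run_compare

cfg = RunConfig(n_persons=50_000, master_seed=1, out_dir="results/base_case")
result = run_compare(cfg)

table = result["outcomes"].sort_values("cost_disc_meur")
cols = ["n_biopsies_screen", "n_dx_screen", "n_overdiagnosed",
        "n_pca_deaths", "qaly_disc", "cost_disc_meur"]
print(table[cols].round(1).to_string())
print("\nefficient strategies:", ", ".join(result["frontier"].efficient))
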