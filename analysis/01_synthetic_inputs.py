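"""Generate the external-style inputs: the all-cause life table and the
registry-style incidence / grade-distribution / mortality targets used for
calibration and validation.

Writes results/synthetic/{life_table.csv, incidence_targets.csv,
mortality_targets.csv} and prints the headline epidemiology of the
synthetic ground truth.
"""

from pathlib import Path

from prostasim.synthetic import SyntheticConfig, life_expectancy, make_life_table, make_registry_targets

OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig()
life = make_life_table(cfg)
life.to_csv(OUT / "life_table.csv", index=False)
print(f"life table: ages 35-105, LE at 45 = {life_expectancy(life, 45):.1f} years")

targets = make_registry_targets(cfg)
targets.incidence.to_csv(OUT / "incidence_targets.csv", index=False)
targets.mortality.to_csv(OUT / "mortality_targets.csv", index=False)

rates = 1e5 * targets.incidence["cases"] / targets.incidence["person_years"]
peak = targets.incidence.loc[rates.idxmax()]
print(
    f"incidence targets: {len(targets.incidence)} age groups, peak "
    f"{rates.max():.0f}/100k person-years in {peak.age_low:.0f}-{peak.age_high:.0f}"
)
print(f"wrote {OUT}/")
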