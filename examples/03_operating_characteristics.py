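"""Operating-characteristics study over scenarios x designs.

Replicates many virtual trials per cell and tabulates how often each
schedule is selected as the MTD, mean allocation, sample size and
duration — the evidence used to pick a design before a trial starts.
Scaled to 100 replicates per cell here so it runs in under a minute.
"""

import dataclasses

from titecrm import DesignConfig, ScheduleGrid, run_oc_study, scenario_set

grid = ScheduleGrid(skeleton=(0.05, 0.10, 0.15, 0.25, 0.35, 0.45))
design = DesignConfig(ttl=0.25, max_n=25, window=12.0)
early = dataclasses.replace(design, success_m=6)  # stop once 6 patients sit on the recommendation

scenarios = scenario_set(grid, design)[:2]  # skeleton-true and shifted-up
table = run_oc_study(scenarios, [design, early], grid, n_rep=100, master_seed=0,
                     design_names=["no-stop", "stop6"])

df = table.to_dataframe()
pct = [c for c in df.columns if "pct" in c]
df[pct] = df[pct].round(1)
print(df[["scenario", "design"] + pct[:7] + ["mean_n", "mean_duration_weeks"]]
      .round(1).to_string(index=False))
print("\nsel_pct_s* is the percentage of replicates declaring that schedule the")
print("MTD (stopped_toxic_pct: no schedule declared safe). Under skeleton-true")
print("the mass should peak at schedule 4; shifting the truth up moves it down.")
print("Early stopping (stop6) trades some precision for a smaller mean n.")
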