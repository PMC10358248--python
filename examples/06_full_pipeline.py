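"""End-to-end run: simulate, select, classify, segment, aggregate, report.

Writes every report CSV to ./pipeline_reports and prints the treatment
pattern flow (first-line shares; per-arm split between second-line
chemotherapy and best supportive care).
"""

from oncoclaims import run_pipeline, write_claims_dataset
from oncoclaims.simulate import SimulationConfig, generate_dataset

sim = SimulationConfig(n_patients=500, seed=1)
ds, gt = generate_dataset(sim)
write_claims_dataset(ds, "pipeline_data")
res = run_pipeline("pipeline_data", out_dir="pipeline_reports")

print(res.attrition.to_text())
print()
print(res.patterns.to_text())
print("\nreports written to pipeline_reports/:")
print("  cohort.csv, regimens.csv, episodes.csv, monthly_costs.csv,")
print("  cost_summary.csv, category_shares.csv, episode_totals.csv, ...")
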