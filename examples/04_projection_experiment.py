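"""Two-arm Monte Carlo projection: baseline vs. contaminant remediation.

Runs reduced-scale ensembles (500 runs x 100 years; the full analysis uses
1000 runs) of the stochastic life cycle model, with and without the 1.54x
spring-subyearling survival multiplier, and summarizes the change in
spawner abundance and the quasi-extinction risk at 250 adults.
"""

import chinook_pva as cp

params = cp.default_parameters().evolve(n_runs=500)
result = cp.run_table2(params, seed=42)

for label, row in result["rows"].items():
    print(
        f"{label:>8}: survival +{row['survival_increase_pct']:.0f}%  "
        f"change {row['median_change_pct']:+.0f}% "
        f"(IQR {row['q25_change_pct']:+.0f}%, {row['q75_change_pct']:+.0f}%)  "
        f"quasi-extinction risk {row['quasi_extinction_risk']:.2f}"
    )

print()
print("Relative change is measured against the baseline median of per-run")
print("mean spawner abundance.  Removing the 54% contaminant loss raises the")
print("median abundance by roughly a quarter and cuts the probability that a")
print("century-long trajectory averages below 250 adults by about half or more.")
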