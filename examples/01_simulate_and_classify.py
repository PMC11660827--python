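"""Simulate a three-group study and recover the planted rescued genes.

Builds a synthetic control / disease / disease+drug count study (4/5/5
samples) with 10% of genes planted as "rescued" (shifted two log2 units by
disease, restored by the drug), runs both differential-expression callers,
classifies every gene by the DE-based Strategy A and the five-rule CI-overlap
Strategy B, and compares the calls with the planted truth.
"""

from txrescue import (
    SimulationConfig,
    classify_study,
    normalize_fpm,
    recovery_metrics,
    run_de,
    simulate_counts,
    summarize_strategies,
)

config = SimulationConfig(n_genes=2000, effect_log2fc=2.0, dispersion=0.05, seed=42)
cm, truth = simulate_counts(config)
am = normalize_fpm(cm)

de_cd = run_de(cm, ("control", "disease"))
de_ce = run_de(cm, ("control", "disease_drug"))
calls = classify_study(am, de_cd, de_ce)

summary = summarize_strategies(calls)
metrics = recovery_metrics(calls, truth)

print(f"genes simulated:            {summary.n_genes}")
print(f"disease-regulated genes:    {summary.n_regulated} "
      f"({summary.pct_up:.0f}% up, {summary.pct_down:.0f}% down)")
print(f"drug-sensitive, strategy A: {int(calls['strategy_a'].sum())}")
print(f"drug-sensitive, strategy B: {int(calls['strategy_b'].sum())}")
print(f"strategy overlap |A∩B|/|B|: {summary.overlap_a_in_b:.2f}")
for s in ("A", "B"):
    m = metrics[s]
    print(f"strategy {s} vs planted truth: sensitivity {m['sensitivity']:.3f}, "
          f"specificity {m['specificity']:.3f}, FDP {m['fdp']:.3f}")

# Sensitivity/specificity are against the 200 planted rescued genes: both
# strategies should recover most of them while calling almost no null or
# persistently dysregulated gene sensitive.
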