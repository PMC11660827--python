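"""Metabolic stoichiometry, qPCR relative expression and outlier screening.

Three small derived-assay computations: the excess-lactate fraction at
normoxic and hypoxic lactate/glucose ratios, ddCq percent-of-control with two
reference genes, and modified Z-score / Grubbs outlier screens.
"""

import pandas as pd

from txrescue import ddcq_percent_of_control, detect_outliers, excess_lactate_fraction

# --- lactate / glucose stoichiometry --------------------------------------
# Glycolysis caps lactate yield at 2 per glucose; lactate above that ceiling
# must come from other carbon sources (e.g. glucogenic amino acids).
for label, glucose, lactate in (("normoxia", 0.9, 2.0), ("hypoxia", 2.0, 7.0)):
    s = excess_lactate_fraction(glucose, lactate)
    print(f"{label:9s} L/G ratio {s.lactate_glucose_ratio:.2f}  "
          f"excess lactate {100 * s.excess_lactate_fraction:.1f}%")

# --- qPCR relative expression (ddCq) ---------------------------------------
cq = pd.DataFrame({
    "sample": [f"s{i}" for i in range(6)],
    "group": ["control"] * 3 + ["disease"] * 3,
    "cq_target": [24.0, 24.2, 23.8, 26.1, 26.0, 25.9],
    "cq_ref1": [15.0, 15.1, 14.9, 15.0, 15.1, 15.0],
    "cq_ref2": [18.0, 18.0, 18.1, 18.0, 17.9, 18.1],
})
rel = ddcq_percent_of_control(cq)
print("\npercent of control (two reference genes):")
print(rel[["sample", "group", "percent_of_control"]].round(1).to_string(index=False))
# ~2 cycles higher target Cq in disease -> roughly 25% of control expression.

# --- outlier screening ------------------------------------------------------
values = [10.2, 9.8, 10.0, 10.1, 9.9, 10.0, 14.5]
for method in ("modified_z", "grubbs"):
    report = detect_outliers(values, method=method)
    print(f"\n{method}: flagged {[float(v) for v in report.flagged_values]}")
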