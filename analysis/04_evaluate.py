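"""Hierarchy-aware accuracy estimates, ETDRS subfield breakdown and
test-retest agreement.

Writes the subfield MAE table for the best feature-set, the Bland-Altman
summary of the retest cohort, and a Bland-Altman figure.
"""

from pathlib import Path

import pandas as pd

from infersens import evaluate as ev
from infersens import plots

OUT = Path(__file__).resolve().parents[1] / "results" / "study"

preds = pd.read_csv(OUT / "predictions_set5.csv")
table = ev.subfield_table(preds, metric="MAE")
table.to_csv(OUT / "mae_by_subfield_set5.csv", index=False)
print("MAE by ETDRS subfield (feature-set 5):")
for _, row in table.iterrows():
    print(f"  {row.stratum:20s} {row.estimate:5.2f} dB "
          f"[{row.ci_low:.2f}-{row.ci_high:.2f}]")

retest = pd.read_csv(OUT / "retest_patients.csv")
pairs = ev.make_retest_pairs(retest)
ba = ev.bland_altman(pairs, mode="retest")
pd.DataFrame([{
    "mean_diff_db": ba.mean_diff, "loa_low_db": ba.loa_low, "loa_high_db": ba.loa_high,
}]).to_csv(OUT / "bland_altman_retest.csv", index=False)
plots.bland_altman_plot(pairs, ba, OUT / "bland_altman_retest.png")
print(f"retest Bland-Altman: mean {ba.mean_diff:+.2f} dB, "
      f"LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] dB")

retest_frame = pairs.assign(observed=pairs.value1, predicted=pairs.value2, seed=0)
mae = ev.hierarchical_metric(retest_frame, metric="MAE")
print(f"retest MAE {mae.estimate:.2f} dB [{mae.ci_low:.2f}-{mae.ci_high:.2f}] "
      f"vs feature-set-5 prediction MAE "
      f"{ev.hierarchical_metric(preds, metric='MAE').estimate:.2f} dB")
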