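"""Permutation feature importance (%IncMSE) and feature contributions.

Writes the per-(seed, fold) importance table and a contribution plot for the
top feature; prints the pooled median ranking.
"""

from pathlib import Path

import pandas as pd

from infersens import featuresets as fs
from infersens import importance as imp
from infersens import model as mdl
from infersens import plots
from infersens import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "study"

data = pd.read_csv(OUT / "standardized.csv")
grid = sim.StimulusGrid(points=pd.read_csv(OUT / "grid.csv"))
fm = fs.build(1, data, grid)

plan = mdl.CVPlan(seeds=tuple(range(7)), outer_folds=2, n_trees=40)
table = imp.importance_over_folds(fm, plan, mtry=6)
table.to_csv(OUT / "importance_set1.csv")
pooled = table.summary()
print("median %IncMSE across 7 seeds x 2 folds (top 5):")
for feat, row in pooled.head(5).iterrows():
    print(f"  {feat:15s} {row['median']:7.1f}  [IQR {row.q25:.1f}-{row.q75:.1f}]")
ranks = table.per_seed_ranks()
top2 = ranks[["ISOS_thickness", "RPE_thickness"]].le(2).all(axis=1)
print(f"IS&OS + RPE thickness in the top 2 in {int(top2.sum())}/7 seeds")

forest = mdl.fit_forest(fm.X.to_numpy(float), fm.y.to_numpy(float), mtry=6,
                        n_trees=40, rng=0)
cs = imp.feature_contributions(forest, fm.X)
r2 = plots.contribution_plot(cs, "ISOS_thickness", fm.X["ISOS_thickness"],
                             OUT / "contribution_isos_thickness.png")
print(f"goodness-of-visualization R^2 (IS&OS thickness): {r2:.2f}")
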