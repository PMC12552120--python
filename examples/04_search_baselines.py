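"""Nearest-neighbour baselines quantify train-test leakage.

A predictor that simply averages the labels of the most similar training
complexes is accurate exactly where near-duplicates of the test complexes
leak into the training set -- and collapses on independent test complexes.
"""

import numpy as np

from gems import evaluate_scoring, predict_by_complex_search, predict_by_ligand_search
from gems.cleansplit import leakage_exclude
from gems.fixtures import ScenarioSpec, make_scenario

scenario = make_scenario(ScenarioSpec(seed=1))
truth = scenario.test_labels()
labels = scenario.train_labels()

preds = predict_by_complex_search(
    scenario.test_ids, labels, scenario.train_test_table, k=1
)
overall = evaluate_scoring(preds.predictions, truth)
print(f"complex search (k=1): Pearson r={overall.pearson_r:.3f} "
      f"RMSE={overall.rmse:.3f} pK")

leaked = {
    te for te in scenario.test_ids
    if any(leakage_exclude(scenario.train_test_table.get(tr, te)).excluded
           for tr in scenario.train_ids)
}
independent = set(scenario.test_ids) - leaked


def rmse(ids):
    return float(np.sqrt(np.mean([(preds.predictions[i] - truth[i]) ** 2
                                  for i in ids])))


print(f"  RMSE on leaked tests ({len(leaked)}):      {rmse(leaked):.3f} pK")
print(f"  RMSE on independent tests ({len(independent)}): {rmse(independent):.3f} pK")
print("  -> memorization only works where leakage exists")

lig = predict_by_ligand_search(scenario.test_ids, labels, scenario.train_test_table, k=1)
lig_eval = evaluate_scoring(lig.predictions, truth)
print(f"\nligand-only search (k=1): RMSE={lig_eval.rmse:.3f} pK")
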