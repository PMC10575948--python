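"""The metric suite and the multi-seed statistical comparison protocol.

Shows why threshold-dependent predictive values (PPV/NPV at a Youden
threshold) tell a different story than AUROC on imbalanced data, and why
single-split "winners" mislead compared to Mann-Whitney tests over
repeated splits.
"""

import numpy as np
import pandas as pd

from molbench import (
    classification_metrics,
    count_wins,
    pairwise_compare,
    youden_threshold,
)

rng = np.random.default_rng(0)

# an imbalanced screen: 5% actives, a decent but imperfect ranker
n = 2000
labels = (rng.random(n) < 0.05).astype(float)
scores = np.clip(0.25 * labels + rng.normal(0.3, 0.12, n), 0, 1)
threshold = youden_threshold(scores, labels)
results, cm = classification_metrics(scores, labels)
got = {r.metric: r.value for r in results}
print(f"Youden threshold = {threshold:.3f}  (TP={cm.tp} FP={cm.fp} TN={cm.tn} FN={cm.fn})")
print(
    "AUROC = {AUROC:.3f}  AUPRC = {AUPRC:.3f}  PPV = {PPV:.3f}  NPV = {NPV:.3f}".format(**got)
)
# AUROC looks strong, but PPV says most predicted actives are false
# positives at 5% prevalence — the number a screening campaign lives with.

# two models compared over 30 split seeds: B is slightly better on average
seeds = 30
table = pd.DataFrame(
    {
        "model_A": rng.normal(0.80, 0.03, seeds),
        "model_B": rng.normal(0.82, 0.03, seeds),
    }
)
report = pairwise_compare(table, metric="AUROC", better="higher")
single, ties = count_wins(table, mode="single")
triple, _ = count_wins(table, mode="triple")
print(
    f"mean AUROC: A = {report.means['model_A']:.3f}, B = {report.means['model_B']:.3f}; "
    f"Mann-Whitney p = {report.p_values.loc['model_A', 'model_B']:.4f}"
)
print(f"single-fold wins: {single} (of {seeds});  triple-combination wins: {triple} (of 4060)")
# even when B truly dominates, A still wins a sizeable share of individual
# folds — picking a winner from one split is a coin with a memory.
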