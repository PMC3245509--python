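"""Compare the trained predictor against the naïve ss baseline.

Scores every corpus chain with both the random-forest model and the naïve
secondary-structure formula, then assesses them with the margin MAE,
per-chain correlation, and the threshold-swept ROC AUC.
"""

import numpy as np

import flexmotion as fm

corpus = fm.generate_training_corpus(16, seed=42)
model = fm.train_from_corpus(corpus, "internal", config=fm.TrainConfig(seed=7))

preds, naives, refs, masks = [], [], [], []
for chain in corpus.chains:
    res = fm.predict_profile(chain.annotated, model)
    mask = res.mask & chain.norm_internal.mask
    preds.append(res.smoothed)
    naives.append(fm.naive_score(chain.annotated.ss, fm.INTERNAL_NAIVE))
    refs.append(chain.norm_internal.scores)
    masks.append(mask)

for name, scores in [("random forest", preds), ("naive baseline", naives)]:
    report = fm.evaluate_chains(scores, refs, masks=masks, thresholds=(1.0, 0.0))
    print(
        f"{name:14s}  MAE {report.mae_avg:.3f}  "
        f"CC {report.cc_avg:.3f} ± {report.cc_sd:.3f}  "
        f"AUC(0) {report.auc['0.0']:.3f}"
    )
print(
    "The forests use mobility, physicochemical, ss and ASA pair features;\n"
    "the baseline only knows distance to the nearest ss-run center, so a\n"
    "large AUC gap shows the model learned more than topology."
)
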