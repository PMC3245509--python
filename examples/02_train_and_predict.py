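"""Train the sequence-based predictor and score a chain.

Generates a labeled synthetic corpus (structures → normal modes →
normalized motion scores → window labels), trains the per-category random
forests for internal motion, and predicts per-residue scores for one chain
from its sequence annotations alone.
"""

import numpy as np

import flexmotion as fm

corpus = fm.generate_training_corpus(16, seed=42)
model = fm.train_from_corpus(corpus, "internal", config=fm.TrainConfig(seed=7))

chain = corpus.chains[3]
result = fm.predict_profile(chain.annotated, model)
truth = chain.norm_internal.scores

mask = result.mask & chain.norm_internal.mask
cc = fm.correlation(result.smoothed, truth, mask=mask)
mae = fm.mae_margin(result.smoothed, truth, margin=0.2, mask=mask)
print(f"chain of {len(chain.annotated)} residues")
print(f"  CC  vs normalized NMA score: {cc:.3f}")
print(f"  MAE (±0.2 margin):           {mae:.3f}")

regions = fm.extract_flexible_regions(result, threshold=1.0, min_len=3)
print("  predicted high-motion regions (1-based, score > 1, ≥ 3 residues):")
for r in regions:
    print(f"    {r.start:3d}–{r.end:3d}  mean score {r.mean_score:.2f}")
print("  planted long coils:", [(a + 1, b) for a, b in chain.planted_regions])
print(
    "A high CC means the forests rank mobile and rigid residues like the\n"
    "physics-derived reference; extracted regions are candidates for\n"
    "conformational-change segments."
)
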