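"""Train a focal-loss relation classifier on a separable synthetic corpus.

Focal loss down-weights well-classified terms by (1-p)^gamma / p^gamma,
focusing learning on hard examples under class imbalance; at gamma=0 it
is binary cross-entropy.
"""

import math

import numpy as np

from dtre.model import FocalLossParams, HashingEncoder, TrainConfig, focal_loss, predict_probs, train
from dtre.pipeline import _build_instances, split_docs
from dtre.synthetic_data import SyntheticCorpusConfig, generate_corpus

# the single-term anatomy of the loss
p = FocalLossParams(gamma=0.5, eps=1e-6)
print(f"term(y=1, p=0.5): {focal_loss(np.array([0.5]), np.array([1.0]), p):.6f}"
      f"  (= sqrt(0.5) * -log(0.5+1e-6) = {math.sqrt(0.5) * -math.log(0.5 + 1e-6):.6f})")
print(f"term(y=1, p=1.0): {focal_loss(np.array([1.0]), np.array([1.0]), p):.6f}  (perfectly classified)")

# train one member on a trigger-separable corpus and score held-out docs
corpus = generate_corpus(SyntheticCorpusConfig(n_docs=120, trigger_strength=1.0, seed=7))
train_docs, eval_docs = split_docs(corpus.docs, 0.8)
tr, _ = _build_instances(train_docs, corpus.entities, corpus.relations, {}, {})
ev, _ = _build_instances(eval_docs, corpus.entities, corpus.relations, {}, {})

encoder = HashingEncoder(dim=4096, seed=7)
state = train(tr, encoder, TrainConfig(seed=0, use_chem_desc=False, use_gene_desc=False))
probs = predict_probs(state, ev, encoder)
Y = np.stack([i.label for i in ev])
pred = probs >= 0.5
tp = int((pred & (Y == 1)).sum()); fp = int((pred & (Y == 0)).sum()); fn = int((~pred & (Y == 1)).sum())
print(f"held-out: TP={tp} FP={fp} FN={fn}  micro-F1={200 * tp / (2 * tp + fp + fn):.1f}")
# Each relation class has a unique trigger lexeme, so a linear head over
# hashed bag-of-tokens features separates the corpus; held-out micro-F1
# is high because the trigger, not the one-off gene name, carries the label.
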