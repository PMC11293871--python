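"""Full pipeline: seed ensembles, per-class thresholds, micro-F1 evaluation.

Runs the sentence-only (SBE) and gene-description (GDE) ensemble presets
on a corpus whose class signal lives ONLY in the gene descriptions, then
prints both reports - the description-augmented configuration wins.
"""

import tempfile

from dtre.pipeline import load_report, run_pipeline

base = {
    "seed": 7,
    "corpus": {
        "n_docs": 150,
        "trigger_strength": 0.0,           # no signal in the sentences
        "description_informativeness": 1.0,  # all signal in gene descriptions
    },
    "train": {"member_seeds": [0, 1, 2]},   # 3-seed probability-averaging ensemble
}

for preset in ("SBE", "GDE"):
    with tempfile.TemporaryDirectory() as tmp:
        run_pipeline(dict(base, preset=preset), tmp)
        micro = load_report(tmp).micro
    print(f"{preset}: P={micro['precision']:.1f} R={micro['recall']:.1f} F1={micro['f1']:.1f}")
# SBE cannot recover relations that are invisible from the sentence alone;
# GDE reads the class cue from each gene's description and scores far higher.
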