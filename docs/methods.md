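# Methods

## Problem and model

The package extracts typed chemical–gene relations from titled abstracts.
A candidate is any chemical mention and gene mention co-occurring inside
one sentence; each candidate is an independent multi-label classification
problem over 13 relation types. There is no NONE class: a pair with no
relation carries the all-zero label vector, and prediction is by
per-class probability thresholding, so one pair may yield zero, one or
several relation types.

The classifier is `sigmoid(W·h + b)` where `h` is a fixed-length context
embedding of the marker-tagged, optionally description-augmented text.
The four sentinel tokens (`[HEAD-S]`, `[HEAD-E]`, `[TAIL-S]`, `[TAIL-E]`)
tell the encoder which pair is being asked about; augmentation appends
the chemical definition and gene summary after `[SEP]` separators.
Cross-sentence gold relations cannot be represented by any candidate;
they are excluded from instance generation but counted
(`find_unreachable`) because they bound attainable recall.

Assumptions inherited from this design: relations are expressed within a
sentence; entity spans are gold (no NER is performed); normalized IDs
(MeSH, NCBI Gene) arrive with the data — GENE-N mentions without an ID
simply get empty descriptions and the model degrades to sentence-only
evidence for them.

## Focal loss

`loss = −Σ [ y·(1−p)^γ·log(p+ε) + (1−y)·p^γ·log(1−p+ε) ]`, summed over
every instance–class term. Defaults γ = 0.5, ε = 1e−6. The sum is the
loss as defined; a mean reduction (default during optimization) divides
by the number of terms for step-size stability and changes nothing about
the minimizer. Probabilities are clamped to [1e−7, 1−1e−7] before the
loss: ε alone does not bound `log(1−p+ε)` as p→1 in floating point. The
γ = 0, ε → 0 limit is binary cross-entropy; the test suite holds the
implementation to that identity at 1e−9 against an independently written
oracle, and checks the analytic gradient against finite differences.

## Reference encoder

`HashingEncoder(dim=4096, seed)` lowercases, splits on whitespace, strips
sentence-final punctuation from each token (so `levels.` ≡ `levels`),
hashes each token with a keyed BLAKE2b digest to a bucket and a sign,
accumulates, and L2-normalizes. It is deterministic across processes and
platforms — Python's built-in `hash` is deliberately avoided. Transformer
encoders fit behind the same contract (`name`, `dim`, `encode`,
`encode_batch`) but are not shipped; everything downstream of the
embedding is encoder-agnostic.

## Training

Adam (β₁ = 0.9, β₂ = 0.999) on the linear head only; defaults: learning
rate 0.2, 150 epochs, batch size 32, decoupled (AdamW-style) weight decay
0.003. One integer seed drives initialization, shuffling and any feature
projection, so identical inputs + config + seed reproduce bit-identical
serialized states. Non-finite loss raises immediately with the seed in
the message — divergence is reported, never hidden.

Two regularization choices matter for generalization with the hashing
encoder and are worth explaining:

* **Minimum feature support** (`min_feature_count=2`): hash buckets
  active in fewer than two training instances are masked out, the
  hashing analogue of a min-document-frequency cutoff. Without it, a
  linear head on separable data spreads its margin onto one-off tokens
  (e.g. an entity surface seen once), which is harmless in training and
  useless on held-out text where those tokens are fresh.
* **Decoupled weight decay** shrinks noise weights on rarely-active
  buckets; it is applied to the update, not folded into the Adam
  moments, because coupling it into the gradient makes Adam rescale the
  penalty away.

Sequence-feature fusion (`SFTDE`) concatenates the L2-normalized
576-vector of the tail gene's protein with the context embedding
(optionally through a seeded random projection); genes without a
sequence get a zero vector.

## Protein sequence descriptor (576 values)

Layout: 20 monopeptide frequencies (alphabetical one-letter order), 400
dipeptide frequencies (row-major, counted over the L−1 overlapping
pairs), 156 physicochemical features. Non-standard residues
(B, J, O, U, X, Z, …) are removed before counting — the 20/400 block
sizes mandate the standard alphabet — with the dropped count logged.

The 156 physicochemical features are: 16 whole-sequence properties
(length, molecular weight, aromaticity, instability index, GRAVY,
isoelectric point, net charge at pH 7, helix/turn/sheet fractions, molar
extinction coefficients reduced and oxidized, and mean/sd/min/max of the
windowed flexibility profile), plus 10 distribution statistics (mean,
sd, min, max, range, quartiles, first/second-half means) for each of 14
per-residue property scales: Kyte–Doolittle hydropathy, Hopp–Woods
hydrophilicity, Emini surface accessibility, Janin buried fraction,
Vihinen flexibility and residue mass (from Biopython), and Grantham
polarity, Zamyatnin volume, Charton polarizability, Charton free energy
of solution, Charton steric parameter, Zimmerman bulkiness, normalized
van der Waals volume and free-residue isoelectric point (bundled in
`data/aa_scales.tsv`). The ordered manifest ships machine-readably as
`data/physchem_manifest.json`; the choice of scales covers the property
families the descriptor is meant to express (mass, length, free energy,
hydrophobicity, flexibility, polarizability, steric, aromaticity,
stability, charge) and is configuration, not a hidden constant. Whole-
sequence properties are computed with Biopython's ProtParam. Sequences
shorter than the flexibility window (10 residues) report zeros for the
four flexibility statistics.

## Ensembles and thresholds

Members are combined by unweighted element-wise probability averaging —
no weighting or voting. Thresholds are inclusive (≥). Default 0.5 for
every class; the CGDE preset overrides AGONIST-INHIBITOR to 0.2,
compensating for that class's extreme scarcity and the correspondingly
low probabilities models assign it. No other per-class override is
presumed. Lowering a threshold can only add predictions (monotonicity, a
property test).

## Evaluation

Exact-tuple matching on (doc_id, rtype, arg1, arg2) after collapsing
both sides to sets: matched predictions are TP, unmatched predictions FP,
unmatched gold FN, each attributed to its relation type. Micro precision
= ΣTP/Σ(TP+FP), micro recall = ΣTP/Σ(TP+FN), F1 their harmonic mean,
reported on the 0–100 scale with one decimal in the text rendering. 0/0
conventions: a metric with a zero denominator is 0 when the opposing
count is nonzero; an entirely empty gold-and-prediction pair reports 100
with an explicit `vacuous` flag. Classes with no gold and no predictions
are flagged `empty` rather than diluting the micro average.

## Synthetic corpora

The generator emulates the *shape* of an annotated DTI corpus so every
stage is testable without downloads: titled abstracts; one chemical and
one gene span per generated sentence plus filler; class labels drawn
from a configurable distribution whose default mirrors the heavy
INHIBITOR skew of real DTI corpora (the three rare types at per-mille
rates); description tables; FASTA sequences per gene. All randomness
flows from one integer seed; identical configs produce byte-identical
files.

Two knobs place the class signal. `trigger_strength` is the probability
that a relation sentence contains its class's unique, otherwise-unused
trigger lexeme; at 1.0 the corpus is linearly separable from sentence
text by construction, so end-to-end learnability is a constructive
guarantee, not an empirical hope. `description_informativeness` is the
probability that, when the sentence signal was withheld, the gene's
description carries the cue instead; at (0, 1) the corpus is solvable
only by description-reading models, which is the setting that
demonstrates the advantage of description augmentation. Every gene
mention is a fresh surface form carrying one class, so a sentence-only
model cannot shortcut a description-only corpus by memorizing gene names
across the document split. The ledger records every pair, its class and
its signal placement, and is the exact oracle for corpus statistics and
instance enumeration.

What the generator does **not** emulate: realistic biomedical prose,
nested or overlapping entity spans, cross-sentence relations,
coreference, annotation noise beyond what the signal knobs induce, and
multi-pair sentences with correlated labels. Passing the synthetic
experiments therefore shows that the pipeline's machinery is correct and
that the model exploits the evidence channel it is given — not that any
particular score would transfer to real corpora, where the evidence is
distributional rather than lexical.

## Study conditions and problem sizes

The end-to-end experiments use 200 documents (≈ 800 instances, 80/20
document split), the 4096-dimensional reference encoder, and 3-seed
ensembles — sizes chosen so the full suite and the reproduction script
run in about a minute on one CPU while leaving the separable-corpus
micro-F1 comfortably above its bar across seeds. Unit and property
tests use smaller corpora (5–100 documents).

## Known limitations

* The reference encoder is a bag of tokens: no word order, no syntax; it
  exists to exercise the pipeline and the synthetic experiments, not to
  compete with pretrained transformers on real text.
* Mentions straddling the title/abstract boundary are rejected rather
  than guessed at (the offset dialect makes them ambiguous).
* Overlapping chemical/gene spans are skipped with a warning; their
  markup would be ambiguous.
* The evaluator's 0/0 conventions match common challenge-scorer
  behavior but are configurable in principle; deviations discovered
  against any particular official scorer would be switchable rather
  than silent.
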