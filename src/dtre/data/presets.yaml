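# Ensemble preset definitions.
# Each preset names which augmentation channels its member models use and
# any per-class decision-threshold overrides (default threshold is 0.5).
SBE:            # sentence-based ensemble
  use_chem_desc: false
  use_gene_desc: false
  use_seq_features: false
GDE:            # gene-description ensemble
  use_chem_desc: false
  use_gene_desc: true
  use_seq_features: false
CDE:            # chemical-description ensemble
  use_chem_desc: true
  use_gene_desc: false
  use_seq_features: false
CGDE:           # chemical + gene description ensemble
  use_chem_desc: true
  use_gene_desc: true
  use_seq_features: false
  class_overrides:
    AGONIST-INHIBITOR: 0.2
SFTDE:          # sequence features + text description ensemble
  use_chem_desc: false
  use_gene_desc: true
  use_seq_features: true
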