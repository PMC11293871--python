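"""Seed-ensemble prediction: probability averaging and per-class thresholds.

Member models' per-class probabilities are combined by an unweighted
arithmetic mean; a relation type is predicted for an instance when its
averaged probability reaches the class threshold (inclusive ``>=``). The
default threshold is 0.5; rare classes may carry overrides - the shipped
CGDE preset lowers the AGONIST-INHIBITOR threshold to 0.2, compensating
for that class's scarcity and the correspondingly low probabilities the
models assign to it.

Five named presets mirror the classic ensemble configurations:

========  =========  ==========  ============  ==================
preset    chem desc  gene desc   seq features  threshold override
========  =========  ==========  ============  ==================
SBE       no         no          no            -
GDE       no         yes         no            -
CDE       yes        no          no            -
CGDE      yes        yes         no            AGONIST-INHIBITOR >= 0.2
SFTDE     no         yes         yes           -
========  =========  ==========  ============  ==================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from dtre.corpus_io import RelationAnnotation
from dtre.instance_gen import RelationInstance
from dtre.relations import N_CLASSES, RELATION_TYPES, label_index


@dataclass
class PresetSpec:
    """Which augmentation channels a configuration uses, plus overrides."""

    name: str
    use_chem_desc: bool
    use_gene_desc: bool
    use_seq_features: bool
    class_overrides: dict[str, float] = field(default_factory=dict)


def _load_presets() -> dict[str, PresetSpec]:
    text = (resources.files("dtre") / "data" / "presets.yaml").read_text("utf-8")
    out: dict[str, PresetSpec] = {}
    for name, fields in yaml.safe_load(text).items():
        out[name] = PresetSpec(
            name=name,
            use_chem_desc=fields["use_chem_desc"],
            use_gene_desc=fields["use_gene_desc"],
            use_seq_features=fields["use_seq_features"],
            class_overrides=dict(fields.get("class_overrides", {})),
        )
    return out


PRESETS: dict[str, PresetSpec] = _load_presets()


@dataclass
class EnsembleConfig:
    """Member list plus thresholding rules."""

    members: list = field(default_factory=list)
    default_threshold: float = 0.5
    class_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.default_threshold < 1.0):
            raise ValueError("default_threshold must lie in (0, 1)")
        for rtype in self.class_overrides:
            label_index(rtype)  # validates the class name

    def threshold(self, rtype: str) -> float:
        return self.class_overrides.get(rtype, self.default_threshold)

    @classmethod
    def from_preset(cls, name: str, members: list | None = None) -> "EnsembleConfig":
        spec = PRESETS.get(name)
        if spec is None:
            raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        return cls(members=members or [], class_overrides=dict(spec.class_overrides))


def average_probs(member_probs: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise unweighted mean of member probability matrices."""
    if len(member_probs) == 0:
        raise ValueError("cannot average an empty member list")
    mats = [np.asarray(m, dtype=float) for m in member_probs]
    shape = mats[0].shape
    for i, m in enumerate(mats[1:], start=1):
        if m.shape != shape:
            raise ValueError(f"member {i} shape {m.shape} != member 0 shape {shape}")
    return np.mean(mats, axis=0)


def apply_thresholds(
    probs: np.ndarray,
    config: EnsembleConfig,
    instances: Sequence[RelationInstance],
) -> list[RelationAnnotation]:
    """Probabilities -> relation predictions; inclusive per-class thresholds.

    Row ``i`` of ``probs`` must correspond to ``instances[i]``. An
    instance can contribute zero, one or several predictions (multi-label).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != N_CLASSES:
        raise ValueError(f"probs must be (n, {N_CLASSES}), got {probs.shape}")
    if probs.shape[0] != len(instances):
        raise ValueError(
            f"{probs.shape[0]} probability rows vs {len(instances)} instances"
        )
    thresholds = np.array([config.threshold(r) for r in RELATION_TYPES])
    out: list[RelationAnnotation] = []
    for inst, row in zip(instances, probs):
        for c in np.flatnonzero(row >= thresholds):
            out.append(
                RelationAnnotation(
                    doc_id=inst.doc_id,
                    rtype=RELATION_TYPES[c],
                    arg1=inst.head_id,
                    arg2=inst.tail_id,
                )
            )
    return out
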