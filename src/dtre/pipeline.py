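"""End-to-end orchestration: simulate -> preprocess -> featurize -> train
seeds -> ensemble -> evaluate, with a reproducible run manifest.

A run is described by a single config mapping (usually loaded from YAML).
All stage outputs land under one output directory and a ``RunManifest``
records the config snapshot, SHA-256 digests of every artifact, the seeds
used and the package version. Identical config + seed reproduces an
identical evaluation report.

Config schema (all keys optional except none; defaults shown)::

    seed: 0                     # master seed; member seeds derive from it
    corpus:                     # SyntheticCorpusConfig fields
      n_docs: 100
      trigger_strength: 1.0
      description_informativeness: 0.0
    split:
      train_frac: 0.8           # leading fraction of docs used for training
    preset: SBE                 # SBE | GDE | CDE | CGDE | SFTDE
    encoder:
      dim: 4096
    train:                      # TrainConfig fields (seed list separate)
      epochs: 150
      learning_rate: 0.2
      member_seeds: [0, 1, 2]
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from dtre import __version__
from dtre.corpus_io import (
    Document,
    read_abstracts,
    read_entities,
    read_relations,
    write_predictions,
)
from dtre.descriptions import load_description_table
from dtre.ensemble import PRESETS, EnsembleConfig, apply_thresholds, average_probs
from dtre.evaluation import EvaluationReport, evaluate, format_report
from dtre.instance_gen import (
    RelationInstance,
    augment_instance,
    find_unreachable,
    generate_instances,
    write_instances,
)
from dtre.model import HashingEncoder, TrainConfig, predict_probs, train
from dtre.seq_features import N_FEATURES, compute_descriptors, l2_normalize
from dtre.synthetic_data import (
    SyntheticCorpus,
    SyntheticCorpusConfig,
    generate_corpus,
    generate_description_tables,
    generate_fasta,
    write_description_table,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunManifest:
    config: dict
    seeds: list[int]
    artifacts: dict[str, str]  # path -> sha256
    version: str = __version__

    def save(self, path: str | Path) -> None:
        """Atomic write: temp file in the same directory, then rename."""
        path = Path(path)
        payload = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(payload, encoding="utf-8")
        os.replace(tmp, path)

    def verify(self) -> bool:
        return all(
            _sha256(Path(p)) == digest for p, digest in self.artifacts.items()
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def split_docs(
    docs: Sequence[Document], train_frac: float
) -> tuple[list[Document], list[Document]]:
    """Deterministic leading-fraction split by document order."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    k = max(1, min(len(docs) - 1, int(round(len(docs) * train_frac))))
    return list(docs[:k]), list(docs[k:])


def _attach_features(
    instances: Sequence[RelationInstance], seqs: dict[str, str]
) -> None:
    """L2-normalized 576-dim descriptors per gene; zeros for GENE-N."""
    cache: dict[str, np.ndarray] = {}
    for inst in instances:
        key = inst.gene_norm_id
        if key is None or key not in seqs:
            inst.feature_vector = np.zeros(N_FEATURES)
            continue
        if key not in cache:
            cache[key] = np.asarray(l2_normalize(compute_descriptors(seqs[key])).values)
        inst.feature_vector = cache[key]


def _build_instances(
    docs: Sequence[Document],
    entities,
    relations,
    chem_table,
    gene_table,
) -> tuple[list[RelationInstance], int]:
    instances: list[RelationInstance] = []
    unreachable = 0
    for doc in docs:
        insts = generate_instances(doc, entities, relations)
        instances.extend(
            augment_instance(inst, chem_table, gene_table) for inst in insts
        )
        unreachable += len(find_unreachable(doc, entities, relations))
    return instances, unreachable


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> RunManifest:
    """Execute all stages; raises :class:`StageError` naming a failed stage.

    Partial outputs are retained on failure for debugging.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    preset_name = config.get("preset", "SBE")
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; available {sorted(PRESETS)}")
    preset = PRESETS[preset_name]
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[str(path)] = _sha256(path)

    # ---- simulate ----------------------------------------------------
    try:
        corpus_cfg = SyntheticCorpusConfig(
            **{**config.get("corpus", {}), "seed": master_seed}
        )
        corpus = generate_corpus(corpus_cfg)
        chem_desc, gene_desc = generate_description_tables(corpus)
        corpus_dir = outdir / "corpus"
        paths = corpus.write(corpus_dir)
        write_description_table(chem_desc, corpus_dir / "chem_descriptions.tsv")
        write_description_table(gene_desc, corpus_dir / "gene_descriptions.tsv")
        seqs = generate_fasta(corpus, corpus_dir / "genes.fasta")
        for p in [*paths.values(), corpus_dir / "chem_descriptions.tsv",
                  corpus_dir / "gene_descriptions.tsv", corpus_dir / "genes.fasta"]:
            record(p)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(f"simulate: {exc}") from exc

    # ---- preprocess (round-trips through corpus_io readers) ----------
    try:
        docs = read_abstracts(corpus_dir / "abstracts.tsv")
        entities = read_entities(corpus_dir / "entities.tsv", documents=docs)
        # file round-trip drops norm ids (the TSV dialect has no column for
        # them); restore from the in-memory corpus by mention identity
        norm_by_key = {(m.doc_id, m.mention_id): m.norm_id for m in corpus.entities}
        entities = [
            dataclasses.replace(m, norm_id=norm_by_key.get((m.doc_id, m.mention_id)))
            for m in entities
        ]
        relations = read_relations(corpus_dir / "relations.tsv", entities=entities)
        chem_table = load_description_table(
            corpus_dir / "chem_descriptions.tsv", "CTD_CHEMICAL"
        )
        gene_table = load_description_table(
            corpus_dir / "gene_descriptions.tsv", "ENTREZ_GENE"
        )
        train_docs, eval_docs = split_docs(
            docs, float(config.get("split", {}).get("train_frac", 0.8))
        )
        train_insts, _ = _build_instances(
            train_docs, entities, relations, chem_table, gene_table
        )
        eval_insts, eval_unreachable = _build_instances(
            eval_docs, entities, relations, chem_table, gene_table
        )
        if not train_insts or not eval_insts:
            raise ValueError("empty train or eval instance set; enlarge the corpus")
        write_instances(train_insts, outdir / "train_instances.tsv")
        write_instances(eval_insts, outdir / "eval_instances.tsv")
        record(outdir / "train_instances.tsv")
        record(outdir / "eval_instances.tsv")
        log.info(
            "instances: %d train, %d eval (%d unreachable gold)",
            len(train_insts),
            len(eval_insts),
            eval_unreachable,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"preprocess: {exc}") from exc

    # ---- featurize ---------------------------------------------------
    try:
        if preset.use_seq_features:
            _attach_features(train_insts, seqs)
            _attach_features(eval_insts, seqs)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"featurize: {exc}") from exc

    # ---- train member models -----------------------------------------
    try:
        train_cfg_raw = dict(config.get("train", {}))
        member_seeds = [
            int(s) for s in train_cfg_raw.pop("member_seeds", [0, 1, 2])
        ]
        encoder = HashingEncoder(
            dim=int(config.get("encoder", {}).get("dim", 4096)), seed=master_seed
        )
        states = []
        for ms in member_seeds:
            tc = TrainConfig(
                **train_cfg_raw,
                seed=master_seed * 1000 + ms,
                use_chem_desc=preset.use_chem_desc,
                use_gene_desc=preset.use_gene_desc,
                feature_fusion="concat" if preset.use_seq_features else "none",
            )
            state = train(train_insts, encoder, tc)
            state_path = outdir / f"model_seed{ms}.json"
            state.save(state_path)
            record(state_path)
            states.append(state)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"train: {exc}") from exc

    # ---- predict + ensemble ------------------------------------------
    try:
        member_probs = [predict_probs(s, eval_insts, encoder) for s in states]
        probs = average_probs(member_probs)
        ens = EnsembleConfig.from_preset(preset_name, members=states)
        predictions = apply_thresholds(probs, ens, eval_insts)
        pred_path = outdir / "predictions.tsv"
        write_predictions(predictions, pred_path)
        record(pred_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"ensemble: {exc}") from exc

    # ---- evaluate ----------------------------------------------------
    try:
        eval_doc_ids = {d.doc_id for d in eval_docs}
        gold = [r for r in relations if r.doc_id in eval_doc_ids]
        report = evaluate(gold, predictions, unreachable_gold=eval_unreachable)
        report_path = outdir / "report.json"
        report.save(report_path)
        record(report_path)
        log.info("evaluation:\n%s", format_report(report))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"evaluate: {exc}") from exc

    manifest = RunManifest(
        config=dict(config),
        seeds=[master_seed, *member_seeds],
        artifacts=artifacts,
    )
    manifest.save(outdir / "manifest.json")
    return manifest


def load_report(outdir: str | Path) -> EvaluationReport:
    payload = json.loads((Path(outdir) / "report.json").read_text("utf-8"))
    return EvaluationReport(
        per_class=payload["per_class"],
        micro=payload["micro"],
        vacuous=payload["vacuous"],
        unreachable_gold=payload["unreachable_gold"],
    )
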