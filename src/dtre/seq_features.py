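"""576-dimensional protein sequence descriptors.

Layout, fixed and documented for reproducibility:

* 20 monopeptide frequencies, alphabetical one-letter order (A..Y over the
  20 standard residues);
* 400 dipeptide frequencies, row-major over the same order (AA, AC, ..,
  YV, YY), counted over the L-1 overlapping adjacent pairs;
* 156 physicochemical features: 16 whole-sequence properties computed with
  Biopython's ProtParam (length, molecular weight, aromaticity,
  instability index, GRAVY, isoelectric point, net charge at pH 7,
  secondary-structure fractions, molar extinction coefficients, and
  summary statistics of the windowed flexibility profile) followed by 14
  per-residue property scales x 10 distribution statistics each. Six
  scales come from Biopython (Kyte-Doolittle hydropathy, Hopp-Woods
  hydrophilicity, Emini surface accessibility, Janin buried fraction,
  Vihinen flexibility, residue mass); eight further published scales
  (Grantham polarity, Zamyatnin volume, Charton polarizability, Charton
  free energy of solution, Charton steric parameter, Zimmerman bulkiness,
  normalized van der Waals volume, residue isoelectric point) ship as a
  TSV next to this module.

The full feature manifest is available machine-readably from
:func:`feature_names` and as ``data/physchem_manifest.json``.

Non-standard residues (B, J, O, U, X, Z and anything else outside the
20-letter alphabet) are removed before any computation, with a logged
count; the 20/400 block sizes mandate the standard alphabet.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import Flex, em, hw, ja, kd

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter order
_AA_SET = frozenset(AMINO_ACIDS)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

N_MONO, N_DI, N_PHYSCHEM = 20, 400, 156
N_FEATURES = N_MONO + N_DI + N_PHYSCHEM

_SCALE_STATS = (
    "mean",
    "sd",
    "min",
    "max",
    "range",
    "q25",
    "median",
    "q75",
    "mean_first_half",
    "mean_second_half",
)

_BASIC_NAMES = (
    "length",
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "gravy",
    "isoelectric_point",
    "charge_at_pH7",
    "ss_helix_fraction",
    "ss_turn_fraction",
    "ss_sheet_fraction",
    "extinction_coeff_reduced",
    "extinction_coeff_oxidized",
    "flexibility_profile_mean",
    "flexibility_profile_sd",
    "flexibility_profile_min",
    "flexibility_profile_max",
)


def _load_bundled_scales() -> dict[str, dict[str, float]]:
    scales: dict[str, dict[str, float]] = {}
    text = (resources.files("dtre") / "data" / "aa_scales.tsv").read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    for name in header:
        scales[name] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        residue = fields[0]
        for name, value in zip(header, fields[1:]):
            scales[name][residue] = float(value)
    return scales


def _residue_scales() -> dict[str, dict[str, float]]:
    scales: dict[str, dict[str, float]] = {
        "hydropathy_kd": kd,
        "hydrophilicity_hw": hw,
        "surface_accessibility_em": em,
        "buried_fraction_ja": ja,
        "flexibility_vihinen": Flex,
        "residue_mass": {a: protein_weights[a] for a in AMINO_ACIDS},
    }
    scales.update(_load_bundled_scales())
    for name, table in scales.items():
        missing = _AA_SET - set(table)
        if missing:
            raise RuntimeError(f"scale {name} missing residues {sorted(missing)}")
    return scales


_SCALES = _residue_scales()
SCALE_NAMES = tuple(_SCALES)  # insertion order: 6 Biopython + 8 bundled

assert len(SCALE_NAMES) * len(_SCALE_STATS) + len(_BASIC_NAMES) == N_PHYSCHEM


@dataclass
class SequenceFeatureVector:
    """Ordered 576-float descriptor vector for one protein sequence."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"descriptor vector must have length {N_FEATURES}, "
                f"got {self.values.shape}"
            )

    @property
    def monopeptide(self) -> np.ndarray:
        return self.values[:N_MONO]

    @property
    def dipeptide(self) -> np.ndarray:
        return self.values[N_MONO : N_MONO + N_DI]

    @property
    def physchem(self) -> np.ndarray:
        return self.values[N_MONO + N_DI :]


def clean_sequence(seq: str) -> str:
    """Uppercase and drop residues outside the standard 20-letter alphabet."""
    upper = seq.upper()
    cleaned = "".join(a for a in upper if a in _AA_SET)
    dropped = len(upper) - len(cleaned)
    if dropped:
        log.info("dropped %d non-standard residue(s) from sequence", dropped)
    return cleaned


def monopeptide_frequencies(seq: str) -> np.ndarray:
    """Relative frequency of each standard residue (sums to 1)."""
    cleaned = clean_sequence(seq)
    if not cleaned:
        raise ValueError("sequence empty after removing non-standard residues")
    counts = np.zeros(N_MONO)
    for a in cleaned:
        counts[_AA_INDEX[a]] += 1
    return counts / len(cleaned)


def dipeptide_frequencies(seq: str) -> np.ndarray:
    """Relative frequency of each ordered adjacent residue pair.

    Counted over the L-1 overlapping windows, row-major over alphabetical
    one-letter order (AA, AC, .., YY); sums to 1 for L >= 2.
    """
    cleaned = clean_sequence(seq)
    if len(cleaned) < 2:
        raise ValueError("dipeptide frequencies need >= 2 standard residues")
    counts = np.zeros(N_DI)
    for a, b in zip(cleaned, cleaned[1:]):
        counts[_AA_INDEX[a] * N_MONO + _AA_INDEX[b]] += 1
    return counts / (len(cleaned) - 1)


def _profile_stats(values: np.ndarray) -> list[float]:
    if values.size == 0:
        return [0.0] * len(_SCALE_STATS)
    half = (values.size + 1) // 2
    return [
        float(values.mean()),
        float(values.std()),
        float(values.min()),
        float(values.max()),
        float(values.max() - values.min()),
        float(np.quantile(values, 0.25)),
        float(np.quantile(values, 0.5)),
        float(np.quantile(values, 0.75)),
        float(values[:half].mean()),
        float(values[-half:].mean()),
    ]


def physchem_features(seq: str) -> np.ndarray:
    """The 156 physicochemical descriptors, in manifest order."""
    cleaned = clean_sequence(seq)
    if not cleaned:
        raise ValueError("sequence empty after removing non-standard residues")
    pa = ProteinAnalysis(cleaned)
    helix, turn, sheet = pa.secondary_structure_fraction()
    eps_red, eps_ox = pa.molar_extinction_coefficient()
    flex_profile = np.asarray(pa.flexibility()) if len(cleaned) > 9 else np.array([])
    out: list[float] = [
        float(len(cleaned)),
        pa.molecular_weight(),
        pa.aromaticity(),
        pa.instability_index(),
        pa.gravy(),
        pa.isoelectric_point(),
        pa.charge_at_pH(7.0),
        helix,
        turn,
        sheet,
        float(eps_red),
        float(eps_ox),
        float(flex_profile.mean()) if flex_profile.size else 0.0,
        float(flex_profile.std()) if flex_profile.size else 0.0,
        float(flex_profile.min()) if flex_profile.size else 0.0,
        float(flex_profile.max()) if flex_profile.size else 0.0,
    ]
    for name in SCALE_NAMES:
        table = _SCALES[name]
        profile = np.array([table[a] for a in cleaned])
        out.extend(_profile_stats(profile))
    vec = np.array(out)
    assert vec.shape == (N_PHYSCHEM,)
    return vec


def compute_descriptors(seq: str) -> SequenceFeatureVector:
    """Concatenate the 20 + 400 + 156 blocks into the full descriptor."""
    values = np.concatenate(
        [monopeptide_frequencies(seq), dipeptide_frequencies(seq), physchem_features(seq)]
    )
    return SequenceFeatureVector(values=values, normalized=False)


def l2_normalize(vec: np.ndarray | SequenceFeatureVector) -> np.ndarray | SequenceFeatureVector:
    """Divide a vector by its Euclidean norm.

    An all-zero vector is returned unchanged with a warning. Accepts a raw
    array or a :class:`SequenceFeatureVector` (returned with
    ``normalized=True``).
    """
    if isinstance(vec, SequenceFeatureVector):
        return SequenceFeatureVector(
            values=np.asarray(l2_normalize(vec.values)), normalized=True
        )
    arr = np.asarray(vec, dtype=float)
    norm = float(np.linalg.norm(arr))
    if norm == 0.0:
        log.warning("l2_normalize: zero vector left unchanged")
        return arr
    return arr / norm


def physchem_feature_names() -> list[str]:
    names = list(_BASIC_NAMES)
    for scale in SCALE_NAMES:
        names.extend(f"{scale}_{stat}" for stat in _SCALE_STATS)
    return names


def feature_names() -> list[str]:
    """Header names for all 576 descriptor columns, in vector order."""
    names = [f"mono_{a}" for a in AMINO_ACIDS]
    names += [f"di_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    names += physchem_feature_names()
    assert len(names) == N_FEATURES
    return names


def load_manifest() -> list[str]:
    """The shipped machine-readable manifest of the 156 physicochemical names."""
    text = (resources.files("dtre") / "data" / "physchem_manifest.json").read_text("utf-8")
    return json.loads(text)


def featurize_fasta(
    fasta_path: str | Path,
    out_path: str | Path | None = None,
    l2: bool = False,
) -> dict[str, np.ndarray]:
    """Descriptor vectors for every record of a FASTA file.

    Optionally L2-normalizes each vector and writes a TSV matrix with a
    header naming all 576 features.
    """
    feats: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        vec = compute_descriptors(str(rec.seq))
        if l2:
            vec = l2_normalize(vec)
        feats[rec.id] = vec.values
    if out_path is not None:
        header = "\t".join(["id"] + feature_names())
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            for rid, values in feats.items():
                fh.write(rid + "\t" + "\t".join(repr(v) for v in values) + "\n")
    return feats
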