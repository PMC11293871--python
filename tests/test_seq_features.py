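from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtre.seq_features import (
    AMINO_ACIDS,
    N_FEATURES,
    compute_descriptors,
    dipeptide_frequencies,
    feature_names,
    featurize_fasta,
    l2_normalize,
    load_manifest,
    monopeptide_frequencies,
    physchem_feature_names,
    physchem_features,
)

SEQS = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=200)


def random_seq(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


class TestMonopeptide:
    def test_single_letter(self):
        v = monopeptide_frequencies("AAA")
        assert v[AMINO_ACIDS.index("A")] == 1.0
        assert v.sum() == 1.0

    def test_two_letters(self):
        v = monopeptide_frequencies("ACAC")
        assert v[AMINO_ACIDS.index("A")] == 0.5
        assert v[AMINO_ACIDS.index("C")] == 0.5

    def test_matches_counting_oracle_on_random_200mer(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 200)
        counts = Counter(seq)
        v = monopeptide_frequencies(seq)
        for i, a in enumerate(AMINO_ACIDS):
            assert v[i] == pytest.approx(counts[a] / 200)

    def test_nonstandard_residues_removed(self):
        assert np.allclose(monopeptide_frequencies("AXA"), monopeptide_frequencies("AA"))

    def test_empty_after_cleaning_rejected(self):
        with pytest.raises(ValueError):
            monopeptide_frequencies("XXXB")

    @given(SEQS)
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        assert np.allclose(monopeptide_frequencies(seq), monopeptide_frequencies(shuffled))


class TestDipeptide:
    def test_homopolymer(self):
        v = dipeptide_frequencies("AAA")
        assert v[0] == 1.0  # AA is the first row-major cell
        assert v.sum() == 1.0

    def test_alternating(self):
        v = dipeptide_frequencies("ACA")
        ac = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("C")
        ca = AMINO_ACIDS.index("C") * 20 + AMINO_ACIDS.index("A")
        assert v[ac] == 0.5
        assert v[ca] == 0.5

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 200)
        pairs = Counter(seq[i : i + 2] for i in range(199))
        v = dipeptide_frequencies(seq)
        for pair, n in pairs.items():
            idx = AMINO_ACIDS.index(pair[0]) * 20 + AMINO_ACIDS.index(pair[1])
            assert v[idx] == pytest.approx(n / 199)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dipeptide_frequencies("A")


class TestPhyschem:
    def test_vector_length_156(self):
        assert physchem_features("MKTAYIAKQR").shape == (156,)

    def test_length_feature(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 120)
        names = physchem_feature_names()
        v = physchem_features(seq)
        assert v[names.index("length")] == 120

    def test_molecular_weight_of_glycine(self):
        # C2H5NO2: 2*12.011 + 5*1.008 + 14.007 + 2*15.999 = 75.067
        names = physchem_feature_names()
        v = physchem_features("G")
        assert v[names.index("molecular_weight")] == pytest.approx(75.067, abs=0.01)

    def test_manifest_matches_computed_order(self):
        assert load_manifest() == physchem_feature_names()


class TestComputeDescriptors:
    def test_total_length_and_block_layout(self):
        vec = compute_descriptors("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        assert vec.values.shape == (N_FEATURES,)
        assert 20 + 400 + 156 == N_FEATURES
        assert vec.monopeptide.sum() == pytest.approx(1.0)
        assert vec.dipeptide.sum() == pytest.approx(1.0)

    def test_equals_concatenation_of_components(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            seq = random_seq(rng, int(rng.integers(2, 80)))
            vec = compute_descriptors(seq)
            expected = np.concatenate(
                [
                    monopeptide_frequencies(seq),
                    dipeptide_frequencies(seq),
                    physchem_features(seq),
                ]
            )
            assert np.array_equal(vec.values, expected)

    def test_deterministic(self):
        a = compute_descriptors("MKTAYIAKQR").values
        b = compute_descriptors("MKTAYIAKQR").values
        assert np.array_equal(a, b)

    def test_feature_names_cover_all_columns(self):
        names = feature_names()
        assert len(names) == N_FEATURES
        assert len(set(names)) == N_FEATURES


class TestL2Normalize:
    def test_three_four_five(self):
        assert np.allclose(l2_normalize(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_unit_vector_unchanged(self):
        v = np.array([1.0, 0.0])
        assert np.allclose(l2_normalize(v), v)

    def test_zero_vector_unchanged_with_warning(self, caplog):
        v = np.zeros(4)
        assert np.array_equal(l2_normalize(v), v)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_for_nonzero(self, values):
        v = np.array(values)
        if np.linalg.norm(v) < 1e-6:
            return
        once = l2_normalize(v)
        assert np.allclose(l2_normalize(once), once, atol=1e-12)
        assert np.linalg.norm(once) == pytest.approx(1.0)


class TestFastaMatrix:
    def test_featurize_fasta_writes_header_and_rows(self, tmp_path):
        fasta = tmp_path / "p.fa"
        fasta.write_text(">p1\nMKTAYIAKQR\n>p2\nGGGGCCCCAA\n", encoding="utf-8")
        out = tmp_path / "feats.tsv"
        feats = featurize_fasta(fasta, out, l2=True)
        assert set(feats) == {"p1", "p2"}
        for v in feats.values():
            assert np.linalg.norm(v) == pytest.approx(1.0)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["id"] + feature_names()
        assert len(lines) == 3
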