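"""Accumulated natural vector construction: worked-example pins, layout,
invariants, and equivalence with a naive double-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anv import (
    AMINO_ACIDS,
    ANV_COLUMNS,
    ANV_DIMENSION,
    RESIDUE_PAIRS,
    ANVVectorizer,
    InvalidResidueError,
    ProteinSequence,
    accumulate_indicators,
    build_anv,
    count_residues,
    covariance,
    make_sequence,
    mean_positions,
    variance,
    vectorize_collection,
)
from anv.alphabet import RESIDUE_INDEX


def naive_anv(residues: str) -> np.ndarray:
    """Independent double-loop evaluation of the defining formulas."""
    n = len(residues)
    acc = {a: [0] * n for a in AMINO_ACIDS}
    for a in AMINO_ACIDS:
        run = 0
        for k in range(n):
            run += residues[k] == a
            acc[a][k] = run
    counts = {a: acc[a][-1] for a in AMINO_ACIDS}
    zeta = {
        a: (sum(acc[a]) / counts[a] if counts[a] else 0.0) for a in AMINO_ACIDS
    }
    theta = {a: sum(acc[a]) / n for a in AMINO_ACIDS}

    def cov(a, b):
        if counts[a] == 0 or counts[b] == 0:
            return 0.0
        s = sum(
            (acc[a][k] - theta[a]) * (acc[b][k] - theta[b]) for k in range(n)
        )
        return s / (counts[a] * counts[b])

    vec = (
        [float(counts[a]) for a in AMINO_ACIDS]
        + [zeta[a] for a in AMINO_ACIDS]
        + [cov(a, a) for a in AMINO_ACIDS]
        + [cov(a, b) for a, b in RESIDUE_PAIRS]
    )
    return np.asarray(vec)


class TestWorkedExample:
    """Every printed value of the ten-residue example is reproduced."""

    def test_accumulated_indicator_rows(self, example_table):
        expected = {
            "A": [1, 1, 1, 1, 2, 2, 2, 2, 2, 2],
            "R": [0, 1, 2, 2, 2, 2, 2, 2, 2, 2],
            "N": [0, 0, 0, 1, 1, 1, 1, 1, 1, 1],
            "D": [0, 0, 0, 0, 0, 1, 1, 2, 2, 2],
            "C": [0, 0, 0, 0, 0, 0, 1, 1, 2, 3],
        }
        for residue, row in expected.items():
            assert example_table.row(residue).tolist() == row
        for residue in set(AMINO_ACIDS) - set(expected):
            assert example_table.row(residue).tolist() == [0] * 10

    def test_counts(self, example_table):
        counts = count_residues(example_table)
        expected = {"A": 2, "R": 2, "N": 1, "D": 2, "C": 3}
        for residue, n in expected.items():
            assert counts[RESIDUE_INDEX[residue]] == n
        assert counts.sum() == 10

    def test_mean_positions(self, example_table):
        zeta = mean_positions(example_table)
        expected = {"A": 8.0, "R": 8.5, "N": 7.0, "D": 4.0, "C": 7 / 3}
        for residue, z in expected.items():
            assert zeta[RESIDUE_INDEX[residue]] == pytest.approx(z)
        absent = set(AMINO_ACIDS) - set(expected)
        for residue in absent:
            assert zeta[RESIDUE_INDEX[residue]] == 0.0

    def test_theta_centering_constant(self, example_table):
        # theta is the time-average of the accumulated curve, not zeta
        from anv.vectorize import _theta

        theta = _theta(example_table)
        assert theta[RESIDUE_INDEX["A"]] == pytest.approx(1.6)
        assert theta[RESIDUE_INDEX["R"]] == pytest.approx(1.7)

    @pytest.mark.parametrize(
        "residue, expected",
        [("A", 0.6), ("R", 1.025), ("N", 2.1), ("D", 1.9), ("C", 1.122)],
    )
    def test_variances(self, example_table, residue, expected):
        assert variance(example_table, residue) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "pair, expected",
        [
            ("AR", 0.45), ("AN", 0.9), ("AD", 0.8), ("AC", 0.467),
            ("RN", 1.05), ("RD", 0.6), ("RC", 0.35), ("ND", 1.2),
            ("NC", 0.7), ("DC", 1.233),
        ],
    )
    def test_covariances(self, example_table, pair, expected):
        value = covariance(example_table, pair[0], pair[1])
        assert value == pytest.approx(expected, abs=5e-4)
        assert covariance(example_table, pair[1], pair[0]) == pytest.approx(value)

    def test_full_vector_nonzero_pattern(self, example_seq):
        vec = build_anv(example_seq)
        # counts block
        assert vec[:5].tolist() == [2, 2, 1, 2, 3]
        assert np.all(vec[5:20] == 0)
        # mean-position block
        np.testing.assert_allclose(vec[20:25], [8, 8.5, 7, 4, 7 / 3])
        assert np.all(vec[25:40] == 0)
        # variance block
        np.testing.assert_allclose(
            vec[40:45], [0.6, 1.025, 2.1, 1.9, 1.122], atol=5e-4
        )
        assert np.all(vec[45:60] == 0)
        # covariance block: only pairs within {A,R,N,D,C} are nonzero
        cov_block = dict(zip(RESIDUE_PAIRS, vec[60:]))
        present = set("ARNDC")
        for (a, b), value in cov_block.items():
            if not ({a, b} <= present):
                assert value == 0.0
        assert cov_block[("A", "R")] == pytest.approx(0.45)
        assert cov_block[("D", "C")] == pytest.approx(1.233, abs=5e-4)


class TestLayout:
    def test_dimension_and_block_sizes(self):
        assert ANV_DIMENSION == 250
        assert len(RESIDUE_PAIRS) == 190
        assert len(ANV_COLUMNS) == 250
        assert ANV_COLUMNS[0] == "n_A"
        assert ANV_COLUMNS[20] == "zeta_A"
        assert ANV_COLUMNS[40] == "D_A"
        assert ANV_COLUMNS[60] == "cov_A_R"
        assert ANV_COLUMNS[-1] == "cov_Y_V"

    def test_pair_order_is_lexicographic_in_alphabet_order(self):
        assert RESIDUE_PAIRS[0] == ("A", "R")
        assert RESIDUE_PAIRS[1] == ("A", "N")
        assert RESIDUE_PAIRS[19] == ("R", "N")
        assert RESIDUE_PAIRS[-1] == ("Y", "V")


@st.composite
def protein_strings(draw, max_length=30):
    length = draw(st.integers(1, max_length))
    return "".join(
        draw(st.lists(st.sampled_from(AMINO_ACIDS), min_size=length, max_size=length))
    )


class TestProperties:
    @given(protein_strings())
    @settings(max_examples=150, deadline=None)
    def test_matches_naive_oracle(self, residues):
        vec = build_anv(ProteinSequence("p", residues))
        expected = naive_anv(residues)
        np.testing.assert_allclose(vec, expected, rtol=1e-12, atol=1e-12)

    @given(protein_strings())
    @settings(max_examples=100, deadline=None)
    def test_table_invariants(self, residues):
        table = accumulate_indicators(ProteinSequence("p", residues))
        n = len(residues)
        # exactly one residue per position: column k sums to k (1-based)
        np.testing.assert_array_equal(
            table.values.sum(axis=0), np.arange(1, n + 1)
        )
        # rows non-decreasing with steps 0 or 1
        steps = np.diff(table.values, axis=1)
        assert np.all((steps == 0) | (steps == 1))
        assert count_residues(table).sum() == n

    @given(protein_strings())
    @settings(max_examples=100, deadline=None)
    def test_variance_nonneg_and_cauchy_schwarz(self, residues):
        vec = build_anv(ProteinSequence("p", residues))
        counts, variances = vec[:20], vec[40:60]
        assert np.all(variances >= -1e-15)
        cov_block = vec[60:]
        for (a, b), value in zip(RESIDUE_PAIRS, cov_block):
            i, j = RESIDUE_INDEX[a], RESIDUE_INDEX[b]
            if counts[i] > 0 and counts[j] > 0:
                bound = np.sqrt(variances[i] * variances[j])
                assert abs(value) <= bound + 1e-10

    def test_deterministic_and_order_sensitive(self):
        s = "ARRNADCDCC"
        v1 = build_anv(ProteinSequence("a", s))
        v2 = build_anv(ProteinSequence("b", s))
        assert np.array_equal(v1, v2)
        reversed_vec = build_anv(ProteinSequence("r", s[::-1]))
        assert not np.allclose(v1, reversed_vec)

    def test_single_residue_sequence(self):
        vec = build_anv(ProteinSequence("g", "G"))
        g = RESIDUE_INDEX["G"]
        assert vec[g] == 1
        assert vec[20 + g] == 1.0  # zeta = accumulated sum / count = 1
        assert vec[40 + g] == 0.0  # curve equals theta everywhere
        assert np.count_nonzero(vec) == 2


class TestSanitization:
    def test_strict_rejects_with_position(self):
        with pytest.raises(InvalidResidueError, match="'X' at position 3"):
            make_sequence("s1", "ARXND", policy="strict")

    def test_drop_removes_and_reindexes(self, caplog):
        seq = make_sequence("s1", "ARXND*", policy="drop")
        assert seq.residues == "ARND"

    def test_lowercase_uppercased(self):
        assert make_sequence("s", "arrna").residues == "ARRNA"


class TestCollection:
    def test_row_order_and_ids(self):
        seqs = [ProteinSequence(f"s{i}", "ARRNADCDCC") for i in range(3)]
        table = vectorize_collection(seqs)
        assert table.shape == (3, 250)
        assert list(table.index) == ["s0", "s1", "s2"]
        assert list(table.columns) == list(ANV_COLUMNS)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vectorize_collection([])

    def test_duplicate_ids_disambiguated(self):
        seqs = [ProteinSequence("dup", "AR"), ProteinSequence("dup", "RA")]
        table = vectorize_collection(seqs)
        assert list(table.index) == ["dup", "dup__1"]

    def test_synthetic_collection_all_finite(self, benchmark_point_sets):
        for fam in benchmark_point_sets:
            assert fam.points.shape[1] == 250
            assert np.all(np.isfinite(fam.points))


class TestVectorizerEstimator:
    def test_transform_matches_build_anv(self, example_seq):
        mat = ANVVectorizer().fit_transform(["ARRNADCDCC"])
        np.testing.assert_array_equal(mat[0], build_anv(example_seq))

    def test_sklearn_pipeline_compatibility(self):
        from sklearn.pipeline import make_pipeline

        from anv import NearestNeighborFamilyClassifier

        pipe = make_pipeline(ANVVectorizer(), NearestNeighborFamilyClassifier())
        train = ["AAAAAAAAAAAAAAAAAAAA", "WWWWWWWWWWWWWWWWWWWW"]
        pipe.fit(train, ["polyA", "polyW"])
        assert list(pipe.predict(["AAAAAAAAAAWAAAAAAAAA"])) == ["polyA"]

    def test_feature_names(self):
        names = ANVVectorizer().get_feature_names_out()
        assert names[0] == "n_A" and names[-1] == "cov_Y_V"
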