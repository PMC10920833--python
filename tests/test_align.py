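import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtclan.align import (
    DistanceMatrix,
    Msa,
    SequenceRecord,
    all_vs_all,
    bit_score,
    blosum62,
    center_star_msa,
    scoredist_variant,
    smith_waterman,
)
from gtclan.errors import ConfigurationError, DegenerateInputError, InputError


def sw_oracle(a: str, b: str, m, gap_open: float, gap_extend: float) -> float:
    """Exhaustive affine-gap local alignment DP, kept independent of the
    production route (plain Python, three explicit state matrices)."""
    na, nb = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (nb + 1) for _ in range(na + 1)]
    Ix = [[neg] * (nb + 1) for _ in range(na + 1)]
    Iy = [[neg] * (nb + 1) for _ in range(na + 1)]
    best = 0.0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            M[i][j] = m.score(a[i - 1], b[j - 1]) + max(
                0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]
            )
            best = max(best, M[i][j])
    return best


def rec(name: str, seq: str) -> SequenceRecord:
    return SequenceRecord(id=name, sequence=seq)


class TestSmithWaterman:
    def test_identical_poly_a(self, matrix):
        result = smith_waterman(rec("a", "AAAA"), rec("b", "AAAA"), matrix)
        assert result.raw_score == 4 * matrix.score("A", "A") == 16
        assert result.identity_fraction == 1.0
        assert result.alignment_length == 4

    def test_all_negative_cross_scores_empty_alignment(self, matrix):
        # C vs P scores -3 in BLOSUM62; no positive local path exists
        result = smith_waterman(rec("a", "CCCC"), rec("b", "PPPP"), matrix)
        assert result.raw_score == 0
        assert result.aligned_pairs == []

    def test_illegal_residue_rejected(self):
        with pytest.raises(InputError, match="position 2"):
            rec("bad", "AC1DE")

    def test_self_score_dominates(self, matrix):
        a = rec("a", "MKVLATTREW")
        b = rec("b", "GGGPPPCCCW")
        self_score = smith_waterman(a, a, matrix).raw_score
        assert self_score >= smith_waterman(a, b, matrix).raw_score

    @given(
        st.text(alphabet="ACDE", min_size=1, max_size=8),
        st.text(alphabet="ACDE", min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_oracle(self, a, b):
        m = blosum62()
        result = smith_waterman(rec("a", a), rec("b", b), m)
        assert result.raw_score == pytest.approx(sw_oracle(a, b, m, 11.0, 1.0))


class TestBitScore:
    def test_worked_value(self, matrix):
        assert bit_score(100, matrix) == pytest.approx(43.13, abs=0.05)

    def test_intercept_at_zero(self, matrix):
        assert bit_score(0, matrix) == pytest.approx(-math.log(0.041) / math.log(2))

    def test_strictly_increasing(self, matrix):
        scores = [bit_score(raw, matrix) for raw in range(0, 200, 10)]
        assert all(x < y for x, y in zip(scores, scores[1:]))

    def test_missing_parameters_raise(self, matrix):
        import dataclasses

        broken = dataclasses.replace(matrix, lambda_=None)
        with pytest.raises(ConfigurationError):
            bit_score(10, broken)


class TestScoredistVariant:
    def test_identical_sequences_zero(self, matrix):
        d = scoredist_variant(500, 500, 500, 100, 100, matrix)
        assert d == 0.0

    def test_cap_when_sigma_n_nonpositive(self, matrix):
        d = scoredist_variant(-100, 500, 500, 100, 100, matrix)
        assert d == 300.0

    def test_half_ratio_closed_form(self, matrix):
        # choose raw so that sigma_n / sigma_u = 1/2 exactly
        per = matrix.expected_score()
        sigma_r = 100 * per
        sigma_u = 500 - sigma_r
        raw = sigma_r + sigma_u / 2
        d = scoredist_variant(raw, 500, 500, 100, 100, matrix)
        assert d == pytest.approx(100 * math.log(2), abs=1e-9)

    def test_degenerate_self_scores_raise(self, matrix):
        with pytest.raises(DegenerateInputError):
            scoredist_variant(0, -500, -500, 100, 100, matrix)

    def test_monotone_in_raw_score(self, matrix):
        distances = [
            scoredist_variant(raw, 500, 500, 100, 100, matrix)
            for raw in range(50, 500, 50)
        ]
        assert all(x >= y for x, y in zip(distances, distances[1:]))

    def test_expected_score_is_negative(self, matrix):
        assert matrix.expected_score() < 0


class TestAllVsAll:
    def test_identical_sequences_zero_distances(self, matrix):
        seqs = [rec(f"s{i}", "MKVLATTREWGG") for i in range(4)]
        bits, dist = all_vs_all(seqs, matrix)
        off = dist.values[~np.eye(4, dtype=bool)]
        assert (off == 0).all()
        assert np.allclose(bits, bits.T)

    def test_duplicate_ids_rejected(self, matrix):
        seqs = [rec("x", "MKVLAT"), rec("x", "MKVLAT")]
        with pytest.raises(InputError):
            all_vs_all(seqs, matrix)

    def test_planted_two_family_bimodal(self, matrix):
        from gtclan.simulate import ProteinFamilySpec, generate_protein_families

        data = generate_protein_families(
            ProteinFamilySpec(n_families=2, sequences_per_family=6, seed=4)
        )
        bits, _ = all_vs_all(data.records, matrix)
        ids = [r.id for r in data.records]
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                same = data.labels[ids[i]] == data.labels[ids[j]]
                (within if same else between).append(bits[i, j])
        assert min(within) > max(between)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(InputError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(InputError):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))

    def test_submatrix(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]]))
        sub = d.submatrix(["c", "a"])
        assert sub.ids == ["c", "a"]
        assert sub.values[0, 1] == 2


class TestCenterStarMsa:
    def test_identical_sequences_gap_free(self, matrix):
        msa = center_star_msa([rec(f"s{i}", "MKVLATT") for i in range(3)], matrix)
        assert all("-" not in row for row in msa.rows)
        assert msa.n_columns == 7

    def test_two_sequences(self, matrix):
        msa = center_star_msa([rec("a", "MKVLATT"), rec("b", "MKVATT")], matrix)
        assert len(msa.rows) == 2
        assert msa.rows[0].replace("-", "") == "MKVLATT"
        assert msa.rows[1].replace("-", "") == "MKVATT"
        assert msa.n_columns == 7

    def test_insertion_creates_gap_column(self, matrix):
        seqs = [
            rec("a", "MKVLATTREW"),
            rec("b", "MKVLATTREW"),
            rec("c", "MKVLAWWTTREW"),
        ]
        msa = center_star_msa(seqs, matrix)
        assert msa.n_columns == 12
        assert msa.rows[0].count("-") == 2
        assert msa.rows[2].count("-") == 0

    def test_row_order_preserved(self, matrix):
        seqs = [rec("z", "MKVLATT"), rec("a", "MKVLATT")]
        msa = center_star_msa(seqs, matrix)
        assert msa.ids == ["z", "a"]

    def test_single_sequence(self, matrix):
        msa = center_star_msa([rec("only", "MKVL")], matrix)
        assert msa.rows == ["MKVL"]


class TestMsa:
    def test_unequal_rows_rejected(self):
        with pytest.raises(InputError):
            Msa(["a", "b"], ["AC", "ACD"])
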