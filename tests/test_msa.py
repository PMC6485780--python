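import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxogen.msa import (DistanceMatrix, MsaWarning, MultipleAlignment,
                         PairCounts, count_pair, coverage_filter,
                         distance_matrix, k2p_distance, k2p_standard_error)


def _msa(rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return MultipleAlignment(taxa, rows)


def _related_rows(seed, n, length, rate=0.1):
    """Rows mutated from one template so no pair is saturated."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), length)
    rows = []
    for _ in range(n):
        row = base.copy()
        mask = rng.random(length) < rate
        row[mask] = rng.choice(list("ACGT"), int(mask.sum()))
        rows.append("".join(row))
    return rows


class TestCoverageFilter:
    def test_gap_free_unchanged(self):
        m = _msa(["ACGT", "ACGA", "ACGG"])
        assert coverage_filter(m).rows == m.rows

    def test_single_gap_column_removed_at_095(self):
        rows = ["ACGT"] * 9 + ["A-GT"]
        filtered = coverage_filter(_msa(rows), 0.95)
        assert filtered.length == 3
        assert filtered.rows[0] == "AGT"

    def test_matches_independent_per_column_recount(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list("ACGT-N"), 80)) for _ in range(12)]
        m = _msa(rows)
        filtered = coverage_filter(m, 0.8)
        kept = [c for c in range(80)
                if sum(r[c] in "ACGT" for r in rows) / 12 >= 0.8]
        assert filtered.rows == ["".join(r[c] for c in kept) for r in rows]

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACGT-"), 60)) for _ in range(10)]
        once = coverage_filter(_msa(rows), 0.9)
        twice = coverage_filter(once, 0.9)
        assert once.rows == twice.rows

    def test_all_columns_removed_is_error(self):
        with pytest.raises(ValueError, match="lower"):
            coverage_filter(_msa(["A-", "-A", "--"]), 0.95)


class TestCountPair:
    def test_identical_rows(self):
        pc = count_pair(_msa(["ACGT", "ACGT"]), "t0", "t1")
        assert (pc.P, pc.Q, pc.n_sites) == (0.0, 0.0, 4)

    def test_single_transition(self):
        pc = count_pair(_msa(["AAAA", "GAAA"]), "t0", "t1")
        assert (pc.P, pc.Q, pc.n_sites) == (0.25, 0.0, 4)

    def test_two_transversions(self):
        # columns 2 (C->A) and 4 (T->A) differ, both transversions
        pc = count_pair(_msa(["ACGT", "AAGA"]), "t0", "t1")
        assert (pc.P, pc.Q, pc.n_sites) == (0.0, 0.5, 4)

    def test_pairwise_deletion_skips_gaps_and_ambiguity(self):
        pc = count_pair(_msa(["A-GNT", "AAGCT"]), "t0", "t1")
        assert pc.n_sites == 3  # columns 1, 3, 5

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="no comparable"):
            count_pair(_msa(["--", "AA"]), "t0", "t1")


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance(PairCounts(0.0, 0.0, 10)) == 0.0

    def test_closed_form_value(self):
        # -1/2 ln(0.75 * sqrt(0.9))
        expected = -0.5 * math.log(0.75 * math.sqrt(0.9))
        assert k2p_distance(PairCounts(0.1, 0.05, 100)) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.1701812, abs=1e-7)

    def test_saturation_reported_as_infinity(self):
        with pytest.warns(MsaWarning, match="saturated"):
            assert math.isinf(k2p_distance(PairCounts(0.5, 0.0, 10)))

    @given(st.floats(0.0, 0.45), st.floats(0.0, 0.45))
    @settings(max_examples=200, derandomize=True)
    def test_k2p_at_least_p_distance(self, p, q):
        if 1 - 2 * p - q <= 1e-6 or 1 - 2 * q <= 1e-6:
            return
        assert k2p_distance(PairCounts(p, q, 100)) >= p + q - 1e-12

    def test_standard_error_shrinks_with_sites(self):
        assert k2p_standard_error(PairCounts(0.1, 0.05, 10000)) < \
            k2p_standard_error(PairCounts(0.1, 0.05, 100))


class TestDistanceMatrix:
    def test_identical_rows_all_zero(self):
        dm = distance_matrix(_msa(["ACGTACGT"] * 4))
        assert np.allclose(dm.values, 0.0)

    def test_matches_per_pair_recomputation(self):
        m = _msa(_related_rows(9, 5, 200))
        dm = distance_matrix(m, min_coverage=0.95)
        for i, ti in enumerate(m.taxa):
            for j, tj in enumerate(m.taxa):
                if i < j:
                    expected = k2p_distance(count_pair(m, ti, tj))
                    assert dm.values[i, j] == pytest.approx(expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        rows = _related_rows(10, 5, 150)
        taxa = [f"t{i}" for i in range(5)]
        dm = distance_matrix(_msa(rows, taxa))
        perm = [3, 1, 4, 0, 2]
        dmp = distance_matrix(_msa([rows[i] for i in perm],
                                   [taxa[i] for i in perm]))
        for a in taxa:
            for b in taxa:
                assert dm.get(a, b) == pytest.approx(dmp.get(a, b))

    def test_too_few_taxa_is_error(self):
        with pytest.raises(ValueError, match="3 taxa"):
            distance_matrix(_msa(["ACGT", "ACGT"]))

    def test_symmetric_zero_diagonal(self):
        dm = distance_matrix(_msa(_related_rows(11, 4, 100)))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)

    def test_tsv_roundtrip(self, tmp_path):
        dm = distance_matrix(_msa(_related_rows(12, 4, 100)))
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[1:] == dm.taxa
        assert len(lines) == 5
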