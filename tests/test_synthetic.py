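import math

import numpy as np
import pytest

from taxogen.msa import MultipleAlignment, PairCounts, count_pair, \
    k2p_distance, k2p_standard_error
from taxogen.seqio import Sequence, translate_cds
from taxogen.synthetic import (STOP_CODONS, evolve_k2p, expected_pq,
                               make_pair, simulate_ancestor,
                               two_clade_alignment)


class TestSimulateAncestor:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_ancestor(n_genes=30, seed=35)
        b = simulate_ancestor(n_genes=30, seed=35)
        assert [s.residues for s in a.scaffolds] == \
            [s.residues for s in b.scaffolds]
        assert a.genes == b.genes

    def test_gc_within_two_points_at_500kb(self):
        g = simulate_ancestor(n_genes=500, gene_len_mean=900,
                              intergenic_mean=120, gc=0.40, seed=36)
        total = sum(len(s) for s in g.scaffolds)
        assert total > 450_000
        gc = sum(s.residues.count("G") + s.residues.count("C")
                 for s in g.scaffolds) / total
        assert abs(100 * gc - 40.0) < 2.0

    def test_cds_structure(self):
        g = simulate_ancestor(n_genes=25, seed=37)
        for gid, cds in g.cds.items():
            assert cds.residues.startswith("ATG")
            assert cds.residues[-3:] in STOP_CODONS
            assert len(cds.residues) % 3 == 0
            prot = translate_cds(cds.residues)
            assert "*" not in prot
            assert g.proteins[gid].residues == prot

    def test_genes_do_not_overlap(self):
        g = simulate_ancestor(n_genes=40, seed=38)
        for scaf in g.scaffolds:
            spans = sorted((x.start, x.end) for x in g.genes
                           if x.scaffold_id == scaf.id)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_multiple_scaffolds(self):
        g = simulate_ancestor(n_genes=10, n_scaffolds=3, seed=39)
        assert len(g.scaffolds) == 3
        assert {x.scaffold_id for x in g.genes} == \
            {s.id for s in g.scaffolds}

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            simulate_ancestor(n_genes=0)
        with pytest.raises(ValueError):
            simulate_ancestor(n_genes=2, n_scaffolds=5)


class TestEvolveK2p:
    def test_zero_distance_identity(self):
        seq = "ACGTACGTAA"
        out, p, q = evolve_k2p(seq, 0.0, 2.0, seed=1)
        assert (out, p, q) == (seq, 0.0, 0.0)

    def test_realized_pq_match_analytic_expectation(self):
        rng = np.random.default_rng(40)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        d, kappa = 0.1, 2.0
        out, p_real, q_real = evolve_k2p(seq, d, kappa, seed=41)
        p_exp, q_exp = expected_pq(d, kappa)
        n = len(seq)
        assert abs(p_real - p_exp) < 4 * math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(q_real - q_exp) < 4 * math.sqrt(q_exp * (1 - q_exp) / n)
        # realized proportions equal observed difference proportions
        diff = sum(1 for x, y in zip(seq, out) if x != y)
        assert diff / n == pytest.approx(p_real + q_real)

    def test_k2p_estimator_recovery_within_3_se(self):
        rng = np.random.default_rng(42)
        anc = "".join(rng.choice(list("ACGT"), 100_000))
        a, _, _ = evolve_k2p(anc, 0.05, 2.0, seed=43)
        b, _, _ = evolve_k2p(anc, 0.05, 2.0, seed=44)
        msa = MultipleAlignment(["a", "b"], [a, b])
        pc = count_pair(msa, "a", "b")
        est = k2p_distance(pc)
        se = k2p_standard_error(pc)
        assert abs(est - 0.1) < 3 * se

    def test_non_acgt_left_untouched(self):
        out, _, _ = evolve_k2p("NNNN", 0.5, 2.0, seed=2)
        assert out == "NNNN"

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            evolve_k2p("ACGT", -0.1, 2.0)
        with pytest.raises(ValueError):
            evolve_k2p("ACGT", 0.1, 0.0)


class TestMakePair:
    def test_zero_distance_identical_genes(self, tiny_ancestor):
        ga, gb, truth = make_pair(tiny_ancestor, 0.0, seed=45)
        assert truth.mean_gene_identity == 1.0
        for gid in ga.cds:
            assert ga.cds[gid].residues == gb.cds[gid].residues

    def test_gene_loss_exact_count(self, small_ancestor):
        _, gb, truth = make_pair(small_ancestor, 0.05,
                                 gene_loss_fraction=0.1, seed=46)
        expected = int(round(0.1 * small_ancestor.n_genes))
        assert len(truth.deleted_genes) == expected
        assert len(gb.genes) == small_ancestor.n_genes - expected
        assert truth.deleted_genes <= {g.gene_id for g in small_ancestor.genes}

    def test_descendants_have_valid_annotations(self, tiny_ancestor):
        ga, gb, _ = make_pair(tiny_ancestor, 0.15, indel_rate=0.001, seed=47)
        for g in (ga, gb):
            for ann in g.genes:
                scaf = g.scaffold(ann.scaffold_id)
                from taxogen.seqio import extract_cds
                assert extract_cds(scaf, ann) == g.cds[ann.gene_id].residues
                assert "*" not in translate_cds(g.cds[ann.gene_id].residues)

    def test_truth_identity_matches_hamming(self, tiny_ancestor):
        ga, gb, truth = make_pair(tiny_ancestor, 0.1, seed=48)
        for gid, ident in truth.realized_gene_identity.items():
            ca, cb = ga.cds[gid].residues, gb.cds[gid].residues
            diff = sum(1 for x, y in zip(ca, cb) if x != y)
            assert ident == pytest.approx(1 - diff / len(ca))
            assert truth.realized_substitutions[gid] == diff

    def test_pure_function_of_seed(self, tiny_ancestor):
        r1 = make_pair(tiny_ancestor, 0.1, seed=49)
        r2 = make_pair(tiny_ancestor, 0.1, seed=49)
        assert [s.residues for s in r1[0].scaffolds] == \
            [s.residues for s in r2[0].scaffolds]
        assert r1[2].realized_gene_identity == r2[2].realized_gene_identity

    def test_truth_json_roundtrip(self, tmp_path, tiny_ancestor):
        import json
        _, _, truth = make_pair(tiny_ancestor, 0.1, gene_loss_fraction=0.2,
                                seed=50)
        path = tmp_path / "truth.json"
        truth.save(path)
        data = json.loads(path.read_text())
        assert set(data["deleted_genes"]) == truth.deleted_genes
        assert data["d_true"] == 0.1


class TestTwoCladeAlignment:
    def test_shape_and_determinism(self):
        m1 = two_clade_alignment(3, 300, 40, seed=51)
        m2 = two_clade_alignment(3, 300, 40, seed=51)
        assert m1.rows == m2.rows
        assert len(m1.taxa) == 6 and m1.length == 300

    def test_diagnostic_sites_separate_clades(self):
        m = two_clade_alignment(4, 400, 50, noise=0.0, seed=52)
        a_row, b_row = m.row("A1"), m.row("B1")
        diffs = sum(1 for x, y in zip(a_row, b_row) if x != y)
        assert diffs == 50
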