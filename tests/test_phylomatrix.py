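import math

import dendropy
import numpy as np
import pytest

from plastcomp.model import AlignmentMatrix, GeneFeature, PlastomeRecord
from plastcomp.phylomatrix import (
    DistanceUndefinedError,
    TaxonSetMismatchError,
    build_partition_schemes,
    concatenate,
    extract_shared_cds,
    nj_tree,
    pairwise_distances,
    scheme_sizes,
    to_nexus,
    to_phylip,
    to_raxml_partitions,
)

from conftest import random_dna


def _rec(name, genes, n=600, seed=0):
    rng = np.random.default_rng(seed)
    feats = [GeneFeature(g, "protein_coding", "+", [iv], pseudogene=p)
             for g, iv, p in genes]
    return PlastomeRecord(name, random_dna(rng, n), circular=True, features=feats)


class TestExtractSharedCds:
    def test_only_common_genes_survive(self):
        a = _rec("a", [("rbcL", (0, 30), False), ("matK", (60, 90), False)], seed=1)
        b = _rec("b", [("rbcL", (10, 40), False)], seed=2)
        shared, warnings = extract_shared_cds([a, b])
        assert set(shared) == {"rbcL"}
        assert set(shared["rbcL"]) == {"a", "b"}
        assert not warnings

    def test_pseudogene_excluded_from_shared_set(self):
        a = _rec("a", [("ycf1", (0, 30), False)], seed=1)
        b = _rec("b", [("ycf1", (0, 30), True)], seed=2)
        shared, _ = extract_shared_cds([a, b])
        assert "ycf1" not in shared

    def test_out_of_frame_gene_retained_with_warning(self):
        a = _rec("a", [("rps4", (0, 31), False)], seed=1)
        b = _rec("b", [("rps4", (0, 31), False)], seed=2)
        shared, warnings = extract_shared_cds([a, b])
        assert "rps4" in shared and len(warnings) == 2

    def test_ir_duplicated_gene_contributes_one_copy(self, default_truth):
        records = list(default_truth.records.values())
        shared, _ = extract_shared_cds(records)
        # the 13 non-pseudogene protein-coding genes, rpl2 once despite 2 copies
        assert "rpl2" in shared
        assert len(shared["rpl2"]) == len(records)

    def test_minus_strand_cds_is_strand_resolved(self, default_truth):
        shared, _ = extract_shared_cds(list(default_truth.records.values()))
        rec = default_truth.records["Nyssa"]
        f = rec.feature_by_name("ndhF")
        assert shared["ndhF"]["Nyssa"] == f.spliced(rec.sequence)


class TestConcatenate:
    def test_blocks_tile_in_lexicographic_order(self):
        alns = {
            "b": AlignmentMatrix(["x", "y"], ["A" * 600, "C" * 600]),
            "a": AlignmentMatrix(["x", "y"], ["G" * 300, "T" * 300]),
        }
        sm = concatenate(alns)
        assert sm.gene_blocks == [("a", 0, 300), ("b", 300, 900)]
        assert sm.n_columns == 900
        assert sm.alignment.row("x") == "G" * 300 + "A" * 600

    def test_single_gene_is_identity(self):
        aln = AlignmentMatrix(["x", "y"], ["ACGTAA", "ACGTAA"])
        sm = concatenate({"g": aln})
        assert sm.alignment.row("x") == "ACGTAA"
        assert sm.gene_blocks == [("g", 0, 6)]

    def test_taxon_set_mismatch_rejected(self):
        alns = {
            "a": AlignmentMatrix(["x", "y"], ["AAA", "CCC"]),
            "b": AlignmentMatrix(["x", "z"], ["AAA", "CCC"]),
        }
        with pytest.raises(TaxonSetMismatchError):
            concatenate(alns)

    def test_total_columns_equal_sum_of_parts(self, default_truth):
        from plastcomp.phylomatrix import extract_shared_cds

        shared, _ = extract_shared_cds(list(default_truth.records.values()))
        alns = {g: AlignmentMatrix.from_rows(sorted(s.items())) for g, s in shared.items()}
        sm = concatenate(alns)
        assert sm.n_columns == sum(a.n_columns for a in alns.values())


class TestPartitionSchemes:
    def _sm(self, widths):
        alns = {
            f"g{i:02d}": AlignmentMatrix(["x", "y"], ["A" * w, "C" * w])
            for i, w in enumerate(widths)
        }
        return concatenate(alns)

    def test_single_gene_scheme_sizes(self):
        sm = self._sm([300])
        assert scheme_sizes(build_partition_schemes(sm)) == {
            "S1": 1, "S2": 3, "S3": 1, "S4": 3}

    def test_scheme_sizes_scale_with_gene_count(self):
        k = 7
        sm = self._sm([30] * k)
        assert scheme_sizes(build_partition_schemes(sm)) == {
            "S1": 1, "S2": 3, "S3": k, "S4": 3 * k}

    def test_every_column_in_exactly_one_subset_per_scheme(self):
        sm = self._sm([30, 60, 90])
        for scheme in build_partition_schemes(sm).values():
            cols = sorted(c for cs in scheme.values() for c in cs)
            assert cols == list(range(sm.n_columns))

    def test_out_of_frame_gene_dropped_from_codon_schemes(self):
        sm = self._sm([30, 31])
        schemes = build_partition_schemes(sm)
        assert scheme_sizes(schemes)["S3"] == 2
        assert scheme_sizes(schemes)["S4"] == 3  # only the in-frame gene
        s2_cols = sum(len(v) for v in schemes["S2"].values())
        assert s2_cols == 30

    def test_codon_positions_interleave_by_offset(self):
        sm = self._sm([9])
        schemes = build_partition_schemes(sm)
        assert schemes["S2"]["pos1"] == [0, 3, 6]
        assert schemes["S2"]["pos2"] == [1, 4, 7]
        assert schemes["S2"]["pos3"] == [2, 5, 8]


class TestDistancesAndNJ:
    def test_jc69_reduces_to_p_distance_at_small_divergence(self):
        n = 1000
        a = "A" * n
        b = "C" + "A" * (n - 1)
        aln = AlignmentMatrix(["a", "b"], [a, b])
        p = pairwise_distances(aln, "p")[0, 1]
        jc = pairwise_distances(aln, "JC69")[0, 1]
        assert p == 0.001
        assert abs(jc - p) / p < 0.01

    def test_gap_and_n_sites_ignored(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGT-N", "ACGAAN"])
        # comparable sites: 4 (positions 0-3); one differs
        assert pairwise_distances(aln, "p")[0, 1] == 0.25

    def test_no_comparable_columns_is_undefined(self):
        aln = AlignmentMatrix(["a", "b"], ["A---", "-CGT"])
        with pytest.raises(DistanceUndefinedError):
            pairwise_distances(aln, "p")

    def test_three_taxon_tree_is_additive_in_the_input_distances(self):
        """For 3 taxa the unique unrooted tree is exactly additive: leaf-to-
        leaf path lengths reproduce the input distance triple, and the
        closed-form leaf branches (d_AB + d_AC - d_BC)/2 etc. are recovered
        as distances to the central vertex."""
        n = 100
        a = "A" * n
        b = "C" * 4 + "A" * 96  # d_ab = 0.04
        c = "G" * 4 + "T" * 6 + "A" * 90  # d_ac = 0.10, d_bc = 0.10
        aln = AlignmentMatrix(["A", "B", "C"], [a, b, c])
        tree = nj_tree(aln, distance="p")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        d = lambda x, y: pdm.patristic_distance(taxa[x], taxa[y])
        assert d("A", "B") == pytest.approx(0.04)
        assert d("A", "C") == pytest.approx(0.10)
        assert d("B", "C") == pytest.approx(0.10)
        # closed-form leaf branches from the three pairwise path lengths
        assert (d("A", "B") + d("A", "C") - d("B", "C")) / 2 == pytest.approx(0.02)
        assert (d("A", "C") + d("B", "C") - d("A", "B")) / 2 == pytest.approx(0.08)

    def test_additive_five_taxon_distances_reconstructed_exactly(self):
        """Sequences built so that every tree edge owns a disjoint block of
        substituted sites have exactly additive p-distances; NJ then returns
        the generating tree, verified by path-length additivity."""
        n = 1000
        # edge -> (sites, leaves below the edge); tree ((A,B),(C,D),E)
        edges = {
            "A": (range(0, 20), {"A"}),
            "B": (range(20, 50), {"B"}),
            "AB": (range(50, 65), {"A", "B"}),
            "C": (range(65, 105), {"C"}),
            "D": (range(105, 115), {"D"}),
            "CD": (range(115, 135), {"C", "D"}),
            "E": (range(135, 185), {"E"}),
        }
        labels = ["A", "B", "C", "D", "E"]
        rows = []
        for leaf in labels:
            seq = ["A"] * n
            for sites, below in edges.values():
                if leaf in below:
                    for i in sites:
                        seq[i] = "C"
            rows.append("".join(seq))
        aln = AlignmentMatrix(labels, rows)
        tree = nj_tree(aln, distance="p")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}

        def true_distance(x, y):
            total = 0
            for sites, below in edges.values():
                if (x in below) != (y in below):
                    total += len(sites)
            return total / n

        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(
                    true_distance(x, y), abs=1e-9)

    def test_recovers_simulated_topology(self, default_truth):
        from plastcomp.phylomatrix import extract_shared_cds

        shared, _ = extract_shared_cds(list(default_truth.records.values()))
        alns = {g: AlignmentMatrix.from_rows(sorted(s.items())) for g, s in shared.items()}
        tree = nj_tree(concatenate(alns))
        split = {"Nyssa", "Camptotheca"}
        found = any(
            {lf.taxon.label for lf in e.head_node.leaf_iter()} in (split,)
            or {lf.taxon.label for lf in e.head_node.leaf_iter()}
            == set(default_truth.records) - split
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        )
        assert found

    def test_invariant_under_taxon_input_order(self, default_truth):
        shared, _ = extract_shared_cds(list(default_truth.records.values()))
        alns_f = {g: AlignmentMatrix.from_rows(sorted(s.items())) for g, s in shared.items()}
        alns_r = {g: AlignmentMatrix.from_rows(sorted(s.items(), reverse=True))
                  for g, s in shared.items()}
        t1 = nj_tree(concatenate(alns_f))
        t2 = nj_tree(concatenate(alns_r))
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                              taxon_namespace=tns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                              taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0

    def test_fewer_than_three_taxa_rejected(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGT", "ACGA"])
        with pytest.raises(Exception):
            nj_tree(aln)


class TestWriters:
    def _sm(self):
        alns = {
            "psbA": AlignmentMatrix(["x", "y"], ["ACGACG", "ACGACT"]),
            "rbcL": AlignmentMatrix(["x", "y"], ["GGGTTT", "GGGTTA"]),
        }
        return concatenate(alns)

    def test_phylip_header_and_rows(self):
        sm = self._sm()
        text = to_phylip(sm)
        lines = text.strip().split("\n")
        assert lines[0].split() == ["2", "12"]
        assert lines[1].startswith("x") and lines[1].endswith("ACGACGGGGTTT")

    def test_raxml_partition_file_uses_codon_stride(self):
        sm = self._sm()
        schemes = build_partition_schemes(sm)
        text = to_raxml_partitions(sm, schemes["S4"])
        assert "DNA, psbA_pos1 = 1-4\\3" in text
        assert "DNA, rbcL_pos3 = 9-12\\3" in text

    def test_nexus_contains_matrix_and_charsets(self):
        sm = self._sm()
        schemes = build_partition_schemes(sm)
        text = to_nexus(sm, schemes["S3"])
        assert "#NEXUS" in text and "DIMENSIONS NTAX=2 NCHAR=12;" in text
        assert "CHARSET psbA = 1-6;" in text
        assert "CHARSET rbcL = 7-12;" in text
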