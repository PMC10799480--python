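"""Per-genome statistics, tree clustering and sequence QC."""

import itertools
import random
import statistics

import dendropy
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tefuse.fusion import annotate_te_status, classify_protein
from tefuse.model import GenomeMeta, ProteinRecord, TEDomainCatalogue
from tefuse.simulate import _pure_birth_tree
from tefuse.summarize import (
    clade_contrast,
    cluster_tree_leaves,
    domain_tally,
    gap_filter_alignment,
    map_fusions_on_tree,
    per_genome_stats,
    qc_protein_sequences,
    rip_join,
)

from conftest import make_hit

CAT = TEDomainCatalogue(te_accessions={"PF90001"})


def _meta(gid, clade="C1", n_genes=100, rip=None):
    return GenomeMeta(genome_id=gid, species=gid, phylum="P", clade=clade,
                      order="O1", n_genes=n_genes, rip_fraction=rip)


def _candidate(pid, gid):
    rec = ProteinRecord(protein_id=pid, genome_id=gid, hits=[
        make_hit(pid, gid, "PF90001", 1, 100),
        make_hit(pid, gid, "PF95001", 120, 220),
    ])
    return classify_protein(annotate_te_status(rec, CAT))


class TestPerGenomeStats:
    def test_fraction_and_zero_count_inclusion(self):
        cls = [_candidate(f"p{i}", "g1") for i in range(5)]
        summaries = per_genome_stats(cls, [_meta("g1"), _meta("g2")])
        assert summaries[0].n_fusion_proteins == 5
        assert summaries[0].fraction_of_genes == pytest.approx(0.05)
        assert summaries[1].n_fusion_proteins == 0

    def test_totals_conserved(self):
        cls = [_candidate(f"p{i}", f"g{i % 3 + 1}") for i in range(11)]
        summaries = per_genome_stats(cls, [_meta(f"g{i}") for i in range(1, 4)])
        assert sum(s.n_fusion_proteins for s in summaries) == 11

    def test_zero_genes_with_candidates_rejected(self):
        with pytest.raises(ValueError, match="0 genes"):
            per_genome_stats([_candidate("p1", "g1")], [_meta("g1", n_genes=0)])


class TestCladeContrast:
    def _summaries(self):
        cls = (
            [_candidate(f"a{i}", "g1") for i in range(2)]
            + [_candidate(f"b{i}", "g2") for i in range(4)]
            + [_candidate(f"c{i}", "g3") for i in range(1)]
            + [_candidate(f"d{i}", "g4") for i in range(3)]
        )
        taxonomy = [
            _meta("g1", clade="Sac"), _meta("g2", clade="Sac"),
            _meta("g3", clade="Pez"), _meta("g4", clade="Pez"),
        ]
        return per_genome_stats(cls, taxonomy)

    def test_means(self):
        c = clade_contrast(self._summaries(), "Sac")
        assert c.mean_in == pytest.approx(3.0)
        assert c.mean_out == pytest.approx(2.0)
        assert c.mean_fraction_in == pytest.approx(0.03)
        assert c.mean_fraction_out == pytest.approx(0.02)

    def test_degenerate_clades_rejected(self):
        summaries = self._summaries()
        with pytest.raises(ValueError):
            clade_contrast(summaries, "Nowhere")
        only_sac = [s for s in summaries if s.clade == "Sac"]
        with pytest.raises(ValueError, match="out-group"):
            clade_contrast(only_sac, "Sac")


class TestDomainTally:
    def test_counts_by_side(self):
        from tefuse.fusion import collect_fusion_orthogroups
        from tefuse.model import Orthogroup

        genomes = [f"g{i}" for i in range(1, 6)]
        cls = [_candidate(f"p{g}", g) for g in genomes]
        ogs = [
            Orthogroup("OG1", [(f"p{g}", g) for g in genomes[:3]]),
            Orthogroup("OG2", [(f"p{g}", g) for g in genomes[3:]]),
        ]
        fogs = collect_fusion_orthogroups(cls, ogs, [_meta(g) for g in genomes])
        te = domain_tally(fogs, "TE")
        host = domain_tally(fogs, "HOST")
        assert list(te) == ["PF90001"]
        assert te["PF90001"] == {"n_orthogroups": 2, "n_occurrences": 5}
        assert host["PF95001"]["n_occurrences"] == 5
        assert domain_tally([], "TE") == {}
        with pytest.raises(ValueError):
            domain_tally(fogs, "BOTH")


class TestRipJoin:
    def test_claim_logic(self):
        quiet = per_genome_stats([], [_meta("g1", rip=0.15), _meta("g2", rip=0.02)])
        _t, claim = rip_join(quiet)
        assert claim is True

        noisy = per_genome_stats(
            [_candidate(f"p{i}", "g1") for i in range(3)],
            [_meta("g1", rip=0.15)],
        )
        _t, claim = rip_join(noisy)
        assert claim is False

    def test_vacuous_when_no_genome_above_threshold(self):
        summaries = per_genome_stats(
            [_candidate("p1", "g1")], [_meta("g1", rip=0.05), _meta("g2")]
        )
        joined, claim = rip_join(summaries)
        assert claim is True
        assert {s.genome_id for s in joined} == {"g1"}  # unknown RIP left out


# --------------------------------------------------------------------------
# med_clade tree clustering
# --------------------------------------------------------------------------

def _independent_distances(tree):
    """Leaf-to-leaf path lengths via root paths and explicit LCA search."""
    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf] = d

    leaves = list(tree.leaf_node_iter())
    dist = {}
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = root_path(a), root_path(b)
        lca = next(x for x in pa if x in pb)
        d_lca, node = 0.0, lca
        while node.parent_node is not None:
            d_lca += node.edge.length or 0.0
            node = node.parent_node
        dist[frozenset((a.taxon.label, b.taxon.label))] = (
            depths[a] + depths[b] - 2 * d_lca
        )
    return dist


def brute_force_min_clade_partition(tree, threshold):
    """Minimum cluster count over ALL clade partitions, by enumeration."""
    dist = _independent_distances(tree)

    def feasible(node):
        labels = [lf.taxon.label for lf in node.leaf_iter()]
        if len(labels) < 2:
            return True
        vals = [dist[frozenset((a, b))] for a, b in itertools.combinations(labels, 2)]
        return statistics.median(vals) <= threshold

    def covers(node):
        if node.is_leaf():
            return [[node]]
        child_opts = [covers(c) for c in node.child_nodes()]
        merged = [
            list(itertools.chain.from_iterable(combo))
            for combo in itertools.product(*child_opts)
        ]
        return [[node]] + merged

    sizes = [
        len(cover)
        for cover in covers(tree.seed_node)
        if all(feasible(part) for part in cover)
    ]
    return min(sizes)


BALANCED4 = "((A:0.2,B:0.2):0.0,(C:0.2,D:0.2):0.0);"


class TestClusterTreeLeaves:
    def test_all_pairs_under_threshold_one_cluster(self):
        clustering = cluster_tree_leaves(BALANCED4, 1.0)
        assert clustering.n_clusters == 1

    def test_no_pair_admissible_all_singletons(self):
        clustering = cluster_tree_leaves(BALANCED4, 0.3)
        assert clustering.n_clusters == 4
        assert all(len(c) == 1 for c in clustering.clusters.values())

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cluster_tree_leaves("((A:0.2,B:-0.1):0.1,C:0.2);", 1.0)

    def test_matches_exhaustive_search(self):
        rng = random.Random(99)
        for i in range(50):
            n = rng.randint(6, 8)
            labels = [f"L{j}" for j in range(n)]
            tree = _pure_birth_tree(labels, random.Random(1000 + i))
            scale = rng.uniform(0.3, 2.0)
            for e in tree.preorder_edge_iter():
                if e.length:
                    e.length *= scale
            threshold = rng.uniform(0.2, 2.5)
            got = cluster_tree_leaves(tree, threshold)
            expect = brute_force_min_clade_partition(tree, threshold)
            assert got.n_clusters == expect, f"tree {i} threshold {threshold}"

    def test_monotone_in_threshold_and_clusters_are_clades(self):
        tree = _pure_birth_tree([f"L{j}" for j in range(12)], random.Random(5))
        prev = None
        for t in (1.0, 1.5, 2.0, 2.5):
            clustering = cluster_tree_leaves(tree, t)
            if prev is not None:
                assert clustering.n_clusters <= prev
            prev = clustering.n_clusters
            # every cluster is monophyletic: some node's exact leaf set
            clades = {
                frozenset(lf.taxon.label for lf in node.leaf_iter())
                for node in tree.preorder_node_iter()
            }
            assert set(clustering.clusters.values()) <= clades
        assert cluster_tree_leaves(tree, float("inf")).n_clusters == 1


class TestMapFusionsOnTree:
    def test_counts(self):
        tree = "((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3);"
        clustering = cluster_tree_leaves(tree, 0.5)  # {A,B} and {C,D}
        assert clustering.n_clusters == 2
        counts = map_fusions_on_tree(clustering, {"A", "B"})
        assert counts.n_fusion_bearing == 1
        assert map_fusions_on_tree(clustering, set()).n_fusion_bearing == 0
        every = map_fusions_on_tree(clustering, {"A", "B", "C", "D"})
        assert every.n_fusion_bearing == 2
        with pytest.raises(ValueError, match="not on tree"):
            map_fusions_on_tree(clustering, {"Z"})


# --------------------------------------------------------------------------
# sequence QC
# --------------------------------------------------------------------------

def _rec(rid, seq):
    return SeqRecord(Seq(seq), id=rid)


class TestSequenceQC:
    def test_qc_rules(self):
        kept = qc_protein_sequences([
            _rec("ok", "MKVLA"),
            _rec("no_met", "KVALA"),
            _rec("internal_stop", "MKV*LA"),
            _rec("terminal_stop", "MKVLA*"),
        ])
        assert [r.id for r in kept] == ["ok", "terminal_stop"]
        assert str(kept[1].seq) == "MKVLA"  # trailing * stripped

    def test_gap_filter_strict_boundary(self):
        rows = [
            _rec("r20", "MK--LAVILA"),  # 2/10 gaps: kept
            _rec("r30", "M---LAVILA"),  # 3/10 gaps: removed
        ]
        kept = gap_filter_alignment(rows, 0.20)
        assert [r.id for r in kept] == ["r20"]
        assert len(kept[0].seq) == 10  # columns untouched

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="length"):
            gap_filter_alignment([_rec("a", "MKVL"), _rec("b", "MKV")])
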