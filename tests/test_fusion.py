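"""Protein classification and orthogroup lift.

The overlap rule is checked against an explicit position-set oracle:
the overlap fraction of two 1-based inclusive intervals equals the size
of the intersection of their residue sets over the size of the smaller.
"""

import numpy as np
import pytest

from tefuse.fusion import (
    classify_protein,
    classify_proteins,
    collect_fusion_orthogroups,
    overlap_fraction,
)
from tefuse.model import (
    GenomeMeta,
    Orthogroup,
    PipelineConfig,
    ProteinLabel,
    ProteinRecord,
    TEDomainCatalogue,
    TEStatus,
)

from conftest import make_hit


def position_set_overlap(a, b):
    """Independent oracle: residue-set intersection over the shorter hit."""
    sa = set(range(a.env_start, a.env_end + 1))
    sb = set(range(b.env_start, b.env_end + 1))
    return len(sa & sb) / min(len(sa), len(sb))


CAT = TEDomainCatalogue(
    te_accessions={"PF90001", "PF90002"},
    excluded_accessions={"PF98001"},
)


def protein(hits):
    rec = ProteinRecord(protein_id=hits[0].protein_id, genome_id=hits[0].genome_id, hits=hits)
    from tefuse.fusion import annotate_te_status

    return annotate_te_status(rec, CAT)


class TestOverlapFraction:
    def test_five_percent_boundary(self):
        a = make_hit(start=1, end=100)
        b = make_hit(start=96, end=200)
        assert overlap_fraction(a, b) == pytest.approx(5 / 100)
        assert overlap_fraction(a, b) == pytest.approx(position_set_overlap(a, b))

    def test_disjoint_and_identical(self):
        assert overlap_fraction(make_hit(start=1, end=50), make_hit(start=60, end=100)) == 0.0
        assert overlap_fraction(make_hit(start=10, end=40), make_hit(start=10, end=40)) == 1.0

    def test_different_proteins_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(make_hit("p1"), make_hit("p2"))

    def test_agrees_with_position_set_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s1, s2 = rng.integers(1, 300, size=2)
            a = make_hit(start=int(s1), end=int(s1 + rng.integers(0, 150)))
            b = make_hit(start=int(s2), end=int(s2 + rng.integers(0, 150)))
            assert overlap_fraction(a, b) == pytest.approx(position_set_overlap(a, b))


class TestClassifyProtein:
    def test_boundary_overlap_is_candidate(self):
        # exactly 5% overlap is not "more than 5%"
        p = protein([
            make_hit(pfam_acc="PF90001", start=1, end=100),
            make_hit(pfam_acc="PF95001", start=96, end=200),
        ])
        c = classify_protein(p)
        assert c.label is ProteinLabel.FUSION_CANDIDATE
        assert c.max_pair_overlap_frac == pytest.approx(0.05)

    def test_large_overlap_removed(self):
        p = protein([
            make_hit(pfam_acc="PF90001", start=1, end=100),
            make_hit(pfam_acc="PF95001", start=50, end=150),
        ])
        c = classify_protein(p)
        assert c.label is ProteinLabel.REMOVED_OVERLAP
        assert c.max_pair_overlap_frac == pytest.approx(0.51)

    def test_te_only_and_no_te(self):
        assert classify_protein(protein([make_hit(pfam_acc="PF90001")])).label is ProteinLabel.TE_ONLY
        assert classify_protein(protein([make_hit(pfam_acc="PF95001")])).label is ProteinLabel.NO_TE

    def test_excluded_counts_for_neither_side(self):
        # TE + excluded: no host evidence left
        p = protein([
            make_hit(pfam_acc="PF90001", start=1, end=100),
            make_hit(pfam_acc="PF98001", start=150, end=250),
        ])
        assert classify_protein(p).label is ProteinLabel.TE_ONLY
        # excluded + host: no TE evidence left
        q = protein([
            make_hit(pfam_acc="PF98001", start=1, end=100),
            make_hit(pfam_acc="PF95001", start=150, end=250),
        ])
        assert classify_protein(q).label is ProteinLabel.NO_TE

    def test_partition_over_labels(self):
        rng = np.random.default_rng(3)
        accs = ["PF90001", "PF90002", "PF95001", "PF95002", "PF98001"]
        records = []
        for i in range(200):
            hits = []
            pos = 1
            for j in range(rng.integers(1, 5)):
                acc = accs[rng.integers(len(accs))]
                ln = int(rng.integers(30, 120))
                start = max(1, pos - int(rng.integers(0, 40)))
                hits.append(make_hit(f"p{i}", "g1", acc, start, start + ln))
                pos = start + ln + 5
            records.append(protein(hits))
        classes = [classify_protein(r) for r in records]
        assert len(classes) == len(records)
        from collections import Counter

        counts = Counter(c.label for c in classes)
        assert sum(counts.values()) == len(records)

    def test_overlap_threshold_monotone_and_extremes(self):
        p = protein([
            make_hit(pfam_acc="PF90001", start=1, end=100),
            make_hit(pfam_acc="PF95001", start=80, end=180),
        ])
        # overlap 21/100 = 0.21
        labels = [
            classify_protein(p, PipelineConfig(max_overlap_frac=f)).label
            for f in (0.0, 0.20, 0.21, 1.0)
        ]
        assert labels == [
            ProteinLabel.REMOVED_OVERLAP,
            ProteinLabel.REMOVED_OVERLAP,
            ProteinLabel.FUSION_CANDIDATE,  # boundary inclusive
            ProteinLabel.FUSION_CANDIDATE,
        ]


def test_gene_scope_is_stricter_than_pair_scope():
    """Under the whole-gene rule one bad pair removes the gene even when
    another TE/host pair is admissible; the pair scope keeps it.  This is
    also why only the pair scope is monotone in the score thresholds:
    dropping the low-scoring overlapping TE hit below rescues the gene."""
    hits = [
        make_hit("p", "g", "PF90001", 1, 100, bitscore=55),    # overlaps host
        make_hit("p", "g", "PF95001", 50, 150, bitscore=120),
        make_hit("p", "g", "PF90001", 300, 400, bitscore=120),  # clean TE copy
    ]
    p = protein(hits)
    assert classify_protein(p).label is ProteinLabel.REMOVED_OVERLAP
    assert classify_protein(
        p, PipelineConfig(overlap_scope="pair")
    ).label is ProteinLabel.FUSION_CANDIDATE
    # raising the score floor past 55 drops the offending hit: the gene
    # becomes a candidate under the strict scope too
    from tefuse.ingest import filter_domain_hits

    strict = PipelineConfig(min_bitscore=100)
    survivors = filter_domain_hits(hits, strict)
    q = protein(survivors)
    assert classify_protein(q, strict).label is ProteinLabel.FUSION_CANDIDATE


def _meta(gid, order="O1"):
    return GenomeMeta(genome_id=gid, species=gid, phylum="P", clade="C",
                      order=order, n_genes=100)


def _fusion_protein(pid, gid):
    return protein([
        make_hit(pid, gid, "PF90001", 1, 100),
        make_hit(pid, gid, "PF95001", 120, 220),
    ])


class TestCollectFusionOrthogroups:
    def test_five_genomes_reach_min5(self):
        genomes = [f"g{i}" for i in range(1, 6)]
        cls = [classify_protein(_fusion_protein(f"p{g}", g)) for g in genomes]
        ogs = [Orthogroup("OG1", [(f"p{g}", g) for g in genomes])]
        (fog,) = collect_fusion_orthogroups(cls, ogs, [_meta(g) for g in genomes])
        assert fog.n_genomes == 5
        assert fog.tier.name == "MIN5"
        assert fog.anchor_te_acc == "PF90001" and fog.anchor_host_acc == "PF95001"

    def test_paralogs_count_single_genome(self):
        # 5 proteins but only 4 distinct genomes: stays RAW
        pairs = [("pa", "g1"), ("pb", "g1"), ("pc", "g2"), ("pd", "g3"), ("pe", "g4")]
        cls = [classify_protein(_fusion_protein(p, g)) for p, g in pairs]
        ogs = [Orthogroup("OG1", pairs)]
        (fog,) = collect_fusion_orthogroups(cls, ogs, [_meta(f"g{i}") for i in range(1, 5)])
        assert fog.n_genomes == 4
        assert fog.tier.name == "RAW"

    def test_no_candidates_yields_empty(self):
        cls = [classify_protein(protein([make_hit("p1", "g1", "PF95001")]))]
        assert collect_fusion_orthogroups(cls, [], [_meta("g1")]) == []

    def test_missing_taxonomy_rejected(self):
        cls = [classify_protein(_fusion_protein("p1", "gX"))]
        with pytest.raises(ValueError, match="gX"):
            collect_fusion_orthogroups(cls, [], [_meta("g1")])

    def test_invariant_to_hit_and_genome_order(self):
        genomes = [f"g{i}" for i in range(1, 7)]
        recs = []
        for g in genomes:
            hits = [
                make_hit(f"p{g}", g, "PF95001", 120, 220),
                make_hit(f"p{g}", g, "PF90001", 1, 100),
            ]
            recs.append(ProteinRecord(protein_id=f"p{g}", genome_id=g, hits=hits))
        cls_fwd = classify_proteins(recs, CAT)
        cls_rev = classify_proteins(list(reversed(recs)), CAT)
        ogs = [Orthogroup("OG1", [(f"p{g}", g) for g in genomes])]
        metas = [_meta(g) for g in genomes]
        fog_fwd = collect_fusion_orthogroups(cls_fwd, ogs, metas)[0]
        fog_rev = collect_fusion_orthogroups(cls_rev, list(ogs), list(reversed(metas)))[0]
        assert {m.protein_id for m in fog_fwd.fusion_members} == {
            m.protein_id for m in fog_rev.fusion_members
        }
        assert fog_fwd.tier == fog_rev.tier

    def test_strict_anchor_mode_blocks_unshared_architectures(self):
        genomes = [f"g{i}" for i in range(1, 6)]
        cls = []
        for i, g in enumerate(genomes):
            te = "PF90001" if i % 2 == 0 else "PF90002"
            cls.append(classify_protein(protein([
                make_hit(f"p{g}", g, te, 1, 100),
                make_hit(f"p{g}", g, "PF95001", 120, 220),
            ])))
        ogs = [Orthogroup("OG1", [(f"p{g}", g) for g in genomes])]
        metas = [_meta(g) for g in genomes]
        (strict,) = collect_fusion_orthogroups(cls, ogs, metas)
        assert strict.tier.name == "RAW"  # no TE accession shared by all
        (relaxed,) = collect_fusion_orthogroups(
            cls, ogs, metas, PipelineConfig(anchor_mode="any")
        )
        assert relaxed.tier.name == "MIN5"
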