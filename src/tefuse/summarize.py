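"""Descriptive surfaces over the fusion-candidate sets.

Per-genome counts and gene fractions, clade contrasts (e.g. the
Saccharomycotina versus all other genomes), TE/host domain tallies, the
join against repeat-induced-point-mutation (RIP) coverage estimates, and
the distribution of fusion candidates over a protein phylogeny clustered
with the median-pairwise-distance clade criterion (med_clade).

Sequence utilities used ahead of external alignment/tree inference — start
methionine / in-frame stop QC and the post-trimming gap filter — live here
as well.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import dendropy
from Bio.SeqRecord import SeqRecord

from .fusion import FusionOrthogroup, ProteinClassification
from .model import GenomeMeta, ProteinLabel


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    n_fusion_proteins: int
    fraction_of_genes: float
    clade: str
    order: str
    rip_fraction: Optional[float] = None


def per_genome_stats(
    classifications: Iterable[ProteinClassification],
    taxonomy: list[GenomeMeta],
) -> list[GenomeSummary]:
    """Fusion-candidate count and gene fraction per genome.

    Genomes without any candidate are included with count 0; the counts
    over all genomes sum to the number of FUSION_CANDIDATE records.
    """
    counts: dict[str, int] = defaultdict(int)
    for c in classifications:
        if c.label is ProteinLabel.FUSION_CANDIDATE:
            counts[c.genome_id] += 1
    known = {m.genome_id for m in taxonomy}
    stray = set(counts) - known
    if stray:
        raise ValueError(f"candidate genomes missing from taxonomy: {sorted(stray)[:5]}")

    out: list[GenomeSummary] = []
    for m in taxonomy:
        n = counts.get(m.genome_id, 0)
        if m.n_genes == 0:
            if n > 0:
                raise ValueError(
                    f"genome {m.genome_id} reports 0 genes but {n} fusion candidates"
                )
            frac = 0.0
        else:
            frac = n / m.n_genes
        out.append(
            GenomeSummary(
                genome_id=m.genome_id,
                n_fusion_proteins=n,
                fraction_of_genes=frac,
                clade=m.clade,
                order=m.order,
                rip_fraction=m.rip_fraction,
            )
        )
    return out


@dataclass(frozen=True)
class CladeContrast:
    clade: str
    mean_in: float
    mean_out: float
    mean_fraction_in: float
    mean_fraction_out: float


def clade_contrast(summaries: list[GenomeSummary], clade_label: str) -> CladeContrast:
    """Arithmetic means of counts and gene fractions inside vs outside a clade."""
    inside = [s for s in summaries if s.clade == clade_label]
    outside = [s for s in summaries if s.clade != clade_label]
    if not inside:
        raise ValueError(f"no genome belongs to clade {clade_label!r}")
    if not outside:
        raise ValueError(f"every genome belongs to clade {clade_label!r}; no out-group")
    return CladeContrast(
        clade=clade_label,
        mean_in=statistics.fmean(s.n_fusion_proteins for s in inside),
        mean_out=statistics.fmean(s.n_fusion_proteins for s in outside),
        mean_fraction_in=statistics.fmean(s.fraction_of_genes for s in inside),
        mean_fraction_out=statistics.fmean(s.fraction_of_genes for s in outside),
    )


def domain_tally(
    fogs: list[FusionOrthogroup], side: str
) -> dict[str, dict[str, int]]:
    """Per-accession orthogroup and occurrence counts on one side.

    ``side`` is ``"TE"`` or ``"HOST"``; occurrences count (member,
    accession) pairs over fusion members.
    """
    if side not in ("TE", "HOST"):
        raise ValueError(f"side must be 'TE' or 'HOST', got {side!r}")
    ogs_per_acc: dict[str, set[str]] = defaultdict(set)
    occurrences: dict[str, int] = defaultdict(int)
    for fog in fogs:
        for m in fog.fusion_members:
            accs = m.te_accessions if side == "TE" else m.host_accessions
            for acc in accs:
                ogs_per_acc[acc].add(fog.og_id)
                occurrences[acc] += 1
    return {
        acc: {"n_orthogroups": len(ogs_per_acc[acc]), "n_occurrences": occurrences[acc]}
        for acc in sorted(ogs_per_acc)
    }


def rip_join(
    summaries: list[GenomeSummary], min_rip_for_zero_claim: float = 0.10
) -> tuple[list[GenomeSummary], bool]:
    """Join fusion counts with RIP coverage and check the zero-fusion claim.

    Returns the genomes with known RIP fraction and a boolean that is true
    iff every genome with RIP coverage above the threshold has zero fusion
    candidates (vacuously true when no genome is above it).
    """
    joined = [s for s in summaries if s.rip_fraction is not None]
    claim = all(
        s.n_fusion_proteins == 0
        for s in joined
        if s.rip_fraction > min_rip_for_zero_claim
    )
    return joined, claim


# --------------------------------------------------------------------------
# tree clustering (med_clade)
# --------------------------------------------------------------------------

@dataclass
class LeafClustering:
    threshold: float
    assignment: dict[str, int]
    n_clusters: int
    #: leaf label sets per cluster id, each a clade of the input tree
    clusters: dict[int, frozenset[str]] = field(default_factory=dict)


TreeLike = Union[dendropy.Tree, str]


def _as_tree(tree: TreeLike) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    data = str(tree)
    if "(" not in data:  # a path, not newick text
        return dendropy.Tree.get(path=data, schema="newick")
    return dendropy.Tree.get(data=data, schema="newick")


def _leaf_distances(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    dist: dict[frozenset[str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            dist[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return dist


def _median_pairwise(leaves: Sequence[str], dist: dict[frozenset[str], float]) -> float:
    if len(leaves) < 2:
        return 0.0
    vals = [
        dist[frozenset((a, b))]
        for i, a in enumerate(leaves)
        for b in leaves[i + 1:]
    ]
    return statistics.median(vals)


def cluster_tree_leaves(tree: TreeLike, threshold: float) -> LeafClustering:
    """Partition tree leaves into the minimum number of clades whose median
    pairwise patristic distance is at most ``threshold``.

    Exact minimisation by dynamic programming over the rooted tree: a node
    either forms one cluster (when its clade satisfies the constraint) or
    delegates to its children — the optimal clade partition restricted to a
    subtree decomposes over the children, so the recursion is optimal.
    Singleton clusters always satisfy the constraint.  Where the cost is
    tied the deeper decomposition is never preferred, so the left-most
    admissible clade in post-order wins.
    """
    t = _as_tree(tree)
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    dist = _leaf_distances(t)

    best_cut: dict[object, list] = {}  # node -> list of chosen clade nodes
    for node in t.postorder_node_iter():
        if node.is_leaf():
            best_cut[node] = [node]
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if _median_pairwise(leaves, dist) <= threshold:
            best_cut[node] = [node]
        else:
            cut: list = []
            for child in node.child_nodes():
                cut.extend(best_cut[child])
            best_cut[node] = cut

    assignment: dict[str, int] = {}
    clusters: dict[int, frozenset[str]] = {}
    for cid, node in enumerate(best_cut[t.seed_node]):
        labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clusters[cid] = labels
        for lab in labels:
            assignment[lab] = cid
    return LeafClustering(
        threshold=threshold,
        assignment=assignment,
        n_clusters=len(clusters),
        clusters=clusters,
    )


@dataclass(frozen=True)
class ClusterFusionCounts:
    per_cluster: dict[int, dict[str, float]]
    n_fusion_bearing: int


def map_fusions_on_tree(
    clustering: LeafClustering, fusion_leaf_labels: set[str]
) -> ClusterFusionCounts:
    """Count fusion-bearing leaves per tree cluster."""
    unknown = fusion_leaf_labels - set(clustering.assignment)
    if unknown:
        raise ValueError(f"fusion labels not on tree: {sorted(unknown)[:5]}")
    per_cluster: dict[int, dict[str, float]] = {}
    bearing = 0
    for cid, labels in sorted(clustering.clusters.items()):
        n_fusion = len(labels & fusion_leaf_labels)
        bearing += n_fusion > 0
        per_cluster[cid] = {
            "n_leaves": len(labels),
            "n_fusion": n_fusion,
            "fraction": n_fusion / len(labels),
        }
    return ClusterFusionCounts(per_cluster=per_cluster, n_fusion_bearing=bearing)


# --------------------------------------------------------------------------
# sequence QC for external alignment / tree steps
# --------------------------------------------------------------------------

def qc_protein_sequences(seqs: Iterable[SeqRecord]) -> list[SeqRecord]:
    """Keep sequences starting with methionine and free of in-frame stops.

    A single terminal ``*`` is a translation artifact and is stripped
    rather than disqualifying the sequence.
    """
    kept: list[SeqRecord] = []
    for rec in seqs:
        s = str(rec.seq)
        if s.endswith("*"):
            s = s[:-1]
            rec = rec[: len(s)]
        if not s.startswith("M"):
            continue
        if "*" in s:
            continue
        kept.append(rec)
    return kept


def gap_filter_alignment(
    aln: Sequence[SeqRecord], max_gap_frac: float = 0.20
) -> list[SeqRecord]:
    """Drop alignment rows with strictly more than ``max_gap_frac`` gaps.

    Column count is never changed; a row at exactly the bound is kept.
    """
    rows = list(aln)
    if not rows:
        return []
    width = len(rows[0].seq)
    for rec in rows:
        if len(rec.seq) != width:
            raise ValueError(
                f"alignment row {rec.id} has length {len(rec.seq)}, expected {width}"
            )
    return [
        rec for rec in rows if str(rec.seq).count("-") / width <= max_gap_frac
    ]


def write_genome_summary_table(summaries: list[GenomeSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tn_fusion_proteins\tfraction_of_genes\tclade\torder\trip_fraction\n")
        for s in summaries:
            rip = "" if s.rip_fraction is None else f"{s.rip_fraction:g}"
            fh.write(
                f"{s.genome_id}\t{s.n_fusion_proteins}\t{s.fraction_of_genes:.6g}\t"
                f"{s.clade}\t{s.order}\t{rip}\n"
            )
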