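"""Detection of host-TE fusion candidates.

A protein qualifies as a fusion candidate when, after score filtering and
annotation against the TE catalogue, it carries at least one TE-associated
Pfam domain and at least one host (non-TE, non-excluded) domain, and no
(TE, host) domain pair overlaps by strictly more than 5% of the shorter
domain — large overlaps usually mean the two annotations describe the same
physical domain.  Candidates are then lifted to orthogroup level and
counted over distinct genomes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    DomainHit,
    GenomeMeta,
    Orthogroup,
    PipelineConfig,
    ProteinLabel,
    ProteinRecord,
    TEDomainCatalogue,
    TEStatus,
    Tier,
)


@dataclass
class ProteinClassification:
    protein_id: str
    genome_id: str
    label: ProteinLabel
    te_hits: list[DomainHit] = field(default_factory=list)
    host_hits: list[DomainHit] = field(default_factory=list)
    max_pair_overlap_frac: float = 0.0

    @property
    def te_accessions(self) -> set[str]:
        return {h.pfam_acc for h in self.te_hits}

    @property
    def host_accessions(self) -> set[str]:
        return {h.pfam_acc for h in self.host_hits}


@dataclass
class FusionOrthogroup:
    """An orthogroup-level fusion candidate with its conservation tier.

    ``anchor_te_accs`` / ``anchor_host_accs`` are the accessions shared by
    every fusion member (the architecture consistently found across all
    orthologs); the single anchor reported downstream is the
    lexicographically smallest of each set.
    """

    og_id: str
    fusion_members: list[ProteinClassification]
    n_genomes: int
    genomes_per_order: dict[str, int]
    tier: Tier = Tier.RAW
    flags: set[str] = field(default_factory=set)
    anchor_te_accs: frozenset[str] = frozenset()
    anchor_host_accs: frozenset[str] = frozenset()

    @property
    def anchor_te_acc(self) -> Optional[str]:
        return min(self.anchor_te_accs) if self.anchor_te_accs else None

    @property
    def anchor_host_acc(self) -> Optional[str]:
        return min(self.anchor_host_accs) if self.anchor_host_accs else None

    @property
    def member_genomes(self) -> set[str]:
        return {m.genome_id for m in self.fusion_members}


def annotate_te_status(
    protein: ProteinRecord, catalogue: TEDomainCatalogue
) -> ProteinRecord:
    """Set each hit's TE status from the catalogue.

    Excluded accessions (host families with profile similarity to TE
    families) count as neither TE nor host evidence downstream.
    """
    return ProteinRecord(
        protein_id=protein.protein_id,
        genome_id=protein.genome_id,
        length=protein.length,
        hits=[h.with_status(catalogue.status_of(h.pfam_acc)) for h in protein.hits],
    )


def overlap_fraction(
    a: DomainHit, b: DomainHit, denominator: str = "shorter"
) -> float:
    """Fraction of amino-acid positions shared by two hits on one protein.

    Coordinates are 1-based inclusive; the denominator is the length of the
    shorter hit by default, so a domain fully nested in a larger one always
    scores 1.0.  Disjoint hits score 0.0.
    """
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"hits on different proteins: {a.protein_id!r} vs {b.protein_id!r}"
        )
    shared = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
    if shared <= 0:
        return 0.0
    if denominator == "shorter":
        denom = min(a.length, b.length)
    elif denominator == "longer":
        denom = max(a.length, b.length)
    else:  # "protein": span of both hits as a proxy when length is unknown
        denom = max(a.env_end, b.env_end) - min(a.env_start, b.env_start) + 1
    return shared / denom


def classify_protein(
    protein: ProteinRecord, config: Optional[PipelineConfig] = None
) -> ProteinClassification:
    """Label a protein from its annotated domain hits.

    NO_TE            no TE-associated hit
    TE_ONLY          TE hits but no host hit (pure TE protein/pseudogene)
    REMOVED_OVERLAP  overlapping TE/host annotation per the overlap scope
    FUSION_CANDIDATE TE and host hits with an admissible pairing

    Under the default ``"gene"`` overlap scope the protein is removed as
    soon as any (TE, host) pair overlaps by more than ``max_overlap_frac``
    — the strict reading of the rule.  Under the ``"pair"`` scope one
    admissible pair suffices, which makes the candidate set monotone in
    the score-filter thresholds (dropping a low-scoring overlapping hit
    can never rescue a gene that a surviving pair already qualifies).
    """
    config = config or PipelineConfig()
    te_hits = [h for h in protein.hits if h.te_status is TEStatus.TE]
    host_hits = [h for h in protein.hits if h.te_status is TEStatus.HOST]
    if any(h.te_status is TEStatus.UNASSIGNED for h in protein.hits):
        raise ValueError(f"protein {protein.protein_id} has unannotated hits")

    base = dict(protein_id=protein.protein_id, genome_id=protein.genome_id,
                te_hits=te_hits, host_hits=host_hits)
    if not te_hits:
        return ProteinClassification(label=ProteinLabel.NO_TE, **base)
    if not host_hits:
        return ProteinClassification(label=ProteinLabel.TE_ONLY, **base)
    fracs = [
        overlap_fraction(t, h, config.overlap_denominator)
        for t in te_hits
        for h in host_hits
    ]
    max_frac = max(fracs)
    if config.overlap_scope == "gene":
        ok = max_frac <= config.max_overlap_frac
    else:
        ok = min(fracs) <= config.max_overlap_frac
    label = ProteinLabel.FUSION_CANDIDATE if ok else ProteinLabel.REMOVED_OVERLAP
    return ProteinClassification(label=label, max_pair_overlap_frac=max_frac, **base)


def classify_proteins(
    proteins: list[ProteinRecord],
    catalogue: TEDomainCatalogue,
    config: Optional[PipelineConfig] = None,
) -> list[ProteinClassification]:
    """Annotate and classify a whole proteome set."""
    config = config or PipelineConfig()
    return [
        classify_protein(annotate_te_status(p, catalogue), config) for p in proteins
    ]


def _shared_accessions(
    members: list[ProteinClassification],
) -> tuple[frozenset[str], frozenset[str]]:
    te = set(members[0].te_accessions)
    host = set(members[0].host_accessions)
    for m in members[1:]:
        te &= m.te_accessions
        host &= m.host_accessions
    return frozenset(te), frozenset(host)


def collect_fusion_orthogroups(
    classifications: list[ProteinClassification],
    orthogroups: list[Orthogroup],
    taxonomy: list[GenomeMeta],
    config: Optional[PipelineConfig] = None,
) -> list[FusionOrthogroup]:
    """Lift fusion candidates to orthogroup level.

    One :class:`FusionOrthogroup` is produced per orthogroup containing at
    least one FUSION_CANDIDATE protein; proteins missing from every
    orthogroup count as singletons.  Genomes are counted as distinct
    genome ids.  Tier MIN5 requires >= ``min_genomes_og`` genomes and — in
    strict anchor mode — at least one TE and one host accession shared by
    all fusion members.
    """
    config = config or PipelineConfig()
    meta_by_genome = {m.genome_id: m for m in taxonomy}

    owner: dict[str, str] = {}
    for og in orthogroups:
        for pid, _gid in og.members:
            owner[pid] = og.og_id

    by_og: dict[str, list[ProteinClassification]] = defaultdict(list)
    for c in classifications:
        if c.label is not ProteinLabel.FUSION_CANDIDATE:
            continue
        og_id = owner.get(c.protein_id, f"singleton:{c.protein_id}")
        by_og[og_id].append(c)

    fogs: list[FusionOrthogroup] = []
    for og_id in sorted(by_og):
        members = sorted(by_og[og_id], key=lambda c: (c.genome_id, c.protein_id))
        genomes = {m.genome_id for m in members}
        per_order: dict[str, int] = defaultdict(int)
        for gid in genomes:
            meta = meta_by_genome.get(gid)
            if meta is None:
                raise ValueError(
                    f"genome {gid!r} of fusion member in {og_id!r} missing from taxonomy"
                )
            per_order[meta.order] += 1
        anchor_te, anchor_host = _shared_accessions(members)
        anchored = bool(anchor_te) and bool(anchor_host)
        tier = Tier.RAW
        if len(genomes) >= config.min_genomes_og and (
            config.anchor_mode == "any" or anchored
        ):
            tier = Tier.MIN5
        fogs.append(
            FusionOrthogroup(
                og_id=og_id,
                fusion_members=members,
                n_genomes=len(genomes),
                genomes_per_order=dict(per_order),
                tier=tier,
                anchor_te_accs=anchor_te,
                anchor_host_accs=anchor_host,
            )
        )
    return fogs


def write_candidate_table(
    classifications: list[ProteinClassification],
    fogs: list[FusionOrthogroup],
    path,
) -> None:
    """TSV of per-protein classifications with orthogroup tier context."""
    og_of: dict[str, tuple[str, Tier]] = {}
    for fog in fogs:
        for m in fog.fusion_members:
            og_of[m.protein_id] = (fog.og_id, fog.tier)
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tgenome_id\tog_id\tlabel\tte_accs\thost_accs\t"
            "max_pair_overlap_frac\ttier\n"
        )
        for c in classifications:
            og_id, tier = og_of.get(c.protein_id, ("", None))
            fh.write(
                f"{c.protein_id}\t{c.genome_id}\t{og_id}\t{c.label.value}\t"
                f"{','.join(sorted(c.te_accessions))}\t"
                f"{','.join(sorted(c.host_accessions))}\t"
                f"{c.max_pair_overlap_frac:.6g}\t{tier.name if tier else ''}\n"
            )
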