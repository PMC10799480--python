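"""Deep-conservation, domain-order, gene-cluster and curation filters.

Fusion orthogroups that pass the initial >= 5 genome screen are refined in
four independent steps:

1. *conservation*: promotion to CONSERVED20 requires presence in at least
   20 genomes, at least 5 of which belong to the same taxonomic order —
   this guards against recent, lineage-specific TE insertion events;
2. *domain order*: the relative order of the anchor TE and host domains
   along the protein must agree across all fusion members;
3. *gene clusters*: members inside predicted secondary-metabolite gene
   clusters are removed, since physical proximity of clustered genes can
   mimic a fusion signal;
4. *curation*: promotion to CURATED requires the anchor TE accession to be
   unambiguously TE-derived and the anchor host accession unambiguously of
   host origin, per the curation catalogue.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Optional

from .fusion import FusionOrthogroup, ProteinClassification, _shared_accessions
from .model import (
    CLUSTER_EXCLUDED,
    ORDER_NOT_CONSERVED,
    CurationTier,
    DomainHit,
    GenomeMeta,
    PipelineConfig,
    TEDomainCatalogue,
    Tier,
    sort_hits,
)


@dataclass(frozen=True)
class DomainOrderSignature:
    """Ordered tuple of Pfam accessions along one protein."""

    protein_id: str
    signature: tuple[str, ...]


def domain_order_signature(
    protein_id: str,
    hits: Iterable[DomainHit],
    restrict_to: Optional[set[str]] = None,
) -> DomainOrderSignature:
    """Accessions sorted by env_start (ties by env_end, then accession)."""
    selected = [h for h in hits if restrict_to is None or h.pfam_acc in restrict_to]
    return DomainOrderSignature(
        protein_id=protein_id,
        signature=tuple(h.pfam_acc for h in sort_hits(selected)),
    )


def _copy_fog(fog: FusionOrthogroup, **changes) -> FusionOrthogroup:
    changes.setdefault("flags", set(fog.flags))
    return dc_replace(fog, **changes)


# --------------------------------------------------------------------------
# 1. deep conservation
# --------------------------------------------------------------------------

def apply_conservation_filter(
    fogs: list[FusionOrthogroup],
    taxonomy: list[GenomeMeta],
    config: Optional[PipelineConfig] = None,
) -> list[FusionOrthogroup]:
    """Promote MIN5 orthogroups meeting the deep-conservation bounds.

    Both bounds are inclusive: exactly 20 genomes with exactly 5 in one
    order is promoted.
    """
    config = config or PipelineConfig()
    out: list[FusionOrthogroup] = []
    for fog in fogs:
        if fog.tier >= Tier.MIN5:
            if "" in fog.genomes_per_order:
                raise ValueError(
                    f"orthogroup {fog.og_id} has members with an empty order field"
                )
            max_same_order = max(fog.genomes_per_order.values(), default=0)
            if (
                fog.n_genomes >= config.min_genomes_conserved
                and max_same_order >= config.min_genomes_same_order
                and fog.tier < Tier.CONSERVED20
            ):
                fog = _copy_fog(fog, tier=Tier.CONSERVED20)
        out.append(fog)
    return out


# --------------------------------------------------------------------------
# 2. domain order
# --------------------------------------------------------------------------

def _pair_orderings(member: ProteinClassification, te_acc: str, host_acc: str) -> set[str]:
    """Relative orderings realised by (te_acc, host_acc) hit pairs in one
    member: "TH" (TE first), "HT" (host first).  A member with TE copies
    straddling the host anchor realises both and is internally
    inconsistent."""
    orderings: set[str] = set()
    te_keys = [(h.env_start, h.env_end) for h in member.te_hits if h.pfam_acc == te_acc]
    host_keys = [(h.env_start, h.env_end) for h in member.host_hits if h.pfam_acc == host_acc]
    for tk in te_keys:
        for hk in host_keys:
            if tk == hk:
                orderings |= {"TH", "HT"}
            elif tk < hk:
                orderings.add("TH")
            else:
                orderings.add("HT")
    return orderings


def check_domain_order(
    fog: FusionOrthogroup, config: Optional[PipelineConfig] = None
) -> FusionOrthogroup:
    """Set or clear the ORDER_NOT_CONSERVED flag on one orthogroup.

    Under the default "unanimity" strictness every fusion member must
    realise the same single ordering for every (anchor TE, anchor host)
    accession pair; "majority" tolerates a consistent minority below 50%.
    Orthogroups without shared anchors have nothing to test and are left
    unflagged.
    """
    config = config or PipelineConfig()
    flags = set(fog.flags) - {ORDER_NOT_CONSERVED}
    conserved = True
    for te_acc in sorted(fog.anchor_te_accs):
        for host_acc in sorted(fog.anchor_host_accs):
            per_member = [_pair_orderings(m, te_acc, host_acc) for m in fog.fusion_members]
            per_member = [o for o in per_member if o]
            if not per_member:
                continue
            if config.order_strictness == "unanimity":
                union = set().union(*per_member)
                if len(union) != 1:
                    conserved = False
            else:  # majority
                votes = Counter(
                    next(iter(o)) for o in per_member if len(o) == 1
                )
                top = votes.most_common(1)[0][1] if votes else 0
                if top / len(per_member) < 0.5:
                    conserved = False
    if not conserved:
        flags.add(ORDER_NOT_CONSERVED)
    return _copy_fog(fog, flags=flags)


def check_domain_orders(
    fogs: list[FusionOrthogroup], config: Optional[PipelineConfig] = None
) -> list[FusionOrthogroup]:
    return [check_domain_order(f, config) for f in fogs]


# --------------------------------------------------------------------------
# 3. gene-cluster exclusion
# --------------------------------------------------------------------------

def _recompute(
    fog: FusionOrthogroup,
    members: list[ProteinClassification],
    order_of: dict[str, str],
    config: PipelineConfig,
) -> FusionOrthogroup:
    genomes = {m.genome_id for m in members}
    per_order: dict[str, int] = defaultdict(int)
    for gid in genomes:
        per_order[order_of[gid]] += 1
    anchor_te, anchor_host = (
        _shared_accessions(members) if members else (frozenset(), frozenset())
    )
    anchored = bool(anchor_te) and bool(anchor_host)
    new_tier = Tier.RAW
    if (
        members
        and len(genomes) >= config.min_genomes_og
        and (config.anchor_mode == "any" or anchored)
    ):
        new_tier = Tier.MIN5
        if (
            fog.tier >= Tier.CONSERVED20
            and len(genomes) >= config.min_genomes_conserved
            and max(per_order.values(), default=0) >= config.min_genomes_same_order
        ):
            new_tier = min(fog.tier, Tier.CURATED if fog.tier is Tier.CURATED else Tier.CONSERVED20)
    new_tier = min(new_tier, fog.tier)
    flags = set(fog.flags)
    if new_tier < fog.tier:
        flags.add(CLUSTER_EXCLUDED)
    return _copy_fog(
        fog,
        fusion_members=members,
        n_genomes=len(genomes),
        genomes_per_order=dict(per_order),
        tier=new_tier,
        flags=flags,
        anchor_te_accs=anchor_te,
        anchor_host_accs=anchor_host,
    )


def exclude_cluster_candidates(
    fogs: list[FusionOrthogroup],
    cluster_genes: set[str],
    taxonomy: list[GenomeMeta],
    config: Optional[PipelineConfig] = None,
) -> list[FusionOrthogroup]:
    """Drop fusion members located inside predicted gene clusters.

    Genome counts and tiers are recomputed from the remaining members; an
    orthogroup demoted by the removal is flagged CLUSTER_EXCLUDED.  The
    operation is idempotent.
    """
    config = config or PipelineConfig()
    order_of = {m.genome_id: m.order for m in taxonomy}
    out: list[FusionOrthogroup] = []
    for fog in fogs:
        kept = [m for m in fog.fusion_members if m.protein_id not in cluster_genes]
        if len(kept) == len(fog.fusion_members):
            out.append(fog)
        else:
            out.append(_recompute(fog, kept, order_of, config))
    return out


# --------------------------------------------------------------------------
# 4. curation
# --------------------------------------------------------------------------

def apply_curation(
    fogs: list[FusionOrthogroup],
    catalogue: TEDomainCatalogue,
    config: Optional[PipelineConfig] = None,
) -> list[FusionOrthogroup]:
    """Promote to CURATED the conserved orthogroups whose anchors are
    unambiguous.

    Requires tier CONSERVED20, no outstanding flags, at least one shared TE
    accession curated UNAMBIGUOUS_TE and at least one shared host accession
    curated UNAMBIGUOUS_HOST.  Everything else is returned unchanged.
    """
    out: list[FusionOrthogroup] = []
    for fog in fogs:
        if (
            fog.tier is Tier.CONSERVED20
            and not fog.flags
            and any(
                catalogue.curation_of(a) is CurationTier.UNAMBIGUOUS_TE
                for a in fog.anchor_te_accs
            )
            and any(
                catalogue.curation_of(a) is CurationTier.UNAMBIGUOUS_HOST
                for a in fog.anchor_host_accs
            )
        ):
            fog = _copy_fog(fog, tier=Tier.CURATED)
        out.append(fog)
    return out


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def write_tier_report(
    fogs: list[FusionOrthogroup],
    path,
    config: Optional[PipelineConfig] = None,
) -> None:
    """Tiered candidate report TSV."""
    config = config or PipelineConfig()
    with open(path, "w") as fh:
        fh.write(
            "og_id\ttier\tn_genomes\tn_orders_ge_min\tflags\t"
            "anchor_te_acc\tanchor_host_acc\tn_members\n"
        )
        for fog in sorted(fogs, key=lambda f: (-int(f.tier), f.og_id)):
            n_orders = sum(
                1
                for v in fog.genomes_per_order.values()
                if v >= config.min_genomes_same_order
            )
            fh.write(
                f"{fog.og_id}\t{fog.tier.name}\t{fog.n_genomes}\t{n_orders}\t"
                f"{','.join(sorted(fog.flags))}\t{fog.anchor_te_acc or ''}\t"
                f"{fog.anchor_host_acc or ''}\t{len(fog.fusion_members)}\n"
            )
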