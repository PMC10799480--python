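"""Core data model for the host-TE fusion screen.

A *host-TE fusion* is a protein-coding gene that combines a domain derived
from a transposable element (TE) — a transposase, reverse transcriptase,
TE helicase, and the like — with a host-derived domain, and that has been
retained across genomes by selection for a host function.  The screen
classifies proteins from their Pfam domain architecture, lifts candidates
to orthogroup level, and applies a cascade of conservation filters.

The types here are deliberately plain dataclasses: the pipeline stages pass
them around and the I/O layer (:mod:`tefuse.ingest`) materialises them from
the standard file formats.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class TEStatus(enum.Enum):
    """Role of one Pfam accession with respect to the TE catalogue."""

    TE = "TE"
    HOST = "HOST"
    EXCLUDED = "EXCLUDED"
    UNASSIGNED = "UNASSIGNED"


class CurationTier(enum.Enum):
    UNAMBIGUOUS_TE = "UNAMBIGUOUS_TE"
    AMBIGUOUS_TE = "AMBIGUOUS_TE"
    UNAMBIGUOUS_HOST = "UNAMBIGUOUS_HOST"
    AMBIGUOUS_HOST = "AMBIGUOUS_HOST"
    UNKNOWN = "UNKNOWN"


class ProteinLabel(enum.Enum):
    NO_TE = "NO_TE"
    TE_ONLY = "TE_ONLY"
    REMOVED_OVERLAP = "REMOVED_OVERLAP"
    FUSION_CANDIDATE = "FUSION_CANDIDATE"


class Tier(enum.IntEnum):
    """Conservation tier of a fusion orthogroup; higher is stricter.

    RAW          any orthogroup with at least one fusion candidate
    MIN5         fusion members span >= 5 distinct genomes (with shared
                 anchor accessions in strict mode)
    CONSERVED20  >= 20 genomes overall and >= 5 genomes in one order
    CURATED      both anchor accessions unambiguous per curation catalogue
    """

    RAW = 0
    MIN5 = 1
    CONSERVED20 = 2
    CURATED = 3


#: Flag set on an orthogroup whose fusion members disagree on the relative
#: order of the anchor TE / anchor host domains along the protein.
ORDER_NOT_CONSERVED = "ORDER_NOT_CONSERVED"
#: Flag set when removal of gene-cluster members demoted the orthogroup.
CLUSTER_EXCLUDED = "CLUSTER_EXCLUDED"


@dataclass(frozen=True)
class DomainHit:
    """One Pfam hit on one protein.

    Coordinates are envelope coordinates, 1-based inclusive; ``evalue`` is
    the sequence-level independent E-value of the domain.
    """

    protein_id: str
    genome_id: str
    pfam_acc: str
    pfam_name: str
    env_start: int
    env_end: int
    bitscore: float
    evalue: float
    te_status: TEStatus = TEStatus.UNASSIGNED

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"invalid envelope coordinates [{self.env_start}, {self.env_end}] "
                f"on {self.protein_id}/{self.pfam_acc}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative E-value on {self.protein_id}/{self.pfam_acc}")

    @property
    def length(self) -> int:
        return self.env_end - self.env_start + 1

    def with_status(self, status: TEStatus) -> "DomainHit":
        return replace(self, te_status=status)


def sort_hits(hits: list[DomainHit]) -> list[DomainHit]:
    """Canonical hit order: by env_start, ties by env_end then accession."""
    return sorted(hits, key=lambda h: (h.env_start, h.env_end, h.pfam_acc))


@dataclass
class ProteinRecord:
    """A protein with its ordered domain hits and genome of origin."""

    protein_id: str
    genome_id: str
    hits: list[DomainHit] = field(default_factory=list)
    length: Optional[int] = None

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.protein_id != self.protein_id or h.genome_id != self.genome_id:
                raise ValueError(
                    f"hit {h.protein_id}/{h.genome_id} does not belong to "
                    f"protein {self.protein_id}/{self.genome_id}"
                )
            if self.length is not None and h.env_end > self.length:
                raise ValueError(
                    f"hit end {h.env_end} beyond protein length {self.length} "
                    f"on {self.protein_id}"
                )
        self.hits = sort_hits(self.hits)


@dataclass(frozen=True)
class GenomeMeta:
    genome_id: str
    species: str
    phylum: str
    clade: str  # class or subphylum label, e.g. "Saccharomycotina"
    order: str
    n_genes: int
    genome_size_bp: Optional[int] = None
    gc_percent: Optional[float] = None
    rip_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError(f"negative gene count for {self.genome_id}")
        if self.rip_fraction is not None and not (0.0 <= self.rip_fraction <= 1.0):
            raise ValueError(f"rip_fraction out of [0,1] for {self.genome_id}")


@dataclass
class TEDomainCatalogue:
    """TE-associated, excluded, and curated Pfam accessions.

    ``te_accessions`` are diagnostic of TE-encoded proteins.
    ``excluded_accessions`` show profile similarity to TE families (per an
    external SCOOP/HHSearch analysis) and count as neither TE nor host
    evidence.  ``curation`` records the manual-confidence tier per accession.
    """

    te_accessions: set[str] = field(default_factory=set)
    excluded_accessions: set[str] = field(default_factory=set)
    curation: dict[str, CurationTier] = field(default_factory=dict)

    def __post_init__(self) -> None:
        both = self.te_accessions & self.excluded_accessions
        if both:
            raise ValueError(
                f"accessions in both te and excluded sets: {sorted(both)}"
            )

    def status_of(self, pfam_acc: str) -> TEStatus:
        if pfam_acc in self.te_accessions:
            return TEStatus.TE
        if pfam_acc in self.excluded_accessions:
            return TEStatus.EXCLUDED
        return TEStatus.HOST

    def curation_of(self, pfam_acc: str) -> CurationTier:
        return self.curation.get(pfam_acc, CurationTier.UNKNOWN)


@dataclass
class Orthogroup:
    og_id: str
    members: list[tuple[str, str]]  # (protein_id, genome_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.og_id} has no members")
        seen: set[str] = set()
        for pid, _ in self.members:
            if pid in seen:
                raise ValueError(f"protein {pid} duplicated within {self.og_id}")
            seen.add(pid)


NAMESPACES = ("MF", "BP", "CC")


@dataclass
class GOAnnotation:
    """Pfam accession -> set of (GO id, namespace) pairs."""

    mapping: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, pairs in self.mapping.items():
            for go_id, ns in pairs:
                if not (go_id.startswith("GO:") and len(go_id) == 10 and go_id[3:].isdigit()):
                    raise ValueError(f"malformed GO id {go_id!r} for {acc}")
                if ns not in NAMESPACES:
                    raise ValueError(f"unknown GO namespace {ns!r} for {acc}")

    def terms_for(self, pfam_acc: str) -> set[tuple[str, str]]:
        return self.mapping.get(pfam_acc, set())


@dataclass
class PipelineConfig:
    """All numeric thresholds of the screen, with their published defaults.

    min_bitscore / max_evalue     per-domain score filter on HMM hits
    max_overlap_frac              a gene is dropped when a TE and a host
                                  domain overlap by strictly more than this
                                  fraction of the shorter domain
    min_genomes_og                distinct genomes required for tier MIN5
    min_genomes_conserved         distinct genomes required for CONSERVED20
    min_genomes_same_order        genomes within one taxonomic order
                                  required for CONSERVED20
    background_fraction           fraction of all genes sampled as the
                                  enrichment background universe
    go_p_cutoff / go_min_term_size  significance rule for GO terms
    max_gap_frac                  alignment rows with strictly more gaps
                                  than this are discarded
    tree_thresholds               med_clade thresholds for tree clustering
    """

    min_bitscore: float = 50.0
    max_evalue: float = 1e-17
    max_overlap_frac: float = 0.05
    min_genomes_og: int = 5
    min_genomes_conserved: int = 20
    min_genomes_same_order: int = 5
    background_fraction: float = 0.01
    go_p_cutoff: float = 1e-10
    go_min_term_size: int = 20
    max_gap_frac: float = 0.20
    tree_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    rng_seed: int = 0
    # -- behaviour switches for under-specified corners ------------------
    # E-value column used from domain tables: "independent" (per-domain
    # i-Evalue) or "full" (whole-sequence E-value).
    evalue_column: str = "independent"
    # Denominator of the overlap fraction: "shorter" | "longer" | "protein".
    overlap_denominator: str = "shorter"
    # Overlap removal scope: "gene" drops the whole gene when any
    # (TE, host) pair overlaps beyond the bound; "pair" keeps the gene as
    # long as some pair stays within it.  The gene scope is the stricter,
    # literal rule; the pair scope makes the candidate set monotone in the
    # hit-score thresholds.
    overlap_scope: str = "gene"
    # Orthogroup anchor mode: "strict" requires one TE and one host
    # accession shared by every fusion member; "any" does not.
    anchor_mode: str = "strict"
    # Domain-order check: "unanimity" or "majority".
    order_strictness: str = "unanimity"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_overlap_frac <= 1.0):
            raise ValueError("max_overlap_frac must lie in [0, 1]")
        if not (0.0 < self.background_fraction <= 1.0):
            raise ValueError("background_fraction must lie in (0, 1]")
        if not (0.0 <= self.max_gap_frac <= 1.0):
            raise ValueError("max_gap_frac must lie in [0, 1]")
        if self.min_genomes_same_order > self.min_genomes_conserved:
            raise ValueError("min_genomes_same_order exceeds min_genomes_conserved")
        if self.evalue_column not in ("independent", "full"):
            raise ValueError(f"unknown evalue_column {self.evalue_column!r}")
        if self.overlap_denominator not in ("shorter", "longer", "protein"):
            raise ValueError(f"unknown overlap_denominator {self.overlap_denominator!r}")
        if self.overlap_scope not in ("gene", "pair"):
            raise ValueError(f"unknown overlap_scope {self.overlap_scope!r}")
        if self.anchor_mode not in ("strict", "any"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")
        if self.order_strictness not in ("unanimity", "majority"):
            raise ValueError(f"unknown order_strictness {self.order_strictness!r}")
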