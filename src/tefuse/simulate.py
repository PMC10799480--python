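"""Synthetic input bundles with planted ground truth.

The generator emits a complete, format-valid input set — domain table,
orthogroups, taxonomy, TE catalogue, pfam2go, gene-cluster list, genome
tree, protein FASTA — in which a configurable number of fusion
orthogroups is planted at chosen conservation tiers, alongside decoy
records each violating exactly one filtering rule of the screen:

========================  ====================================================
decoy class               rule it must fail
========================  ====================================================
TE_ONLY                   proteins annotated exclusively with TE domains
OVERLAP_GT5               TE/host domain overlap above 5% of the shorter
RECENT_LT5_GENOMES        orthogroup in fewer than 5 genomes
BELOW20_CONSERVED         in >= 5 genomes but fewer than 20
SCRAMBLED_ORDER           inconsistent anchor domain order across members
CLUSTER_PROXIMITY         all members inside predicted gene clusters
AMBIGUOUS_TE_ANCHOR       anchor TE domain not unambiguously TE-derived
EXCLUDED_PFAM_ONLY        "host" evidence is an excluded (TE-similar) domain
========================  ====================================================

Synthetic Pfam accessions live in a reserved ``PF9xxxx`` range so they can
never collide with real accessions in a user-supplied catalogue.  The
sequences are random amino-acid strings: the generator emulates the
statistical structure the screen consumes (architectures, orthogroup
spread, taxonomy), not protein biophysics, TE transposition or RIP
mutation processes.
"""

from __future__ import annotations

import enum
import json
import random
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from . import ingest
from .model import (
    CurationTier,
    DomainHit,
    GenomeMeta,
    GOAnnotation,
    Orthogroup,
    PipelineConfig,
    TEDomainCatalogue,
    Tier,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class DecoyClass(enum.Enum):
    TE_ONLY = "TE_ONLY"
    OVERLAP_GT5 = "OVERLAP_GT5"
    RECENT_LT5_GENOMES = "RECENT_LT5_GENOMES"
    BELOW20_CONSERVED = "BELOW20_CONSERVED"
    SCRAMBLED_ORDER = "SCRAMBLED_ORDER"
    CLUSTER_PROXIMITY = "CLUSTER_PROXIMITY"
    AMBIGUOUS_TE_ANCHOR = "AMBIGUOUS_TE_ANCHOR"
    EXCLUDED_PFAM_ONLY = "EXCLUDED_PFAM_ONLY"


#: decoy classes that act at the protein level (the orthogroup never gains
#: a single fusion candidate)
PROTEIN_LEVEL_DECOYS = frozenset(
    {DecoyClass.TE_ONLY, DecoyClass.OVERLAP_GT5, DecoyClass.EXCLUDED_PFAM_ONLY}
)


def _default_te_pool() -> list[str]:
    return [f"PF9{100 + i:04d}" for i in range(8)]


def _default_host_pool() -> list[str]:
    return [f"PF9{500 + i:04d}" for i in range(30)]


def _default_excluded_pool() -> list[str]:
    return [f"PF9{900 + i:04d}" for i in range(3)]


def _default_tier_profile() -> dict[Tier, int]:
    return {Tier.MIN5: 4, Tier.CONSERVED20: 3, Tier.CURATED: 3}


def _default_decoys() -> dict[DecoyClass, int]:
    return {c: 5 for c in DecoyClass}


@dataclass
class SimulationParams:
    """Shape and scale of one synthetic bundle.

    ``n_genomes_per_order`` may be a single int or one count per order
    (phyla are filled in row-major order).  ``planted_tier_profile`` gives
    the tier each planted orthogroup must reach — and no higher.
    ``planted_go_term`` is enriched among planted fusion genes;
    ``background_term_fraction`` controls how often background genes also
    carry it (the effect-size dial).
    """

    n_phyla: int = 2
    n_orders_per_phylum: int = 2
    n_genomes_per_order: Union[int, Sequence[int]] = (8, 8, 7, 7)
    genes_per_genome: tuple[int, int] = (60, 90)
    planted_tier_profile: dict[Tier, int] = field(default_factory=_default_tier_profile)
    decoy_counts: dict[DecoyClass, int] = field(default_factory=_default_decoys)
    te_accession_pool: list[str] = field(default_factory=_default_te_pool)
    host_accession_pool: list[str] = field(default_factory=_default_host_pool)
    excluded_accession_pool: list[str] = field(default_factory=_default_excluded_pool)
    planted_go_term: str = "GO:0099001"
    background_term_fraction: float = 0.01
    #: probability that a planted TE/host pair overlaps in (0, 5%] rather
    #: than being disjoint, to exercise the overlap boundary
    p_edge_overlap: float = 0.2
    #: genomes kept free of fusion candidates and given high RIP coverage
    n_rip_genomes: int = 2
    seed: int = 0

    @property
    def n_orders(self) -> int:
        return self.n_phyla * self.n_orders_per_phylum

    def genomes_per_order_list(self) -> list[int]:
        if isinstance(self.n_genomes_per_order, int):
            return [self.n_genomes_per_order] * self.n_orders
        counts = list(self.n_genomes_per_order)
        if len(counts) != self.n_orders:
            raise ValueError(
                f"n_genomes_per_order lists {len(counts)} orders, "
                f"expected {self.n_orders}"
            )
        return counts

    @property
    def n_genomes(self) -> int:
        return sum(self.genomes_per_order_list())

    @property
    def n_planted_fusion_ogs(self) -> int:
        return sum(self.planted_tier_profile.values())


@dataclass
class PlantedRecord:
    og_id: str
    intended_tier: Tier
    anchor_te_acc: str
    anchor_host_acc: str
    member_proteins: list[str]


@dataclass
class DecoyRecord:
    record_id: str
    decoy_class: DecoyClass
    og_id: Optional[str]
    member_proteins: list[str]


@dataclass
class TruthTable:
    planted: list[PlantedRecord]
    decoys: list[DecoyRecord]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": [
                    {
                        "og_id": p.og_id,
                        "intended_tier": p.intended_tier.name,
                        "anchor_te_acc": p.anchor_te_acc,
                        "anchor_host_acc": p.anchor_host_acc,
                        "member_proteins": p.member_proteins,
                    }
                    for p in self.planted
                ],
                "decoys": [
                    {
                        "record_id": d.record_id,
                        "decoy_class": d.decoy_class.value,
                        "og_id": d.og_id,
                        "member_proteins": d.member_proteins,
                    }
                    for d in self.decoys
                ],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        obj = json.loads(text)
        return cls(
            planted=[
                PlantedRecord(
                    og_id=p["og_id"],
                    intended_tier=Tier[p["intended_tier"]],
                    anchor_te_acc=p["anchor_te_acc"],
                    anchor_host_acc=p["anchor_host_acc"],
                    member_proteins=p["member_proteins"],
                )
                for p in obj["planted"]
            ],
            decoys=[
                DecoyRecord(
                    record_id=d["record_id"],
                    decoy_class=DecoyClass(d["decoy_class"]),
                    og_id=d["og_id"],
                    member_proteins=d["member_proteins"],
                )
                for d in obj["decoys"]
            ],
        )


@dataclass
class Bundle:
    """In-memory view of one generated bundle plus its file paths."""

    out_dir: Path
    hits: list[DomainHit]
    orthogroups: list[Orthogroup]
    taxonomy: list[GenomeMeta]
    catalogue: TEDomainCatalogue
    annotation: GOAnnotation
    cluster_genes: set[str]
    tree_newick: str
    truth: TruthTable

    @property
    def paths(self) -> dict[str, Path]:
        return {
            "domains": self.out_dir / "domains.tsv",
            "orthogroups": self.out_dir / "orthogroups.tsv",
            "taxonomy": self.out_dir / "taxonomy.tsv",
            "te_catalogue": self.out_dir / "te_catalogue.tsv",
            "pfam2go": self.out_dir / "pfam2go.txt",
            "cluster_genes": self.out_dir / "cluster_genes.txt",
            "tree": self.out_dir / "tree.nwk",
            "fasta": self.out_dir / "proteins.fasta",
            "truth": self.out_dir / "truth.json",
        }


class _GenomeState:
    """Per-genome gene allocation during generation."""

    def __init__(self, meta_stub: dict):
        self.stub = meta_stub
        self.n_alloc = 0
        self.has_fusion_candidate = False

    def new_gene(self, genome_id: str) -> str:
        self.n_alloc += 1
        return f"{genome_id}|g{self.n_alloc:05d}"


def _validate(params: SimulationParams, config: PipelineConfig) -> None:
    usable = params.n_genomes - params.n_rip_genomes
    needs20 = params.planted_tier_profile.get(Tier.CONSERVED20, 0) + \
        params.planted_tier_profile.get(Tier.CURATED, 0)
    if needs20 and usable < config.min_genomes_conserved:
        raise ValueError(
            f"cannot plant CONSERVED20-tier orthogroups: only {usable} usable "
            f"genomes, need >= {config.min_genomes_conserved}"
        )
    if params.n_planted_fusion_ogs and usable < config.min_genomes_og:
        raise ValueError(
            f"cannot plant MIN5-tier orthogroups with {usable} usable genomes"
        )
    deep_decoys = params.decoy_counts.get(DecoyClass.SCRAMBLED_ORDER, 0) + \
        params.decoy_counts.get(DecoyClass.AMBIGUOUS_TE_ANCHOR, 0)
    if deep_decoys and usable < config.min_genomes_conserved:
        raise ValueError(
            "SCRAMBLED_ORDER / AMBIGUOUS_TE_ANCHOR decoys need "
            f">= {config.min_genomes_conserved} usable genomes"
        )
    if params.planted_tier_profile.get(Tier.RAW, 0):
        raise ValueError("planted orthogroups must target tier MIN5 or higher; "
                         "use RECENT_LT5_GENOMES decoys for sub-MIN5 records")


def generate_bundle(
    params: SimulationParams,
    out_dir: Union[str, Path],
    config: Optional[PipelineConfig] = None,
) -> Bundle:
    """Generate one bundle under ``out_dir`` and return its in-memory view.

    Deterministic: the same ``params`` (including seed) produce
    byte-identical files.
    """
    config = config or PipelineConfig()
    _validate(params, config)
    rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- taxonomy scaffold -------------------------------------------
    genome_states: dict[str, _GenomeState] = {}
    genome_order: dict[str, str] = {}
    gi = 0
    counts = params.genomes_per_order_list()
    for p in range(params.n_phyla):
        for o in range(params.n_orders_per_phylum):
            order_idx = p * params.n_orders_per_phylum + o
            order_id = f"O{p + 1}_{o + 1}"
            for _ in range(counts[order_idx]):
                gi += 1
                gid = f"G{gi:03d}"
                genome_order[gid] = order_id
                genome_states[gid] = _GenomeState(
                    {
                        "species": f"Species {gid.lower()}",
                        "phylum": f"P{p + 1}",
                        "clade": f"C{p + 1}",
                        "order": order_id,
                    }
                )
    all_genomes = sorted(genome_states)
    rip_genomes = [
        str(g) for g in rng.choice(all_genomes, size=params.n_rip_genomes, replace=False)
    ]
    fusion_pool = sorted(set(all_genomes) - set(rip_genomes))

    # ---- accession bookkeeping ---------------------------------------
    te_pool = list(params.te_accession_pool)
    host_pool = list(params.host_accession_pool)
    excl_pool = list(params.excluded_accession_pool)
    n_planted = params.n_planted_fusion_ogs
    n_ambig_decoys = params.decoy_counts.get(DecoyClass.AMBIGUOUS_TE_ANCHOR, 0)
    if len(te_pool) < 2 or len(host_pool) < n_planted + 2:
        raise ValueError("accession pools too small for the requested plantings")

    # anchors: planted orthogroups draw dedicated host anchors so the
    # planted GO term stays tied to fusion genes
    anchor_host_accs = host_pool[: n_planted]
    background_hosts = host_pool[n_planted:]
    unambiguous_te = te_pool[: max(1, len(te_pool) // 2)]
    ambiguous_te = te_pool[len(unambiguous_te):] or [te_pool[-1]]

    catalogue = TEDomainCatalogue(
        te_accessions=set(te_pool),
        excluded_accessions=set(excl_pool),
    )
    for acc in unambiguous_te:
        catalogue.curation[acc] = CurationTier.UNAMBIGUOUS_TE
    for acc in ambiguous_te:
        catalogue.curation[acc] = CurationTier.AMBIGUOUS_TE

    hits: list[DomainHit] = []
    ogs: list[Orthogroup] = []
    cluster_genes: set[str] = set()
    planted_records: list[PlantedRecord] = []
    decoy_records: list[DecoyRecord] = []
    og_serial = 0

    def next_og() -> str:
        nonlocal og_serial
        og_serial += 1
        return f"OG{og_serial:07d}"

    def add_hit(pid: str, gid: str, acc: str, start: int, end: int) -> None:
        hits.append(
            DomainHit(
                protein_id=pid,
                genome_id=gid,
                pfam_acc=acc,
                pfam_name=f"syn_{acc}",
                env_start=start,
                env_end=end,
                bitscore=float(np.round(60 + 240 * rng.random(), 1)),
                evalue=float(10.0 ** -(20 + 40 * rng.random())),
            )
        )

    def fusion_architecture(pid: str, gid: str, te_acc: str, host_acc: str,
                            host_first: bool = False,
                            extra_host: Optional[str] = None) -> None:
        """Two 100-aa domains, disjoint or overlapping by at most 5 aa."""
        if rng.random() < params.p_edge_overlap:
            gap = -int(rng.integers(1, 6))  # overlap of 1..5 aa: frac <= 0.05
        else:
            gap = int(rng.integers(10, 40))
        first = (10, 109)
        second = (110 + gap, 209 + gap)
        if host_first:
            add_hit(pid, gid, host_acc, *first)
            add_hit(pid, gid, te_acc, *second)
        else:
            add_hit(pid, gid, te_acc, *first)
            add_hit(pid, gid, host_acc, *second)
        if extra_host is not None:
            add_hit(pid, gid, extra_host, 260, 339)

    def pick_genomes(n: int, same_order_min: int = 0) -> list[str]:
        pool = fusion_pool
        if same_order_min:
            # choose an order with enough usable genomes, take its quota
            by_order: dict[str, list[str]] = defaultdict(list)
            for g in pool:
                by_order[genome_order[g]].append(g)
            candidates = sorted(
                o for o, gs in by_order.items() if len(gs) >= same_order_min
            )
            if not candidates:
                raise ValueError("no order has enough usable genomes")
            order = candidates[int(rng.integers(len(candidates)))]
            core = list(
                rng.choice(by_order[order], size=same_order_min, replace=False)
            )
            rest_pool = sorted(set(pool) - set(core))
            rest = list(
                rng.choice(rest_pool, size=n - same_order_min, replace=False)
            )
            return sorted(str(g) for g in core + rest)
        return sorted(str(g) for g in rng.choice(pool, size=n, replace=False))

    # ---- planted fusion orthogroups ----------------------------------
    anchor_i = 0
    for tier in (Tier.CURATED, Tier.CONSERVED20, Tier.MIN5):
        for _ in range(params.planted_tier_profile.get(tier, 0)):
            og_id = next_og()
            host_acc = anchor_host_accs[anchor_i]
            anchor_i += 1
            if tier is Tier.CURATED:
                te_acc = unambiguous_te[int(rng.integers(len(unambiguous_te)))]
                catalogue.curation[host_acc] = CurationTier.UNAMBIGUOUS_HOST
                n = int(rng.integers(config.min_genomes_conserved,
                                     len(fusion_pool) + 1))
                genomes = pick_genomes(n, config.min_genomes_same_order)
            elif tier is Tier.CONSERVED20:
                # stays below CURATED: host anchor left uncurated (UNKNOWN)
                te_acc = unambiguous_te[int(rng.integers(len(unambiguous_te)))]
                n = int(rng.integers(config.min_genomes_conserved,
                                     len(fusion_pool) + 1))
                genomes = pick_genomes(n, config.min_genomes_same_order)
            else:  # MIN5: too few genomes for CONSERVED20
                te_acc = te_pool[int(rng.integers(len(te_pool)))]
                hi = min(config.min_genomes_conserved - 1, len(fusion_pool))
                n = int(rng.integers(config.min_genomes_og, hi + 1))
                genomes = pick_genomes(n)
            members = []
            for gid in genomes:
                pid = genome_states[gid].new_gene(gid)
                genome_states[gid].has_fusion_candidate = True
                extra = (
                    background_hosts[int(rng.integers(len(background_hosts)))]
                    if rng.random() < 0.3
                    else None
                )
                fusion_architecture(pid, gid, te_acc, host_acc, extra_host=extra)
                members.append(pid)
            ogs.append(Orthogroup(og_id=og_id,
                                  members=[(m, m.split("|")[0]) for m in members]))
            planted_records.append(
                PlantedRecord(
                    og_id=og_id,
                    intended_tier=tier,
                    anchor_te_acc=te_acc,
                    anchor_host_acc=host_acc,
                    member_proteins=members,
                )
            )

    # ---- decoys -------------------------------------------------------
    def decoy_og(cls: DecoyClass, idx: int, genomes: list[str],
                 build_member) -> DecoyRecord:
        og_id = next_og()
        members = []
        for j, gid in enumerate(genomes):
            pid = genome_states[gid].new_gene(gid)
            build_member(pid, gid, j)
            members.append(pid)
        ogs.append(Orthogroup(og_id=og_id,
                              members=[(m, m.split("|")[0]) for m in members]))
        return DecoyRecord(
            record_id=f"{cls.value}_{idx}",
            decoy_class=cls,
            og_id=og_id,
            member_proteins=members,
        )

    for cls in sorted(params.decoy_counts, key=lambda c: c.value):
        for idx in range(params.decoy_counts[cls]):
            te_acc = te_pool[int(rng.integers(len(te_pool)))]
            host_acc = background_hosts[int(rng.integers(len(background_hosts)))]
            if cls is DecoyClass.TE_ONLY:
                genomes = pick_genomes(config.min_genomes_og)

                def build(pid, gid, j, te_acc=te_acc):
                    add_hit(pid, gid, te_acc, 10, 109)
                    if rng.random() < 0.5:
                        add_hit(pid, gid, te_acc, 150, 230)

            elif cls is DecoyClass.OVERLAP_GT5:
                genomes = pick_genomes(config.min_genomes_og)

                def build(pid, gid, j, te_acc=te_acc, host_acc=host_acc):
                    # 51/100 overlap: the same physical domain annotated twice
                    add_hit(pid, gid, te_acc, 1, 100)
                    add_hit(pid, gid, host_acc, 50, 150)

            elif cls is DecoyClass.EXCLUDED_PFAM_ONLY:
                excl = excl_pool[int(rng.integers(len(excl_pool)))]
                genomes = pick_genomes(config.min_genomes_og)

                def build(pid, gid, j, te_acc=te_acc, excl=excl):
                    add_hit(pid, gid, te_acc, 10, 109)
                    add_hit(pid, gid, excl, 150, 249)

            elif cls is DecoyClass.RECENT_LT5_GENOMES:
                genomes = pick_genomes(config.min_genomes_og - 1)

                def build(pid, gid, j, te_acc=te_acc, host_acc=host_acc):
                    genome_states[gid].has_fusion_candidate = True
                    fusion_architecture(pid, gid, te_acc, host_acc)

            elif cls is DecoyClass.BELOW20_CONSERVED:
                # satisfies the same-order condition so only the >= 20
                # genome bound is violated
                hi = min(config.min_genomes_conserved - 1, len(fusion_pool))
                n = int(rng.integers(config.min_genomes_og, hi + 1))
                genomes = pick_genomes(n, min(config.min_genomes_same_order, n))

                def build(pid, gid, j, te_acc=te_acc, host_acc=host_acc):
                    genome_states[gid].has_fusion_candidate = True
                    fusion_architecture(pid, gid, te_acc, host_acc)

            elif cls is DecoyClass.SCRAMBLED_ORDER:
                n = int(rng.integers(config.min_genomes_conserved,
                                     len(fusion_pool) + 1))
                genomes = pick_genomes(n, config.min_genomes_same_order)

                def build(pid, gid, j, te_acc=te_acc, host_acc=host_acc):
                    genome_states[gid].has_fusion_candidate = True
                    fusion_architecture(pid, gid, te_acc, host_acc,
                                        host_first=(j % 2 == 1))

            elif cls is DecoyClass.CLUSTER_PROXIMITY:
                genomes = pick_genomes(config.min_genomes_og)

                def build(pid, gid, j, te_acc=te_acc, host_acc=host_acc):
                    genome_states[gid].has_fusion_candidate = True
                    fusion_architecture(pid, gid, te_acc, host_acc)
                    cluster_genes.add(pid)

            else:  # AMBIGUOUS_TE_ANCHOR
                te_acc = ambiguous_te[int(rng.integers(len(ambiguous_te)))]
                host_acc_c = background_hosts[int(rng.integers(len(background_hosts)))]
                catalogue.curation.setdefault(host_acc_c, CurationTier.UNAMBIGUOUS_HOST)
                n = int(rng.integers(config.min_genomes_conserved,
                                     len(fusion_pool) + 1))
                genomes = pick_genomes(n, config.min_genomes_same_order)

                def build(pid, gid, j, te_acc=te_acc, host_acc=host_acc_c):
                    genome_states[gid].has_fusion_candidate = True
                    fusion_architecture(pid, gid, te_acc, host_acc)

            decoy_records.append(decoy_og(cls, idx, genomes, build))

    # ---- background genes --------------------------------------------
    lo, hi = params.genes_per_genome
    bg_genes: list[tuple[str, str]] = []
    for gid in all_genomes:
        state = genome_states[gid]
        target = max(int(rng.integers(lo, hi + 1)), state.n_alloc)
        while state.n_alloc < target:
            pid = state.new_gene(gid)
            bg_genes.append((pid, gid))
            n_dom = int(rng.integers(1, 4))
            pos = 10
            for _ in range(n_dom):
                acc = background_hosts[int(rng.integers(len(background_hosts)))]
                length = int(rng.integers(60, 140))
                add_hit(pid, gid, acc, pos, pos + length - 1)
                pos += length + int(rng.integers(10, 40))

    # group a third of background genes into host-only orthogroups of ~4,
    # leave the rest unassigned (singletons)
    rng.shuffle(bg_genes)
    n_grouped = len(bg_genes) // 3
    for i in range(0, n_grouped, 4):
        chunk = bg_genes[i: i + 4]
        if not chunk:
            break
        ogs.append(Orthogroup(og_id=next_og(), members=list(chunk)))

    # ---- taxonomy + RIP ----------------------------------------------
    taxonomy: list[GenomeMeta] = []
    for gid in all_genomes:
        st = genome_states[gid]
        if gid in rip_genomes:
            rip = float(np.round(0.12 + 0.10 * rng.random(), 3))
            assert not st.has_fusion_candidate
        else:
            rip = (
                float(np.round(0.08 * rng.random(), 3))
                if rng.random() < 0.5
                else None
            )
        taxonomy.append(
            GenomeMeta(
                genome_id=gid,
                species=st.stub["species"],
                phylum=st.stub["phylum"],
                clade=st.stub["clade"],
                order=st.stub["order"],
                n_genes=st.n_alloc,
                genome_size_bp=int(rng.integers(8_000_000, 80_000_000)),
                gc_percent=float(np.round(30 + 30 * rng.random(), 1)),
                rip_fraction=rip,
            )
        )

    # ---- GO annotation -----------------------------------------------
    go_serial = 100
    mapping: dict[str, set[tuple[str, str]]] = {}
    for acc in sorted(set(background_hosts)):
        terms = set()
        for _ in range(int(rng.integers(1, 3))):
            go_serial += 1
            ns = ("MF", "BP", "CC")[int(rng.integers(3))]
            terms.add((f"GO:{go_serial:07d}", ns))
        if rng.random() < params.background_term_fraction:
            # rare background families share the planted term
            terms.add((params.planted_go_term, "MF"))
        mapping[acc] = terms
    for acc in anchor_host_accs:
        go_serial += 1
        mapping[acc] = {(params.planted_go_term, "MF"),
                        (f"GO:{go_serial:07d}", "BP")}
    # TE families deliberately carry no GO terms: pfam2go leaves most
    # TE-specific families unannotated
    annotation = GOAnnotation(mapping=mapping)

    # ---- genome tree (pure birth) ------------------------------------
    tree = _pure_birth_tree(all_genomes, random.Random(params.seed))
    tree_newick = tree.as_string(schema="newick").strip() + "\n"

    # ---- FASTA for planted fusion proteins ----------------------------
    fasta_lines: list[str] = []
    for rec in planted_records:
        for pid in rec.member_proteins:
            n = int(rng.integers(250, 400))
            seq = "M" + "".join(
                AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n)
            )
            fasta_lines.append(f">{pid}")
            fasta_lines.extend(seq[i: i + 60] for i in range(0, len(seq), 60))

    # ---- emit ----------------------------------------------------------
    truth = TruthTable(planted=planted_records, decoys=decoy_records)
    bundle = Bundle(
        out_dir=out_dir,
        hits=hits,
        orthogroups=ogs,
        taxonomy=taxonomy,
        catalogue=catalogue,
        annotation=annotation,
        cluster_genes=cluster_genes,
        tree_newick=tree_newick,
        truth=truth,
    )
    paths = bundle.paths
    ingest.write_domain_table_tsv(hits, paths["domains"])
    ingest.write_orthogroups(ogs, all_genomes, paths["orthogroups"])
    ingest.write_taxonomy(taxonomy, paths["taxonomy"])
    ingest.write_te_catalogue(catalogue, paths["te_catalogue"])
    ingest.write_pfam2go(annotation, paths["pfam2go"])
    ingest.write_cluster_genes(cluster_genes, paths["cluster_genes"])
    paths["tree"].write_text(tree_newick)
    paths["fasta"].write_text("\n".join(fasta_lines) + ("\n" if fasta_lines else ""))
    paths["truth"].write_text(truth.to_json() + "\n")
    return bundle


def _pure_birth_tree(labels: list[str], rng: random.Random) -> dendropy.Tree:
    """Pure-birth (Yule) tree over the given leaf labels.

    Grown by repeatedly splitting a uniformly chosen extant lineage, with
    exponential waiting times accumulated on branch lengths.
    """
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    extant = [tree.seed_node]
    while len(extant) < len(labels):
        wait = rng.expovariate(len(extant))
        for node in extant:
            node.edge.length += wait
        parent = extant.pop(rng.randrange(len(extant)))
        for _ in range(2):
            child = parent.new_child()
            child.edge.length = 0.0
            extant.append(child)
    # final stretch so leaves are non-zero from their parents
    wait = rng.expovariate(len(extant))
    for node in extant:
        node.edge.length += wait
    order = list(range(len(extant)))
    rng.shuffle(order)
    for node, i in zip(extant, order):
        node.taxon = taxa.get_taxon(labels[i])
    return tree


# --------------------------------------------------------------------------
# recovery scoring
# --------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    precision: dict[str, Optional[float]]
    recall: dict[str, Optional[float]]
    rejection_rate: dict[str, Optional[float]]

    @property
    def all_perfect(self) -> bool:
        vals = (
            list(self.precision.values())
            + list(self.recall.values())
            + list(self.rejection_rate.values())
        )
        return all(v is None or v == 1.0 for v in vals)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def score_recovery(result, truth: TruthTable) -> RecoveryReport:
    """Compare pipeline output against the planted truth.

    ``result`` is a :class:`tefuse.pipeline.PipelineResult`.  Precision and
    recall are computed on orthogroup ids per tier; the expected set at a
    tier includes the decoys whose single violated rule guards a *higher*
    tier.  The rejection rate of a decoy class is the fraction of its
    records absent from the tier its rule guards.
    """
    from .model import ORDER_NOT_CONSERVED

    candidates = {
        c.protein_id for c in result.classifications
        if c.label.value == "FUSION_CANDIDATE"
    }
    min5 = {f.og_id for f in result.fusion_orthogroups if f.tier >= Tier.MIN5}
    conserved = {
        f.og_id
        for f in result.fusion_orthogroups
        if f.tier >= Tier.CONSERVED20 and ORDER_NOT_CONSERVED not in f.flags
    }
    curated = {f.og_id for f in result.fusion_orthogroups if f.tier is Tier.CURATED}

    by_class: dict[DecoyClass, list[DecoyRecord]] = defaultdict(list)
    for d in truth.decoys:
        by_class[d.decoy_class].append(d)

    def planted_at(tier: Tier) -> set[str]:
        return {p.og_id for p in truth.planted if p.intended_tier >= tier}

    expected_min5 = planted_at(Tier.MIN5) | {
        d.og_id
        for cls in (DecoyClass.BELOW20_CONSERVED, DecoyClass.SCRAMBLED_ORDER,
                    DecoyClass.AMBIGUOUS_TE_ANCHOR)
        for d in by_class.get(cls, [])
        if d.og_id
    }
    expected_conserved = planted_at(Tier.CONSERVED20) | {
        d.og_id for d in by_class.get(DecoyClass.AMBIGUOUS_TE_ANCHOR, []) if d.og_id
    }
    expected_curated = planted_at(Tier.CURATED)

    known_ogs = {og.og_id for og in result.orthogroups} | {
        f"singleton:{pid}" for pid in candidates
    }
    for s, name in ((expected_min5, "truth"),):
        stray = s - known_ogs
        if stray:
            raise ValueError(f"{name} references unknown orthogroups: {sorted(stray)[:5]}")

    precision = {}
    recall = {}
    for name, obs, exp in (
        ("MIN5", min5, expected_min5),
        ("CONSERVED20", conserved, expected_conserved),
        ("CURATED", curated, expected_curated),
    ):
        precision[name] = _ratio(len(obs & exp), len(obs))
        recall[name] = _ratio(len(obs & exp), len(exp))

    rejection: dict[str, Optional[float]] = {}
    guard_sets = {
        DecoyClass.TE_ONLY: ("protein", candidates),
        DecoyClass.OVERLAP_GT5: ("protein", candidates),
        DecoyClass.EXCLUDED_PFAM_ONLY: ("protein", candidates),
        DecoyClass.RECENT_LT5_GENOMES: ("og", min5),
        DecoyClass.CLUSTER_PROXIMITY: ("og", min5),
        DecoyClass.BELOW20_CONSERVED: ("og", conserved),
        DecoyClass.SCRAMBLED_ORDER: ("og", conserved),
        DecoyClass.AMBIGUOUS_TE_ANCHOR: ("og", curated),
    }
    for cls, (kind, guard) in guard_sets.items():
        records = by_class.get(cls, [])
        if not records:
            rejection[cls.value] = None
            continue
        ok = 0
        for d in records:
            if kind == "protein":
                ok += not (set(d.member_proteins) & guard)
            else:
                ok += d.og_id not in guard
        rejection[cls.value] = ok / len(records)

    return RecoveryReport(precision=precision, recall=recall, rejection_rate=rejection)
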