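"""Readers and writers for the screen's external file formats.

Formats consumed:

* HMMER3 domain tables (``hmmsearch --domtblout``) or a 7-column TSV
  dialect carrying the same fields plus an explicit genome id;
* OrthoFinder-style ``Orthogroups.tsv`` (first column orthogroup id, one
  column per genome, cells ``", "``-joined protein ids);
* a taxonomy/metadata TSV;
* a TE Pfam catalogue TSV (accession, role, curation tier);
* the community ``pfam2go`` flat-text mapping (with an optional trailing
  namespace token used by fixtures);
* a flat list of gene-cluster member protein ids.

All readers validate invariants on load and raise :class:`IngestError`
with a line number on malformed input.  Matching writers allow synthetic
bundles to round-trip exactly.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import (
    NAMESPACES,
    CurationTier,
    DomainHit,
    GenomeMeta,
    GOAnnotation,
    Orthogroup,
    PipelineConfig,
    ProteinRecord,
    TEDomainCatalogue,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class IngestError(ValueError):
    """Malformed or inconsistent input file."""


def strip_pfam_version(acc: str) -> str:
    """Drop a trailing Pfam release suffix, e.g. ``PF00271.33 -> PF00271``."""
    return _VERSION_SUFFIX.sub("", acc)


# --------------------------------------------------------------------------
# domain tables
# --------------------------------------------------------------------------

# hmmsearch --domtblout whitespace-separated columns (0-based):
#   0 target name, 3 query name, 4 query accession, 6 full-sequence E-value,
#   12 i-Evalue, 13 domain score, 19 env from, 20 env to
_DOMTBL_MIN_COLS = 22


def _split_genome(protein_id: str) -> str:
    # "genome|protein" convention; bare ids map to an empty genome field
    return protein_id.split("|", 1)[0] if "|" in protein_id else ""


def read_domain_table(
    path: PathLike,
    format: str = "auto",
    config: Optional[PipelineConfig] = None,
    genome_id: Optional[str] = None,
) -> list[DomainHit]:
    """Read per-protein Pfam hits from a domain table.

    ``format`` is ``"domtblout"``, ``"tsv"`` (the 7-column fixture dialect:
    protein_id, genome_id, pfam_acc, env_start, env_end, bitscore, evalue)
    or ``"auto"`` to sniff.  Envelope coordinates are kept 1-based
    inclusive; Pfam version suffixes are stripped.  For domtblout input the
    E-value column follows ``config.evalue_column`` (per-domain independent
    E-value by default) and the genome id is ``genome_id`` if given, else
    the ``genome|protein`` prefix of the target name.
    """
    path = Path(path)
    config = config or PipelineConfig()
    lines = path.read_text().splitlines()

    fmt = format
    if fmt == "auto":
        fmt = "tsv"
        for ln in lines:
            if ln.strip() and not ln.startswith("#"):
                fmt = "tsv" if "\t" in ln else "domtblout"
                break
    if fmt not in ("domtblout", "tsv"):
        raise IngestError(f"unknown domain-table format {fmt!r}")

    hits: list[DomainHit] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if fmt == "tsv":
                fields = line.split("\t")
                if len(fields) < 7:
                    raise ValueError(f"expected 7 tab-separated columns, got {len(fields)}")
                pid, gid, acc, start, end, score, evalue = fields[:7]
                name = fields[7] if len(fields) > 7 else ""
                hit = DomainHit(
                    protein_id=pid,
                    genome_id=gid,
                    pfam_acc=strip_pfam_version(acc),
                    pfam_name=name,
                    env_start=int(start),
                    env_end=int(end),
                    bitscore=float(score),
                    evalue=float(evalue),
                )
            else:
                fields = line.split()
                if len(fields) < _DOMTBL_MIN_COLS:
                    raise ValueError(
                        f"expected >= {_DOMTBL_MIN_COLS} whitespace-separated "
                        f"columns, got {len(fields)}"
                    )
                pid = fields[0]
                evalue_col = 12 if config.evalue_column == "independent" else 6
                hit = DomainHit(
                    protein_id=pid,
                    genome_id=genome_id if genome_id is not None else _split_genome(pid),
                    pfam_acc=strip_pfam_version(fields[4]),
                    pfam_name=fields[3],
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                    bitscore=float(fields[13]),
                    evalue=float(fields[evalue_col]),
                )
        except ValueError as exc:
            raise IngestError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_domain_table_tsv(hits: Iterable[DomainHit], path: PathLike) -> None:
    """Write hits in the 7-column TSV dialect (plus the Pfam name)."""
    with open(path, "w") as fh:
        fh.write("# protein_id\tgenome_id\tpfam_acc\tenv_start\tenv_end\tbitscore\tevalue\tpfam_name\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.genome_id}\t{h.pfam_acc}\t{h.env_start}\t"
                f"{h.env_end}\t{h.bitscore!r}\t{h.evalue!r}\t{h.pfam_name}\n"
            )


def filter_domain_hits(
    hits: list[DomainHit], config: Optional[PipelineConfig] = None
) -> list[DomainHit]:
    """Apply the per-hit score filter: bitscore >= 50 and E-value <= 1e-17.

    Both bounds are inclusive.  Input order is preserved; the operation is
    idempotent and its output is always a subset of its input.
    """
    config = config or PipelineConfig()
    kept = [
        h
        for h in hits
        if h.bitscore >= config.min_bitscore and h.evalue <= config.max_evalue
    ]
    logger.debug(
        "score filter kept %d/%d hits (bitscore >= %g, evalue <= %g)",
        len(kept), len(hits), config.min_bitscore, config.max_evalue,
    )
    return kept


def build_protein_records(hits: Iterable[DomainHit]) -> list[ProteinRecord]:
    """Group hits into per-protein records, sorted by (genome, protein) id."""
    grouped: dict[tuple[str, str], list[DomainHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.genome_id, h.protein_id)].append(h)
    return [
        ProteinRecord(protein_id=pid, genome_id=gid, hits=hs)
        for (gid, pid), hs in sorted(grouped.items())
    ]


# --------------------------------------------------------------------------
# orthogroups
# --------------------------------------------------------------------------

def read_orthogroups(path: PathLike) -> list[Orthogroup]:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    The header row names the genomes; each data row is an orthogroup whose
    cells hold ``", "``-joined protein ids.  Duplicate orthogroup ids,
    proteins appearing in two orthogroups, and empty orthogroups are
    rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise IngestError(f"{path}: empty orthogroup file")
    header = lines[0].split("\t")
    genome_ids = header[1:]
    if not genome_ids:
        raise IngestError(f"{path}:1: header lists no genome columns")

    ogs: list[Orthogroup] = []
    seen_og: set[str] = set()
    protein_owner: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        og_id = cells[0]
        if og_id in seen_og:
            raise IngestError(f"{path}:{lineno}: duplicate orthogroup id {og_id!r}")
        seen_og.add(og_id)
        members: list[tuple[str, str]] = []
        for gid, cell in zip(genome_ids, cells[1:]):
            cell = cell.strip()
            if not cell:
                continue
            for pid in cell.split(", "):
                if pid in protein_owner:
                    raise IngestError(
                        f"{path}:{lineno}: protein {pid!r} already assigned "
                        f"to {protein_owner[pid]!r}"
                    )
                protein_owner[pid] = og_id
                members.append((pid, gid))
        if not members:
            raise IngestError(f"{path}:{lineno}: orthogroup {og_id!r} is empty")
        ogs.append(Orthogroup(og_id=og_id, members=members))
    return ogs


def write_orthogroups(ogs: Iterable[Orthogroup], genome_ids: list[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genome_ids) + "\n")
        for og in ogs:
            per_genome: dict[str, list[str]] = defaultdict(list)
            for pid, gid in og.members:
                per_genome[gid].append(pid)
            cells = [", ".join(per_genome.get(g, [])) for g in genome_ids]
            fh.write(og.og_id + "\t" + "\t".join(cells) + "\n")


def assign_orthogroups(
    protein_ids: Iterable[tuple[str, str]], ogs: list[Orthogroup]
) -> dict[str, str]:
    """Map every protein to its orthogroup id, giving singletons a
    pseudo-orthogroup ``singleton:<protein_id>``.

    A large share of proteins is typically left unassigned by orthology
    clustering; keeping them as size-1 groups preserves accounting without
    ever letting them pass a multi-genome filter.
    """
    owner: dict[str, str] = {}
    for og in ogs:
        for pid, _gid in og.members:
            owner[pid] = og.og_id
    for pid, _gid in protein_ids:
        if pid not in owner:
            owner[pid] = f"singleton:{pid}"
    return owner


# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------

_TAX_COLUMNS = ("genome_id", "species", "phylum", "clade", "order", "n_genes")


def read_taxonomy(path: PathLike) -> list[GenomeMeta]:
    """Read the genome metadata TSV (header row required)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise IngestError(f"{path}: empty taxonomy file")
    header = lines[0].split("\t")
    if tuple(header[:6]) != _TAX_COLUMNS:
        raise IngestError(
            f"{path}:1: expected columns {_TAX_COLUMNS}, got {tuple(header[:6])}"
        )
    idx = {name: i for i, name in enumerate(header)}

    def _opt(fields: list[str], col: str, cast):
        i = idx.get(col)
        if i is None or i >= len(fields) or fields[i] in ("", "NA"):
            return None
        return cast(fields[i])

    metas: list[GenomeMeta] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            meta = GenomeMeta(
                genome_id=fields[0],
                species=fields[1],
                phylum=fields[2],
                clade=fields[3],
                order=fields[4],
                n_genes=int(fields[5]),
                genome_size_bp=_opt(fields, "genome_size_bp", int),
                gc_percent=_opt(fields, "gc_percent", float),
                rip_fraction=_opt(fields, "rip_fraction", float),
            )
        except (IndexError, ValueError) as exc:
            raise IngestError(f"{path}:{lineno}: {exc}") from exc
        if meta.genome_id in seen:
            raise IngestError(f"{path}:{lineno}: duplicate genome_id {meta.genome_id!r}")
        seen.add(meta.genome_id)
        metas.append(meta)
    return metas


def write_taxonomy(metas: Iterable[GenomeMeta], path: PathLike) -> None:
    def _fmt(v) -> str:
        return "" if v is None else (f"{v:g}" if isinstance(v, float) else str(v))

    with open(path, "w") as fh:
        fh.write("\t".join(_TAX_COLUMNS + ("genome_size_bp", "gc_percent", "rip_fraction")) + "\n")
        for m in metas:
            fh.write(
                f"{m.genome_id}\t{m.species}\t{m.phylum}\t{m.clade}\t{m.order}\t"
                f"{m.n_genes}\t{_fmt(m.genome_size_bp)}\t{_fmt(m.gc_percent)}\t"
                f"{_fmt(m.rip_fraction)}\n"
            )


# --------------------------------------------------------------------------
# TE catalogue
# --------------------------------------------------------------------------

def read_te_catalogue(path: PathLike) -> TEDomainCatalogue:
    """Read the TE Pfam catalogue TSV: pfam_acc, role (te|excluded|host),
    curation_tier.

    ``host`` rows carry curation information for accessions that are
    neither TE-associated nor excluded.
    """
    path = Path(path)
    cat = TEDomainCatalogue()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("pfam_acc\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise IngestError(f"{path}:{lineno}: expected >= 2 columns")
        acc = strip_pfam_version(fields[0])
        role = fields[1].strip().lower()
        if role == "te":
            if acc in cat.excluded_accessions:
                raise IngestError(f"{path}:{lineno}: {acc} in both te and excluded sets")
            cat.te_accessions.add(acc)
        elif role == "excluded":
            if acc in cat.te_accessions:
                raise IngestError(f"{path}:{lineno}: {acc} in both te and excluded sets")
            cat.excluded_accessions.add(acc)
        elif role != "host":
            raise IngestError(f"{path}:{lineno}: unknown role {fields[1]!r}")
        if len(fields) > 2 and fields[2].strip():
            tier_str = fields[2].strip().upper()
            try:
                tier = CurationTier[tier_str]
            except KeyError as exc:
                raise IngestError(f"{path}:{lineno}: unknown curation tier {fields[2]!r}") from exc
            if acc in cat.curation and cat.curation[acc] is not tier:
                raise IngestError(f"{path}:{lineno}: conflicting curation for {acc}")
            cat.curation[acc] = tier
    return cat


def write_te_catalogue(cat: TEDomainCatalogue, path: PathLike) -> None:
    rows: list[tuple[str, str]] = [(a, "te") for a in sorted(cat.te_accessions)]
    rows += [(a, "excluded") for a in sorted(cat.excluded_accessions)]
    rows += [
        (a, "host")
        for a in sorted(set(cat.curation) - cat.te_accessions - cat.excluded_accessions)
    ]
    with open(path, "w") as fh:
        fh.write("pfam_acc\trole\tcuration_tier\n")
        for acc, role in rows:
            tier = cat.curation.get(acc)
            fh.write(f"{acc}\t{role}\t{tier.name if tier else ''}\n")


# --------------------------------------------------------------------------
# pfam2go
# --------------------------------------------------------------------------

_PFAM2GO = re.compile(
    r"^Pfam:(?P<acc>PF\d{5})(?:\.\d+)?\s+\S+\s+>\s+GO:.*?;\s*(?P<go>GO:\d{7})"
    r"(?:\s*;\s*(?P<ns>\S+))?\s*$"
)


def read_pfam2go(path: PathLike) -> GOAnnotation:
    """Read the pfam2go flat-text mapping.

    Lines look like ``Pfam:PF00270 DEAD > GO:ATP binding ; GO:0005524``.
    Fixtures may append a namespace token (``; MF`` / ``; BP`` / ``; CC``);
    the community file does not carry one, in which case MF is assumed.
    ``!`` and ``#`` lines are comments.
    """
    path = Path(path)
    mapping: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("!", "#")):
            continue
        m = _PFAM2GO.match(line)
        if not m:
            raise IngestError(f"{path}:{lineno}: unparseable pfam2go line")
        ns = m.group("ns") or "MF"
        if ns not in NAMESPACES:
            raise IngestError(f"{path}:{lineno}: unknown GO namespace {ns!r}")
        mapping[m.group("acc")].add((m.group("go"), ns))
    return GOAnnotation(mapping=dict(mapping))


def write_pfam2go(annotation: GOAnnotation, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("!pfam2go mapping (fixture dialect with namespace column)\n")
        for acc in sorted(annotation.mapping):
            for go_id, ns in sorted(annotation.mapping[acc]):
                fh.write(f"Pfam:{acc} {acc} > GO:term ; {go_id} ; {ns}\n")


# --------------------------------------------------------------------------
# cluster gene list
# --------------------------------------------------------------------------

def read_cluster_genes(path: PathLike) -> set[str]:
    """Read the flat list of gene-cluster member protein ids."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def write_cluster_genes(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
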