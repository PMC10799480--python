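"""End-to-end driver composing the screen's stages.

Order of operations: score filtering -> TE-status annotation and protein
classification -> orthogroup lift (>= 5 genomes) -> deep-conservation
promotion -> domain-order check -> gene-cluster exclusion -> curation.
Each stage is a pure function from :mod:`tefuse`'s modules; this driver
only wires file paths and carries the intermediate products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import conservation, enrichment, fusion, ingest, summarize
from .enrichment import EnrichmentResult
from .fusion import FusionOrthogroup, ProteinClassification
from .model import GenomeMeta, GOAnnotation, Orthogroup, PipelineConfig, TEDomainCatalogue
from .summarize import GenomeSummary


@dataclass
class PipelineResult:
    config: PipelineConfig
    classifications: list[ProteinClassification]
    fusion_orthogroups: list[FusionOrthogroup]
    orthogroups: list[Orthogroup]
    taxonomy: list[GenomeMeta]
    catalogue: TEDomainCatalogue
    genome_summaries: list[GenomeSummary]
    enrichment: list[EnrichmentResult] = field(default_factory=list)
    annotation: Optional[GOAnnotation] = None


def run_pipeline(
    bundle_dir: Union[str, Path],
    config: Optional[PipelineConfig] = None,
    with_enrichment: bool = True,
) -> PipelineResult:
    """Run the full screen on a bundle directory.

    The directory must hold ``domains.tsv`` (or a domtblout file named
    ``domains.domtblout``), ``orthogroups.tsv``, ``taxonomy.tsv``,
    ``te_catalogue.tsv`` and optionally ``pfam2go.txt`` and
    ``cluster_genes.txt`` — the layout written by
    :func:`tefuse.simulate.generate_bundle`.
    """
    bundle_dir = Path(bundle_dir)
    config = config or PipelineConfig()

    domains_path = bundle_dir / "domains.tsv"
    if not domains_path.exists():
        domains_path = bundle_dir / "domains.domtblout"
    hits = ingest.read_domain_table(domains_path, config=config)
    hits = ingest.filter_domain_hits(hits, config)
    proteins = ingest.build_protein_records(hits)

    orthogroups = ingest.read_orthogroups(bundle_dir / "orthogroups.tsv")
    taxonomy = ingest.read_taxonomy(bundle_dir / "taxonomy.tsv")
    catalogue = ingest.read_te_catalogue(bundle_dir / "te_catalogue.tsv")

    classifications = fusion.classify_proteins(proteins, catalogue, config)
    fogs = fusion.collect_fusion_orthogroups(
        classifications, orthogroups, taxonomy, config
    )
    fogs = conservation.apply_conservation_filter(fogs, taxonomy, config)
    fogs = conservation.check_domain_orders(fogs, config)
    cluster_path = bundle_dir / "cluster_genes.txt"
    if cluster_path.exists():
        cluster_genes = ingest.read_cluster_genes(cluster_path)
        fogs = conservation.exclude_cluster_candidates(
            fogs, cluster_genes, taxonomy, config
        )
    fogs = conservation.apply_curation(fogs, catalogue, config)

    summaries = summarize.per_genome_stats(classifications, taxonomy)

    results: list[EnrichmentResult] = []
    annotation: Optional[GOAnnotation] = None
    pfam2go_path = bundle_dir / "pfam2go.txt"
    if with_enrichment and pfam2go_path.exists():
        annotation = ingest.read_pfam2go(pfam2go_path)
        results = enrich_fusion_genes(
            classifications, proteins, annotation, config
        )

    return PipelineResult(
        config=config,
        classifications=classifications,
        fusion_orthogroups=fogs,
        orthogroups=orthogroups,
        taxonomy=taxonomy,
        catalogue=catalogue,
        genome_summaries=summaries,
        enrichment=results,
        annotation=annotation,
    )


def enrich_fusion_genes(
    classifications: list[ProteinClassification],
    proteins,
    annotation: GOAnnotation,
    config: PipelineConfig,
) -> list[EnrichmentResult]:
    """GO over-representation of fusion candidates against a subsampled
    background of all genes."""
    from .model import ProteinLabel

    selected = {
        c.protein_id
        for c in classifications
        if c.label is ProteinLabel.FUSION_CANDIDATE
    }
    all_ids = [p.protein_id for p in proteins]
    background = enrichment.sample_background(
        all_ids, config.background_fraction, config.rng_seed
    )
    gene2go = enrichment.map_genes_to_go(proteins, annotation)
    return enrichment.hypergeom_enrichment(selected, background, gene2go, config)
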