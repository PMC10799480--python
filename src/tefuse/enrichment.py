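"""GO-term over-representation of fusion genes via the hypergeometric test.

Genes receive GO terms through the pfam2go translation of their retained
Pfam hits.  The universe is a random subsample of all genes (1% by
default, to keep the test tractable at millions of genes) united with the
tested gene set, so tested genes are never missing from their own
universe.  Per namespace and term, the one-sided upper-tail hypergeometric
p-value is

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

with N the universe size, K the term's annotated genes in the universe,
n the tested set size and k the overlap.  Significance follows a raw
p-value cutoff (1e-10) and a minimum term size (20), without
multiple-testing correction; a Benjamini-Hochberg column is reported for
reference only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import false_discovery_control, hypergeom

from .model import GOAnnotation, PipelineConfig
from .fusion import ProteinClassification


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    namespace: str
    universe_size: int  # N
    term_size: int      # K, annotated genes in universe
    selected_size: int  # n
    overlap: int        # k
    p_value: float
    significant: bool
    fdr_bh: float = float("nan")


def sample_background(
    all_gene_ids: Iterable[str], fraction: float, seed: int
) -> set[str]:
    """Uniform sample without replacement of ``round(fraction * N)`` genes.

    Deterministic under a fixed seed regardless of input ordering.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"background fraction {fraction} outside (0, 1]")
    ids = sorted(set(all_gene_ids))
    k = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=k, replace=False)
    return {ids[i] for i in picked}


def map_genes_to_go(
    proteins: Iterable[ProteinClassification] | Iterable,
    annotation: GOAnnotation,
) -> dict[str, set[tuple[str, str]]]:
    """Union of GO terms over each gene's Pfam hits.

    Accepts protein classifications or protein records — anything with a
    ``protein_id`` and a ``hits`` or ``te_hits``/``host_hits`` attribute.
    Genes with no mapped term carry the empty set.
    """
    gene2go: dict[str, set[tuple[str, str]]] = {}
    for p in proteins:
        hits = getattr(p, "hits", None)
        if hits is None:
            hits = list(getattr(p, "te_hits", [])) + list(getattr(p, "host_hits", []))
        terms: set[tuple[str, str]] = set()
        for h in hits:
            terms |= annotation.terms_for(h.pfam_acc)
        gene2go[p.protein_id] = terms
    return gene2go


def propagate_to_ancestors(
    gene2go: Mapping[str, set[tuple[str, str]]],
    parents: Mapping[str, set[str]],
    namespaces: Optional[Mapping[str, str]] = None,
) -> dict[str, set[tuple[str, str]]]:
    """Close each gene's annotation over the is-a parent map.

    ``parents`` maps a GO id to its direct parents; ancestors inherit the
    child's namespace unless ``namespaces`` overrides them.
    """
    # transitive closure per term, memoised
    closure: dict[str, set[str]] = {}

    def ancestors(go_id: str) -> set[str]:
        if go_id in closure:
            return closure[go_id]
        closure[go_id] = set()  # cycle guard
        anc: set[str] = set()
        for p in parents.get(go_id, ()):
            anc.add(p)
            anc |= ancestors(p)
        closure[go_id] = anc
        return anc

    out: dict[str, set[tuple[str, str]]] = {}
    for gene, terms in gene2go.items():
        full = set(terms)
        for go_id, ns in terms:
            for a in ancestors(go_id):
                full.add((a, namespaces.get(a, ns) if namespaces else ns))
        out[gene] = full
    return out


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail p-value P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    selected: set[str],
    background: set[str],
    gene2go: Mapping[str, set[tuple[str, str]]],
    config: Optional[PipelineConfig] = None,
    parents: Optional[Mapping[str, set[str]]] = None,
) -> list[EnrichmentResult]:
    """Test every annotated GO term for over-representation in ``selected``.

    The universe is ``selected | background``.  Results are sorted by
    p-value ascending, ties broken by GO id, and are byte-stable for a
    fixed input.
    """
    config = config or PipelineConfig()
    universe = selected | background
    missing = selected - universe
    if missing:  # cannot happen by construction; guards future refactors
        raise ValueError(f"selected genes outside universe: {sorted(missing)[:5]}")

    annot = {g: gene2go.get(g, set()) for g in universe}
    if parents:
        annot = propagate_to_ancestors(annot, parents)

    term_genes: dict[tuple[str, str], set[str]] = defaultdict(set)
    for gene, terms in annot.items():
        for go_id, ns in terms:
            term_genes[(go_id, ns)].add(gene)

    N = len(universe)
    n = len(selected)
    results: list[EnrichmentResult] = []
    for (go_id, ns), genes in term_genes.items():
        K = len(genes)
        k = len(genes & selected)
        p = hypergeom_pvalue(N, K, n, k)
        results.append(
            EnrichmentResult(
                go_id=go_id,
                namespace=ns,
                universe_size=N,
                term_size=K,
                selected_size=n,
                overlap=k,
                p_value=p,
                significant=(p <= config.go_p_cutoff and K >= config.go_min_term_size),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.go_id, r.namespace))
    if results:
        fdr = false_discovery_control([r.p_value for r in results], method="bh")
        results = [
            EnrichmentResult(**{**r.__dict__, "fdr_bh": float(q)})
            for r, q in zip(results, fdr)
        ]
    return results


def write_enrichment_table(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("namespace\tgo_id\tN\tK\tn\tk\tp_value\tfdr_bh\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.namespace}\t{r.go_id}\t{r.universe_size}\t{r.term_size}\t"
                f"{r.selected_size}\t{r.overlap}\t{r.p_value:.12g}\t"
                f"{r.fdr_bh:.12g}\t{int(r.significant)}\n"
            )


def read_go_parents(path) -> dict[str, set[str]]:
    """Read an optional GO parent-map TSV (child_go, parent_go)."""
    parents: dict[str, set[str]] = defaultdict(set)
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("child_go\t"):
            continue
        child, parent = line.split("\t")[:2]
        parents[child].add(parent)
    return dict(parents)
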