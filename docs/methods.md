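# Methods

This note records the screen's model, its tunable parameters, the
numerical and design choices made where the rules admit more than one
reading, and what the synthetic data do and do not establish.

## The screen

The unit of evidence is a Pfam domain hit: one profile-HMM match on one
protein, carried with envelope coordinates (1-based, inclusive), the
domain bitscore and the sequence-level independent E-value.  Envelope
coordinates are used for all interval arithmetic because they bound the
region plausibly covered by the domain, which is what physical
overlap between two annotations is about; intervals are converted to
half-open form only inside the arithmetic.  Hits survive filtering at
bitscore ≥ 50 **and** E-value ≤ 1e-17, both bounds inclusive ("minimal"
and "maximal" read as attainable).

A protein is classified from its filtered, catalogue-annotated hits:

* accessions in the TE catalogue are TE evidence;
* accessions flagged as merely *similar* to TE families (per an external
  profile–profile comparison) are invisible on both sides — they
  neither qualify a protein as TE-bearing nor count as host evidence;
* everything else is host evidence.

A fusion candidate needs both kinds of evidence and an admissible
overlap structure.  The overlap fraction of a TE/host pair is the shared
residue count over the length of the *shorter* hit — the most
conservative denominator against nested double-annotations, since a
domain fully contained in another always scores 1.0 (the denominator is
switchable: `shorter` | `longer` | `protein` span).  "More than 5%" is
strict: a pair sharing exactly 5% is admissible.

Two removal scopes are implemented.  The default `gene` scope removes
the protein when **any** TE/host pair exceeds the bound (the literal
reading of "filter out genes if the domains overlap").  The `pair`
scope disqualifies only inadmissible pairs and keeps the gene while some
pair is admissible.  The scopes differ only for proteins with ≥ 3
domains on mixed sides.  A consequence worth recording: the candidate
set is monotone in the score-filter thresholds only under the `pair`
scope.  Under the `gene` scope, raising the bitscore floor can *rescue*
a gene by deleting a low-scoring overlapping hit while an independent
clean TE copy survives — the unit test
`test_gene_scope_is_stricter_than_pair_scope` constructs the
counterexample.  The property suite therefore asserts score-threshold
monotonicity under the `pair` scope, overlap-threshold monotonicity
under both scopes, and retained-hit monotonicity unconditionally.

## Orthogroup lift and tiers

Candidates are aggregated by orthogroup; proteins unassigned by the
orthology clustering become singleton pseudo-orthogroups (they can never
pass a multi-genome filter, but accounting stays exact).  Genomes are
counted as distinct genome ids, never member counts, so paralogs do not
inflate spread.  Tiers form a lattice:

| tier | requirement (all inclusive bounds) |
|---|---|
| `RAW` | ≥ 1 fusion member |
| `MIN5` | ≥ 5 genomes, and (strict mode) ≥ 1 TE and ≥ 1 host accession shared by *all* fusion members |
| `CONSERVED20` | ≥ 20 genomes and ≥ 5 genomes in one order |
| `CURATED` | anchors unambiguous per the curation catalogue |

The shared-accession ("anchor") requirement operationalises a fusion
being *consistently found across all orthologs*; an `any` anchor mode
relaxes it to any TE + any host per member.  Promotion to `CURATED`
starts from `CONSERVED20` so the tiers stay strictly nested — the
manual-curation step could equally be read as starting from the ≥ 5
genome set, but a non-nested tier would make every downstream
set-comparison ambiguous.  Curation is mechanised as catalogue tiers
(`UNAMBIGUOUS_TE`, `AMBIGUOUS_TE`, `UNAMBIGUOUS_HOST`, …), so the human
judgement is versioned input rather than irreproducible procedure.

**Domain order.**  An orthogroup's order is conserved when every fusion
member realises the same relative order for every (anchor TE, anchor
host) accession pair; a member whose duplicate TE copies straddle the
host anchor is internally inconsistent and violates conservation by
itself.  Full-architecture identity is deliberately *not* required —
auxiliary domains vary widely within genuine fusion families — and a
`majority` strictness (≥ 50% of members agree) is available.  The check
sets a flag rather than demoting, so the information survives later
stages; the "effective" conserved set excludes flagged orthogroups.

**Gene clusters.**  Members inside predicted biosynthetic gene clusters
are removed at the protein level (physical proximity of clustered genes
can mimic fusion signals in annotation pipelines); genome counts and
tiers are recomputed and a demoted orthogroup is flagged.  The operation
is idempotent.

## Enrichment

GO terms reach genes through pfam2go over the genes' retained hits.
The universe is a uniform `background_fraction` subsample (default 1%,
mirroring what is tractable at millions of genes) **united with** the
tested set, so tested genes are never absent from their own universe —
the alternative (background only) silently truncates `k` whenever the
sample misses tested genes.  The test is the exact one-sided upper-tail
hypergeometric; significance is a raw p ≤ 1e-10 with term size ≥ 20 and
no multiple-testing correction, matching the convention the screen is
built around; a Benjamini–Hochberg column is emitted for reference but
never affects the significance call.  Optional ancestor propagation
closes annotations over a provided GO parent map before testing.

## Tree clustering (med_clade)

Leaves of a rooted tree with branch lengths are partitioned into the
minimum number of clades such that each clade's median pairwise
patristic distance is ≤ the threshold.  The implementation is an exact
dynamic program: a node either forms one cluster (if its clade is
feasible) or delegates to its children; since any partition of a
subtree's leaves into clades either uses the subtree root or splits
cleanly across children, the recursion attains the global minimum, and
taking the feasible node when available is optimal because every cover
costs ≥ 1.  Ties therefore never arise on cost; where the same minimum
could be realised by different cuts, the shallowest (left-most in
post-order) feasible clade wins.  The median is the standard midpoint
convention for even pair counts.  Correctness is tested against
exhaustive enumeration of all clade partitions on random 6–8-leaf trees.

Sequence utilities used ahead of external alignment/tree steps: protein
QC keeps sequences starting with methionine and free of internal stop
codons — a single terminal `*` is treated as a translation artifact and
stripped, not disqualifying — and the alignment gap filter removes rows
with strictly more than 20% gaps, never touching columns.

## Synthetic data

The generator emits a full input bundle — domain table, orthogroups,
taxonomy, TE catalogue, pfam2go, cluster list, Yule genome tree, FASTA,
truth table — with planted fusion orthogroups and decoys.  Default
scale: 2 phyla × 2 orders × (8, 8, 7, 7) genomes = 30 genomes, 60–90
genes per genome, 10 planted orthogroups (4 `MIN5`, 3 `CONSERVED20`,
3 `CURATED`), 5 decoys per class.  Choices that matter:

* planted TE/host pairs are disjoint or overlap in (0, 5%] with
  probability 0.2 (`p_edge_overlap`), so the boundary is exercised by
  construction;
* synthetic accessions use a reserved `PF9xxxx` range and cannot collide
  with real catalogues;
* each decoy violates exactly one rule: e.g. the below-20 decoy still
  satisfies the 5-per-order condition, and the scrambled-order decoy
  satisfies both genome bounds, so each filter's effect is observable in
  isolation;
* two genomes are kept free of fusion candidates and assigned RIP
  coverage above 10%, reflecting that RIP-heavy genomes suppress the
  duplications fusions arise from;
* the planted GO term is attached to the planted orthogroups' dedicated
  host anchors (and, at a configurable low rate, to background
  families); synthetic TE families carry no GO terms, as pfam2go leaves
  most TE-specific families unannotated;
* all randomness flows from one seed; identical parameters give
  byte-identical bundles.

The generator emulates the *statistical structure* the screen consumes —
architectures, orthogroup spread, taxonomy, annotation — and none of the
biology underneath: sequences are random strings, the tree is not
inferred from them, there is no insertion-age signal, no RIP mutational
process, no annotation noise (hits are emitted only where intended), and
no partial-domain degradation.  Passing the recovery tests therefore
shows the *rules are implemented exactly as stated*, not that the rules
have any particular sensitivity or specificity on real proteomes, where
domain annotation error and orthology mis-clustering dominate.

## Problem sizes and numerics

The standard test scale (30 genomes, ~2,300 genes, ~4,500 hits) runs the
full pipeline in well under a second and keeps exhaustive oracles exact:
hypergeometric p-values are checked against complete enumeration for
N ≤ 12 and against 100,000-draw Monte-Carlo estimates (within 3 standard
errors) for N ≤ 50; tree clustering against complete clade-partition
enumeration for ≤ 8 leaves.  Headline counts from genome-panel studies
at the thousand-genome scale (tens of thousands of fusion proteins,
hundreds of orthogroups) are functions of the input genomes and domain
models and are not reproduced by synthetic data; the acceptance script
reports the quantities the pipeline actually computes at the scale it
runs.

Known limitations: no support for circular permutations or split
domains when comparing domain order; overlap uses envelope coordinates
only (alignment coordinates would be slightly tighter); enrichment
treats genes, not orthogroups, as sampling units; med_clade assumes a
rooted tree and non-negative branch lengths.
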