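# Methods

## The typing model

A strain's Rgp genotype is determined by two independent PCR panels run on
its genome sequence. `rgptyper` replaces the thermocycler with approximate
string matching:

* **Primer annealing.** A primer of length *k* binds wherever it aligns
  ungapped with at most `max_mismatch` mismatches and its 3′-terminal
  `exact_3prime` bases matching with zero mismatches. The 3′ constraint
  models the polymerase's intolerance of terminal mismatches; internal
  mismatches merely destabilise annealing. IUPAC degeneracy codes on
  either side match iff their expansion sets intersect, which is
  deliberately permissive toward ambiguous assembly bases. Matching is
  implemented as vectorised bitmask comparisons over all windows
  (numpy), identical by construction on both strands.
* **Amplicons.** A product is any convergent placement of the two primers
  of a pair on opposite strands, in either orientation, with length
  measured inclusively from the first base of the upstream site to the
  last base of the downstream site — the convention in which the scheme's
  expected sizes are stated. Products never span contigs.
* **Panels.** A pair is *amplified* iff at least one product lies within
  `expected × (1 ± size_tolerance)`; a panel is valid iff its control pair
  is amplified. Amplified pairs whose size-concordant products map to
  more than one location are flagged *ambiguous* (the scheme assumes
  single-copy targets).

Defaults: `max_mismatch = 0` (wet-lab mismatch tolerance is not
quantified anywhere usable, so the strict setting is the honest one),
`exact_3prime = 3`, `size_tolerance = 0.10` (a gel-resolution surrogate).
All three are configurable on the API and the CLI.

Calling is a direct translation of the published decision rules: exactly
one Var product → that variable type; none (with valid control) →
`untypeable`; more than one → `ambiguous`; likewise for Fg pairs and
backbone types. Definite Vt + Bt yields a binomial name looked up in the
observed-combination table, anything outside it is `novel`. The one
asymmetric rule is Rgp5: Bt3 with an untypeable variable region is
reported as group 5 with `tentative = True`, because the panel cannot
distinguish "variable region absent" (Rgp5) from "variable region present
but unmatched by any Var pair" (a novel variable type). Ambiguous calls
never propagate into a binomial. The legacy single-step caller returns a
group only when exactly one group pair amplified; it structurally cannot
emit Rgp5 (no such pair exists) and inherits the published inability to
separate groups 1/6/7 and 2/2A.

Distribution summaries use half-up decimal rounding (2 decimals by
default, 1-decimal mode for comparisons against older reports). Half-up
is the mode that reproduces the published percentages; percentages sum to
100 up to accumulated rounding error.

## Locus extraction

The locus is the ordered run of genes strictly between two anchors — the
30S ribosomal-protein gene on the variable side and a transcriptional
regulator on the backbone side. Anchors are located by local protein
alignment of user-supplied queries against the annotated proteome; a gene
qualifies at ≥ `min_id` percent identity with ≥ `min_cov` percent of the
*query* covered (50/50 by default — the same contract as family
construction, kept single for the whole package), the best score wins and
coordinate order breaks ties. If the anchors appear in descending
coordinate order the gene list is flipped, so extraction is invariant to
the strand the locus happens to be assembled on. Anchor protein sequences
are not published as text; the fixture generator's anchors double as
working queries, and real genomes need user-supplied ones. For bare FASTA
a naive ORF fallback exists (ATG-initiated, ≥100 codons, standard code),
clearly flagged lower-confidence: it may extend a gene to an upstream
in-frame ATG and knows nothing of pseudogenes.

## Family construction and clustering

All-vs-all local alignment (BLOSUM62, gap open 11 / extend 1, via
Biopython's PairwiseAligner) yields percent identity (identities over
alignment columns, gaps included) and per-sequence coverage (aligned
residues over sequence length). An edge passes at ≥50 % identity with
both coverages ≥50 %; the `coverage_mode="either"` flag relaxes this to
one sequence, the closest operational reading of a query-only coverage
criterion for a symmetric aligner. Families are connected components of
the pass graph by default; Markov clustering (expansion 2, configurable
inflation defaulting to 2.0) is available and agrees with components on
well-separated graphs. Native alignment with the 50/50 criterion applied
directly replaces a BLAST prefilter at this scale; an exact shared-5-mer
prefilter skips alignment of pairs that share no 5-mer word — such pairs
fail 50/50 with overwhelming probability, but the prefilter can be
disabled (`prefilter=False`) for exhaustive behaviour near the decision
boundary. Sorting proteins canonically before graph construction makes
the partition input-order invariant.

Loci are compared as binary presence/absence vectors over family columns,
clustered hierarchically with Jaccard distance and average linkage (the
original analysis named the clustering tool but not its metric; Jaccard +
average is the natural choice for sparse binary profiles and is fixed
here for determinism). Flat clusters are cut at a target count or a
height; dendrograms export as Newick.

## Structure knowledge base

The genotype→structure link is an empirical result, so it is shipped as a
curated static table, not computed. Confidence is `elucidated` for groups
1, 2, 3, 4 and 6 (NMR-determined in representative strains),
`predicted` for group 7 (a UDP-galactopyranose mutase gene in its
variable region predicts a Galf-containing side chain), `unknown` for 2A
and 5. Backbone repeats and disaccharide side chains are stored residue
by residue and render to linear strings (`-2-α-Rha-3-α-Rha-`,
`β-Gal-3-β-GalNAc`) that round-trip through the parser; the branched
tetrasaccharide side chains of groups 1/2/6/7 are stored as composition +
branch residue only, their full linkage assignments living in the source
studies' supplementary data. The glucose found in group-1/6 backbones
(and predicted for group 7) is recorded as a flag rather than a repeat
position. `check_consistency` is informational: an *n*-residue side
chain needs at least *n − 1* elongating glycosyltransferases in the
variable region (the priming transferase contributes the first residue);
loci without functional annotations, or models without a known side-chain
size, skip the check with a warning.

## The fixture generator

Fixtures emulate exactly what the pipeline reads: anchor genes flanking a
variable-then-backbone gene neighbourhood, priming sites at scheme-exact
spacings (Var sites inside the variable region, Fg sites near *rgpF*, the
MSControl sites 2,724 bp apart around a DNA-primase placeholder, legacy
sites downstream), and a roster of 28 planted protein families assigned
per genotype following the published locus architectures — shared
backbone machinery (rgpA–D), the three *rgpF* alleles, *rgpE* in groups
2/2A/3/4/5 versus the three-gene central block of 1/6/7, two diverged
priming-transferase (WpsA-like) families, genotype-specific variable
genes, and the vestigial genotype-5 variable region with its two
oligosaccharyltransferase-like genes. Genotype 5 plants no Var sites and
no legacy site.

Family seed proteins are fixed (generated once from internal constants,
independent of the user seed), so family identity is stable across
strains and sessions; each strain carries copies mutated at
`mutation_rate` substitutions per site (default 0.02, giving intra-family
identities around 96 % — comfortably above the 50/50 criterion — while
independently generated families sit near random-background similarity,
far below it) and reverse-translated with random synonymous codons.
Intergenic filler is random DNA at ~39 % GC, the *S. thermophilus*-like
composition. After assembly the genome is verified to contain each
planted priming site exactly once and no site of any other scheme primer
(a failure redraws the filler; with 18–22-mers this is vanishingly rare).
A fixed `FixtureSpec` therefore yields byte-identical FASTA/GFF3/FAA.

What fixtures do **not** emulate: real gene sequences and lengths, operon
structure, partial primer-site matches in off-target genotypes (e.g. a
real Rgp2A genome carrying a degenerate Var1 target), pseudogenes,
fragmented assemblies. Passing round-trip tests therefore demonstrates
the correctness of the scheme logic and the search machinery, not the
wet-lab sensitivity of the primers on field strains.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen as the package's
own defaults: fixture genomes of ~15–22 kb; five seeds per genotype for
round-trip typing; three replicate loci per genotype (21 loci, ~260
proteins) for family recovery and co-clustering; 100 seeded random
sequences of 0.5–20 kb, against an independent pure-Python
sliding-window oracle, for PCR search equivalence. The published
78-genome comparison (49 gene families) requires external genome
downloads and is out of scope; the property-based fixture-recovery tests
stand in for it. Ties in anchor location break by coordinate; family
labels are assigned by first member id; scipy's linkage is deterministic
given row order. Degenerate inputs are defined errors: empty collections,
empty proteomes, sequences with non-IUPAC characters and malformed scheme
files all raise typed exceptions rather than returning empty results.
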