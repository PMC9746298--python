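# rgptyper

In-silico Rgp typing and *rgp*-locus comparison for *Streptococcus
thermophilus*.

## The problem

The rhamnose-glucose polysaccharide (Rgp) is the major cell-wall
polysaccharide of *S. thermophilus* and the receptor for several dairy
phages, which makes the Rgp genotype of a strain directly relevant to
starter-culture design. Rgp is encoded by the bipartite *rgp* locus: a
variable 5′ region specifying the decorative side chain and a more
conserved 3′ region specifying the rhamnan backbone (keyed on the divergent
rhamnosyltransferase gene *rgpF*). The two halves mix and match across
strains, so a strain is properly described by **two** genotypes:

* the **variable type** Vt1–Vt5, called by multiplex PCR 1 (pairs
  Var1–Var5 targeting genotype-specific variable-region genes), and
* the **backbone type** Bt1–Bt3, called by multiplex PCR 2 (pairs Fg1–Fg3
  targeting the three *rgpF* alleles),

combined into a binomial name V*i*B*j* that maps to an overall Rgp group.
Seven combinations have been observed (V1B1→1, V1B2→2, V2B2→2A, V3B2→3,
V3B3→4, V4B1→6, V5B1→7); the eight unobserved combinations are reported as
`novel`. Backbone type 3 with no variable-region product is the signature
of Rgp5, whose variable region is vestigial — such strains are reported as
group 5, *tentative*. Both panels share a control pair (MSControl,
2,724 bp) targeting the DNA-primase gene adjacent to the locus; the older
single-step panel (RGPgroup1–4 plus the RGPpos 801-bp control) is also
implemented, with its known limitations (it lumps groups 1/6/7 together and
2A with 2, and cannot detect Rgp5 at all).

`rgptyper` runs this whole typing system *in silico* on genome assemblies:
primer-site search with IUPAC degeneracy and bounded mismatches (3′ ends
exact), convergent amplicon enumeration, panel evaluation with a fractional
size tolerance, genotype calling, and collection-level distribution
summaries. It also reimplements the comparative side of the scheme —
extraction of the locus between its two anchor genes (30S ribosomal protein
and a transcriptional regulator), gene families under the bidirectional
50 %-identity / 50 %-coverage criterion, binary presence/absence matrices,
and hierarchical clustering (Jaccard distance, average linkage) — and ships
a curated knowledge base linking each genotype to its elucidated or
predicted Rgp chemical architecture (e.g. group 4: trisaccharide rhamnan
repeat `-3-α-Rha-2-α-Rha-2-α-Rha-` carrying `β-Gal-3-β-GalNAc` side chains
at variable positions).

A deterministic fixture generator (`rgptyper.fixtures`) produces synthetic
genomes for every genotype with planted anchors, priming sites at
scheme-exact spacings and genotype-specific gene families; it is the test
substrate for the whole pipeline and is exposed as `rgptyper simulate`.

## Worked example

```
$ rgptyper simulate --collection "1:1,3:1,5:1" --seed 1 -o genomes
wrote 3 genomes + truth.tsv to genomes

$ rgptyper type --legacy genomes/*.fasta
strain   vt          bt   binomial  group  tentative  structure_confidence  branch_residue  legacy_group
SYN1-01  Vt1         Bt1  V1B1      1      False      elucidated            GlcNAc          1
SYN3-01  Vt3         Bt2  V3B2      3      False      elucidated            GalNAc          3
SYN5-01  untypeable  Bt3            5      True       unknown                               unassigned
```

Reading the output: the genotype-1 genome gives the Var1 (895 bp), Fg1
(1,481 bp) and MSControl (2,724 bp) products, hence Vt1 + Bt1 = V1B1 =
group 1, with a GlcNAc-branched side chain in the structure model. The
genotype-5 genome yields no Var product but the Fg3 (852 bp) product, the
tentative-Rgp5 signature; the legacy panel, which has no Rgp5 primer pair,
leaves it `unassigned`. Structure models are available directly:

```
$ rgptyper structure 4
group                  4
backbone_repeat        -3-α-Rha-2-α-Rha-2-α-Rha-
backbone_contains_glc  False
side_chain             β-Gal-3-β-GalNAc
...
```

Locus comparison takes one protein FASTA per locus and writes the family
table, the presence/absence matrix and a Newick dendrogram:

```
$ rgptyper compare locus1.faa locus3.faa locus6.faa -k 3 -o cmp
```

## Layout

```
src/rgptyper/
  scheme_db.py            typing scheme: primers, panels, genotype maps
  data/scheme_v1.tsv      the bundled 14-pair scheme definition
  insilico_pcr.py         binding-site search, amplicon prediction, panels
  genotype_caller.py      Vt/Bt calls, binomial names, legacy calls, summaries
  locus_tools.py          anchor location, locus extraction, ORF fallback
  family_clustering.py    50/50 families, presence/absence, HCL, MCL
  structure_predictor.py  genotype -> Rgp architecture knowledge base
  fixtures.py             deterministic synthetic-genome generator
  cli.py                  rgptyper type / extract-locus / compare / structure / simulate
```
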