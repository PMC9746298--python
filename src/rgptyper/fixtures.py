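"""Deterministic synthetic rgp-locus fixtures for every genotype.

Each generated genome is one contig laid out like a real *rgp*
neighbourhood:

* a DNA-primase placeholder gene carrying the MSControl priming sites at
  exactly the expected control-product spacing (2,724 bp);
* the 30S ribosomal-protein anchor gene, then the variable (5') region,
  then the backbone (3') region, then the transcriptional-regulator anchor
  gene;
* the genotype's multiplex-1 (Var) priming sites inside the variable
  region and multiplex-2 (Fg) sites inside the backbone region, spaced so
  the inclusive amplicon equals the scheme's expected size — genotype 5
  plants no Var sites, emulating its vestigial variable region;
* the legacy classification sites (RGPpos plus the genotype's RGPgroup
  pair, where one exists) downstream of the locus.

Locus genes are drawn from a fixed roster of protein families: every
family has an immutable seed protein (generated from a fixed internal
seed, independent of the user seed) and each strain carries a copy mutated
at ``mutation_rate`` substitutions per site, then reverse-translated with
random synonymous codons.  Intergenic filler is random DNA at ~39% GC
(S. thermophilus-like).  After assembly the genome is checked to contain
every planted primer site exactly once and no spurious site of any other
scheme primer; a fixed seed therefore yields byte-identical output.

What these fixtures do not emulate: real gene sequences, operon structure,
pseudogenes, or assembly artefacts — they are a controlled substrate for
round-trip testing, not genome simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .insilico_pcr import reverse_complement
from .locus_tools import GeneRecord
from .scheme_db import TypingScheme, load_scheme

_SALT = 0x52475053  # stable stream-derivation constant

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG"]


@dataclass(frozen=True)
class FamilyDef:
    label: str
    region: str  # variable | backbone | flank
    product: str
    aa_len: int


# the planted gene-family roster; order fixes the seed-protein streams
FAMILY_DEFS: tuple[FamilyDef, ...] = (
    FamilyDef("rgpI", "variable", "branching-frequency regulator glycosyltransferase RgpI", 280),
    FamilyDef("rmlD", "variable", "dTDP-L-rhamnose biosynthesis reductase RmlD", 260),
    FamilyDef("wpsA_a", "variable", "side-chain priming glycosyltransferase (WpsA homolog, GlcNAc-type)", 220),
    FamilyDef("wpsA_b", "variable", "side-chain priming glycosyltransferase (WpsA homolog, GalNAc-type)", 220),
    FamilyDef("scbC", "variable", "side-chain glycosyltransferase ScbC", 250),
    FamilyDef("scbD", "variable", "side-chain glycosyltransferase ScbD", 240),
    FamilyDef("scbE", "variable", "side-chain glycosyltransferase ScbE", 230),
    FamilyDef("vt2_gt", "variable", "variable-region glycosyltransferase (GT2 family)", 240),
    FamilyDef("vt2_flp", "variable", "Wzx-like side-chain flippase", 300),
    FamilyDef("vt3_gt", "variable", "variable-region glycosyltransferase", 240),
    FamilyDef("vt3_flp", "variable", "Wzx-like side-chain flippase", 300),
    FamilyDef("vt4_gt", "variable", "large multidomain variable-region glycosyltransferase", 320),
    FamilyDef("vt4_flp", "variable", "Wzx-like side-chain flippase", 300),
    FamilyDef("vt5_glf", "variable", "UDP-galactopyranose mutase Glf", 270),
    FamilyDef("vt5_gt", "variable", "variable-region glycosyltransferase", 240),
    FamilyDef("cen_gt", "backbone", "large multidomain glycosyltransferase", 340),
    FamilyDef("cen_duf", "backbone", "DUF2142 domain polytopic membrane protein", 260),
    FamilyDef("cen_rgpE2", "backbone", "putative rhamnan-capping glycosyltransferase (RgpE-like)", 250),
    FamilyDef("rgpE", "backbone", "rhamnan-capping glycosyltransferase RgpE", 250),
    FamilyDef("rgpA", "backbone", "rhamnosyltransferase RgpA", 290),
    FamilyDef("rgpB", "backbone", "rhamnosyltransferase RgpB", 280),
    FamilyDef("rgpC", "backbone", "rhamnan ABC transporter permease RgpC", 270),
    FamilyDef("rgpD", "backbone", "rhamnan ABC transporter ATP-binding protein RgpD", 260),
    FamilyDef("rgpF1", "backbone", "rhamnosyltransferase RgpF (backbone genotype 1)", 310),
    FamilyDef("rgpF2", "backbone", "rhamnosyltransferase RgpF (backbone genotype 2)", 310),
    FamilyDef("rgpF3", "backbone", "rhamnosyltransferase RgpF (backbone genotype 3)", 310),
    FamilyDef("osc1", "backbone", "oligosaccharyltransferase-like polytopic membrane protein", 320),
    FamilyDef("osc2", "backbone", "oligosaccharyltransferase-like polytopic membrane protein 2", 300),
    # flanking placeholders (outside the locus, not part of family analysis)
    FamilyDef("anchor_30S", "flank", "30S ribosomal protein (locus anchor)", 140),
    FamilyDef("anchor_reg", "flank", "transcriptional regulator (locus anchor)", 190),
    FamilyDef("primase", "flank", "DNA primase", 600),
)

_DEF_BY_LABEL = {d.label: d for d in FAMILY_DEFS}

#: ordered gene content per genotype (variable region first, then backbone)
GENOTYPE_GENES: dict[str, tuple[str, ...]] = {
    "1": ("rgpI", "rmlD", "wpsA_a", "scbC", "scbD", "scbE",
          "cen_gt", "cen_duf", "cen_rgpE2", "rgpA", "rgpB", "rgpC", "rgpD", "rgpF1"),
    "2": ("rgpI", "rmlD", "wpsA_a", "scbC", "scbD", "scbE",
          "rgpA", "rgpB", "rgpC", "rgpD", "rgpE", "rgpF2"),
    "2A": ("rgpI", "rmlD", "wpsA_b", "vt2_gt", "vt2_flp",
           "rgpA", "rgpB", "rgpC", "rgpD", "rgpE", "rgpF2"),
    "3": ("rgpI", "rmlD", "wpsA_b", "vt3_gt", "vt3_flp",
          "rgpA", "rgpB", "rgpC", "rgpD", "rgpE", "rgpF2"),
    "4": ("rgpI", "rmlD", "wpsA_b", "vt3_gt", "vt3_flp",
          "rgpA", "rgpB", "rgpC", "rgpD", "rgpE", "rgpF3"),
    "5": ("rmlD",
          "rgpA", "rgpB", "rgpC", "rgpD", "rgpE", "rgpF3", "osc1", "osc2"),
    "6": ("rgpI", "rmlD", "wpsA_a", "vt4_gt", "vt4_flp",
          "cen_gt", "cen_duf", "cen_rgpE2", "rgpA", "rgpB", "rgpC", "rgpD", "rgpF1"),
    "7": ("rgpI", "rmlD", "wpsA_a", "vt5_glf", "vt5_gt",
          "cen_gt", "cen_duf", "cen_rgpE2", "rgpA", "rgpB", "rgpC", "rgpD", "rgpF1"),
}

GENOTYPE_VAR_PAIR = {"1": "Var1", "2": "Var1", "2A": "Var2", "3": "Var3",
                     "4": "Var3", "5": None, "6": "Var4", "7": "Var5"}
GENOTYPE_FG_PAIR = {"1": "Fg1", "2": "Fg2", "2A": "Fg2", "3": "Fg2",
                    "4": "Fg3", "5": "Fg3", "6": "Fg1", "7": "Fg1"}
# the legacy single-step panel lumps 1/6/7 together and 2A with 2
GENOTYPE_LEGACY_PAIR = {"1": "RGPgroup1", "2": "RGPgroup2", "2A": "RGPgroup2",
                        "3": "RGPgroup3", "4": "RGPgroup4", "5": None,
                        "6": "RGPgroup1", "7": "RGPgroup1"}

_GENOTYPES = tuple(GENOTYPE_GENES)


def _seed_protein(index: int, length: int) -> str:
    rng = np.random.default_rng([_SALT, 7, index])
    return "M" + "".join(rng.choice(AA20, size=length - 1))


#: immutable per-family seed proteins (independent of the user seed)
SEED_PROTEINS: dict[str, str] = {
    d.label: _seed_protein(i, d.aa_len) for i, d in enumerate(FAMILY_DEFS)
}

#: anchor queries for locus extraction on generated fixtures
ANCHOR_30S = SEED_PROTEINS["anchor_30S"]
ANCHOR_REGULATOR = SEED_PROTEINS["anchor_reg"]


@dataclass(frozen=True)
class FixtureSpec:
    genotype: str
    seed: int = 1
    mutation_rate: float = 0.02
    include_control: bool = True
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_GENES:
            raise InputError(
                f"unknown genotype {self.genotype!r}; expected one of {_GENOTYPES}"
            )
        if not (0.0 <= self.mutation_rate < 1.0):
            raise InputError("mutation_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """What was planted: the answer the pipeline must recover."""

    strain: str
    genotype: str
    vt: str | None
    bt: str
    binomial: str | None
    tentative: bool
    legacy_group: str | None
    families: tuple[str, ...]
    n_locus_genes: int


@dataclass
class Fixture:
    spec: FixtureSpec
    strain: str
    sequence: str
    genes: list[GeneRecord]
    truth: TruthRecord

    @property
    def locus_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.region in ("variable", "backbone")]

    def proteins(self) -> dict[str, str]:
        return {g.id: g.protein for g in self.genes}

    def genome_fasta(self) -> str:
        lines = [f">{self.strain}"]
        for i in range(0, len(self.sequence), 80):
            lines.append(self.sequence[i : i + 80])
        return "\n".join(lines) + "\n"

    def protein_fasta(self) -> str:
        lines = []
        for g in self.genes:
            lines.append(f">{g.id} {g.product}")
            for i in range(0, len(g.protein), 80):
                lines.append(g.protein[i : i + 80])
        return "\n".join(lines) + "\n"

    def gff3(self) -> str:
        lines = [
            "##gff-version 3",
            f"##sequence-region {self.strain} 1 {len(self.sequence)}",
        ]
        for g in self.genes:
            attrs = f"ID={g.id};product={g.product}"
            if g.region and g.region != "flank":
                attrs += f";region={g.region}"
            if "family" in g.extras:
                attrs += f";family={g.extras['family']}"
            lines.append(
                f"{self.strain}\trgptyper-sim\tgene\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}"
            )
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{self.strain}.fasta",
            "gff3": outdir / f"{self.strain}.gff3",
            "faa": outdir / f"{self.strain}.faa",
        }
        paths["fasta"].write_text(self.genome_fasta())
        paths["gff3"].write_text(self.gff3())
        paths["faa"].write_text(self.protein_fasta())
        return paths


def _mutate(protein: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return protein
    arr = np.array(list(protein))
    hit = rng.random(len(arr)) < rate
    hit[0] = False  # keep the initiator Met
    for i in np.flatnonzero(hit):
        choices = AA20[AA20 != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _filler(rng: np.random.Generator, n: int) -> str:
    # ~39% GC, S. thermophilus-like
    return "".join(
        rng.choice(np.array(list("ACGT")), size=n, p=[0.305, 0.195, 0.195, 0.305])
    )


class _Builder:
    def __init__(self, strain: str, rng: np.random.Generator, rate: float):
        self.strain = strain
        self.rng = rng
        self.rate = rate
        self.parts: list[str] = []
        self.pos = 0  # 0-based length so far
        self.genes: list[GeneRecord] = []
        self.n = 0

    def seq(self, s: str) -> None:
        self.parts.append(s)
        self.pos += len(s)

    def fill(self, n: int) -> None:
        self.seq(_filler(self.rng, n))

    def gene(self, label: str) -> GeneRecord:
        d = _DEF_BY_LABEL[label]
        protein = _mutate(SEED_PROTEINS[label], self.rate, self.rng)
        dna = _reverse_translate(protein, self.rng)
        self.n += 1
        rec = GeneRecord(
            id=f"{self.strain}_{self.n:04d}",
            contig=self.strain,
            start=self.pos + 1,
            end=self.pos + len(dna),
            strand="+",
            protein=protein,
            product=d.product,
            region=d.region,
            extras={"family": label},
        )
        self.seq(dna)
        self.genes.append(rec)
        return rec

    def amplicon_block(self, pair, inner_gene: str | None = None) -> None:
        """Plant fwd-site ... rc(rev-site) at exactly the expected spacing."""
        fwd = pair.forward.sequence
        rev_rc = reverse_complement(pair.reverse.sequence)
        inner = pair.expected_amplicon - len(fwd) - len(rev_rc)
        self.seq(fwd)
        if inner_gene is not None:
            d = _DEF_BY_LABEL[inner_gene]
            gene_len = 3 * (d.aa_len + 1)
            pad_a = (inner - gene_len) // 2
            if pad_a < 0:
                raise InputError(
                    f"gene {inner_gene} does not fit inside the "
                    f"{pair.name} amplicon"
                )
            self.fill(pad_a)
            self.gene(inner_gene)
            self.fill(inner - gene_len - pad_a)
        else:
            self.fill(inner)
        self.seq(rev_rc)

    def build(self) -> str:
        return "".join(self.parts)


def _planted_counts(spec: FixtureSpec, scheme: TypingScheme) -> dict[str, int]:
    planted = {}
    for name in filter(None, (
        GENOTYPE_VAR_PAIR[spec.genotype],
        GENOTYPE_FG_PAIR[spec.genotype],
        GENOTYPE_LEGACY_PAIR[spec.genotype],
        "RGPpos",
        "MSControl" if spec.include_control else None,
    )):
        planted[name] = 1
    return planted


def generate_locus(
    spec: FixtureSpec,
    scheme: TypingScheme | None = None,
    strain: str | None = None,
) -> Fixture:
    """One synthetic genome for *spec* (deterministic in the spec)."""
    if scheme is None:
        scheme = load_scheme()
    gidx = _GENOTYPES.index(spec.genotype)
    if strain is None:
        strain = f"SYN{spec.genotype}-{spec.replicate + 1:02d}"
    for attempt in range(8):
        rng = np.random.default_rng(
            [_SALT, gidx, spec.seed, spec.replicate, attempt]
        )
        b = _Builder(strain, rng, spec.mutation_rate)
        b.fill(300)
        if spec.include_control:
            b.amplicon_block(scheme.pair("MSControl"), inner_gene="primase")
            b.fill(200)
        b.gene("anchor_30S")
        b.fill(150)
        labels = GENOTYPE_GENES[spec.genotype]
        var_labels = [l for l in labels if _DEF_BY_LABEL[l].region == "variable"]
        bb_labels = [l for l in labels if _DEF_BY_LABEL[l].region == "backbone"]
        for label in var_labels:
            b.gene(label)
            b.fill(int(rng.integers(80, 150)))
        var_pair = GENOTYPE_VAR_PAIR[spec.genotype]
        if var_pair is not None:
            b.amplicon_block(scheme.pair(var_pair))
            b.fill(int(rng.integers(80, 150)))
        for label in bb_labels:
            b.gene(label)
            b.fill(int(rng.integers(80, 150)))
        b.amplicon_block(scheme.pair(GENOTYPE_FG_PAIR[spec.genotype]))
        b.fill(150)
        b.gene("anchor_reg")
        b.fill(200)
        b.amplicon_block(scheme.pair("RGPpos"))
        b.fill(100)
        legacy_pair = GENOTYPE_LEGACY_PAIR[spec.genotype]
        if legacy_pair is not None:
            b.amplicon_block(scheme.pair(legacy_pair))
        b.fill(300)
        sequence = b.build()
        if _sites_unique(sequence, spec, scheme):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not build a collision-free fixture")
    vt = scheme.vt_map[var_pair] if var_pair else None
    bt = scheme.bt_map[GENOTYPE_FG_PAIR[spec.genotype]]
    binomial = f"V{vt[2:]}B{bt[2:]}" if vt else None
    truth = TruthRecord(
        strain=strain,
        genotype=spec.genotype,
        vt=vt,
        bt=bt,
        binomial=binomial,
        tentative=spec.genotype == "5",
        legacy_group=scheme.legacy_map.get(legacy_pair) if legacy_pair else None,
        families=tuple(l for l in GENOTYPE_GENES[spec.genotype]),
        n_locus_genes=len(GENOTYPE_GENES[spec.genotype]),
    )
    return Fixture(spec=spec, strain=strain, sequence=sequence, genes=b.genes, truth=truth)


def _sites_unique(sequence: str, spec: FixtureSpec, scheme: TypingScheme) -> bool:
    """Every planted priming site occurs exactly once; nothing else occurs."""
    planted = _planted_counts(spec, scheme)
    for pair in scheme.pairs:
        want = planted.get(pair.name, 0)
        if sequence.count(pair.forward.sequence) != want:
            return False
        if sequence.count(reverse_complement(pair.reverse.sequence)) != want:
            return False
        if sequence.count(reverse_complement(pair.forward.sequence)) != 0:
            return False
        if sequence.count(pair.reverse.sequence) != 0:
            return False
    return True


def reverse_complement_fixture(fix: Fixture) -> Fixture:
    """The same fixture on the opposite strand (coordinates remapped)."""
    L = len(fix.sequence)
    genes = [
        replace(
            g,
            start=L - g.end + 1,
            end=L - g.start + 1,
            strand="-" if g.strand == "+" else "+",
        )
        for g in fix.genes
    ]
    genes.sort(key=lambda g: g.start)
    return Fixture(
        spec=fix.spec,
        strain=fix.strain,
        sequence=reverse_complement(fix.sequence),
        genes=genes,
        truth=fix.truth,
    )


def generate_collection(
    counts: Mapping[str, int],
    seed: int = 1,
    mutation_rate: float = 0.02,
    scheme: TypingScheme | None = None,
) -> tuple[list[Fixture], pd.DataFrame]:
    """*counts* fixtures per genotype, each an independent strain.

    Returns the fixtures and a truth table (one row per strain).
    """
    if not counts:
        raise InputError("empty genotype counts")
    if scheme is None:
        scheme = load_scheme()
    fixtures: list[Fixture] = []
    for genotype in sorted(counts, key=_GENOTYPES.index):
        n = counts[genotype]
        if n < 1:
            raise InputError(f"count for genotype {genotype} must be >= 1")
        for k in range(n):
            spec = FixtureSpec(
                genotype=genotype,
                seed=seed,
                mutation_rate=mutation_rate,
                replicate=k,
            )
            fixtures.append(generate_locus(spec, scheme=scheme))
    truth = pd.DataFrame(
        [
            {
                "strain": f.truth.strain,
                "genotype": f.truth.genotype,
                "vt": f.truth.vt or "",
                "bt": f.truth.bt,
                "binomial": f.truth.binomial or "",
                "tentative": f.truth.tentative,
                "legacy_group": f.truth.legacy_group or "",
                "n_locus_genes": f.truth.n_locus_genes,
            }
            for f in fixtures
        ]
    )
    return fixtures, truth
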