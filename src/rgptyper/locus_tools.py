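"""Locating and extracting the *rgp* locus from an annotated genome.

The locus is delimited by two conserved flanking anchor genes — a 30S
ribosomal-protein gene on the variable (5') side and a transcriptional
regulator gene on the backbone (3') side.  Anchors are located by local
protein alignment of user-supplied anchor query sequences against the
proteome (the same identity/coverage contract as gene-family construction,
50/50 by default), and the locus is the ordered run of genes strictly
between them.  If the anchors lie in descending coordinate order (the locus
sits on the reverse strand), the gene list is flipped so the variable
region always precedes the backbone region.

Annotation is the expected input (GFF3 plus proteins, either supplied or
translated from the genome).  For bare FASTA a naive ORF caller
(ATG-initiated, >=100 codons, standard code) is provided as a clearly
lower-confidence fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AnchorNotFoundError, InputError, SplitLocusError
from .family_clustering import pairwise_similarity


@dataclass
class GeneRecord:
    """One annotated gene (1-based inclusive coordinates)."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str
    product: str = ""
    region: str = ""  # variable | backbone | "" (unknown/other)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"gene {self.id}: start {self.start} > end {self.end}")


@dataclass
class RgpLocus:
    """Extracted locus: genes between the two anchors, anchors excluded."""

    strain: str
    genes: list[GeneRecord]
    contig: str
    span: tuple[int, int]  # 1-based inclusive, bounded by the anchors
    orientation_normalized: bool = False

    def proteins(self) -> dict[str, str]:
        return {g.id: g.protein for g in self.genes}


def read_genome(path: str | Path) -> dict[str, str]:
    """Multi-contig FASTA -> {contig id: sequence}."""
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise InputError(f"no FASTA records in {path}")
    return contigs


def read_annotation(
    gff_path: str | Path,
    genome: Mapping[str, str] | None = None,
    proteins: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Parse GFF3 gene/CDS features into :class:`GeneRecord` objects.

    Protein sequences come from *proteins* (id-keyed) when supplied,
    otherwise by translating the CDS span from *genome*.
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        fid = feat.attributes.get("ID", [feat.id])[0]
        if feat.featuretype == "CDS" and any(r.id == fid for r in records):
            continue
        protein = ""
        if proteins and fid in proteins:
            protein = proteins[fid]
        elif genome is not None and feat.seqid in genome:
            dna = genome[feat.seqid][feat.start - 1 : feat.end]
            if feat.strand == "-":
                dna = str(Seq(dna).reverse_complement())
            protein = str(Seq(dna).translate(to_stop=True))
        records.append(
            GeneRecord(
                id=fid,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or "+",
                protein=protein,
                product=feat.attributes.get("product", [""])[0],
                region=feat.attributes.get("region", [""])[0],
                extras={
                    k: v[0]
                    for k, v in feat.attributes.items()
                    if k not in ("ID", "product", "region")
                },
            )
        )
    if not records:
        raise InputError(f"no gene/CDS features in {gff_path}")
    return records


def locate_anchor(
    proteins: Sequence[GeneRecord],
    anchor_query: str,
    min_id: float = 50.0,
    min_cov: float = 50.0,
) -> GeneRecord:
    """Best gene matching *anchor_query* at >= min_id identity over
    >= min_cov percent of the query; deterministic tie-break by coordinate."""
    if not proteins:
        raise InputError("empty proteome")
    best: tuple[float, tuple, GeneRecord] | None = None
    for gene in proteins:
        if not gene.protein:
            continue
        edge = pairwise_similarity(
            anchor_query, gene.protein, "query", gene.id,
            min_id=min_id, min_cov=min_cov,
        )
        # coverage is assessed on the query; identity on the alignment
        if edge.identity < min_id or edge.coverage_a < min_cov:
            continue
        score = edge.identity * edge.coverage_a
        key = (gene.contig, gene.start, gene.id)
        if best is None or score > best[0] or (score == best[0] and key < best[1]):
            best = (score, key, gene)
    if best is None:
        raise AnchorNotFoundError(
            f"no gene reaches {min_id}% identity over {min_cov}% of the anchor query"
        )
    return best[2]


def extract_locus(
    records: Sequence[GeneRecord],
    anchors: tuple[str, str],
    min_id: float = 50.0,
    min_cov: float = 50.0,
    strain: str = "",
) -> RgpLocus:
    """Genes strictly between the two anchor genes, orientation-normalized.

    *anchors* is (variable-side query, backbone-side query) — the 30S
    ribosomal protein and the transcriptional regulator.  The gene list is
    ordered from the variable side to the backbone side regardless of the
    locus' strand in the assembly.
    """
    anchor_a = locate_anchor(records, anchors[0], min_id, min_cov)
    anchor_b = locate_anchor(records, anchors[1], min_id, min_cov)
    if anchor_a.contig != anchor_b.contig:
        raise SplitLocusError(
            f"anchors on different contigs ({anchor_a.contig} vs {anchor_b.contig})"
        )
    if anchor_a.id == anchor_b.id:
        raise AnchorNotFoundError("both anchor queries matched the same gene")
    lo, hi = sorted((anchor_a, anchor_b), key=lambda g: g.start)
    inside = [
        g
        for g in records
        if g.contig == anchor_a.contig
        and g.start > lo.end
        and g.end < hi.start
    ]
    inside.sort(key=lambda g: g.start)
    flipped = anchor_a.start > anchor_b.start
    if flipped:
        inside = inside[::-1]
    return RgpLocus(
        strain=strain,
        genes=inside,
        contig=anchor_a.contig,
        span=(lo.end + 1, hi.start - 1),
        orientation_normalized=flipped,
    )


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(
    contigs: Mapping[str, str],
    min_codons: int = 100,
) -> list[GeneRecord]:
    """Naive ORF fallback for unannotated FASTA (lower confidence).

    ATG-initiated, standard genetic code, >= *min_codons* codons, both
    strands; nested starts within a stop-bounded frame yield the longest
    ORF only.
    """
    warnings.warn(
        "using the naive ORF fallback; supply GFF3 annotation for "
        "confident locus extraction",
        stacklevel=2,
    )
    records: list[GeneRecord] = []
    n = 0
    for contig, seq in contigs.items():
        L = len(seq)
        for strand in ("+", "-"):
            s = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for frame in range(3):
                start_codon = None
                for i in range(frame, L - 2, 3):
                    codon = s[i : i + 3]
                    if codon == "ATG" and start_codon is None:
                        start_codon = i
                    elif codon in _STOPS and start_codon is not None:
                        length = (i + 3 - start_codon) // 3
                        if length - 1 >= min_codons:
                            n += 1
                            if strand == "+":
                                gs, ge = start_codon + 1, i + 3
                            else:
                                gs, ge = L - (i + 3) + 1, L - start_codon
                            records.append(
                                GeneRecord(
                                    id=f"orf{n:05d}",
                                    contig=contig,
                                    start=gs,
                                    end=ge,
                                    strand=strand,
                                    protein=str(Seq(s[start_codon:i]).translate()),
                                    product="predicted ORF (naive caller)",
                                    extras={"method": "naive-orf"},
                                )
                            )
                        start_codon = None
    records.sort(key=lambda g: (g.contig, g.start))
    return records


def locus_gene_table(locus: RgpLocus) -> str:
    """TSV rendering of an extracted locus."""
    lines = ["gene\tcontig\tstart\tend\tstrand\tregion\tproduct\tprotein_length"]
    for g in locus.genes:
        lines.append(
            f"{g.id}\t{g.contig}\t{g.start}\t{g.end}\t{g.strand}\t{g.region}"
            f"\t{g.product}\t{len(g.protein)}"
        )
    return "\n".join(lines) + "\n"
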