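"""Rgp genotype -> chemical-architecture knowledge base.

The link between an *rgp* genotype and the chemistry of the Rgp polymer it
produces is an empirical finding, not something computable from sequence, so
this module is a curated knowledge base rather than an algorithm.  Per
group it records the rhamnan backbone repeat unit, the decorative side
chain (composition, branch-point amino sugar, attachment position on the
backbone) and a confidence level:

* ``elucidated`` — structure determined by NMR/methylation analysis of a
  representative strain (groups 1, 2, 3, 4 and 6);
* ``predicted`` — inferred from locus gene content only (group 7, whose
  variable region carries a UDP-galactopyranose mutase gene, predicting a
  galactofuranose-containing side chain);
* ``unknown`` — no structural or confident predictive data (groups 2A and 5).

Residues use SNFG monosaccharide names; rendering uses a compact linear
notation, e.g. ``-2-α-Rha-3-α-Rha-`` for a disaccharide rhamnan repeat and
``β-Gal-3-β-GalNAc`` for a disaccharide side chain.  The exact linkages of
the branched tetrasaccharide side chains of groups 1/2/6 were determined in
the source studies' supplementary data; the KB stores their composition and
branch residue only.

:func:`check_consistency` is an informational cross-check of a locus
annotation against a model: building an *n*-residue side chain requires at
least *n − 1* elongating glycosyltransferases in the variable region (the
priming transferase puts the first residue on the lipid carrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError
from .scheme_db import RGP_GROUPS

MONOSACCHARIDES = ("Rha", "Glc", "Gal", "Galf", "GlcNAc", "GalNAc")
CONFIDENCE_LEVELS = ("elucidated", "predicted", "unknown")


@dataclass(frozen=True)
class GlycanResidue:
    """One monosaccharide in a repeat unit or side chain.

    ``linkage`` is the substitution position through which the chain
    continues (e.g. ``"2"`` in ``-2-α-Rha-``), or ``None`` for a terminal
    residue.
    """

    monosaccharide: str
    anomer: str  # "α" | "β"
    linkage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.monosaccharide not in MONOSACCHARIDES:
            raise InputError(f"unknown monosaccharide {self.monosaccharide!r}")
        if self.anomer not in ("α", "β"):
            raise InputError(f"anomer must be α or β, got {self.anomer!r}")


@dataclass(frozen=True)
class RgpStructureModel:
    group: str
    backbone_repeat: tuple[GlycanResidue, ...]
    backbone_contains_glc: Optional[bool]
    side_chain: Optional[tuple[GlycanResidue, ...]]
    #: number of residues in the side chain when only its size is known
    side_chain_size: Optional[int]
    branch_residue: Optional[str]
    attachment: Optional[str]
    confidence: str
    source_strain: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise InputError(f"bad confidence {self.confidence!r}")


def render_chain(residues: tuple[GlycanResidue, ...], repeat: bool = False) -> str:
    """Linear text rendering; ``repeat=True`` wraps the unit in dashes."""
    parts = []
    for r in residues:
        token = f"{r.anomer}-{r.monosaccharide}"
        if r.linkage:
            token = f"{r.linkage}-{token}" if repeat else token + f"-{r.linkage}"
        parts.append(token)
    if repeat:
        return "-" + "-".join(parts) + "-"
    # side chains read non-reducing -> reducing end: β-Gal-3-β-GalNAc
    out = parts[0]
    for r, token in zip(residues[1:], parts[1:]):
        out += f"-{r.linkage}-{r.anomer}-{r.monosaccharide}" if r.linkage else f"-{token}"
    return out


def parse_repeat(text: str) -> tuple[GlycanResidue, ...]:
    """Inverse of :func:`render_chain` for backbone repeat strings."""
    body = text.strip("-")
    tokens = body.split("-")
    if len(tokens) % 3:
        raise InputError(f"malformed repeat string {text!r}")
    residues = []
    for i in range(0, len(tokens), 3):
        linkage, anomer, mono = tokens[i : i + 3]
        residues.append(GlycanResidue(mono, anomer, linkage))
    return tuple(residues)


_RHA_DI = (  # -2-α-Rha-3-α-Rha-  (residue A then residue B)
    GlycanResidue("Rha", "α", "2"),
    GlycanResidue("Rha", "α", "3"),
)
_RHA_TRI = (  # -3-α-Rha-2-α-Rha-2-α-Rha-
    GlycanResidue("Rha", "α", "3"),
    GlycanResidue("Rha", "α", "2"),
    GlycanResidue("Rha", "α", "2"),
)
_GAL_GALNAC = (  # β-Gal-3-β-GalNAc disaccharide side chain
    GlycanResidue("Gal", "β"),
    GlycanResidue("GalNAc", "β", "3"),
)

STRUCTURE_KB: dict[str, RgpStructureModel] = {
    "1": RgpStructureModel(
        group="1",
        backbone_repeat=(),
        backbone_contains_glc=True,
        side_chain=None,
        side_chain_size=4,
        branch_residue="GlcNAc",
        attachment="rhamnan backbone (glucosylated)",
        confidence="elucidated",
        source_strain="UCCSt50",
        notes=(
            "Branched tetrasaccharide side chain with GlcNAc at the branch "
            "point; glucose-containing rhamnan backbone. Full linkage "
            "assignments were reported in the source-strain study."
        ),
    ),
    "2": RgpStructureModel(
        group="2",
        backbone_repeat=_RHA_DI,
        backbone_contains_glc=False,
        side_chain=None,
        side_chain_size=4,
        branch_residue="GlcNAc",
        attachment="position 4 of residue A (-2-α-Rha-)",
        confidence="elucidated",
        source_strain="UCCSt95",
        notes=(
            "Branched tetrasaccharide side chain (GlcNAc branch point, "
            "identical to the group-1 side chain); exact linkages in the "
            "supplementary assignments."
        ),
    ),
    "2A": RgpStructureModel(
        group="2A",
        backbone_repeat=(),
        backbone_contains_glc=None,
        side_chain=None,
        side_chain_size=None,
        branch_residue=None,
        attachment=None,
        confidence="unknown",
        source_strain="",
        notes="No representative strain has been analysed biochemically.",
    ),
    "3": RgpStructureModel(
        group="3",
        backbone_repeat=_RHA_DI,
        backbone_contains_glc=False,
        side_chain=_GAL_GALNAC,
        side_chain_size=2,
        branch_residue="GalNAc",
        attachment="position 2 of residue B (-3-α-Rha-)",
        confidence="elucidated",
        source_strain="UCCSt89",
        notes="Cell wall also carries an unrelated neutral polysaccharide (EPS).",
    ),
    "4": RgpStructureModel(
        group="4",
        backbone_repeat=_RHA_TRI,
        backbone_contains_glc=False,
        side_chain=_GAL_GALNAC,
        side_chain_size=2,
        branch_residue="GalNAc",
        attachment="position 2 of either 2-α-Rha residue (variable)",
        confidence="elucidated",
        source_strain="UCCSt12",
        notes=(
            "Side-chain attachment alternates between the two 2-linked "
            "rhamnoses; an additional putative EPS was detected."
        ),
    ),
    "5": RgpStructureModel(
        group="5",
        backbone_repeat=(),
        backbone_contains_glc=None,
        side_chain=None,
        side_chain_size=None,
        branch_residue=None,
        attachment=None,
        confidence="unknown",
        source_strain="N4L",
        notes=(
            "Variable region is vestigial; two oligosaccharyltransferase-like "
            "membrane-protein genes downstream of rgpF may modify the rhamnan."
        ),
    ),
    "6": RgpStructureModel(
        group="6",
        backbone_repeat=(),
        backbone_contains_glc=True,
        side_chain=None,
        side_chain_size=None,
        branch_residue="GlcNAc",
        attachment="rhamnan backbone (glucosylated)",
        confidence="elucidated",
        source_strain="St64987",
        notes=(
            "Glucose-containing rhamnan backbone; GlcNAc at the side-chain "
            "branch point; an EPS co-occurs in the cell wall."
        ),
    ),
    "7": RgpStructureModel(
        group="7",
        backbone_repeat=(),
        backbone_contains_glc=True,
        side_chain=None,
        side_chain_size=4,
        branch_residue="GlcNAc",
        attachment="rhamnan backbone (predicted glucosylated)",
        confidence="predicted",
        source_strain="CNRZ302",
        notes=(
            "Predicted tetrasaccharide side chain containing galactofuranose "
            "(Galf), from the UDP-galactopyranose mutase gene in the variable "
            "region; no biochemical structure available."
        ),
    ),
}


def predict_structure(group: str) -> RgpStructureModel:
    """Knowledge-base structure model for a concrete genotype label."""
    if group not in RGP_GROUPS:
        raise InputError(
            f"unknown Rgp group {group!r}; expected one of {', '.join(RGP_GROUPS)}"
        )
    return STRUCTURE_KB[group]


@dataclass
class ConsistencyReport:
    consistent: Optional[bool]  # None = skipped
    variable_gt_count: int
    required_gt_count: Optional[int]
    messages: list[str] = field(default_factory=list)


def _is_glycosyltransferase(gene) -> bool:
    text = " ".join(
        [getattr(gene, "product", "") or "", str(getattr(gene, "extras", {}) or {})]
    ).lower()
    return "glycosyltransferase" in text or "rhamnosyltransferase" in text


def check_consistency(locus, model: RgpStructureModel) -> ConsistencyReport:
    """Cross-check variable-region glycosyltransferase count against a model.

    Informational only: flags a mismatch when the locus encodes fewer
    variable-region glycosyltransferases than ``side-chain residues - 1``.
    Requires functionally annotated genes; otherwise the check is skipped
    with a warning message.
    """
    genes = list(getattr(locus, "genes", locus))
    annotated = [g for g in genes if getattr(g, "product", "")]
    if not annotated:
        return ConsistencyReport(
            consistent=None,
            variable_gt_count=0,
            required_gt_count=None,
            messages=["locus carries no functional annotations; check skipped"],
        )
    var_genes = [g for g in annotated if getattr(g, "region", "") == "variable"]
    gt_count = sum(1 for g in var_genes if _is_glycosyltransferase(g))
    n_res = model.side_chain_size
    if n_res is None and model.side_chain is not None:
        n_res = len(model.side_chain)
    if n_res is None:
        return ConsistencyReport(
            consistent=None,
            variable_gt_count=gt_count,
            required_gt_count=None,
            messages=[f"group {model.group}: side-chain size unknown; check skipped"],
        )
    required = n_res - 1
    ok = gt_count >= required
    msg = (
        f"group {model.group}: {gt_count} variable-region glycosyltransferase(s) "
        f"vs >= {required} required for a {n_res}-residue side chain"
    )
    return ConsistencyReport(
        consistent=ok,
        variable_gt_count=gt_count,
        required_gt_count=required,
        messages=[msg if ok else "INCONSISTENT: " + msg],
    )


def model_to_dict(model: RgpStructureModel) -> dict:
    """JSON-ready representation, with rendered structure strings."""
    return {
        "group": model.group,
        "backbone_repeat": (
            render_chain(model.backbone_repeat, repeat=True)
            if model.backbone_repeat
            else None
        ),
        "backbone_contains_glc": model.backbone_contains_glc,
        "side_chain": (
            render_chain(model.side_chain) if model.side_chain else None
        ),
        "side_chain_size": model.side_chain_size,
        "branch_residue": model.branch_residue,
        "attachment": model.attachment,
        "confidence": model.confidence,
        "source_strain": model.source_strain,
        "notes": model.notes,
    }
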