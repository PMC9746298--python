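"""Genotype calling from panel results.

Multiplex-1 products call the variable-chain type (Vt1–Vt5), multiplex-2
products call the rhamnan-backbone type (Bt1–Bt3), and the two combine into
a binomial name ``V{i}B{j}`` that maps to an overall Rgp group.  One special
case is built into the calling logic rather than the map: backbone type 3
with no variable-region product is the expected signature of an Rgp5 strain,
whose variable 5' region is too reduced to carry any multiplex-1 target —
such strains are reported as group 5 with ``tentative=True``, since PCR
alone cannot prove the variable region's absence.

The legacy single-step panel (RGPgroup1–4) is also supported; it cannot
distinguish groups 1, 6 and 7 (all yield the Rgp1 product) nor 2 from 2A,
and it has no product at all for Rgp5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .errors import AssayInvalidError, InputError
from .insilico_pcr import PanelResult, run_panel
from .scheme_db import TypingScheme

UNTYPEABLE = "untypeable"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class VariableCall:
    vt: str  # Vt1..Vt5 | untypeable | ambiguous
    evidence: tuple[tuple[str, int], ...] = ()  # (pair name, product length)


@dataclass(frozen=True)
class BackboneCall:
    bt: str  # Bt1..Bt3 | untypeable | ambiguous
    evidence: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class RgpCall:
    binomial: str | None
    group: str
    tentative: bool = False
    strain: str = ""
    vt: str = UNTYPEABLE
    bt: str = UNTYPEABLE


def _evidence(result: PanelResult, names: Iterable[str]) -> tuple[tuple[str, int], ...]:
    ev = []
    for name in names:
        for hit in result.per_pair.get(name, []):
            ev.append((name, hit.length))
    return tuple(ev)


def _call_panel(result: PanelResult, type_map, kind: str) -> tuple[str, tuple]:
    if not result.control_ok:
        raise AssayInvalidError(
            f"{result.panel}: control reaction failed; no {kind} call possible"
        )
    hit_pairs = sorted(p for p in result.amplified if p in type_map)
    evidence = _evidence(result, hit_pairs)
    if not hit_pairs:
        return UNTYPEABLE, evidence
    if len(hit_pairs) > 1 or (set(hit_pairs) & result.ambiguous):
        return AMBIGUOUS, evidence
    return type_map[hit_pairs[0]], evidence


def call_variable_type(result: PanelResult, scheme: TypingScheme) -> VariableCall:
    """Variable-chain type from a multiplex-1 panel result."""
    if result.panel != "multiplex1":
        raise InputError(f"expected a multiplex1 result, got {result.panel!r}")
    vt, ev = _call_panel(result, scheme.vt_map, "variable-type")
    return VariableCall(vt=vt, evidence=ev)


def call_backbone_type(result: PanelResult, scheme: TypingScheme) -> BackboneCall:
    """Rhamnan-backbone (rgpF) type from a multiplex-2 panel result."""
    if result.panel != "multiplex2":
        raise InputError(f"expected a multiplex2 result, got {result.panel!r}")
    bt, ev = _call_panel(result, scheme.bt_map, "backbone-type")
    return BackboneCall(bt=bt, evidence=ev)


def assign_binomial(
    vc: VariableCall,
    bc: BackboneCall,
    scheme: TypingScheme,
    strain: str = "",
) -> RgpCall:
    """Combine variable and backbone calls into a binomial name and group.

    Definite Vt + Bt gives ``V{i}B{j}``; combinations outside the observed
    table are ``novel``.  Untypeable variable region with Bt3 is the Rgp5
    signature (tentative).  Any other untypeable/ambiguous component leaves
    the strain ``unassigned``.
    """
    definite_vt = vc.vt not in (UNTYPEABLE, AMBIGUOUS)
    definite_bt = bc.bt not in (UNTYPEABLE, AMBIGUOUS)
    if definite_vt and definite_bt:
        binomial = f"V{vc.vt[2:]}B{bc.bt[2:]}"
        return RgpCall(
            binomial=binomial,
            group=scheme.group_for_binomial(binomial),
            strain=strain,
            vt=vc.vt,
            bt=bc.bt,
        )
    if vc.vt == UNTYPEABLE and bc.bt == "Bt3":
        return RgpCall(
            binomial=None, group="5", tentative=True, strain=strain,
            vt=vc.vt, bt=bc.bt,
        )
    return RgpCall(
        binomial=None, group="unassigned", strain=strain, vt=vc.vt, bt=bc.bt
    )


def legacy_call(result: PanelResult, scheme: TypingScheme) -> str:
    """Single-step legacy classification (Rgp1–Rgp4 only)."""
    if result.panel != "classification":
        raise InputError(f"expected a classification result, got {result.panel!r}")
    if not result.control_ok:
        raise AssayInvalidError("classification: positive control (801 bp) absent")
    hit_pairs = sorted(p for p in result.amplified if p in scheme.legacy_map)
    if len(hit_pairs) != 1:
        return "unassigned"
    return scheme.legacy_map[hit_pairs[0]]


def type_genome(
    genome,
    scheme: TypingScheme,
    strain: str = "",
    size_tolerance: float = 0.10,
    max_mismatch: int = 0,
    exact_3prime: int = 3,
) -> RgpCall:
    """Run both multiplex panels on a genome and return the combined call."""
    kw = dict(
        size_tolerance=size_tolerance,
        max_mismatch=max_mismatch,
        exact_3prime=exact_3prime,
    )
    m1 = run_panel(genome, scheme, "multiplex1", **kw)
    m2 = run_panel(genome, scheme, "multiplex2", **kw)
    vc = call_variable_type(m1, scheme)
    bc = call_backbone_type(m2, scheme)
    return assign_binomial(vc, bc, scheme, strain=strain)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_collection(
    calls: Sequence,
    by: str | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Distribution table (label, count, percent) over a collection of calls.

    *calls* may be plain labels or objects carrying the attribute named *by*
    (e.g. ``group``, ``vt``, ``bt`` of :class:`RgpCall`).  Percentages are
    half-up rounded to *decimals* places and always sum to 100 up to
    accumulated rounding error.
    """
    if len(calls) == 0:
        raise InputError("cannot summarize an empty collection")
    labels = [getattr(c, by) if by else c for c in calls]
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    df = pd.DataFrame(
        {
            "label": counts.index.astype(str),
            "count": counts.to_numpy(),
            "percent": [
                _round_half_up(100.0 * c / total, decimals) for c in counts.to_numpy()
            ],
        }
    )
    return df.sort_values(["count", "label"], ascending=[False, True]).reset_index(
        drop=True
    )
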