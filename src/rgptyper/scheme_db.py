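"""Typing-scheme database: primers, panels, genotype maps.

The two-step classification of *Streptococcus thermophilus* by its *rgp*
(rhamnose-glucose polysaccharide) locus rests on three PCR panels:

* ``classification`` — the legacy single-step panel (RGPpos control plus four
  group-specific pairs, Rgp1–Rgp4);
* ``multiplex1`` — five pairs (Var1–Var5) targeting unique genes of the
  variable side-chain (5') region, calling the variable type Vt1–Vt5;
* ``multiplex2`` — three pairs (Fg1–Fg3) targeting the divergent *rgpF*
  rhamnosyltransferase gene, calling the backbone type Bt1–Bt3.

A shared control pair (MSControl, targeting the conserved DNA-primase gene
adjacent to the locus) belongs to both multiplex panels.  Variable and
backbone types combine into a binomial name (e.g. ``V3B2``) which maps to an
overall Rgp group; the seven observed combinations are enumerated in the
scheme, and any combination outside that table is reported as ``novel``.

The bundled scheme ships as a flat, versioned, tab-separated text file
(``rgptyper/data/scheme_v1.tsv``); :func:`load_scheme` with no argument loads
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import SchemeError, SchemeLookupError, SchemeParseError

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

VARIABLE_TYPES = ("Vt1", "Vt2", "Vt3", "Vt4", "Vt5")
BACKBONE_TYPES = ("Bt1", "Bt2", "Bt3")

#: concrete genotype labels
RGP_GROUPS = ("1", "2", "2A", "3", "4", "5", "6", "7")
#: closed vocabulary for group calls
RGP_LABELS = RGP_GROUPS + ("novel", "unassigned")

#: the eight V x B combinations not observed in any typed strain
UNOBSERVED_BINOMIALS = (
    "V1B3", "V2B1", "V2B3", "V3B1", "V4B2", "V4B3", "V5B2", "V5B3",
)

PANELS = ("classification", "multiplex1", "multiplex2")
#: panel token marking the control pair shared by both multiplex panels
SHARED_MULTIPLEX = "multiplex"

SCHEME_FORMAT = "rgp-scheme/1"


@dataclass(frozen=True)
class Primer:
    """A single oligonucleotide, written 5'->3' over the IUPAC DNA alphabet."""

    name: str
    sequence: str
    role: str  # forward | reverse

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise SchemeError(f"primer {self.name}: bad role {self.role!r}")
        if not self.sequence:
            raise SchemeError(f"primer {self.name}: empty sequence")
        if not (15 <= len(self.sequence) <= 30):
            raise SchemeError(
                f"primer {self.name}: length {len(self.sequence)} outside 15-30 nt"
            )
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise SchemeError(
                f"primer {self.name}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its expected product size."""

    name: str
    forward: Primer
    reverse: Primer
    expected_amplicon: int
    target_groups: frozenset[str]
    panel: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.panel not in PANELS + (SHARED_MULTIPLEX,):
            raise SchemeError(f"pair {self.name}: unknown panel {self.panel!r}")
        if self.expected_amplicon <= len(self.forward) + len(self.reverse):
            raise SchemeError(
                f"pair {self.name}: amplicon {self.expected_amplicon} bp not "
                f"longer than the two primers combined"
            )
        unknown = self.target_groups - set(RGP_GROUPS)
        if unknown:
            raise SchemeError(
                f"pair {self.name}: unknown target groups {sorted(unknown)}"
            )


@dataclass(frozen=True)
class TypingScheme:
    """A validated scheme: primer pairs plus the genotype maps."""

    pairs: tuple[PrimerPair, ...]
    vt_map: Mapping[str, str]
    bt_map: Mapping[str, str]
    binomial_map: Mapping[str, str]
    legacy_map: Mapping[str, str]
    version: str = SCHEME_FORMAT
    _by_name: Mapping[str, PrimerPair] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_name", {p.name: p for p in self.pairs})
        self._validate()

    # -- lookups ---------------------------------------------------------

    def pair(self, name: str) -> PrimerPair:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemeLookupError(f"no primer pair named {name!r} in scheme") from None

    def expected_amplicon(self, pair_name: str) -> int:
        """Expected product size (bp) of *pair_name*."""
        return self.pair(pair_name).expected_amplicon

    def panel_pairs(self, panel: str) -> tuple[PrimerPair, ...]:
        """All pairs evaluated for *panel*, control included."""
        if panel not in PANELS:
            raise SchemeLookupError(f"unknown panel {panel!r}")
        members = [p for p in self.pairs if p.panel == panel]
        if panel in ("multiplex1", "multiplex2"):
            members += [p for p in self.pairs if p.panel == SHARED_MULTIPLEX]
        return tuple(members)

    def control_pair(self, panel: str) -> PrimerPair:
        controls = [p for p in self.panel_pairs(panel) if p.is_control]
        return controls[0]

    def group_for_binomial(self, binomial: str) -> str:
        """Rgp group for a V{i}B{j} name; combinations outside the observed
        table are ``novel``."""
        return self.binomial_map.get(binomial, "novel")

    @property
    def structure_kb(self):
        """Group -> :class:`~rgptyper.structure_predictor.RgpStructureModel`."""
        from .structure_predictor import STRUCTURE_KB

        return STRUCTURE_KB

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        names = [p.name for p in self.pairs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemeError(f"duplicate pair names: {sorted(dupes)}")
        for panel in PANELS:
            controls = [p for p in self.panel_pairs(panel) if p.is_control]
            if len(controls) != 1:
                raise SchemeError(
                    f"panel {panel}: expected exactly one control pair, "
                    f"found {len(controls)}"
                )
        for name in self.vt_map:
            if self.pair(name).panel != "multiplex1":
                raise SchemeError(f"vt_map entry {name} is not a multiplex1 pair")
        for name, vt in self.vt_map.items():
            if vt not in VARIABLE_TYPES:
                raise SchemeError(f"vt_map: bad variable type {vt!r}")
        for name, bt in self.bt_map.items():
            if self.pair(name).panel != "multiplex2":
                raise SchemeError(f"bt_map entry {name} is not a multiplex2 pair")
            if bt not in BACKBONE_TYPES:
                raise SchemeError(f"bt_map: bad backbone type {bt!r}")
        for p in self.pairs:
            if p.panel == "multiplex1" and not p.is_control and p.name not in self.vt_map:
                raise SchemeError(f"multiplex1 pair {p.name} missing from vt_map")
            if p.panel == "multiplex2" and not p.is_control and p.name not in self.bt_map:
                raise SchemeError(f"multiplex2 pair {p.name} missing from bt_map")
        for binomial, group in self.binomial_map.items():
            if group not in RGP_GROUPS:
                raise SchemeError(f"binomial_map: unknown group {group!r}")
            if not (len(binomial) == 4 and binomial[0] == "V" and binomial[2] == "B"):
                raise SchemeError(f"binomial_map: malformed name {binomial!r}")
        overlap = set(self.binomial_map) & set(UNOBSERVED_BINOMIALS)
        if overlap:
            raise SchemeError(
                f"binomial_map lists unobserved combinations: {sorted(overlap)}"
            )
        for name, group in self.legacy_map.items():
            if self.pair(name).panel != "classification" or self.pair(name).is_control:
                raise SchemeError(f"legacy_map entry {name} is not a classification pair")
            if group not in RGP_GROUPS:
                raise SchemeError(f"legacy_map: unknown group {group!r}")

    # -- serialization ---------------------------------------------------

    def dumps(self) -> str:
        """Serialize to the flat scheme text format (round-trips via loads)."""
        out = [f"# {self.version}", "[pairs]"]
        for p in self.pairs:
            targets = (
                "all" if set(p.target_groups) == set(RGP_GROUPS)
                else ",".join(sorted(p.target_groups))
            )
            out.append(
                "\t".join(
                    [
                        p.name,
                        p.panel,
                        "yes" if p.is_control else "no",
                        p.forward.sequence,
                        p.reverse.sequence,
                        str(p.expected_amplicon),
                        targets,
                    ]
                )
            )
        for section, mapping in (
            ("vt_map", self.vt_map),
            ("bt_map", self.bt_map),
            ("binomial_map", self.binomial_map),
            ("legacy_map", self.legacy_map),
        ):
            out.append(f"[{section}]")
            out.extend(f"{k}\t{v}" for k, v in mapping.items())
        return "\n".join(out) + "\n"

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())


def _bundled_scheme_text() -> str:
    return (resources.files("rgptyper.data") / "scheme_v1.tsv").read_text()


def loads(text: str) -> TypingScheme:
    """Parse a scheme definition from text. See :func:`load_scheme`."""
    section = None
    pairs: list[PrimerPair] = []
    maps: dict[str, dict[str, str]] = {
        "vt_map": {}, "bt_map": {}, "binomial_map": {}, "legacy_map": {},
    }
    seen_any = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        seen_any = True
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section != "pairs" and section not in maps:
                raise SchemeParseError(f"line {lineno}: unknown section {section!r}")
            continue
        if section is None:
            raise SchemeParseError(f"line {lineno}: record before any [section]")
        fields = line.split("\t")
        if section == "pairs":
            if len(fields) != 7:
                raise SchemeParseError(
                    f"line {lineno}: pair record needs 7 fields, got {len(fields)}"
                )
            name, panel, control, fwd, rev, amplicon, targets = fields
            try:
                size = int(amplicon)
            except ValueError:
                raise SchemeParseError(
                    f"line {lineno}: bad amplicon size {amplicon!r} for {name}"
                ) from None
            groups = (
                frozenset(RGP_GROUPS) if targets.lower() == "all"
                else frozenset(t.strip() for t in targets.split(",") if t.strip())
            )
            try:
                pairs.append(
                    PrimerPair(
                        name=name,
                        forward=Primer(f"{name}F", fwd.upper(), "forward"),
                        reverse=Primer(f"{name}R", rev.upper(), "reverse"),
                        expected_amplicon=size,
                        target_groups=groups,
                        panel=panel,
                        is_control=control.lower() in ("yes", "true", "1"),
                    )
                )
            except SchemeError as exc:
                raise SchemeParseError(f"line {lineno}: {exc}") from None
        else:
            if len(fields) != 2:
                raise SchemeParseError(
                    f"line {lineno}: {section} record needs 2 fields, got {len(fields)}"
                )
            key, value = fields
            if key in maps[section]:
                raise SchemeParseError(f"line {lineno}: duplicate {section} key {key!r}")
            maps[section][key] = value
    if not seen_any or not pairs:
        raise SchemeParseError("no primer pairs found (empty or truncated scheme file)")
    return TypingScheme(pairs=tuple(pairs), **maps)


def load_scheme(path: str | Path | None = None) -> TypingScheme:
    """Load and validate a typing scheme.

    With no argument the bundled scheme (all 14 pairs of the published
    classification + two-step multiplex system) is loaded.
    """
    if path is None:
        return loads(_bundled_scheme_text())
    p = Path(path)
    if not p.exists():
        raise SchemeParseError(f"scheme file not found: {p}")
    return loads(p.read_text())


def expected_amplicon(scheme: TypingScheme, pair_name: str) -> int:
    """Expected product size (bp) for *pair_name* in *scheme*."""
    return scheme.expected_amplicon(pair_name)
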