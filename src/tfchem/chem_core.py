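"""Molecular-formula arithmetic and diagnostic fragment-ion prediction.

The objects here describe the long-chain hydrocarbons found in insect
trophallactic fluid and on the cuticle: linear and methyl-branched alkanes
(and, as annotations only, alkenes, fatty acids, esters, an aldehyde and a
sterol-like component).  Under 70 eV electron-impact ionization a saturated
alkane fragments into the alkyl (CnH2n+1+) ladder; a methyl branch promotes
cleavage at the branch carbon, producing a pair of even-electron fragment
ions whose nominal masses invert directly to the branch locant.  For a
backbone of ``L`` carbons with a methyl group at carbon ``b`` the pair is

    m_low  = 14*b + 15          (branch-side secondary fragment)
    m_high = 14*(L - b + 2) + 1 (complement retaining the branch carbon)

and for a monomethyl alkane the two sum to the molecular mass + 28.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MolecularFormula",
    "HydrocarbonStructure",
    "ParsedCompound",
    "UnknownElementError",
    "UnsupportedStructureError",
    "NameParseError",
    "nominal_mass",
    "formula_of",
    "diagnostic_ions",
    "parse_compound_name",
    "format_structure",
    "alkane_name",
]

#: Integer (nominal) masses of the elements that occur in the compound table.
NOMINAL_ELEMENT_MASS = {"C": 12, "H": 1, "O": 16, "N": 14, "S": 32}


class UnknownElementError(ValueError):
    """Formula contains an element with no nominal mass on record."""


class UnsupportedStructureError(ValueError):
    """Operation is defined only for (saturated) pure hydrocarbons."""


class NameParseError(ValueError):
    """Compound name could not be parsed as a hydrocarbon."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map, e.g. ``C30H62``."""

    element_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts or all(c == 0 for c in counts.values()):
            raise ValueError("formula must contain at least one atom")
        if any(c < 0 or int(c) != c for c in counts.values()):
            raise ValueError("element counts must be non-negative integers")

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "MolecularFormula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n > 0))
        return cls(items)

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C16H32O2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            el, num = match.groups()
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = match.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_counts(counts)

    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.element_counts).get(element, 0)

    def __str__(self) -> str:
        counts = self.counts()
        # Hill order: C, H, then remaining elements alphabetically.
        ordered = [el for el in ("C", "H") if el in counts]
        ordered += sorted(el for el in counts if el not in ("C", "H"))
        return "".join(
            f"{el}{counts[el]}" if counts[el] != 1 else el for el in ordered
        )


def nominal_mass(formula: MolecularFormula) -> int:
    """Nominal (integer) molecular mass in Da."""
    total = 0
    for el, n in formula.element_counts:
        if el not in NOMINAL_ELEMENT_MASS:
            raise UnknownElementError(f"no nominal mass for element {el!r}")
        total += NOMINAL_ELEMENT_MASS[el] * n
    return total


def _canonical_locants(positions: tuple[int, ...], backbone: int) -> tuple[int, ...]:
    """Lowest-locant numbering: the lexicographically smaller of the two
    end-to-end numberings of the chain."""
    fwd = tuple(sorted(positions))
    rev = tuple(sorted(backbone + 1 - b for b in positions))
    return min(fwd, rev)


@dataclass(frozen=True)
class HydrocarbonStructure:
    """A (possibly methyl-branched) chain hydrocarbon.

    ``backbone_length`` counts the carbons of the main chain; each entry of
    ``branch_positions`` is the backbone carbon bearing a methyl group,
    numbered from the chain end that gives the lowest locants.  Entries in
    the compound table that are not hydrocarbons (acids, esters, the
    aldehyde, the sterol-like component) carry an ``other_class`` tag and
    support no fragment prediction.
    """

    backbone_length: int
    branch_positions: tuple[int, ...] = ()
    n_double_bonds: int = 0
    other_class: str | None = None

    def __post_init__(self) -> None:
        if self.other_class is not None:
            return
        L = self.backbone_length
        if L < 1:
            raise ValueError("backbone must have at least one carbon")
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be >= 0")
        pos = tuple(int(b) for b in self.branch_positions)
        if any(not (1 < b < L) for b in pos):
            raise ValueError(f"branch positions must satisfy 1 < b < {L}: {pos}")
        if len(set(pos)) != len(pos):
            raise ValueError("branch positions must be distinct")
        object.__setattr__(self, "branch_positions", _canonical_locants(pos, L))

    @property
    def n_branches(self) -> int:
        return len(self.branch_positions)

    @property
    def total_carbons(self) -> int:
        if self.other_class is not None:
            raise UnsupportedStructureError("not a pure hydrocarbon")
        return self.backbone_length + self.n_branches

    @property
    def is_saturated(self) -> bool:
        return self.n_double_bonds == 0

    def name(self) -> str:
        return format_structure(self)


def formula_of(structure: HydrocarbonStructure) -> MolecularFormula:
    """Molecular formula of a pure hydrocarbon: CnH(2n+2-2d)."""
    if structure.other_class is not None:
        raise UnsupportedStructureError(
            f"formula arithmetic only for hydrocarbons, got {structure.other_class!r}"
        )
    n = structure.total_carbons
    h = 2 * n + 2 - 2 * structure.n_double_bonds
    if h <= 0:
        raise ValueError("degree of unsaturation too high for chain length")
    return MolecularFormula.from_counts({"C": n, "H": h})


def diagnostic_ions(structure: HydrocarbonStructure) -> set[int]:
    """Predicted branch-diagnostic fragment ions (nominal m/z).

    For each methyl branch at backbone position ``b`` the cleavages flanking
    the branch carbon yield the even-electron pair ``14*b + 15`` and
    ``14*(L - b + 2) + 1``.  At the chain midpoint the two coincide.  An
    unbranched alkane has no diagnostic ions (empty set); alkenes are out of
    scope for fragment prediction.
    """
    if structure.other_class is not None or not structure.is_saturated:
        raise UnsupportedStructureError(
            "diagnostic ions are defined for saturated alkanes only"
        )
    L = structure.backbone_length
    ions: set[int] = set()
    for b in structure.branch_positions:
        ions.add(14 * b + 15)
        ions.add(14 * (L - b + 2) + 1)
    return ions


# --- IUPAC-style names -----------------------------------------------------

_STEMS = {
    1: "methane", 2: "ethane", 3: "propane", 4: "butane", 5: "pentane",
    6: "hexane", 7: "heptane", 8: "octane", 9: "nonane", 10: "decane",
    11: "undecane", 12: "dodecane", 13: "tridecane", 14: "tetradecane",
    15: "pentadecane", 16: "hexadecane", 17: "heptadecane", 18: "octadecane",
    19: "nonadecane", 20: "eicosane", 21: "heneicosane", 22: "docosane",
    23: "tricosane", 24: "tetracosane", 25: "pentacosane", 26: "hexacosane",
    27: "heptacosane", 28: "octacosane", 29: "nonacosane", 30: "triacontane",
    31: "hentriacontane", 32: "dotriacontane", 33: "tritriacontane",
    34: "tetratriacontane", 35: "pentatriacontane", 36: "hexatriacontane",
    37: "heptatriacontane", 38: "octatriacontane", 39: "nonatriacontane",
    40: "tetracontane",
}
_STEM_TO_CARBONS = {name[:-3]: n for n, name in _STEMS.items()}  # drop "ane"
_MULTIPLIERS = {"": 1, "di": 2, "tri": 3, "tetra": 4, "penta": 5}
_MULT_PREFIX = {v: k for k, v in _MULTIPLIERS.items()}


def alkane_name(n_carbons: int) -> str:
    """Name of the linear alkane with ``n_carbons`` carbons."""
    try:
        return _STEMS[n_carbons]
    except KeyError:
        raise ValueError(f"no alkane name on record for C{n_carbons}") from None


@dataclass(frozen=True)
class ParsedCompound:
    """Result of parsing a compound-table name.

    ``structure`` is populated only when the name pins down a full
    hydrocarbon structure; names with a leading ``*-`` (position unresolved)
    keep carbon/branch counts but ``ambiguous_positions=True``.
    """

    raw: str
    structure: HydrocarbonStructure | None = None
    total_carbons: int | None = None
    n_branches: int | None = None
    n_double_bonds: int | None = None
    ambiguous_positions: bool = False
    other_class: str | None = None
    note: str | None = None

    @property
    def is_hydrocarbon(self) -> bool:
        return self.other_class is None


_HC_NAME = re.compile(
    r"^(?:n-)?(?:(?P<loc>\*|\d+(?:,\d+)*)-)?"
    r"(?:(?P<mult>di|tri|tetra|penta)?methyl)?"
    r"(?P<stem>[a-z]+?)(?P<suffix>ane|ene)$",
    re.IGNORECASE,
)
_NOTE = re.compile(r"\s*\((likely|possibly)[^)]*\)\s*$", re.IGNORECASE)


def _classify_other(name: str) -> str:
    low = name.lower()
    if "cholesterol" in low or "sterol" in low:
        return "sterol-like"
    if "ester" in low or "ethyl" in low or "palmitate" in low or "oleate" in low:
        return "ester"
    if "acid" in low:
        return "fatty acid"
    if low.endswith("al"):
        return "aldehyde"
    return "other"


def parse_compound_name(name: str) -> ParsedCompound:
    """Parse a compound-table name into counts and, when possible, a structure.

    Handles linear alkanes/alkenes ("Tricosane", "*-pentacosene"),
    methyl-branched alkanes with resolved ("9-methylnonacosane",
    "5,9-dimethylhentriacontane") or starred positions
    ("*-trimethyltetratriacontane"), optional "(likely …)" annotations, and
    falls back to an annotated non-hydrocarbon record for everything else.
    """
    raw = name.strip()
    work = raw
    note = None
    m = _NOTE.search(work)
    if m:
        note = m.group(0).strip().strip("()")
        work = work[: m.start()].strip()
    if " or " in work:  # two alternative assignments printed side by side
        note = (note + "; " if note else "") + "alternative: " + work.split(" or ", 1)[1]
        work = work.split(" or ", 1)[0].strip()

    m = _HC_NAME.match(work)
    if m and m.group("stem").lower() in _STEM_TO_CARBONS:
        loc, mult, stem, suffix = (
            m.group("loc"), m.group("mult") or "", m.group("stem").lower(),
            m.group("suffix").lower(),
        )
        backbone = _STEM_TO_CARBONS[stem]
        has_methyl = bool(re.search(r"methyl", work, re.IGNORECASE))
        k = _MULTIPLIERS[mult.lower()] if has_methyl else 0
        d = 1 if suffix == "ene" else 0
        total = backbone + k
        if loc is None or loc == "*":
            ambiguous = loc == "*" or (k > 0)
            structure = None
            if k == 0 and d == 0:
                structure = HydrocarbonStructure(backbone_length=backbone)
                ambiguous = False
            return ParsedCompound(
                raw=raw, structure=structure, total_carbons=total, n_branches=k,
                n_double_bonds=d, ambiguous_positions=ambiguous, note=note,
            )
        positions = tuple(int(p) for p in loc.split(","))
        if len(positions) != max(k, 1):
            raise NameParseError(
                f"{raw!r}: {len(positions)} locants for {k} methyl branches"
            )
        if d == 0 and k > 0:
            structure = HydrocarbonStructure(
                backbone_length=backbone, branch_positions=positions
            )
            return ParsedCompound(
                raw=raw, structure=structure, total_carbons=total, n_branches=k,
                n_double_bonds=0, note=note,
            )
        # located double bond (does not occur in the table, but is well formed)
        return ParsedCompound(
            raw=raw, total_carbons=total, n_branches=k, n_double_bonds=d, note=note,
        )
    return ParsedCompound(raw=raw, other_class=_classify_other(work), note=note)


def format_structure(structure: HydrocarbonStructure, ambiguous: bool = False) -> str:
    """Render a hydrocarbon structure as a compound-table style name.

    Unresolved branch/double-bond positions are rendered with a leading
    ``*-`` as in the published table (``*-pentacosene``).
    """
    if structure.other_class is not None:
        raise UnsupportedStructureError("cannot format a non-hydrocarbon record")
    stem = alkane_name(structure.backbone_length)[:-3]
    suffix = "ene" if structure.n_double_bonds else "ane"
    k = structure.n_branches
    if k == 0:
        base = stem + suffix
        return f"*-{base}" if (ambiguous or structure.n_double_bonds) and suffix == "ene" else base.capitalize()
    mult = _MULT_PREFIX[k]
    if ambiguous:
        return f"*-{mult}methyl{stem}{suffix}"
    locants = ",".join(str(b) for b in structure.branch_positions)
    return f"{locants}-{mult}methyl{stem}{suffix}"
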