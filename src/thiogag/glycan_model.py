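"""Modified glycosaminoglycan chains: compositions, ion masses and enzyme cleavage.

Chains are ordered from the non-reducing to the reducing end. Residue
compositions are glycosyl units (monosaccharide minus water); a full chain
adds one water for the two termini. A thio-glycosidic linkage is accounted
for as a single O -> S substitution in the summed composition, so residue
tables stay in their all-oxygen form. Optional aglycones are stored as the
elemental composition of the radical that replaces the hydrogen of the
anomeric hydroxyl.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

from .constants import AVERAGE_MASS, MONOISOTOPIC_MASS, PROTON_MASS

Composition = dict[str, int]

__all__ = [
    "Composition",
    "CompositionError",
    "ResidueSpec",
    "Aglycone",
    "GlycanChain",
    "IonSpecies",
    "EnzymeRule",
    "HEPARANASE",
    "HEPARIN_LYASE",
    "elemental_composition",
    "composition_mass",
    "hill_formula",
    "parse_formula",
    "predicted_mz",
    "mass_shift",
    "cleave",
    "amac_label_mz",
    "parse_chain",
    "chain_to_string",
    "heparosan",
    "table1_product",
]


class CompositionError(ValueError):
    """Unknown residue/modification token or impossible composition."""


class CleavageError(ValueError):
    """Chain does not satisfy an enzyme rule's backbone preconditions."""


class LabelingError(ValueError):
    """Fragment cannot be reductively aminated (no free reducing end)."""


# ---------------------------------------------------------------------------
# elemental composition helpers
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Composition:
    """Parse a Hill-style formula string (e.g. ``C6H8O6``) into a count map."""
    comp: Composition = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise CompositionError(f"cannot parse formula {formula!r}")
        pos = m.end()
        comp[m.group(1)] = comp.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula) or not comp:
        raise CompositionError(f"cannot parse formula {formula!r}")
    return comp


def _add(a: Composition, b: Composition, sign: int = 1) -> Composition:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
        if out[el] < 0:
            raise CompositionError(f"negative count for element {el}")
        if out[el] == 0:
            del out[el]
    return out


def hill_formula(comp: Composition) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    order = [el for el in ("C", "H") if el in comp]
    order += sorted(el for el in comp if el not in ("C", "H"))
    return "".join(f"{el}{comp[el] if comp[el] != 1 else ''}" for el in order)


def composition_mass(comp: Composition, mass_type: str = "monoisotopic") -> float:
    """Neutral mass of a composition in Da."""
    table = {"monoisotopic": MONOISOTOPIC_MASS, "average": AVERAGE_MASS}.get(mass_type)
    if table is None:
        raise ValueError(f"unknown mass type {mass_type!r}")
    try:
        return sum(table[el] * n for el, n in comp.items())
    except KeyError as exc:
        raise CompositionError(f"no mass for element {exc.args[0]!r}") from None


WATER: Composition = {"H": 2, "O": 1}

# ---------------------------------------------------------------------------
# residues and modifications
# ---------------------------------------------------------------------------

#: Base glycosyl residues: composition (monosaccharide - H2O) and backbone class.
_BASE_RESIDUES: dict[str, tuple[str, str]] = {
    "GlcA": ("C6H8O6", "uronic"),
    "dUA": ("C6H6O5", "uronic"),
    "GlcNAc": ("C8H13NO5", "hexosamine"),
    "GlcN": ("C6H11NO4", "hexosamine"),
    "GlcNS": ("C6H11NO7S", "hexosamine"),
    "4SH-GlcNAc": ("C8H13NO4S", "hexosamine"),
}

_MOD_ALIASES = {
    "4S": "4-thio", "4SH": "4-thio", "4-thio": "4-thio",
    "NS": "N-sulfo", "N-sulfo": "N-sulfo",
    "2S": "2-O-sulfo", "2-O-sulfo": "2-O-sulfo",
    "6S": "6-O-sulfo", "6-O-sulfo": "6-O-sulfo",
    "unsat": "4,5-unsaturated", "4,5-unsaturated": "4,5-unsaturated",
    "NAc": "N-acetyl", "N-acetyl": "N-acetyl",
}

# short forms for serialization; long sulfo names would collide with the
# -O- linkage separator in the chain grammar
_MOD_SHORT = {
    "4-thio": "4S", "N-sulfo": "NS", "2-O-sulfo": "2S",
    "6-O-sulfo": "6S", "4,5-unsaturated": "unsat", "N-acetyl": "NAc",
}

_SO3: Composition = {"S": 1, "O": 3}
_ACETYL_DELTA: Composition = {"C": 2, "H": 2, "O": 1}  # GlcNAc = GlcN + C2H2O


def _apply_modification(comp: Composition, mod: str, base_name: str) -> Composition:
    if mod == "4-thio":
        if comp.get("O", 0) < 1:
            raise CompositionError("4-thio requires an oxygen to replace")
        comp = _add(comp, {"O": 1}, -1)
        return _add(comp, {"S": 1})
    if mod in ("2-O-sulfo", "6-O-sulfo"):
        return _add(comp, _SO3)
    if mod == "N-sulfo":
        # On an N-acetylated hexosamine the sulfo group replaces the acetyl.
        if base_name in ("GlcNAc", "4SH-GlcNAc"):
            comp = _add(comp, _ACETYL_DELTA, -1)
        return _add(comp, _SO3)
    if mod == "4,5-unsaturated":
        return _add(comp, WATER, -1)
    if mod == "N-acetyl":
        return _add(comp, _ACETYL_DELTA)
    raise CompositionError(f"unknown modification {mod!r}")


@dataclass(frozen=True)
class ResidueSpec:
    """A glycosyl residue with optional modifications applied on top."""

    name: str
    modifications: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.name not in _BASE_RESIDUES:
            raise CompositionError(f"unknown residue token {self.name!r}")
        canon = frozenset(_MOD_ALIASES.get(m, m) for m in self.modifications)
        for m in canon:
            if m not in _MOD_ALIASES.values():
                raise CompositionError(f"unknown modification {m!r}")
        object.__setattr__(self, "modifications", canon)
        self.composition  # validate (raises on impossible combinations)

    @classmethod
    def from_token(cls, token: str) -> "ResidueSpec":
        """Parse ``Name`` or ``Name@mod1,mod2``."""
        name, _, mods = token.partition("@")
        return cls(name, frozenset(m for m in mods.split(",") if m))

    @property
    def composition(self) -> Composition:
        comp = parse_formula(_BASE_RESIDUES[self.name][0])
        # deterministic application order: deacetylation-sensitive mods first
        for mod in sorted(self.modifications):
            comp = _apply_modification(comp, mod, self.name)
        return comp

    @property
    def residue_class(self) -> str:
        return _BASE_RESIDUES[self.name][1]

    def to_token(self) -> str:
        if not self.modifications:
            return self.name
        return f"{self.name}@{','.join(sorted(_MOD_SHORT[m] for m in self.modifications))}"


@dataclass(frozen=True)
class Aglycone:
    """Reducing-end aglycone as the radical replacing the anomeric-OH hydrogen."""

    name: str
    composition_formula: str

    @property
    def composition(self) -> Composition:
        return parse_formula(self.composition_formula)


#: Built-in aglycones (editable: construct Aglycone with any formula).
AGLYCONES: dict[str, Aglycone] = {
    "C2H4-amido-benzaldehyde": Aglycone("C2H4-amido-benzaldehyde", "C10H10NO2"),
    "C2H4-NH2": Aglycone("C2H4-NH2", "C2H6N"),
    # -CH2CH2-NH-C(=S)-NH-fluoresceinyl; the exact linker stoichiometry is a
    # documented editable default, not a validated literature value.
    "C2H4-thioamido-fluorescein": Aglycone("C2H4-thioamido-fluorescein", "C23H17N2O5S"),
}


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlycanChain:
    """Ordered residues (non-reducing -> reducing) with per-bond heteroatoms."""

    residues: tuple[ResidueSpec, ...]
    linkages: tuple[str, ...]
    aglycone: Aglycone | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("chain must contain at least one residue")
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "linkages", tuple(self.linkages))
        expected = len(self.residues) - 1 + (1 if self.aglycone else 0)
        if len(self.linkages) != expected:
            raise ValueError(
                f"expected {expected} linkages for {len(self.residues)} residues"
                f"{' + aglycone' if self.aglycone else ''}, got {len(self.linkages)}"
            )
        for het in self.linkages:
            if het not in ("O", "S"):
                raise ValueError(f"linkage heteroatom must be O or S, got {het!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_thio_linkages(self) -> int:
        return sum(1 for het in self.linkages if het == "S")


def elemental_composition(chain: GlycanChain) -> Composition:
    """Total elemental composition of a chain (plus aglycone if present).

    Sum of glycosyl residues + H2O for the termini; each S-linkage replaces
    one O by S; an aglycone contributes its radical minus the anomeric-OH
    hydrogen it displaces.
    """
    comp: Composition = dict(WATER)
    for res in chain.residues:
        comp = _add(comp, res.composition)
    if chain.aglycone is not None:
        comp = _add(comp, chain.aglycone.composition)
        comp = _add(comp, {"H": 1}, -1)
    n_s = chain.n_thio_linkages
    if n_s:
        if comp.get("O", 0) < n_s:
            raise CompositionError("not enough oxygens for thio substitutions")
        comp = _add(comp, {"O": n_s}, -1)
        comp = _add(comp, {"S": n_s})
    return comp


@dataclass(frozen=True)
class IonSpecies:
    """Ion convention for m/z prediction."""

    polarity: str = "negative"
    adduct: str = "[M-H]-"
    mass_type: str = "monoisotopic"


DEFAULT_ION = IonSpecies()


def predicted_mz(chain: GlycanChain, ion: IonSpecies = DEFAULT_ION) -> float:
    """Predicted m/z (Da) of the chain for the given ion species."""
    neutral = composition_mass(elemental_composition(chain), ion.mass_type)
    if ion.adduct == "[M-H]-" and ion.polarity == "negative":
        return neutral - PROTON_MASS
    raise ValueError(f"unsupported adduct {ion.adduct!r} ({ion.polarity})")


def mass_shift(chain_a: GlycanChain, chain_b: GlycanChain,
               ion: IonSpecies = DEFAULT_ION) -> float:
    """Mass difference predicted_mz(chain_a) - predicted_mz(chain_b)."""
    return predicted_mz(chain_a, ion) - predicted_mz(chain_b, ion)


# ---------------------------------------------------------------------------
# enzymes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage rule: donor/acceptor residue classes across an O-linkage."""

    name: str
    target_donor: str
    target_acceptor: str
    mechanism: str  # "hydrolysis" | "beta-elimination"
    required_linkage_heteroatom: str = "O"


HEPARANASE = EnzymeRule("heparanase", "uronic", "hexosamine", "hydrolysis")
HEPARIN_LYASE = EnzymeRule("heparin-lyase", "hexosamine", "uronic", "beta-elimination")


def _check_alternating(chain: GlycanChain) -> None:
    classes = [r.residue_class for r in chain.residues]
    for a, b in zip(classes, classes[1:]):
        if a == b:
            raise CleavageError(
                f"backbone does not alternate uronic/hexosamine ({a} followed by {b})"
            )


def cleave(chain: GlycanChain, rule: EnzymeRule) -> tuple[list[GlycanChain], list[int]]:
    """Cut every bond matching the rule; return fragments and cut-site indices.

    Cut indices are 0-based bond indices (bond ``i`` joins residues ``i`` and
    ``i+1``). Beta-elimination converts the new non-reducing uronic residue of
    the downstream fragment to its 4,5-unsaturated form (net -H2O relative to
    hydrolysis).
    """
    _check_alternating(chain)
    n_res = len(chain.residues)
    cuts = []
    for i in range(n_res - 1):
        donor, acceptor = chain.residues[i], chain.residues[i + 1]
        if (
            donor.residue_class == rule.target_donor
            and acceptor.residue_class == rule.target_acceptor
            and chain.linkages[i] == rule.required_linkage_heteroatom
        ):
            cuts.append(i)
    fragments: list[GlycanChain] = []
    start = 0
    for bounds_i, cut in enumerate(cuts + [n_res - 1]):
        end = cut if bounds_i < len(cuts) else n_res - 1
        residues = list(chain.residues[start : end + 1])
        is_last = end == n_res - 1
        linkages = list(chain.linkages[start:end])
        if is_last and chain.aglycone is not None:
            linkages.append(chain.linkages[-1])
        if rule.mechanism == "beta-elimination" and start > 0:
            nr = residues[0]
            if nr.residue_class != "uronic":
                raise CleavageError("beta-elimination requires a uronic acceptor")
            residues[0] = replace(
                nr, modifications=nr.modifications | {"4,5-unsaturated"}
            )
        fragments.append(
            GlycanChain(tuple(residues), tuple(linkages),
                        chain.aglycone if is_last else None)
        )
        start = end + 1
    return fragments, cuts


# ---------------------------------------------------------------------------
# AMAC labeling
# ---------------------------------------------------------------------------

_AMAC: Composition = parse_formula("C13H10N2O")  # 2-aminoacridone


def amac_label_mz(fragment: GlycanChain,
                  ion: IonSpecies = DEFAULT_ION) -> tuple[float, int]:
    """Exact [M-H]- mass and nominal (nearest-integer) m/z after AMAC labeling.

    Reductive amination: labeled M = M + AMAC + H2 - H2O. Requires a free
    reducing end (no aglycone).
    """
    if fragment.aglycone is not None:
        raise LabelingError("reducing end is aglycone-capped; cannot AMAC-label")
    comp = elemental_composition(fragment)
    comp = _add(comp, _AMAC)
    comp = _add(comp, {"H": 2})
    comp = _add(comp, WATER, -1)
    exact = composition_mass(comp, ion.mass_type) - PROTON_MASS
    # round half away from zero, matching the printed nominal integers
    nominal = int(math.floor(exact + 0.5)) if exact >= 0 else -int(math.floor(-exact + 0.5))
    return exact, nominal


# ---------------------------------------------------------------------------
# chain grammar
# ---------------------------------------------------------------------------

_SEP_RE = re.compile(r"-([OS])-")


def parse_chain(text: str) -> GlycanChain:
    """Parse the chain grammar.

    Residue tokens (optionally with ``@mods``) joined by ``-O-`` / ``-S-``;
    an optional trailing ``-O-[aglycone-name]`` (or custom ``[name:formula]``)
    denotes the reducing-end aglycone. Example::

        GlcA-S-GlcNAc@6S-O-GlcA-O-[C2H4-amido-benzaldehyde]
    """
    text = text.strip()
    if not text:
        raise ValueError("empty chain string")
    aglycone = None
    m = re.search(r"-([OS])-\[([^\]]+)\]$", text)
    aglycone_link: list[str] = []
    if m:
        name = m.group(2)
        if ":" in name:
            nm, formula = name.split(":", 1)
            aglycone = Aglycone(nm, formula)
        elif name in AGLYCONES:
            aglycone = AGLYCONES[name]
        else:
            raise CompositionError(f"unknown aglycone {name!r} (use name:formula)")
        aglycone_link = [m.group(1)]
        text = text[: m.start()]
    parts = _SEP_RE.split(text)
    tokens, linkages = parts[::2], parts[1::2]
    residues = tuple(ResidueSpec.from_token(t) for t in tokens)
    return GlycanChain(residues, tuple(linkages + aglycone_link), aglycone)


def chain_to_string(chain: GlycanChain) -> str:
    """Serialize a chain back to the grammar (round-trips with parse_chain)."""
    n_res_links = len(chain.residues) - 1
    parts = [chain.residues[0].to_token()]
    for i in range(n_res_links):
        parts.append(f"-{chain.linkages[i]}-{chain.residues[i + 1].to_token()}")
    if chain.aglycone is not None:
        ag = chain.aglycone
        tag = ag.name if AGLYCONES.get(ag.name) == ag else f"{ag.name}:{ag.composition_formula}"
        parts.append(f"-{chain.linkages[-1]}-[{tag}]")
    return "".join(parts)


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------


def heparosan(n_residues: int, linkage: str = "O",
              first_residue: str = "GlcA") -> GlycanChain:
    """Alternating GlcA/GlcNAc chain of ``n_residues`` (non-reducing first).

    ``linkage='O'`` gives natural heparosan; ``linkage='hemi-A'`` makes every
    GlcA->GlcNAc bond thio-glycosidic (S) while GlcNAc->GlcA bonds stay O.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if linkage not in ("O", "hemi-A"):
        raise ValueError(f"linkage must be 'O' or 'hemi-A', got {linkage!r}")
    other = {"GlcA": "GlcNAc", "GlcNAc": "GlcA"}[first_residue]
    names = [first_residue if i % 2 == 0 else other for i in range(n_residues)]
    residues = tuple(ResidueSpec(n) for n in names)
    linkages = []
    for i in range(n_residues - 1):
        thio = linkage == "hemi-A" and names[i] == "GlcA"
        linkages.append("S" if thio else "O")
    return GlycanChain(residues, tuple(linkages))


def table1_product(n_repeats: int, analog: bool) -> GlycanChain:
    """Synthase extension products ``(GlcNAc-GlcA)_n-GlcNAc-R'``.

    ``R' = GlcA-GlcNAc-GlcA-C2H4-amido-benzaldehyde`` acceptor. In the 4-SH
    analog every added GlcNAc carries the thio substitution: the non-reducing
    terminal one as a free 4-SH, internal ones as GlcA-S-GlcNAc linkages.
    """
    if n_repeats < 0:
        raise ValueError("n_repeats must be >= 0")
    names = ["GlcNAc"] + ["GlcA", "GlcNAc"] * n_repeats + ["GlcA", "GlcNAc", "GlcA"]
    residues = [ResidueSpec(n) for n in names]
    linkages = ["O"] * len(names)  # includes the reducing-end aglycone bond
    if analog:
        residues[0] = ResidueSpec("GlcNAc", frozenset({"4-thio"}))
        for k in range(1, n_repeats + 1):
            linkages[2 * k - 1] = "S"  # bond GlcA(2k-1) -> GlcNAc(2k), 0-based
    return GlycanChain(tuple(residues), tuple(linkages),
                       AGLYCONES["C2H4-amido-benzaldehyde"])
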