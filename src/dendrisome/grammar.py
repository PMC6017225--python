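"""Generative grammar for bis-MPA Janus dendrimers.

A Janus dendrimer (JD) is built from two dendrons — branched trees of
2,2-bis(hydroxymethyl)propionic acid (bis-MPA) repeat units — joined
through an ethylene glycol diester linker.  One dendron carries free
hydroxyl terminals (the hydrophilic block), the other carries fatty-acyl
(myristoyl) terminals (the hydrophobic block).  Every condensation bond
(ester or acetal) releases one molecule of water, which is accounted for
per bond at assembly time so that partial structures remain chemically
valid.

The grammar is used two ways: as the structural substrate for the
coarse-grained bead mapping (:mod:`dendrisome.cgmap`), and as a formula /
average-mass calculator whose outputs can be checked against calculated
MALDI-TOF adduct masses.

Generation convention
---------------------
A generation-``g`` dendron (``g >= 1``) contains ``2**g - 1`` bis-MPA
units arranged in ``g`` branching layers; the deepest layer bears
``2**g`` terminal positions.  ``g == 0`` with an acid focal point and
hydroxyl terminals denotes the bare bis-MPA monomer (a single-node tree).
An isopropylidene (acetonide) cap protects *two* hydroxyl positions of
one bis-MPA unit, so a fully protected dendron carries ``2**(g-1)`` cap
leaves over the same ``2**g`` positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from .constants import ATOMIC_WEIGHTS

__all__ = [
    "UnitKind",
    "Terminal",
    "FocalPoint",
    "RepeatUnit",
    "DendronSpec",
    "JanusSpec",
    "Node",
    "DendrimerTree",
    "MolecularFormula",
    "ConfigurationError",
    "build_dendron",
    "build_janus",
    "elemental_formula",
    "average_mass",
    "formula_from_string",
]

# Conventional element output order (Hill system: C, H, then alphabetical)
_HILL_TAIL = ("N", "Na", "O", "P", "S")

WATER = {"H": 2, "O": 1}


class ConfigurationError(ValueError):
    """Raised for chemically inconsistent molecule specifications."""


class UnitKind(str, Enum):
    BISMPA_BRANCH = "bisMPA_branch"
    MYRISTOYL_TAIL = "myristoyl_tail"
    HYDROXYL_TERMINAL = "hydroxyl_terminal"
    ETHYLENE_GLYCOL_LINKER = "ethylene_glycol_linker"
    BENZYL_ESTER_CAP = "benzyl_ester_cap"
    ISOPROPYLIDENE_CAP = "isopropylidene_cap"


class Terminal(str, Enum):
    HYDROXYL = "hydroxyl"
    MYRISTOYL = "myristoyl"
    ISOPROPYLIDENE = "isopropylidene-protected"


class FocalPoint(str, Enum):
    ACID = "acid"
    BENZYL_ESTER = "benzyl_ester"
    LINKER = "linker"


def _acyl_formula(alkyl_carbons: int) -> dict[str, int]:
    """Free fatty acid CH3-(CH2)_{n-1}-COOH with ``n`` alkyl carbons.

    The paper's tails are myristoyl: 13 alkyl carbons, i.e. the C14 acid
    C14H28O2.
    """
    n = alkyl_carbons + 1  # + carboxyl carbon
    return {"C": n, "H": 2 * n, "O": 2}


#: Free-molecule elemental formulas of each repeat unit (before
#: condensation; water loss is handled per bond).
_UNIT_FORMULAS: dict[UnitKind, dict[str, int]] = {
    UnitKind.BISMPA_BRANCH: {"C": 5, "H": 10, "O": 4},          # bis-MPA
    UnitKind.HYDROXYL_TERMINAL: {},                               # marker node
    UnitKind.ETHYLENE_GLYCOL_LINKER: {"C": 2, "H": 6, "O": 2},   # HOCH2CH2OH
    UnitKind.BENZYL_ESTER_CAP: {"C": 7, "H": 8, "O": 1},         # benzyl alcohol
    UnitKind.ISOPROPYLIDENE_CAP: {"C": 3, "H": 6, "O": 1},       # acetone
}

#: branching factor of the bis-MPA AB2 monomer
BISMPA_BRANCHING = 2


@dataclass(frozen=True)
class RepeatUnit:
    """A chemically typed repeat unit and its elemental contribution."""

    kind: UnitKind
    element_delta: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.element_delta.values()):
            raise ConfigurationError("element counts must be non-negative")


@dataclass(frozen=True)
class DendronSpec:
    """Specification of one dendron: generation, terminal and focal chemistry."""

    generation: int
    terminal: Terminal = Terminal.HYDROXYL
    focal_point: FocalPoint = FocalPoint.ACID
    tail_carbons: int = 13

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ConfigurationError("generation must be >= 0")
        if self.tail_carbons < 1:
            raise ConfigurationError("tail_carbons must be >= 1")

    @property
    def n_terminal_positions(self) -> int:
        return 2 ** self.generation


@dataclass(frozen=True)
class JanusSpec:
    """Two dendrons joined through an ethylene glycol diester linker."""

    hydrophilic: DendronSpec = DendronSpec(2, Terminal.HYDROXYL, FocalPoint.LINKER)
    hydrophobic: DendronSpec = DendronSpec(2, Terminal.MYRISTOYL, FocalPoint.LINKER)
    tail_carbons: int = 13

    def __post_init__(self) -> None:
        if self.hydrophilic.terminal is not Terminal.HYDROXYL:
            raise ConfigurationError("hydrophilic dendron must be hydroxyl-terminated")
        if self.hydrophobic.terminal is not Terminal.MYRISTOYL:
            raise ConfigurationError("hydrophobic dendron must be acyl-terminated")
        for side in (self.hydrophilic, self.hydrophobic):
            if side.generation < 1:
                raise ConfigurationError(
                    "Janus construction requires generation >= 1 on both sides"
                )


@dataclass
class Node:
    """One repeat unit in a dendrimer tree.

    ``condenses`` marks whether the bond to the parent releases one H2O
    (ester or acetal formation).  Hydroxyl terminal markers do not
    condense — they simply flag a free CH2OH position of the parent.
    """

    kind: UnitKind
    children: list["Node"] = field(default_factory=list)
    condenses: bool = True
    tail_carbons: int = 13

    @property
    def formula(self) -> dict[str, int]:
        if self.kind is UnitKind.MYRISTOYL_TAIL:
            return _acyl_formula(self.tail_carbons)
        return _UNIT_FORMULAS[self.kind]


@dataclass
class DendrimerTree:
    """Rooted chemically typed tree of repeat units."""

    root: Node
    spec: object | None = None

    def nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if not n.children]

    def leaf_counts(self) -> Counter:
        return Counter(n.kind for n in self.leaves())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.nodes())

    @property
    def n_condensation_bonds(self) -> int:
        """Number of water-releasing bonds (every non-root condensing node)."""
        return sum(1 for n in self.nodes() if n is not self.root and n.condenses)

    def count(self, kind: UnitKind) -> int:
        return sum(1 for n in self.nodes() if n.kind is kind)


class MolecularFormula(Counter):
    """Element -> count mapping with Hill-notation rendering.

    Subclasses :class:`collections.Counter`, so formulas add and subtract
    element-wise.  Zero-count elements are dropped on rendering.
    """

    def hill(self) -> str:
        parts = []
        for el in ("C", "H") + _HILL_TAIL:
            n = self.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        extra = sorted(set(self) - set(("C", "H") + _HILL_TAIL))
        for el in extra:
            if self[el] > 0:
                parts.append(f"{el}{self[el]}" if self[el] > 1 else el)
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def formula_from_string(s: str) -> MolecularFormula:
    """Parse a plain Hill-notation formula like ``'C88H158Na2O24'``."""
    import re

    out = MolecularFormula()
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", s):
        if m.group(1):
            out[m.group(1)] += int(m.group(2) or 1)
    return out


# ---------------------------------------------------------------------------
# builders


def _build_branch(level: int, generation: int, terminal: Terminal,
                  tail_carbons: int) -> Node:
    node = Node(UnitKind.BISMPA_BRANCH, tail_carbons=tail_carbons)
    if level == generation:
        if terminal is Terminal.HYDROXYL:
            node.children = [
                Node(UnitKind.HYDROXYL_TERMINAL, condenses=False)
                for _ in range(BISMPA_BRANCHING)
            ]
        elif terminal is Terminal.MYRISTOYL:
            node.children = [
                Node(UnitKind.MYRISTOYL_TAIL, tail_carbons=tail_carbons)
                for _ in range(BISMPA_BRANCHING)
            ]
        else:  # acetonide protects both hydroxyls of this unit with one cap
            node.children = [Node(UnitKind.ISOPROPYLIDENE_CAP)]
    else:
        node.children = [
            _build_branch(level + 1, generation, terminal, tail_carbons)
            for _ in range(BISMPA_BRANCHING)
        ]
    return node


def build_dendron(spec: DendronSpec) -> DendrimerTree:
    """Build a dendron tree from its specification.

    Raises :class:`ConfigurationError` for unsupported terminal/focal
    combinations (e.g. anything but the bare monomer at generation 0) or
    generations above 6.
    """
    if spec.generation > 6:
        raise ConfigurationError("generation > 6 not supported")
    if spec.generation == 0:
        if spec.terminal is Terminal.HYDROXYL and spec.focal_point is FocalPoint.ACID:
            return DendrimerTree(Node(UnitKind.BISMPA_BRANCH), spec=spec)
        raise ConfigurationError(
            "generation 0 denotes the bis-MPA monomer: terminal must be "
            "hydroxyl and the focal point an acid"
        )

    branch_root = _build_branch(1, spec.generation, spec.terminal, spec.tail_carbons)
    if spec.focal_point is FocalPoint.BENZYL_ESTER:
        cap = Node(UnitKind.BENZYL_ESTER_CAP, children=[branch_root])
        return DendrimerTree(cap, spec=spec)
    # ACID and LINKER focal points both expose the root carboxyl; the
    # linker bond is created by build_janus.
    return DendrimerTree(branch_root, spec=spec)


def build_janus(spec: JanusSpec | None = None) -> DendrimerTree:
    """Join two dendrons through the ethylene glycol diester linker.

    The default specification is the amphiphile studied here: G2/G2 with
    four hydroxyl terminals and four myristoyl (C13 alkyl) tails.
    """
    if spec is None:
        spec = JanusSpec()
    phil = build_dendron(
        DendronSpec(spec.hydrophilic.generation, Terminal.HYDROXYL,
                    FocalPoint.LINKER, spec.tail_carbons)
    )
    phob = build_dendron(
        DendronSpec(spec.hydrophobic.generation, Terminal.MYRISTOYL,
                    FocalPoint.LINKER, spec.tail_carbons)
    )
    linker = Node(UnitKind.ETHYLENE_GLYCOL_LINKER,
                  children=[phil.root, phob.root])
    return DendrimerTree(linker, spec=spec)


# ---------------------------------------------------------------------------
# formula and mass


def elemental_formula(tree: DendrimerTree,
                      adducts: dict[str, int] | None = None) -> MolecularFormula:
    """Neutral elemental formula of a tree, with optional adduct deltas.

    Sums the free-molecule formula of every unit, subtracts one H2O per
    condensation bond, then applies the adduct deltas (e.g.
    ``{"Na": 2}`` for [M + 2Na], ``{"H": -1, "Na": 2}`` for [M - H + 2Na]).
    """
    out = MolecularFormula()
    for node in tree.nodes():
        out.update(node.formula)
    n_bonds = tree.n_condensation_bonds
    out["H"] -= WATER["H"] * n_bonds
    out["O"] -= WATER["O"] * n_bonds
    if any(v < 0 for v in out.values()):
        raise ConfigurationError("condensation bookkeeping produced a negative count")
    if adducts:
        for el, delta in adducts.items():
            out[el] += delta
            if out[el] < 0:
                raise ConfigurationError(
                    f"adduct {el}{delta:+d} would make the {el} count negative"
                )
    return MolecularFormula({el: n for el, n in out.items() if n != 0})


def average_mass(formula: MolecularFormula | dict[str, int]) -> float:
    """Average molecular mass in Da from standard atomic weights."""
    total = 0.0
    for el, n in formula.items():
        try:
            total += n * ATOMIC_WEIGHTS[el]
        except KeyError:
            raise KeyError(f"no standard atomic weight for element {el!r}") from None
    return total


def molecule_report(tree: DendrimerTree,
                    adducts: dict[str, int] | None = None) -> dict:
    """JSON-ready summary: formula, mass, unit and leaf counts."""
    neutral = elemental_formula(tree)
    entry = {
        "neutral_formula": neutral.hill(),
        "neutral_mass_da": round(average_mass(neutral), 2),
        "n_units": tree.n_nodes,
        "n_condensation_bonds": tree.n_condensation_bonds,
        "leaves": {k.value: v for k, v in tree.leaf_counts().items()},
    }
    if adducts:
        adduct_formula = elemental_formula(tree, adducts)
        entry["adducts"] = dict(adducts)
        entry["adduct_formula"] = adduct_formula.hill()
        entry["adduct_mass_da"] = round(average_mass(adduct_formula), 2)
    return entry
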