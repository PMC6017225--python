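"""MARTINI coarse-grained mapping and topology emission.

The bis-MPA Janus dendrimer maps onto three MARTINI bead types:

* each myristoyl tail becomes three apolar ``C1`` beads plus one ``Na``
  bead for the ester carbonyl;
* each bis-MPA branch unit (the methyl formate block; the methyl
  substituent is not mapped) becomes one intermediate ``Na`` bead;
* each terminal hydroxymethyl group becomes one small polar ``SP2`` bead.

The ethylene glycol diester linker is absorbed into the two focal branch
beads, so bead connectivity mirrors the chemical tree and the default
G2/G2 dendrimer yields 12 C1 + 10 Na + 4 SP2 = 26 beads joined by 25
bonds.

Bonded parameters default to the MARTINI v2.0 standards (bonds
0.47 nm / 1250 kJ mol^-1 nm^-2; angles 180 deg / 25 kJ mol^-1 along
chains and 120 deg / 45 kJ mol^-1 at branch points) and can be
overridden, e.g. with values fitted by harmonic Boltzmann inversion of
distributions sampled from an atomistic reference simulation
(``K = kB*T / var``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
import numpy as np

from . import constants as c
from .grammar import DendrimerTree, Node, UnitKind

__all__ = [
    "GroupClass",
    "BeadSpec",
    "Bond",
    "Angle",
    "CGTopology",
    "BondedSampleSet",
    "MappingError",
    "DegenerateDistributionError",
    "map_to_cg",
    "assign_bonded_params",
    "boltzmann_invert_bond",
    "boltzmann_invert_angle",
    "write_itp",
    "parse_itp",
    "load_bond_overrides",
]


class MappingError(ValueError):
    """A repeat unit has no coarse-grained image."""


class DegenerateDistributionError(ValueError):
    """Sample distribution has zero variance; no force constant exists."""


class GroupClass(str, Enum):
    POLAR_HEAD = "polar_head"
    HYDROPHILIC = "hydrophilic"
    HYDROPHOBIC = "hydrophobic"
    TAIL_END = "tail_end"


@dataclass(frozen=True)
class BeadSpec:
    index: int                # 0-based
    name: str
    martini_type: str         # C1 | Na | SP2 | P4
    mass: float               # amu
    vdw_radius: float         # nm
    group_class: GroupClass

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    r0: float | None = None   # nm
    k: float | None = None    # kJ mol^-1 nm^-2


@dataclass(frozen=True)
class Angle:
    i: int
    j: int
    k: int
    theta0: float | None = None  # deg
    ktheta: float | None = None  # kJ mol^-1


@dataclass
class CGTopology:
    molecule_name: str
    beads: list[BeadSpec]
    bonds: list[Bond]
    angles: list[Angle] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.beads:
            out[b.martini_type] = out.get(b.martini_type, 0) + 1
        return out

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_beads)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def validate_tree(self) -> None:
        """Connectivity must be a spanning tree over the beads."""
        if len(self.bonds) != self.n_beads - 1:
            raise ValueError("bond count must equal bead count - 1")
        seen = {0}
        stack = [0]
        adj = self.adjacency()
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(seen) != self.n_beads:
            raise ValueError("bead graph is not connected")

    def fully_parameterized(self) -> bool:
        return all(b.r0 is not None and b.k is not None for b in self.bonds) and all(
            a.theta0 is not None and a.ktheta is not None for a in self.angles
        )


@dataclass
class BondedSampleSet:
    """Scalar observable samples from a reference (atomistic) simulation."""

    observable: str           # "bond_length" (nm) | "angle" (deg)
    samples: np.ndarray
    temperature: float        # K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.samples.size < 100:
            raise ValueError("need at least 100 samples for a stable fit")


# ---------------------------------------------------------------------------
# mapping


def _n_tail_c1(tail_carbons: int) -> int:
    """C1 beads per acyl tail at ~4 heavy atoms per bead (carbonyl is Na)."""
    return max(1, round(tail_carbons / 4))


def map_to_cg(tree: DendrimerTree, molecule_name: str = "JD") -> CGTopology:
    """Map a dendrimer tree onto its MARTINI bead topology.

    Bead naming: terminal hydroxymethyls ``OH<n>`` (SP2), branch esters
    ``ES<n>`` (Na), tail carbonyls ``CO<t>`` (Na) and tail carbons
    ``T<t>A..`` (C1, the last letter marking the distal tail-end bead).
    """
    beads: list[BeadSpec] = []
    bonds: list[Bond] = []
    counters = {"OH": 0, "ES": 0, "T": 0}

    def add_bead(name: str, mtype: str, group: GroupClass) -> int:
        idx = len(beads)
        beads.append(BeadSpec(idx, name, mtype, c.bead_mass(mtype),
                              c.bead_radius(mtype), group))
        return idx

    def visit(node: Node, parent_bead: int | None) -> None:
        kind = node.kind
        if kind is UnitKind.BISMPA_BRANCH:
            counters["ES"] += 1
            idx = add_bead(f"ES{counters['ES']}", "Na", GroupClass.HYDROPHILIC)
            if parent_bead is not None:
                bonds.append(Bond(parent_bead, idx))
            for ch in node.children:
                visit(ch, idx)
        elif kind is UnitKind.HYDROXYL_TERMINAL:
            counters["OH"] += 1
            idx = add_bead(f"OH{counters['OH']}", "SP2", GroupClass.POLAR_HEAD)
            bonds.append(Bond(parent_bead, idx))
        elif kind is UnitKind.MYRISTOYL_TAIL:
            counters["T"] += 1
            t = counters["T"]
            idx = add_bead(f"CO{t}", "Na", GroupClass.HYDROPHOBIC)
            bonds.append(Bond(parent_bead, idx))
            prev = idx
            n_c1 = _n_tail_c1(node.tail_carbons)
            for k in range(n_c1):
                group = GroupClass.TAIL_END if k == n_c1 - 1 else GroupClass.HYDROPHOBIC
                letter = chr(ord("A") + k)
                nxt = add_bead(f"T{t}{letter}", "C1", group)
                bonds.append(Bond(prev, nxt))
                prev = nxt
        elif kind is UnitKind.ETHYLENE_GLYCOL_LINKER:
            # absorbed into the two focal branch beads: bridge the children
            child_roots: list[int] = []
            for ch in node.children:
                before = len(beads)
                visit(ch, None)
                child_roots.append(before)
            if parent_bead is not None and child_roots:
                bonds.append(Bond(parent_bead, child_roots[0]))
            for a, b in zip(child_roots, child_roots[1:]):
                bonds.append(Bond(a, b))
        else:
            raise MappingError(f"no coarse-grained mapping for unit kind {kind.value!r}")

    visit(tree.root, None)
    top = CGTopology(molecule_name, beads, bonds)
    top.validate_tree()
    return top


# ---------------------------------------------------------------------------
# bonded parameters


def _enumerate_angles(top: CGTopology) -> list[tuple[int, int, int]]:
    adj = top.adjacency()
    out = []
    for j in range(top.n_beads):
        nbrs = sorted(adj[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append((nbrs[a], j, nbrs[b]))
    return out


def assign_bonded_params(
    top: CGTopology,
    bond_overrides: dict[tuple[int, int], tuple[float, float]] | None = None,
    angle_overrides: dict[tuple[int, int, int], tuple[float, float]] | None = None,
) -> CGTopology:
    """Return a fully parameterized copy of ``top``.

    Bonds default to the MARTINI v2.0 standard (0.47 nm, 1250); angles
    are enumerated from connectivity and default to 180/25 along chains
    and 120/45 where the apex bead branches.  Overrides are keyed by
    0-based bead index pairs/triples (order-insensitive for bonds,
    forward/reverse for angles) and must reference existing bonds.
    """
    bond_overrides = dict(bond_overrides or {})
    angle_overrides = dict(angle_overrides or {})

    existing = {frozenset((b.i, b.j)) for b in top.bonds}
    for key in bond_overrides:
        if frozenset(key) not in existing:
            raise KeyError(f"override references nonexistent bond {key}")

    degree = {i: len(v) for i, v in top.adjacency().items()}

    bonds = []
    for b in top.bonds:
        r0, k = c.MARTINI_BOND_R0, c.MARTINI_BOND_K
        if b.r0 is not None and b.k is not None:
            r0, k = b.r0, b.k
        for key in ((b.i, b.j), (b.j, b.i)):
            if key in bond_overrides:
                r0, k = bond_overrides[key]
        bonds.append(Bond(b.i, b.j, r0, k))

    angles = []
    for (i, j, k) in _enumerate_angles(top):
        theta0, ktheta = (
            c.MARTINI_ANGLE_BRANCH if degree[j] > 2 else c.MARTINI_ANGLE_CHAIN
        )
        for key in ((i, j, k), (k, j, i)):
            if key in angle_overrides:
                theta0, ktheta = angle_overrides[key]
        angles.append(Angle(i, j, k, theta0, ktheta))

    return CGTopology(top.molecule_name, list(top.beads), bonds, angles)


def load_bond_overrides(path_or_text: str) -> dict[tuple[int, int], tuple[float, float]]:
    """Read a bond override table from CSV with columns ``i,j,r0,kb``."""
    try:
        text = open(path_or_text).read()
    except (OSError, ValueError):
        text = path_or_text
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for row in csv.DictReader(io.StringIO(text)):
        out[(int(row["i"]), int(row["j"]))] = (float(row["r0"]), float(row["kb"]))
    return out


# ---------------------------------------------------------------------------
# Boltzmann inversion


def boltzmann_invert_bond(s: BondedSampleSet) -> tuple[float, float]:
    """Harmonic inversion of a bond-length distribution.

    Returns ``(r0, Kb)`` with ``r0`` the sample mean (nm) and
    ``Kb = kB*T / var`` in kJ mol^-1 nm^-2.
    """
    if s.observable != "bond_length":
        raise ValueError("sample set does not hold bond lengths")
    mean = float(np.mean(s.samples))
    var = float(np.var(s.samples))
    if var <= max(1e-20, (1e-8 * abs(mean)) ** 2):
        raise DegenerateDistributionError("zero-variance bond distribution")
    return mean, c.KB * s.temperature / var


def boltzmann_invert_angle(s: BondedSampleSet) -> tuple[float, float]:
    """Harmonic inversion of an angle distribution.

    Returns ``(theta0, Ktheta)``; the mean is reported in degrees but the
    variance entering ``Ktheta = kB*T / var`` is taken in radians, giving
    kJ mol^-1 rad^-2 as GROMACS expects.
    """
    if s.observable != "angle":
        raise ValueError("sample set does not hold angles")
    rad = np.deg2rad(s.samples)
    var = float(np.var(rad))
    if var <= max(1e-20, (1e-8 * abs(float(np.mean(rad)))) ** 2):
        raise DegenerateDistributionError("zero-variance angle distribution")
    return float(np.mean(s.samples)), c.KB * s.temperature / var


# ---------------------------------------------------------------------------
# ITP emission


def write_itp(top: CGTopology) -> str:
    """Emit a GROMACS include-topology (.itp) for one molecule type."""
    if not top.fully_parameterized():
        raise ValueError("topology has unparameterized bonds or angles; "
                         "run assign_bonded_params first")
    lines = [
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{top.molecule_name}  1",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    for b in top.beads:
        lines.append(
            f"{b.index + 1:5d}  {b.martini_type:<4s}  1  {top.molecule_name:<5s}"
            f"  {b.name:<5s}  {b.index + 1:5d}  0.000  {b.mass:7.3f}"
        )
    lines += ["", "[ bonds ]", ";  i   j  funct  r0(nm)  kb"]
    for bd in top.bonds:
        lines.append(
            f"{bd.i + 1:5d} {bd.j + 1:5d}  1  {bd.r0:7.4f}  {bd.k:10.2f}"
        )
    lines += ["", "[ angles ]", ";  i   j   k  funct  theta0  ktheta"]
    for a in top.angles:
        lines.append(
            f"{a.i + 1:5d} {a.j + 1:5d} {a.k + 1:5d}  2  {a.theta0:8.2f}  {a.ktheta:8.2f}"
        )
    return "\n".join(lines) + "\n"


def parse_itp(text: str) -> CGTopology:
    """Parse an ITP written by :func:`write_itp` back into a topology."""
    section = None
    name = "MOL"
    beads: list[BeadSpec] = []
    bonds: list[Bond] = []
    angles: list[Angle] = []
    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        parts = line.split()
        if section == "moleculetype":
            name = parts[0]
        elif section == "atoms":
            nr, mtype, _resnr, _res, atom, _cgnr, _q, mass = parts[:8]
            beads.append(BeadSpec(int(nr) - 1, atom, mtype, float(mass),
                                  c.bead_radius(mtype),
                                  _group_from_name(atom)))
        elif section == "bonds":
            i, j, _f, r0, kb = parts[:5]
            bonds.append(Bond(int(i) - 1, int(j) - 1, float(r0), float(kb)))
        elif section == "angles":
            i, j, k, _f, t0, kt = parts[:6]
            angles.append(Angle(int(i) - 1, int(j) - 1, int(k) - 1,
                                float(t0), float(kt)))
    return CGTopology(name, beads, bonds, angles)


def _group_from_name(name: str) -> GroupClass:
    """Recover the block class from the bead naming convention."""
    if name.startswith("OH"):
        return GroupClass.POLAR_HEAD
    if name.startswith("ES"):
        return GroupClass.HYDROPHILIC
    if name.startswith("T") and name[-1].isalpha():
        # distal bead carries the highest letter; without the full chain
        # context, classify 'C' (the default 3-bead tail terminus) as the end
        return GroupClass.TAIL_END if name.endswith("C") else GroupClass.HYDROPHOBIC
    return GroupClass.HYDROPHOBIC
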