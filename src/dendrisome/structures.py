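"""Synthetic labelled coarse-grained assemblies for analysis testing.

Cluster-scale self-assembly trajectories are far beyond desk scale, so
every analyzer in :mod:`dendrisome.analysis` is exercised on idealized,
self-certifying structures instead: bilayer patches with prescribed
head-plane separation, hydrophobic-core width and molecular lengths;
vesicles (two concentric leaflet shells); micelles (one shell, tails
inward); and boxes of well-separated compact aggregates with ground-truth
cluster labels.  Each generator returns the geometry it actually built in
``BeadFrame.ground_truth`` so downstream estimators can be validated
against construction rather than against themselves.

Reference geometry
------------------
The registry entry ``"reference_patch"`` encodes the bilayer geometry
measured on the simulated dendrimer aggregate: head-to-head thickness
4.1 nm, hydrophobic core 1.8 nm, monomer length 2.0 nm and tail length
0.7 nm, inside a 6.5 x 5.4 x 7.4 nm box.

Molecular conformations are schematic: beads sit on a straight axis
normal to the leaflet with small fixed lateral offsets, scaled so the
head-to-tail-end distance equals L, the first-tail-bead-to-tail-end
distance equals l_t exactly, and the hydrophobic beads tile a slab of
full width d_core.  No thermodynamic realism is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .cgmap import CGTopology, GroupClass, map_to_cg
from .grammar import build_janus

__all__ = [
    "BeadFrame",
    "BilayerParams",
    "GeometryError",
    "make_bilayer_patch",
    "make_vesicle",
    "make_micelle",
    "make_aggregate_box",
    "single_molecule_frame",
    "FIXTURES",
    "get_fixture",
    "default_topology",
]


class GeometryError(ValueError):
    """Requested structure parameters are geometrically inconsistent."""


@dataclass
class BeadFrame:
    """Labelled bead coordinates in an orthorhombic box (all lengths nm)."""

    coords: np.ndarray                 # (N, 3)
    box: np.ndarray                    # (3,)
    molecule_id: np.ndarray            # (N,) int, contiguous from 0
    bead_name: np.ndarray              # (N,) str
    group_class: np.ndarray            # (N,) str (GroupClass values)
    leaflet: np.ndarray | None = None  # (N,) int, optional
    radius: np.ndarray | None = None   # (N,) nm, optional (for SASA)
    time_ps: float | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.bead_name = np.asarray(self.bead_name, dtype=object)
        self.group_class = np.asarray(self.group_class, dtype=object)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for arr in (self.molecule_id, self.bead_name, self.group_class):
            if len(arr) != len(self.coords):
                raise ValueError("labels must cover every bead")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_molecules(self) -> int:
        return 0 if self.n_beads == 0 else int(self.molecule_id.max()) + 1

    def select(self, groups: str | list[str]) -> np.ndarray:
        """Boolean mask of beads whose class is in ``groups``.

        Composite names ``hydrophilic_total`` (polar_head + hydrophilic)
        and ``hydrophobic_total`` (hydrophobic + tail_end) are expanded;
        ``all`` selects everything.
        """
        if isinstance(groups, str):
            groups = [groups]
        expanded: set[str] = set()
        for g in groups:
            if g == "all":
                return np.ones(self.n_beads, dtype=bool)
            if g == "hydrophilic_total":
                expanded |= {GroupClass.POLAR_HEAD.value, GroupClass.HYDROPHILIC.value}
            elif g == "hydrophobic_total":
                expanded |= {GroupClass.HYDROPHOBIC.value, GroupClass.TAIL_END.value}
            else:
                expanded.add(GroupClass(g).value)
        return np.isin(self.group_class, sorted(expanded))


def default_topology() -> CGTopology:
    """Coarse-grained topology of the default G2/G2 Janus dendrimer."""
    return map_to_cg(build_janus())


@dataclass(frozen=True)
class BilayerParams:
    """Geometry of a flat bilayer patch (all lengths nm)."""

    head_plane_separation: float = 4.1   # D_hh
    core_thickness: float = 1.8          # d_core
    monomer_length: float = 2.0          # L, head -> distal tail bead
    tail_length: float = 0.7             # l_t, first tail C1 -> distal
    area_per_molecule: float = 1.1       # nm^2 per molecule per leaflet
    patch_extent: tuple[float, float] = (6.5, 5.4)
    positional_noise: float = 0.05       # Gaussian sigma
    interdigitated: bool = False
    hexagonal: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.positional_noise < 0:
            raise GeometryError("noise sigma must be >= 0")
        if min(self.patch_extent) <= 0 or self.area_per_molecule <= 0:
            raise GeometryError("extents and area per molecule must be positive")
        D, L, lt, dc = (self.head_plane_separation, self.monomer_length,
                        self.tail_length, self.core_thickness)
        if lt >= L:
            raise GeometryError("tail length must be shorter than the monomer")
        if not self.interdigitated:
            if D < 2 * lt:
                raise GeometryError(
                    "non-interdigitated bilayer requires D_hh >= 2*l_t"
                )
            if D < 2 * L:
                raise GeometryError(
                    "non-interdigitated bilayer requires D_hh >= 2*L "
                    "(set interdigitated=True to overlap leaflets)"
                )
            if dc < 2 * (D / 2 - L + lt):
                raise GeometryError(
                    "core_thickness too small to contain the tails"
                )


# per-tail stagger offsets (nm): keep mean zero so mean L is exact
_TAIL_STAGGER = np.array([-0.03, -0.01, 0.01, 0.03])
# lateral offsets (nm): one direction per tail, heads on a small ring
_LATERAL_ANGLES = np.deg2rad([0.0, 90.0, 180.0, 270.0])


def _molecule_template(top: CGTopology, D: float, L: float, lt: float,
                       dc: float) -> np.ndarray:
    """Per-bead offsets for one molecule of an upper leaflet.

    Returns (n_beads, 3) with z measured in the bilayer frame (midplane
    at z = 0, heads near z = +D/2).  The distal tail beads sit at
    z = D/2 - L +/- stagger, first tail beads exactly ``lt`` above their
    distal bead, ester (CO) beads near the core boundary ``dc/2``, so the
    hydrophobic slab spans |z| <= dc/2 and the measured lengths equal the
    parameters by construction.
    """
    n4 = 4  # tails / heads of the default molecule; generalized below
    pos = np.zeros((top.n_beads, 3))
    heads = [b for b in top.beads if b.group_class is GroupClass.POLAR_HEAD]
    branches = [b for b in top.beads if b.group_class is GroupClass.HYDROPHILIC]
    tails: dict[str, list] = {}
    for b in top.beads:
        if b.group_class in (GroupClass.HYDROPHOBIC, GroupClass.TAIL_END):
            key = b.name[2:] if b.name.startswith("CO") else b.name[1:-1]
            tails.setdefault(key, []).append(b)

    z_head = D / 2
    for k, b in enumerate(heads):
        ang = _LATERAL_ANGLES[k % n4]
        pos[b.index] = (0.04 * np.cos(ang), 0.04 * np.sin(ang), z_head)

    # hydrophilic branch beads: evenly between head plane and core edge
    z_top, z_bot = z_head - 0.15, dc / 2 + 0.1
    if z_bot >= z_top:  # strongly interdigitated geometries
        z_bot = 0.6 * z_top
    zs = np.linspace(z_top, z_bot, max(len(branches), 2))
    for k, b in enumerate(branches):
        ang = _LATERAL_ANGLES[(k + 2) % n4] + 0.5
        pos[b.index] = (0.03 * np.cos(ang), 0.03 * np.sin(ang), zs[k])

    for t, (key, beads) in enumerate(sorted(tails.items())):
        beads = sorted(beads, key=lambda b: (not b.name.startswith("CO"), b.name))
        stag = _TAIL_STAGGER[t % len(_TAIL_STAGGER)]
        ang = _LATERAL_ANGLES[t % n4]
        lat = (0.06 * np.cos(ang), 0.06 * np.sin(ang))
        co, chain = beads[0], beads[1:]
        z_distal = z_head - L + stag
        z_first = z_distal + lt
        # ester bead near the core boundary, staggered inward
        z_co = dc / 2 - 0.02 - 0.025 * (t % 4)
        pos[co.index] = (*lat, z_co)
        if len(chain) == 1:
            pos[chain[0].index] = (*lat, z_distal)
        else:
            # first and distal exact; intermediate beads crowd the distal
            # end so the hydrophobic density peaks at the bilayer center,
            # where the tails of the two leaflets meet
            pos[chain[0].index] = (*lat, z_first)
            pos[chain[-1].index] = (*lat, z_distal)
            n_mid = len(chain) - 2
            for m in range(n_mid):
                z_mid = z_distal + 0.07 + 0.03 * (t % 4) + 0.1 * m
                pos[chain[m + 1].index] = (*lat, z_mid)
    return pos


def _leaflet_lattice(extent: tuple[float, float], area: float,
                     hexagonal: bool, offset: float = 0.0) -> np.ndarray:
    """(n, 2) lattice of molecule anchor points covering the patch."""
    ex, ey = extent
    if hexagonal:
        a = np.sqrt(2.0 * area / np.sqrt(3.0))
        dy = a * np.sqrt(3.0) / 2.0
        pts = []
        j = 0
        y = 0.45 * dy + offset
        while y < ey:
            x0 = (0.25 if j % 2 else 0.75) * a + offset
            x = x0
            while x < ex:
                pts.append((x % ex, y % ey))
                x += a
            j += 1
            y += dy
        return np.array(pts)
    a = np.sqrt(area)
    xs = np.arange(0.5 * a + offset, ex, a)
    ys = np.arange(0.5 * a + offset, ey, a)
    return np.array([(x % ex, y % ey) for x in xs for y in ys])


def _assemble(placements: list[tuple[np.ndarray, int]], top: CGTopology,
              box, noise: float, rng: np.random.Generator,
              ground_truth: dict, time_ps=None) -> BeadFrame:
    """Stack per-molecule coordinate blocks into a labelled frame."""
    coords, mol_id, names, groups, leaflets, radii = [], [], [], [], [], []
    for m, (xyz, leaf) in enumerate(placements):
        coords.append(xyz)
        mol_id.append(np.full(top.n_beads, m))
        names.append([b.name for b in top.beads])
        groups.append([b.group_class.value for b in top.beads])
        radii.append([b.vdw_radius for b in top.beads])
        leaflets.append(np.full(top.n_beads, leaf))
    if coords:
        xyz = np.concatenate(coords)
        if noise > 0:
            xyz = xyz + rng.normal(0.0, noise, xyz.shape)
    else:
        xyz = np.zeros((0, 3))
    return BeadFrame(
        coords=xyz,
        box=np.asarray(box, dtype=float),
        molecule_id=np.concatenate(mol_id) if mol_id else np.zeros(0, int),
        bead_name=np.concatenate(names) if names else np.zeros(0, object),
        group_class=np.concatenate(groups) if groups else np.zeros(0, object),
        leaflet=np.concatenate(leaflets) if leaflets else None,
        radius=np.concatenate(radii) if radii else None,
        time_ps=time_ps,
        ground_truth=ground_truth,
    )


def make_bilayer_patch(p: BilayerParams, top: CGTopology | None = None,
                       seed: int | None = None) -> BeadFrame:
    """Two apposed leaflets on a lattice, normal along z.

    With zero noise the polar-head beads sit exactly at z = +/- D_hh/2
    around the box midplane; hydrophobic beads are confined to
    |z| <= d_core/2; the per-molecule head-to-tail-end distance is L and
    the first-tail-bead-to-tail-end distance is l_t.
    """
    p.validate()
    if top is None:
        top = default_topology()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    ex, ey = p.patch_extent
    bz = max(p.head_plane_separation + 3.0, 7.4)
    box = (ex, ey, bz)
    zmid = bz / 2

    template = _molecule_template(top, p.head_plane_separation,
                                  p.monomer_length, p.tail_length,
                                  p.core_thickness)
    upper = template + (0.0, 0.0, zmid)
    lower = template * (1.0, 1.0, -1.0) + (0.0, 0.0, zmid)

    placements = []
    for leaf, (tmpl, shift) in enumerate(
        [(upper, 0.0), (lower, 0.37 * np.sqrt(p.area_per_molecule))]
    ):
        for (x, y) in _leaflet_lattice((ex, ey), p.area_per_molecule,
                                       p.hexagonal, offset=shift):
            placements.append((tmpl + (x, y, 0.0), leaf))

    gt = {
        "kind": "bilayer_patch",
        "D_hh": p.head_plane_separation,
        "d_core": p.core_thickness,
        "L": p.monomer_length,
        "l_t": p.tail_length,
        "interdigitated": p.interdigitated,
        "midplane_z": zmid,
        "n_molecules": len(placements),
        "normal_axis": 2,
    }
    return _assemble(placements, top, box, p.positional_noise, rng, gt)


def make_vesicle(r_outer: float, d_hh: float = 4.1, n_molecules: int = 500,
                 seed: int = 0, monomer_length: float = 2.0,
                 tail_length: float = 0.7, core_thickness: float = 1.8,
                 top: CGTopology | None = None) -> BeadFrame:
    """Two concentric spherical leaflets: heads at R and R - D_hh.

    Molecules are split between leaflets in proportion to shell area and
    distributed on Fibonacci spirals.  Raises :class:`GeometryError` when
    the shells cannot host ``n_molecules`` at a sane area per head
    (>= 0.4 nm^2) or when the lumen closes (R <= D_hh).
    """
    if r_outer <= d_hh:
        raise GeometryError("outer radius must exceed the bilayer thickness")
    if top is None:
        top = default_topology()
    r_inner = r_outer - d_hh
    rng = np.random.default_rng(seed)
    area_out, area_in = 4 * np.pi * r_outer**2, 4 * np.pi * r_inner**2
    if n_molecules > 0 and (area_out + area_in) / n_molecules < 0.4:
        raise GeometryError("too many molecules for the shell area")
    n_out = int(round(n_molecules * area_out / (area_out + area_in)))
    n_in = n_molecules - n_out

    template = _molecule_template(top, d_hh, monomer_length, tail_length,
                                  core_thickness)
    # radial coordinate of each bead measured from the midsurface
    z = template[:, 2].copy()
    lateral = template[:, :2]

    box_l = 2 * (r_outer + monomer_length + 2.0)
    center = np.full(3, box_l / 2)
    r_mid = r_outer - d_hh / 2  # shared midsurface of both leaflets

    placements = []
    for (n, sign, leaf) in ((n_out, +1.0, 0), (n_in, -1.0, 1)):
        for u in _fibonacci_sphere(n, rng):
            t1, t2 = _tangent_frame(u)
            # template z = +D/2 at the heads; outer leaflet points outward,
            # inner leaflet inward, so heads land at R and R - D_hh
            r_bead = r_mid + sign * z
            xyz = (center[None, :] + np.outer(r_bead, u)
                   + np.outer(lateral[:, 0], t1) + np.outer(lateral[:, 1], t2))
            placements.append((xyz, leaf))

    gt = {
        "kind": "vesicle",
        "R_outer": r_outer,
        "R_inner": r_inner,
        "D_hh": d_hh,
        "center": center.tolist(),
        "lumen_radius": max(r_inner - monomer_length, 0.0),
        "n_molecules": n_molecules,
    }
    return _assemble(placements, top, (box_l,) * 3, 0.02, rng, gt)


def make_micelle(n_molecules: int, radius: float, seed: int = 0,
                 top: CGTopology | None = None) -> BeadFrame:
    """Single spherical shell, heads at ``radius`` and tails pointing inward.

    Bead radii scale linearly with ``radius`` (heads at R, tail ends at
    0.15 R), so doubling R doubles every radial coordinate.
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    if top is None:
        top = default_topology()
    rng = np.random.default_rng(seed)

    # fractional radial position per bead class
    frac = {
        GroupClass.POLAR_HEAD.value: 1.0,
        GroupClass.HYDROPHILIC.value: 0.7,
        GroupClass.HYDROPHOBIC.value: 0.4,
        GroupClass.TAIL_END.value: 0.15,
    }
    box_l = 2 * (radius + 2.0)
    center = np.full(3, box_l / 2)
    placements = []
    for u in _fibonacci_sphere(n_molecules, rng):
        t1, t2 = _tangent_frame(u)
        xyz = np.empty((top.n_beads, 3))
        for b in top.beads:
            r = frac[b.group_class.value] * radius
            jitter = 0.03 * ((b.index % 5) - 2)
            xyz[b.index] = center + r * u + jitter * t1 + jitter * t2
        placements.append((xyz, 0))
    gt = {"kind": "micelle", "radius": radius, "center": center.tolist(),
          "n_molecules": n_molecules}
    return _assemble(placements, top, (box_l,) * 3, 0.0, rng, gt)


def make_aggregate_box(sizes: list[int], box, inter_cluster_gap: float = 5.0,
                       seed: int = 0, step: float = 0.35,
                       centers: list | None = None,
                       max_attempts: int = 2000) -> BeadFrame:
    """Compact clusters of small molecules with ground-truth labels.

    Each cluster is a confined random walk with inter-molecule step
    ``step`` (guaranteeing single-linkage connectivity at any cutoff
    greater than ``step``); clusters are placed so that their pairwise
    minimum-image gap is at least ``inter_cluster_gap``.  Each molecule
    carries one hydrophobic bead and one polar-head bead.  Passing
    explicit ``centers`` (e.g. on the box boundary) overrides random
    placement; coordinates are always wrapped into the box.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    radii = [step * max(1.0, np.cbrt(n)) + 0.3 for n in sizes]
    if centers is None:
        centers_arr: list[np.ndarray] = []
        for ri in radii:
            for _ in range(max_attempts):
                cand = rng.uniform(0, 1, 3) * box
                ok = True
                for cj, rj in zip(centers_arr, radii):
                    d = _min_image(cand - cj, box)
                    if np.linalg.norm(d) < inter_cluster_gap + ri + rj:
                        ok = False
                        break
                if ok:
                    centers_arr.append(cand)
                    break
            else:
                raise GeometryError(
                    f"could not place {len(sizes)} clusters with gap "
                    f"{inter_cluster_gap} nm in box {box.tolist()}"
                )
        centers = centers_arr
    else:
        centers = [np.asarray(c, dtype=float) for c in centers]
        if len(centers) != len(sizes):
            raise GeometryError("need one center per cluster")

    coords, mol_id, names, groups, labels = [], [], [], [], []
    mol = 0
    for ci, (n, cen, ri) in enumerate(zip(sizes, centers, radii)):
        pos = cen.copy()
        for _ in range(n):
            coords.append(pos % box)
            coords.append((pos + (0.0, 0.0, 0.12)) % box)
            mol_id += [mol, mol]
            names += ["TC", "GL"]
            groups += [GroupClass.HYDROPHOBIC.value, GroupClass.POLAR_HEAD.value]
            labels.append(ci)
            mol += 1
            for _ in range(max_attempts):
                d = rng.normal(size=3)
                cand = pos + step * d / np.linalg.norm(d)
                if np.linalg.norm(_min_image(cand - cen, box)) <= ri:
                    pos = cand
                    break
            else:  # pragma: no cover - extremely unlikely
                raise GeometryError("random walk failed to stay confined")
    gt = {"kind": "aggregate_box", "sizes": list(sizes),
          "cluster_of_molecule": labels,
          "inter_cluster_gap": inter_cluster_gap}
    return BeadFrame(
        coords=np.array(coords).reshape(-1, 3),
        box=box,
        molecule_id=np.array(mol_id),
        bead_name=np.array(names, dtype=object),
        group_class=np.array(groups, dtype=object),
        ground_truth=gt,
    )


def single_molecule_frame(top: CGTopology | None = None,
                          monomer_length: float = 2.0,
                          tail_length: float = 0.7) -> np.ndarray:
    """Canonical straight-backbone conformation, centered at the origin.

    Used as the template molecule for random packing.
    """
    if top is None:
        top = default_topology()
    xyz = _molecule_template(top, 4.1, monomer_length, tail_length, 1.8)
    return xyz - xyz.mean(axis=0)


# ---------------------------------------------------------------------------
# helpers


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) near-uniform unit vectors (golden-angle spiral)."""
    if n == 0:
        return np.zeros((0, 3))
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, a)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u, t1)


# ---------------------------------------------------------------------------
# fixture registry

#: the bilayer geometry measured on the simulated aggregate patch
REFERENCE_BILAYER = BilayerParams(
    head_plane_separation=4.1,
    core_thickness=1.8,
    monomer_length=2.0,
    tail_length=0.7,
    area_per_molecule=1.1,
    patch_extent=(6.5, 5.4),
    positional_noise=0.05,
    interdigitated=False,
    seed=42,
)

FIXTURES: dict[str, Callable[..., BeadFrame]] = {
    "reference_patch": lambda seed=None: make_bilayer_patch(
        REFERENCE_BILAYER, seed=seed),
    "interdigitated_patch": lambda seed=None: make_bilayer_patch(
        replace(REFERENCE_BILAYER, head_plane_separation=3.0,
                interdigitated=True), seed=seed),
    "vesicle_small": lambda seed=None: make_vesicle(
        10.0, 4.1, 500, seed=0 if seed is None else seed),
    "micelle_small": lambda seed=None: make_micelle(
        30, 2.0, seed=0 if seed is None else seed),
    "aggregates_three": lambda seed=None: make_aggregate_box(
        [5, 7, 9], (30.0, 30.0, 30.0), inter_cluster_gap=5.0,
        seed=1 if seed is None else seed),
}


def get_fixture(name: str, seed: int | None = None) -> BeadFrame:
    """Instantiate a registered fixture, optionally re-seeding its noise."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}") from None
    return factory(seed=seed)
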