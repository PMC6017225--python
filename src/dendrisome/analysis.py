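"""Structural analysis of coarse-grained dendrimer assemblies.

Covers the measurements used to characterize self-assembled aggregates:

* periodic-boundary single-linkage clustering into aggregates with
  aggregation numbers, radii of gyration, sphere-equivalent diameters
  and convex-hull volumes;
* per-group bead density profiles along an axis or patch normal, with
  exact count conservation;
* bilayer thickness (polar-head peak-to-peak distance with parabolic
  sub-bin refinement) and hydrophobic-core thickness (full width at half
  maximum of the hydrophobic density);
* monomer and tail lengths from labelled molecules;
* the interdigitation ratio D/(2L);
* Shrake-Rupley solvent-accessible surface area on a deterministic
  Fibonacci point set, with a plateau detector for SASA time series;
* the amphiphile packing parameter p = v / (a0 * lc) with the Tanford
  estimate for hydrocarbon chain volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .structures import BeadFrame, _fibonacci_sphere, _min_image

__all__ = [
    "AggregateReport",
    "DensityProfile",
    "PackingParams",
    "SasaSeries",
    "NotABilayerError",
    "cluster_aggregates",
    "density_profile",
    "bilayer_thickness",
    "core_thickness",
    "monomer_length",
    "interdigitation_ratio",
    "shrake_rupley_sasa",
    "frame_sasa",
    "sasa_plateau",
    "packing_parameter",
    "tanford_chain_volume",
    "aggregate_metrics",
]

DEFAULT_GROUPS = ("polar_head", "tail_end", "hydrophilic_total", "hydrophobic_total")


class NotABilayerError(ValueError):
    """The density profile does not show two head-group maxima."""


# ---------------------------------------------------------------------------
# clustering


@dataclass
class AggregateReport:
    clusters: list[list[int]]              # molecule ids per cluster
    cutoff: float
    selection: str | list[str]
    metrics: dict = field(default_factory=dict)

    @property
    def aggregation_numbers(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_aggregates(frame: BeadFrame, cutoff: float = 0.6,
                       selection: str | list[str] = "hydrophobic_total",
                       ) -> AggregateReport:
    """Single-linkage aggregates under periodic boundary conditions.

    Two molecules belong to the same aggregate when any pair of their
    selected beads lies within ``cutoff`` (nm) under the minimum-image
    convention.  The default linkage selection is the hydrophobic block,
    through which the aggregates cohere.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= frame.box.min() / 2:
        raise ValueError(
            "cutoff >= half the smallest box length: minimum image is ambiguous"
        )
    mask = frame.select(selection)
    if not mask.any():
        raise ValueError("selection matches no beads")
    pos = np.mod(frame.coords[mask], frame.box)
    # guard against pos == box after the modulo at float precision
    pos = np.where(pos >= frame.box, 0.0, pos)
    mols = frame.molecule_id[mask]
    n_mol = frame.n_molecules

    tree = cKDTree(pos, boxsize=frame.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    mi, mj = mols[pairs[:, 0]], mols[pairs[:, 1]]
    keep = mi != mj
    data = np.ones(keep.sum(), dtype=np.int8)
    graph = coo_matrix((data, (mi[keep], mj[keep])), shape=(n_mol, n_mol))
    n_comp, labels = connected_components(graph, directed=False)

    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for mol, lab in enumerate(labels):
        clusters[lab].append(mol)
    clusters.sort(key=len, reverse=True)
    return AggregateReport(clusters, cutoff, selection)


def aggregate_metrics(report: AggregateReport, frame: BeadFrame) -> AggregateReport:
    """Attach per-cluster radius of gyration, diameter and hull volume.

    Clusters straddling the periodic boundary are unwrapped by shifting
    each molecule to the minimum image of the cluster's first molecule
    (valid while a cluster spans less than half the box).  The diameter
    is the sphere-equivalent value 2 * Rg * sqrt(5/3).
    """
    per_cluster = []
    for cluster in report.clusters:
        beads = np.isin(frame.molecule_id, cluster)
        xyz = frame.coords[beads].copy()
        mols = frame.molecule_id[beads]
        anchor = xyz[mols == cluster[0]].mean(axis=0)
        for m in cluster:
            sel = mols == m
            cm = xyz[sel].mean(axis=0)
            shift = frame.box * np.round((cm - anchor) / frame.box)
            xyz[sel] -= shift
        centroid = xyz.mean(axis=0)
        rg = float(np.sqrt(np.mean(np.sum((xyz - centroid) ** 2, axis=1))))
        entry = {
            "aggregation_number": len(cluster),
            "radius_of_gyration": rg,
            "diameter": 2.0 * rg * np.sqrt(5.0 / 3.0),
            "hull_volume": None,
            "degenerate": False,
        }
        if len(cluster) == 1 and len(xyz) < 4:
            entry["degenerate"] = True
        else:
            try:
                entry["hull_volume"] = float(ConvexHull(xyz).volume)
            except QhullError:
                entry["degenerate"] = True
        per_cluster.append(entry)
    report.metrics = {"per_cluster": per_cluster}
    return report


# ---------------------------------------------------------------------------
# density profiles


@dataclass
class DensityProfile:
    axis: int
    edges: np.ndarray                      # nm, uniform
    densities: dict[str, np.ndarray]       # beads nm^-3 per group
    counts: dict[str, np.ndarray]          # raw per-bin bead counts
    bin_volume: float                      # nm^3

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def density_profile(frame: BeadFrame, groups=DEFAULT_GROUPS, axis: int = 2,
                    bin_width: float = 0.1,
                    region: tuple[float, float] | None = None,
                    ) -> DensityProfile:
    """Binned per-group bead-count density along a box axis.

    ``region`` restricts the profile (and the beads counted) to an
    interval along the axis; the cross-sectional area is taken from the
    other two box lengths, so summing density x bin volume recovers the
    bead count of each group exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = (0.0, float(frame.box[axis])) if region is None else region
    if not (0.0 <= lo < hi <= frame.box[axis] + 1e-9):
        raise ValueError("region must be a nonempty interval within the box")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    others = [i for i in range(3) if i != axis]
    area = float(frame.box[others[0]] * frame.box[others[1]])
    bin_volume = bin_width * area

    x = frame.coords[:, axis]
    densities: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for g in groups:
        mask = frame.select(g)
        vals = x[mask]
        vals = vals[(vals >= lo) & (vals < edges[-1])]
        cnt, _ = np.histogram(vals, bins=edges)
        counts[g] = cnt
        densities[g] = cnt / bin_volume
    return DensityProfile(axis, edges, densities, counts, bin_volume)


def _refine_peak(centers: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic sub-bin refinement of a local maximum at index ``i``."""
    if i == 0 or i == len(y) - 1:
        return float(centers[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(centers[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(centers[i] + np.clip(delta, -0.5, 0.5) * (centers[1] - centers[0]))


def _local_maxima(y: np.ndarray) -> list[int]:
    out = []
    n = len(y)
    for i in range(n):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < n - 1 else -np.inf
        if y[i] > 0 and y[i] >= left and y[i] > right:
            out.append(i)
    return out


def bilayer_thickness(profile: DensityProfile, group: str = "polar_head") -> float:
    """Distance between the two dominant polar-head density maxima (nm)."""
    y = profile.densities[group]
    centers = profile.centers
    peaks = _local_maxima(y)
    # merge maxima closer than 3 bins into one (noise shoulders)
    peaks.sort(key=lambda i: y[i], reverse=True)
    distinct: list[int] = []
    for i in peaks:
        if all(abs(i - j) > 2 for j in distinct):
            distinct.append(i)
    if len(distinct) < 2:
        raise NotABilayerError("polar-head profile has fewer than two maxima")
    a, b = distinct[0], distinct[1]
    return abs(_refine_peak(centers, y, a) - _refine_peak(centers, y, b))


def core_thickness(profile: DensityProfile, group: str = "hydrophobic_total") -> float:
    """Full width at half maximum of the hydrophobic density (nm).

    The width is measured between the outermost half-maximum crossings,
    linearly interpolated between bin centers, so an interior dip (e.g.
    between non-touching leaflets) does not narrow the estimate.
    """
    y = profile.densities[group].astype(float)
    if y.max() <= 0:
        raise ValueError("hydrophobic density is identically zero")
    centers = profile.centers
    half = y.max() / 2.0
    above = np.nonzero(y >= half)[0]
    i0, i1 = above[0], above[-1]
    # left crossing
    if i0 == 0:
        left = centers[0] - profile.bin_width / 2
    else:
        f = (half - y[i0 - 1]) / (y[i0] - y[i0 - 1])
        left = centers[i0 - 1] + f * (centers[i0] - centers[i0 - 1])
    if i1 == len(y) - 1:
        right = centers[-1] + profile.bin_width / 2
    else:
        f = (y[i1] - half) / (y[i1] - y[i1 + 1])
        right = centers[i1] + f * (centers[i1 + 1] - centers[i1])
    return float(right - left)


# ---------------------------------------------------------------------------
# molecular lengths and interdigitation


def monomer_length(frame: BeadFrame, molecule_ids=None) -> tuple[float, float]:
    """Mean monomer length L and tail length l_t (nm).

    L is the distance from the polar-head centroid of a molecule to each
    of its distal tail (tail_end) beads; l_t is the distance from the
    first tail carbon to the distal bead of the same tail, paired through
    the ``T<t>A`` / ``T<t>..`` naming convention.
    """
    if molecule_ids is None:
        molecule_ids = range(frame.n_molecules)
    head_mask = frame.select("polar_head")
    end_mask = frame.select("tail_end")
    if not head_mask.any() or not end_mask.any():
        raise ValueError("frame lacks polar_head or tail_end labels")
    L_vals: list[float] = []
    lt_vals: list[float] = []
    for m in molecule_ids:
        mol = frame.molecule_id == m
        heads = frame.coords[mol & head_mask]
        ends_idx = np.nonzero(mol & end_mask)[0]
        if len(heads) == 0 or len(ends_idx) == 0:
            raise ValueError(f"molecule {m} lacks head or tail-end beads")
        ref = heads.mean(axis=0)
        for ei in ends_idx:
            end = frame.coords[ei]
            L_vals.append(float(np.linalg.norm(end - ref)))
            name = str(frame.bead_name[ei])
            first_name = name[:-1] + "A"
            fi = np.nonzero(mol & (frame.bead_name == first_name))[0]
            if len(fi) and fi[0] != ei:
                lt_vals.append(float(np.linalg.norm(end - frame.coords[fi[0]])))
    return float(np.mean(L_vals)), float(np.mean(lt_vals)) if lt_vals else 0.0


def interdigitation_ratio(thickness: float, monomer: float) -> tuple[float, str]:
    """Ratio D/(2L) and its classification.

    A bilayer whose thickness exceeds twice the monomer length cannot
    have interdigitated leaflets.
    """
    if thickness <= 0 or monomer <= 0:
        raise ValueError("lengths must be positive")
    ratio = thickness / (2.0 * monomer)
    if ratio > 1.0:
        label = "non_interdigitated"
    elif ratio == 1.0:
        label = "boundary"
    else:
        label = "interdigitated"
    return ratio, label


# ---------------------------------------------------------------------------
# SASA


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 0.264, n_points: int = 960,
                       ) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Each bead surface (radius + probe) is sampled on a deterministic
    Fibonacci point set; a point is accessible when it lies outside every
    neighbouring expanded sphere.  Returns (total, per-bead) areas.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if len(radii) != len(coords):
        raise ValueError("need one radius per bead")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    if n_points < 92:
        raise ValueError("use at least 92 sphere points")
    unit = _fibonacci_sphere(n_points, np.random.default_rng(0))
    expanded = radii + probe
    tree = cKDTree(coords)
    per_bead = np.zeros(len(coords))
    rmax = expanded.max()
    for i in range(len(coords)):
        ri = expanded[i]
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax)
                if j != i]
        pts = coords[i] + ri * unit
        if nbrs:
            nbrs = np.array(nbrs)
            # drop exact duplicates of bead i: they occlude nothing extra
            dup = np.all(np.isclose(coords[nbrs], coords[i]), axis=1) & np.isclose(
                expanded[nbrs], ri)
            # a duplicated bead pair shares one surface: count it once
            if dup.any() and i > nbrs[dup].min():
                continue
            nbrs = nbrs[~dup]
        if len(nbrs):
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nbrs] ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        per_bead[i] = 4.0 * np.pi * ri * ri * exposed / n_points
    return float(per_bead.sum()), per_bead


def frame_sasa(frame: BeadFrame, probe: float = 0.264, n_points: int = 960,
               radii: np.ndarray | None = None) -> dict:
    """Total and per-molecule SASA of a frame (uses frame bead radii)."""
    if radii is None:
        if frame.radius is None:
            raise ValueError("frame carries no bead radii; pass radii=")
        radii = frame.radius
    total, per_bead = shrake_rupley_sasa(frame.coords, radii, probe, n_points)
    per_mol = np.zeros(frame.n_molecules)
    np.add.at(per_mol, frame.molecule_id, per_bead)
    return {"total": total, "per_molecule": per_mol}


@dataclass
class SasaSeries:
    time_ps: np.ndarray
    sasa: np.ndarray
    probe: float = 0.264
    n_points: int = 960

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.sasa = np.asarray(self.sasa, dtype=float)
        if np.any(self.sasa < 0):
            raise ValueError("SASA values must be non-negative")


def sasa_plateau(series: SasaSeries, window: int | None = None,
                 slope_tol: float | None = None) -> float | None:
    """Earliest time from which the series stays flat, or None.

    A sliding window of ``window`` points is fitted linearly; the series
    has plateaued from the first window whose slope — and that of every
    later window — stays within ``slope_tol``.  Defaults: window is 10%
    of the series, tolerance a slope shedding 1% of the series mean per
    window span.  Returns ``None`` when the series never flattens
    ("not converged").
    """
    t, y = series.time_ps, series.sasa
    n = len(y)
    if window is None:
        window = max(3, n // 10)
    if n < 2 * window:
        raise ValueError("need at least two windows of data")
    span = t[window - 1] - t[0]
    if slope_tol is None:
        slope_tol = 0.01 * float(np.mean(np.abs(y))) / span if span > 0 else 0.0
    starts = range(0, n - window + 1)
    slopes = np.array([
        np.polyfit(t[i:i + window], y[i:i + window], 1)[0] for i in starts
    ])
    ok = np.abs(slopes) <= slope_tol
    # earliest start from which every later window is flat
    flat_from = None
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            flat_from = i
        else:
            break
    if flat_from is None:
        return None
    return float(t[flat_from])


# ---------------------------------------------------------------------------
# packing parameter


@dataclass(frozen=True)
class PackingParams:
    v: float      # hydrocarbon chain volume, nm^3
    a0: float     # optimal head-group area, nm^2
    lc: float     # chain length, nm
    p: float
    shape_class: str


def tanford_chain_volume(n_carbons: int, n_chains: int = 1) -> float:
    """Tanford estimate of hydrocarbon volume: (27.4 + 26.9 n) A^3/chain."""
    return n_chains * (0.0274 + 0.0269 * n_carbons)


def packing_parameter(v: float, a0: float, lc: float) -> PackingParams:
    """Amphiphile shape factor p = v / (a0 * lc) with morphology class.

    p < 1/3 permits spherical micelles; 1/3..1/2 cylindrical micelles;
    1/2..1 flexible bilayers and vesicles; >= 1 planar or inverted
    phases.  Values on a boundary are flagged as such.
    """
    if min(v, a0, lc) <= 0:
        raise ValueError("v, a0 and lc must all be positive")
    p = v / (a0 * lc)
    if any(np.isclose(p, b, rtol=1e-9, atol=0.0) for b in (1.0 / 3.0, 0.5, 1.0)):
        label = "boundary"
    elif p < 1.0 / 3.0:
        label = "spherical_micelle"
    elif p < 0.5:
        label = "cylindrical_micelle"
    elif p < 1.0:
        label = "bilayer_vesicle"
    else:
        label = "planar_or_inverted"
    return PackingParams(v, a0, lc, p, label)
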