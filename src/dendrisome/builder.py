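"""Initial-system construction for coarse-grained self-assembly runs.

Builds the dilute starting state — many copies of the coarse-grained
dendrimer dropped at random orientations and positions into an
orthorhombic water box — and emits the GROMACS run-parameter (MDP) and
topology stub files.  Water beads are not placed explicitly: the
analyses in this package never need solvent, and a user can solvate the
emitted coordinates externally.  Actually running the molecular dynamics
is outside the scope of the package.

The reference system is 1700 dendrimers in a 37.6 x 37.4 x 37 nm box at
310 K and 1 bar (velocity-rescaling thermostat, Parrinello-Rahman
barostat, 30 fs time step, non-bonded shifts 0.9/0.0 -> 1.2 nm, PME).
The geometric concentration of that system is ~54 mM; see
``docs/methods.md`` for the discrepancy with the nominal 76 mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgmap import CGTopology
from .constants import AVOGADRO
from .structures import BeadFrame, single_molecule_frame

__all__ = [
    "SimulationBox",
    "SystemSpec",
    "RunConfig",
    "PackingError",
    "random_pack",
    "concentration",
    "emit_run_config",
    "emit_topology_stub",
    "REFERENCE_SYSTEM",
    "REFERENCE_RUN_CONFIG",
]


class PackingError(RuntimeError):
    """Random placement failed to reach the requested molecule count."""


@dataclass(frozen=True)
class SimulationBox:
    lengths: tuple[float, float, float]  # nm

    def __post_init__(self) -> None:
        if min(self.lengths) <= 0:
            raise ValueError("box lengths must be positive")

    @property
    def volume(self) -> float:
        lx, ly, lz = self.lengths
        return lx * ly * lz

    def as_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)


@dataclass(frozen=True)
class SystemSpec:
    n_molecules: int
    box: SimulationBox
    min_separation: float = 0.5   # nm, about one bead diameter
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    temperature: float = 310.0          # K
    pressure: float = 1.0               # bar
    thermostat: str = "v-rescale"
    barostat: str = "parrinello-rahman"
    timestep: float = 0.03              # ps (30 fs)
    n_steps: int = 433_333_333          # ~13 us at 30 fs
    lj_shift_start: float = 0.9         # nm
    coulomb_shift_start: float = 0.0    # nm
    cutoff: float = 1.2                 # nm
    electrostatics: str = "PME"

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.cutoff < max(self.lj_shift_start, self.coulomb_shift_start):
            raise ValueError("cutoff must be at least the shift starts")


REFERENCE_SYSTEM = SystemSpec(
    n_molecules=1700,
    box=SimulationBox((37.6, 37.4, 37.0)),
    min_separation=0.5,
    seed=0,
)

REFERENCE_RUN_CONFIG = RunConfig()


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class _CellGrid:
    """Periodic cell list for fast minimum-separation checks."""

    def __init__(self, box: np.ndarray, cell: float) -> None:
        self.box = box
        self.n = np.maximum(1, np.floor(box / cell).astype(int))
        self.cell = box / self.n
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> np.ndarray:
        return np.minimum((p / self.cell).astype(int), self.n - 1)

    def neighbours(self, p: np.ndarray) -> np.ndarray:
        k = self._key(p)
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    kk = tuple((k + (dx, dy, dz)) % self.n)
                    out.extend(self.cells.get(kk, ()))
        return np.array(out).reshape(-1, 3)

    def add(self, pts: np.ndarray) -> None:
        for p in pts:
            kk = tuple(self._key(p))
            self.cells.setdefault(kk, []).append(p)


def random_pack(template: CGTopology, spec: SystemSpec,
                template_coords: np.ndarray | None = None) -> BeadFrame:
    """Place ``n_molecules`` randomly rotated/translated molecule copies.

    Rejection sampling: each candidate placement is accepted only when
    every bead keeps at least ``min_separation`` (minimum image) from all
    previously placed molecules.  Deterministic for a fixed seed.  Raises
    :class:`PackingError` after ``max_attempts`` failures per molecule,
    reporting how many molecules were placed.
    """
    box = spec.box.as_array()
    if template_coords is None:
        template_coords = single_molecule_frame(template)
    template_coords = np.asarray(template_coords, dtype=float)
    rng = np.random.default_rng(spec.seed)

    if spec.n_molecules == 1:
        coords = [(template_coords - template_coords.mean(axis=0)) + box / 2]
        return _pack_frame(coords, template, box)

    grid = _CellGrid(box, max(spec.min_separation, 0.5))
    placed: list[np.ndarray] = []
    for m in range(spec.n_molecules):
        for _attempt in range(spec.max_attempts):
            rot = _random_rotation(rng)
            shift = rng.uniform(0.0, 1.0, 3) * box
            xyz = (template_coords @ rot.T + shift) % box
            if spec.min_separation > 0 and placed:
                ok = True
                for p in xyz:
                    nbrs = grid.neighbours(p)
                    if len(nbrs):
                        d = nbrs - p
                        d -= box * np.round(d / box)
                        if (np.einsum("ij,ij->i", d, d)
                                < spec.min_separation**2).any():
                            ok = False
                            break
                if not ok:
                    continue
            placed.append(xyz)
            grid.add(xyz)
            break
        else:
            raise PackingError(
                f"placed only {m} of {spec.n_molecules} molecules after "
                f"{spec.max_attempts} attempts each; box too dense for "
                f"min_separation={spec.min_separation}"
            )
    return _pack_frame(placed, template, box)


def _pack_frame(placed: list[np.ndarray], template: CGTopology,
                box: np.ndarray) -> BeadFrame:
    n = len(placed)
    nb = template.n_beads
    names = [b.name for b in template.beads]
    groups = [b.group_class.value for b in template.beads]
    radii = [b.vdw_radius for b in template.beads]
    return BeadFrame(
        coords=np.concatenate(placed) if placed else np.zeros((0, 3)),
        box=box,
        molecule_id=np.repeat(np.arange(n), nb),
        bead_name=np.tile(np.array(names, dtype=object), n),
        group_class=np.tile(np.array(groups, dtype=object), n),
        radius=np.tile(np.array(radii, dtype=float), n),
        ground_truth={"kind": "random_pack", "n_molecules": n},
    )


def concentration(n_molecules: int, box: SimulationBox) -> float:
    """Molar concentration in mM of ``n`` molecules in the box.

    1 molecule per 1/0.602214 nm^3 is 1 M by definition.
    """
    litres = box.volume * 1e-24
    return n_molecules / (AVOGADRO * litres) * 1e3


# MDP key order is fixed so emitted files are byte-stable
_MDP_TEMPLATE = (
    ("integrator", "md"),
    ("dt", "{dt}"),
    ("nsteps", "{nsteps}"),
    ("nstxout-compressed", "50000"),
    ("cutoff-scheme", "Verlet"),
    ("nstlist", "20"),
    ("vdwtype", "cutoff"),
    ("vdw-modifier", "Potential-shift"),
    ("rvdw-switch", "{lj_shift}"),
    ("rvdw", "{cutoff}"),
    ("coulombtype", "{electrostatics}"),
    ("rcoulomb-switch", "{coulomb_shift}"),
    ("rcoulomb", "{cutoff}"),
    ("tcoupl", "{thermostat}"),
    ("tc-grps", "System"),
    ("tau-t", "1.0"),
    ("ref-t", "{ref_t}"),
    ("pcoupl", "{barostat}"),
    ("pcoupltype", "isotropic"),
    ("tau-p", "12.0"),
    ("ref-p", "{ref_p}"),
    ("compressibility", "3e-4"),
    ("gen-vel", "yes"),
    ("gen-temp", "{ref_t}"),
    ("gen-seed", "{seed}"),
)


def emit_run_config(rc: RunConfig, seed: int = 42) -> str:
    """GROMACS MDP key=value text for the run settings."""
    subs = {
        "dt": f"{rc.timestep:g}",
        "nsteps": str(rc.n_steps),
        "lj_shift": f"{rc.lj_shift_start:g}",
        "coulomb_shift": f"{rc.coulomb_shift_start:g}",
        "cutoff": f"{rc.cutoff:g}",
        "electrostatics": rc.electrostatics,
        "thermostat": rc.thermostat,
        "barostat": rc.barostat,
        "ref_t": f"{rc.temperature:g}",
        "ref_p": f"{rc.pressure:g}",
        "seed": str(seed),
    }
    lines = [f"{key:<22s} = {val.format(**subs)}" for key, val in _MDP_TEMPLATE]
    return "\n".join(lines) + "\n"


def emit_topology_stub(molecule_name: str, n_molecules: int,
                       itp_filename: str) -> str:
    """Minimal .top referencing the molecule ITP."""
    return (
        f'#include "{itp_filename}"\n\n'
        "[ system ]\n"
        f"{molecule_name} self-assembly\n\n"
        "[ molecules ]\n"
        f"{molecule_name}  {n_molecules}\n"
    )
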