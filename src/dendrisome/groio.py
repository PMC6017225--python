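"""Fixed-column GRO coordinate reading and writing.

GRO is the GROMACS coordinate format: a title line, an atom count, one
fixed-width record per atom (residue number/name, atom name, atom
number, x y z in nm at three decimals, optional velocities) and a box
line.  Multiple concatenated frames in one file are supported and are
the package's trajectory interchange format.  Coordinates round-trip
losslessly at the format's 0.001 nm quantization; residue and atom
numbers wrap modulo 100000 as the format prescribes.

Molecules map to residues (one residue per molecule) and the per-bead
group class, which GRO cannot carry, is reconstructed from the bead
naming convention of :mod:`dendrisome.cgmap` (override with
``name_to_group``).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .cgmap import _group_from_name
from .structures import BeadFrame

__all__ = ["read_gro", "read_gro_frames", "write_gro", "GroParseError"]


class GroParseError(ValueError):
    """Malformed GRO content; the message carries the offending line number."""


def default_name_to_group(name: str) -> str:
    return _group_from_name(name).value


def write_gro(frame: BeadFrame, title: str = "dendrisome frame") -> str:
    """Serialize one frame as GRO text (deterministic, velocity-free)."""
    t = f"{title} t= {frame.time_ps:.3f}" if frame.time_ps is not None else title
    lines = [t, f"{frame.n_beads:5d}"]
    resname = "JD"
    for i in range(frame.n_beads):
        resnr = (int(frame.molecule_id[i]) + 1) % 100000
        atomnr = (i + 1) % 100000
        x, y, z = frame.coords[i]
        lines.append(
            f"{resnr:5d}{resname:<5s}{str(frame.bead_name[i]):>5s}{atomnr:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    bx, by, bz = frame.box
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    return "\n".join(lines) + "\n"


def write_gro_frames(frames: Iterable[BeadFrame], title: str = "dendrisome frame") -> str:
    return "".join(write_gro(f, title) for f in frames)


def read_gro_frames(text: str,
                    name_to_group: Callable[[str], str] = default_name_to_group,
                    ) -> list[BeadFrame]:
    """Parse one or more concatenated GRO frames."""
    lines = text.splitlines()
    frames: list[BeadFrame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip() and all(not l.strip() for l in lines[pos:]):
            break
        frames.append(_parse_frame(lines, pos, name_to_group))
        natoms = frames[-1].n_beads
        pos += natoms + 3
    return frames


def read_gro(text: str,
             name_to_group: Callable[[str], str] = default_name_to_group,
             ) -> BeadFrame:
    """Parse a single-frame GRO (first frame of a multi-frame file)."""
    frames = read_gro_frames(text, name_to_group)
    if not frames:
        raise GroParseError("no frames found")
    return frames[0]


def _parse_frame(lines: list[str], start: int,
                 name_to_group: Callable[[str], str] = default_name_to_group,
                 ) -> BeadFrame:
    if start + 1 >= len(lines):
        raise GroParseError(f"line {start + 1}: truncated header")
    title = lines[start]
    time_ps = None
    if " t= " in title:
        try:
            time_ps = float(title.rsplit(" t= ", 1)[1].split()[0])
        except (ValueError, IndexError):
            pass
    try:
        natoms = int(lines[start + 1])
    except ValueError:
        raise GroParseError(
            f"line {start + 2}: expected atom count, got {lines[start + 1]!r}"
        ) from None
    if start + 2 + natoms >= len(lines):
        raise GroParseError(
            f"file truncated: frame at line {start + 1} promises {natoms} atoms"
        )

    coords = np.empty((natoms, 3))
    names = np.empty(natoms, dtype=object)
    resnrs = np.empty(natoms, dtype=int)
    for k in range(natoms):
        ln = lines[start + 2 + k]
        lineno = start + 3 + k
        if len(ln) < 44:
            raise GroParseError(f"line {lineno}: record shorter than 44 columns")
        try:
            resnrs[k] = int(ln[0:5])
            names[k] = ln[10:15].strip()
            coords[k] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except ValueError:
            raise GroParseError(f"line {lineno}: malformed fixed-width fields") from None

    box_line = lines[start + 2 + natoms].split()
    if len(box_line) < 3:
        raise GroParseError(f"line {start + 3 + natoms}: malformed box line")
    box = np.array([float(v) for v in box_line[:3]])

    # residues -> contiguous molecule ids, tolerant of the modulo-100000 wrap
    mol = np.zeros(natoms, dtype=int)
    if natoms:
        current = 0
        for k in range(1, natoms):
            if resnrs[k] != resnrs[k - 1]:
                current += 1
            mol[k] = current
    groups = np.array([name_to_group(n) for n in names], dtype=object)
    return BeadFrame(coords=coords, box=box, molecule_id=mol,
                     bead_name=names, group_class=groups, time_ps=time_ps)
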