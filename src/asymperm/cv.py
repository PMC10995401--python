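"""Membrane-normal collective variable from coordinate snapshots.

The reaction coordinate for insertion/adsorption is the oriented z-distance
between a probe group's center of mass (a peptide terminus: its first or
last three backbone beads) and the *local* membrane center of mass —
computed from membrane particles inside a vertical cylinder (default radius
2.0 nm) centered on the probe group's xy position.  Using a local rather
than global membrane COM makes the coordinate robust to membrane
undulations far from the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmptyCylinderError(RuntimeError):
    """No membrane particle inside the CV cylinder — pathological geometry."""


@dataclass(frozen=True)
class CVDefinition:
    """Geometry of the collective variable: cylinder radius (nm), z axis."""

    cylinder_radius: float = 2.0
    axis: str = "z"

    def __post_init__(self):
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be > 0")
        if self.axis != "z":
            raise ValueError("only the z axis is supported")


@dataclass
class Snapshot:
    """Particle coordinates with masses and roles, plus the periodic box.

    ``role`` entries are 'membrane', 'probe' or 'other'.  x/y are treated as
    periodic (minimum image) for the cylinder membership test; z — the
    membrane normal — is not.
    """

    xyz: np.ndarray          # (N, 3) nm
    mass: np.ndarray         # (N,) amu
    role: np.ndarray         # (N,) str
    box: tuple[float, float, float]

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.role = np.asarray(self.role, dtype=object)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (N, 3)")
        n = self.xyz.shape[0]
        if self.mass.shape != (n,) or self.role.shape != (n,):
            raise ValueError("mass and role must have one entry per particle")
        if np.any(self.mass <= 0):
            raise ValueError("masses must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if not np.any(self.role == "membrane") or not np.any(self.role == "probe"):
            raise ValueError("snapshot needs at least one membrane and one probe particle")

    def select(self, role: str):
        m = self.role == role
        return self.xyz[m], self.mass[m]


def _com(xyz: np.ndarray, mass: np.ndarray) -> np.ndarray:
    return (xyz * mass[:, None]).sum(axis=0) / mass.sum()


def local_membrane_com_z(snap: Snapshot, axis_xy: tuple[float, float],
                         cv: CVDefinition = CVDefinition()) -> float:
    """Mass-weighted mean z of membrane particles inside the CV cylinder.

    Cylinder membership uses the minimum-image xy distance to ``axis_xy``.
    Raises :class:`EmptyCylinderError` if no membrane particle is inside.
    """
    xyz, mass = snap.select("membrane")
    dx = xyz[:, 0] - axis_xy[0]
    dy = xyz[:, 1] - axis_xy[1]
    Lx, Ly, _ = snap.box
    dx -= Lx * np.round(dx / Lx)
    dy -= Ly * np.round(dy / Ly)
    inside = dx**2 + dy**2 <= cv.cylinder_radius**2
    if not np.any(inside):
        raise EmptyCylinderError(
            f"no membrane particle within {cv.cylinder_radius} nm of "
            f"xy = {axis_xy}")
    m = mass[inside]
    return float((xyz[inside, 2] * m).sum() / m.sum())


def oriented_distance(snap: Snapshot,
                      cv: CVDefinition = CVDefinition()) -> float:
    """The collective variable: z of the probe COM minus the local membrane COM z.

    The cylinder is centered on the probe group's instantaneous xy center of
    mass.  Positive when the probe sits above the local membrane center.
    """
    xyz, mass = snap.select("probe")
    probe_com = _com(xyz, mass)
    mem_z = local_membrane_com_z(snap, (probe_com[0], probe_com[1]), cv)
    return float(probe_com[2] - mem_z)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_snapshot(path) -> Snapshot:
    """Read a snapshot from a minimal whitespace table.

    Layout: comment lines start with '#' or '@'; one line ``box Lx Ly Lz``;
    particle lines ``id role mass x y z`` (id is ignored).
    """
    box = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s[0] in "#@":
                continue
            parts = s.split()
            if parts[0] == "box":
                box = tuple(float(v) for v in parts[1:4])
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 'id role mass x y z'")
            rows.append((parts[1], float(parts[2]),
                         float(parts[3]), float(parts[4]), float(parts[5])))
    if box is None:
        raise ValueError(f"{path}: missing 'box Lx Ly Lz' line")
    if not rows:
        raise ValueError(f"{path}: no particle rows")
    role = np.array([r[0] for r in rows], dtype=object)
    mass = np.array([r[1] for r in rows])
    xyz = np.array([r[2:5] for r in rows])
    return Snapshot(xyz=xyz, mass=mass, role=role, box=box)


def read_gro_snapshot(path, role_by_resname: dict[str, str],
                      mass_by_atomname: dict[str, float] | None = None,
                      default_mass: float = 72.0) -> Snapshot:
    """Convenience GRO-format reader (fixed-column, single frame).

    Roles are assigned from residue names via ``role_by_resname`` (anything
    unmapped becomes 'other'); masses from ``mass_by_atomname`` with
    ``default_mass`` as fallback (72 amu, a regular Martini bead).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[1].strip())
    rows = lines[2:2 + n]
    box_parts = lines[2 + n].split()
    box = (float(box_parts[0]), float(box_parts[1]), float(box_parts[2]))
    xyz = np.empty((n, 3))
    mass = np.empty(n)
    role = np.empty(n, dtype=object)
    for i, line in enumerate(rows):
        resname = line[5:10].strip()
        atomname = line[10:15].strip()
        xyz[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
        role[i] = role_by_resname.get(resname, "other")
        mass[i] = (mass_by_atomname or {}).get(atomname, default_mass)
    return Snapshot(xyz=xyz, mass=mass, role=role, box=box)
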