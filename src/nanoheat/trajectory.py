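"""Particle trajectory container and plain-text trajectory IO.

Two dialects are supported: extended-XYZ (the native format, written and
read losslessly with velocities, masses, box and time metadata) and the
LAMMPS dump text format (read-only convenience; ``real`` units, i.e.
Angstrom and fs, converted to nm and ps on ingest).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "read_extended_xyz",
    "write_extended_xyz",
    "read_lammps_dump",
]


@dataclass
class Trajectory:
    """Frames of particle positions (and optionally velocities).

    Attributes
    ----------
    positions : (n_frames, n_atoms, 3) array, nm
    velocities : (n_frames, n_atoms, 3) array in nm/ps, or None
    masses : (n_atoms,) array, g/mol
    species : (n_atoms,) array of str labels
    box : (3,) array, nm
    periodic : (3,) bool array
    times : (n_frames,) array, ps
    """

    positions: np.ndarray
    masses: np.ndarray
    species: np.ndarray
    box: np.ndarray
    times: np.ndarray
    velocities: np.ndarray | None = None
    periodic: np.ndarray = field(default_factory=lambda: np.array([True, True, False]))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        self.masses = np.asarray(self.masses, dtype=float)
        self.species = np.asarray(self.species, dtype=str)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")
        n = self.n_atoms
        if self.masses.shape != (n,) or self.species.shape != (n,):
            raise ValueError("masses and species must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def area_xy(self) -> float:
        """Interface area Lx*Ly in nm^2."""
        return float(self.box[0] * self.box[1])

    def select(self, species) -> np.ndarray:
        """Boolean mask of atoms whose species label is in `species`."""
        if species is None:
            return np.ones(self.n_atoms, dtype=bool)
        if isinstance(species, str):
            species = [species]
        return np.isin(self.species, list(species))


# ---------------------------------------------------------------------------
# extended-XYZ


def _format_comment(traj: Trajectory, iframe: int, with_vel: bool) -> str:
    lx, ly, lz = traj.box
    lattice = f"{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 {lz:.10g}"
    props = "species:S:1:pos:R:3"
    if with_vel:
        props += ":vel:R:3"
    props += ":mass:R:1"
    pbc = " ".join("T" if p else "F" for p in traj.periodic)
    return (
        f'Lattice="{lattice}" Properties={props} Time={traj.times[iframe]:.10g} '
        f'pbc="{pbc}" distance_unit=nm time_unit=ps'
    )


def write_extended_xyz(traj: Trajectory, path) -> None:
    with_vel = traj.velocities is not None
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(_format_comment(traj, i, with_vel) + "\n")
            for j in range(traj.n_atoms):
                x, y, z = traj.positions[i, j]
                line = f"{traj.species[j]} {x:.17g} {y:.17g} {z:.17g}"
                if with_vel:
                    vx, vy, vz = traj.velocities[i, j]
                    line += f" {vx:.17g} {vy:.17g} {vz:.17g}"
                line += f" {traj.masses[j]:.17g}"
                fh.write(line + "\n")


_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(comment):
        out[m.group(1)] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def read_extended_xyz(path) -> Trajectory:
    frames_pos, frames_vel, times = [], [], []
    species = masses = box = periodic = None
    n_expected = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise ValueError(
                f"frame {frame_no}: atom count {n} differs from first frame "
                f"({n_expected}) at line {i + 1}"
            )
        if i + 1 >= len(lines):
            raise ValueError(f"line {i + 2}: missing comment line")
        meta = _parse_comment(lines[i + 1])
        if "Lattice" in meta:
            cell = np.fromstring(meta["Lattice"], sep=" ").reshape(3, 3)
            box = np.diag(cell).copy()
        elif box is None:
            raise ValueError(f"frame {frame_no}: no Lattice in header")
        if "pbc" in meta:
            periodic = np.array([t == "T" for t in meta["pbc"].split()])
        times.append(float(meta.get("Time", frame_no - 1.0)))
        props = meta.get("Properties", "species:S:1:pos:R:3:mass:R:1")
        fields = props.split(":")
        cols, col = {}, 0
        for k in range(0, len(fields), 3):
            name, _, width = fields[k], fields[k + 1], int(fields[k + 2])
            cols[name] = (col, width)
            col += width
        has_vel = "vel" in cols
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"frame {frame_no}: truncated (expected {n} atoms)")
        sp, ms, pos, vel = [], [], [], []
        for k, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < col:
                raise ValueError(
                    f"frame {frame_no}, line {i + 3 + k}: expected {col} columns"
                )
            c0, _ = cols["species"]
            sp.append(parts[c0])
            c0, _ = cols["pos"]
            pos.append([float(parts[c0 + a]) for a in range(3)])
            if has_vel:
                c0, _ = cols["vel"]
                vel.append([float(parts[c0 + a]) for a in range(3)])
            if "mass" in cols:
                c0, _ = cols["mass"]
                ms.append(float(parts[c0]))
        if species is None:
            species = np.array(sp)
            masses = np.array(ms) if ms else np.full(n, np.nan)
        frames_pos.append(np.array(pos))
        if has_vel:
            frames_vel.append(np.array(vel))
        i += 2 + n
    if not frames_pos:
        raise ValueError("empty trajectory file")
    vel_arr = np.array(frames_vel) if frames_vel else None
    if periodic is None:
        periodic = np.array([True, True, False])
    return Trajectory(
        positions=np.array(frames_pos),
        velocities=vel_arr,
        masses=masses,
        species=species,
        box=box,
        periodic=periodic,
        times=np.array(times),
    )


# ---------------------------------------------------------------------------
# LAMMPS dump (text), `real` units: Angstrom, fs

_ANG_TO_NM = 0.1
_ANG_FS_TO_NM_PS = 100.0  # (0.1 nm) / (1e-3 ps)


def read_lammps_dump(path, masses=None, time_unit_ps: float = 1e-3) -> Trajectory:
    """Read a text LAMMPS dump.

    Supported ATOMS columns: id, type/element, x|xs|xu (y, z likewise),
    vx vy vz, mass. Scaled coordinates (xs...) are unscaled against the box
    bounds. `masses` (g/mol, per atom after id-sorting) overrides or supplies
    the mass column; timestep numbers are converted to ps via `time_unit_ps`.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames_pos, frames_vel, times = [], [], []
    species = file_masses = None
    box = None
    n_expected = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            if not lines[i].strip():
                i += 1
                continue
            raise ValueError(f"line {i + 1}: expected 'ITEM: TIMESTEP'")
        frame_no += 1
        step = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ValueError(f"line {i + 3}: expected 'ITEM: NUMBER OF ATOMS'")
        n = int(lines[i + 3])
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise ValueError(
                f"frame {frame_no}: atom count {n} differs from first frame ({n_expected})"
            )
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ValueError(f"line {i + 5}: expected 'ITEM: BOX BOUNDS'")
        bounds_flags = lines[i + 4].split()[3:6]
        lo, hi = np.empty(3), np.empty(3)
        for a in range(3):
            lo[a], hi[a] = (float(v) for v in lines[i + 5 + a].split()[:2])
        box = (hi - lo) * _ANG_TO_NM
        periodic = np.array([f.startswith("pp") for f in bounds_flags]) if bounds_flags else np.array([True, True, False])
        if not lines[i + 8].startswith("ITEM: ATOMS"):
            raise ValueError(f"line {i + 9}: expected 'ITEM: ATOMS'")
        columns = lines[i + 8].split()[2:]
        ci = {c: k for k, c in enumerate(columns)}
        scaled = "xs" in ci
        unwrapped = "xu" in ci
        xyz = ("xs", "ys", "zs") if scaled else (("xu", "yu", "zu") if unwrapped else ("x", "y", "z"))
        for c in xyz:
            if c not in ci:
                raise ValueError(f"frame {frame_no}: missing coordinate column {c!r}")
        has_vel = "vx" in ci
        body = lines[i + 9 : i + 9 + n]
        if len(body) < n:
            raise ValueError(f"frame {frame_no}: truncated atom section")
        rec = np.array([ln.split() for ln in body], dtype=object)
        order = np.argsort(rec[:, ci["id"]].astype(int)) if "id" in ci else np.arange(n)
        rec = rec[order]
        pos = rec[:, [ci[c] for c in xyz]].astype(float)
        if scaled:
            pos = lo * _ANG_TO_NM + pos * box
        else:
            pos = pos * _ANG_TO_NM
        frames_pos.append(pos)
        if has_vel:
            frames_vel.append(
                rec[:, [ci["vx"], ci["vy"], ci["vz"]]].astype(float) * _ANG_FS_TO_NM_PS
            )
        if species is None:
            key = "element" if "element" in ci else "type"
            species = rec[:, ci[key]].astype(str)
            if "mass" in ci:
                file_masses = rec[:, ci["mass"]].astype(float)
        times.append(step * time_unit_ps)
        i += 9 + n
    if not frames_pos:
        raise ValueError("empty dump file")
    if masses is None:
        masses = file_masses
    if masses is None:
        raise ValueError("dump has no mass column; pass masses= explicitly")
    return Trajectory(
        positions=np.array(frames_pos),
        velocities=np.array(frames_vel) if frames_vel else None,
        masses=np.asarray(masses, dtype=float),
        species=species,
        box=box,
        periodic=periodic,
        times=np.array(times),
    )


def read_trajectory(path, dialect: str = "extended_xyz", **kwargs) -> Trajectory:
    if dialect == "extended_xyz":
        return read_extended_xyz(path)
    if dialect == "lammps_dump":
        return read_lammps_dump(path, **kwargs)
    raise ValueError(f"unknown trajectory dialect {dialect!r}")


def write_trajectory(traj: Trajectory, path, dialect: str = "extended_xyz") -> None:
    if dialect != "extended_xyz":
        raise ValueError("only the extended_xyz dialect is written")
    write_extended_xyz(traj, path)
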