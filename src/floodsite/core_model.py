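"""Topology/trajectory data model, readers and periodic-boundary geometry.

The in-memory model is deliberately small: a :class:`Topology` (atoms,
residue grouping, named selections), a :class:`Frame` (time, orthorhombic
box, positions) and a :class:`Trajectory` (topology + ordered frames).
Standard MD formats (DCD/XTC/GRO) are read through MDAnalysis; in addition
a self-describing plain-text frame archive is supported so synthetic data
round-trips through text files (format documented in docs/methods.md).

All atom indices are 0-based internally; PDB 1-based serials are converted
at the I/O boundary only. Boxes are orthorhombic; triclinic input raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "FormatError",
    "ELEMENT_MASSES",
    "load_topology",
    "write_pdb",
    "iter_frames",
    "read_frame_archive",
    "write_frame_archive",
    "minimum_image",
    "wrap_positions",
    "group_com",
    "molecule_groups",
    "unwrap_traces",
]

# Standard atomic weights (amu) for the elements that occur in
# protein/lipid/water/ion/ligand systems of this kind.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "ZN": 65.38,
    # unit-mass pseudo-particle used by the synthetic generator
    "X": 1.0,
}

_WATER_RESNAMES = {"TIP3", "TIP3P", "HOH", "SOL", "WAT", "SPC", "TIP4"}
_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}
DEFAULT_LIGAND_RESNAMES = frozenset({"ISO", "LIG", "IFL"})


class FormatError(ValueError):
    """A structure or trajectory file violates its format contract."""


@dataclass(frozen=True)
class Topology:
    """Atom table plus residue grouping and named atom selections.

    Atom ids are implicit: row ``i`` of every per-atom array is atom ``i``
    (dense, 0-based). ``selections`` maps labels such as ``"ligand"`` or
    ``"water_oxygen"`` to sorted arrays of atom ids.
    """

    names: tuple[str, ...]
    masses: np.ndarray  # (n_atoms,) amu, strictly positive
    residue_seq: np.ndarray  # (n_atoms,) int
    residue_names: tuple[str, ...]
    subunit_ids: tuple[str, ...]  # chain identifier per atom
    selections: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        masses = np.asarray(self.masses, dtype=float)
        if masses.shape != (n,):
            raise ValueError("masses length must equal atom count")
        if not np.all(masses > 0):
            raise ValueError("all atom masses must be strictly positive")
        object.__setattr__(self, "masses", masses)
        rs = np.asarray(self.residue_seq, dtype=int)
        if rs.shape != (n,):
            raise ValueError("residue_seq length must equal atom count")
        object.__setattr__(self, "residue_seq", rs)
        if len(self.residue_names) != n or len(self.subunit_ids) != n:
            raise ValueError("per-atom fields must share one length")
        sel = {}
        for label, ids in dict(self.selections).items():
            ids = np.asarray(ids, dtype=int)
            if ids.size and (ids.min() < 0 or ids.max() >= n):
                raise ValueError(
                    f"selection {label!r} references atom ids outside 0..{n - 1}"
                )
            sel[label] = np.sort(ids)
        object.__setattr__(self, "selections", sel)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(self, label: str) -> np.ndarray:
        try:
            return self.selections[label]
        except KeyError:
            raise KeyError(
                f"no selection {label!r}; available: {sorted(self.selections)}"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            self.names == other.names
            and np.allclose(self.masses, other.masses, atol=1e-3)
            and np.array_equal(self.residue_seq, other.residue_seq)
            and self.residue_names == other.residue_names
            and self.subunit_ids == other.subunit_ids
            and set(self.selections) == set(other.selections)
            and all(
                np.array_equal(self.selections[k], other.selections[k])
                for k in self.selections
            )
        )


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: time (ns), orthorhombic box edges (Å), positions (Å)."""

    time: float
    box: np.ndarray  # (3,) edge lengths
    positions: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=float)
        if box.shape != (3,) or not np.all(box > 0):
            raise ValueError("box must be three strictly positive edge lengths")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "positions", pos)


@dataclass
class Trajectory:
    """A topology with an ordered, fully materialized frame sequence."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for i, f in enumerate(self.frames):
            if f.positions.shape[0] != self.topology.n_atoms:
                raise ValueError(
                    f"frame {i} has {f.positions.shape[0]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions_array(self) -> np.ndarray:
        """All positions as one (n_frames, n_atoms, 3) array."""
        return np.stack([f.positions for f in self.frames])


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement components into ``(-L/2, +L/2]`` per box edge.

    Works on a single 3-vector or any (..., 3) array of displacements.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be strictly positive")
    return delta - box * np.ceil(delta / box - 0.5)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap absolute positions into the primary image ``[0, L)``."""
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    return positions - box * np.floor(positions / box)


def group_com(frame: Frame, group: np.ndarray, top: Topology) -> np.ndarray:
    """Mass-weighted center of mass of a group, periodic-image aware.

    Group atoms are unwrapped to the periodic image nearest the group's
    first atom (a deterministic anchor) before averaging, so groups that
    straddle a box boundary get a COM near the boundary rather than in
    the middle of the box.
    """
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("cannot compute the center of mass of an empty group")
    pos = frame.positions[group]
    anchor = pos[0]
    unwrapped = anchor + minimum_image(pos - anchor, frame.box)
    masses = top.masses[group]
    return (unwrapped * masses[:, None]).sum(axis=0) / masses.sum()


def molecule_groups(top: Topology, label: str) -> list[np.ndarray]:
    """Split a selection into molecules by (subunit, residue_seq), in order."""
    ids = top.select(label)
    if ids.size == 0:
        return []
    keys = [(top.subunit_ids[i], int(top.residue_seq[i])) for i in ids]
    groups: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for atom, key in zip(ids, keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(int(atom))
    return [np.array(groups[k], dtype=int) for k in order]


def unwrap_traces(traces: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from wrapped per-molecule COM traces.

    ``traces`` is (n_molecules, n_frames, 3); consecutive displacements are
    minimum-imaged and re-accumulated, which is exact as long as no true
    displacement between saved frames exceeds half a box edge.
    """
    traces = np.asarray(traces, dtype=float)
    steps = minimum_image(np.diff(traces, axis=-2), box)
    out = np.concatenate(
        [traces[..., :1, :], traces[..., :1, :] + np.cumsum(steps, axis=-2)], axis=-2
    )
    return out


# ---------------------------------------------------------------------------
# PDB I/O (strict fixed-column ATOM/HETATM reader)
# ---------------------------------------------------------------------------

def _mass_for(name: str, element: str) -> float:
    """Mass lookup: element column first, then leading letters of the name."""
    for key in (element.strip().upper(), ):
        if key and key in ELEMENT_MASSES:
            return ELEMENT_MASSES[key]
    stripped = name.strip().upper().lstrip("0123456789")
    for width in (2, 1):
        if stripped[:width] in ELEMENT_MASSES:
            return ELEMENT_MASSES[stripped[:width]]
    raise FormatError(
        f"cannot assign a mass to atom name {name!r} / element {element!r}; "
        "add the element to the mass table"
    )


def load_topology(
    path: str | Path,
    ligand_resnames: Iterable[str] = DEFAULT_LIGAND_RESNAMES,
) -> Topology:
    """Read ATOM/HETATM records from a PDB file into a :class:`Topology`.

    Residue grouping is by (chain, resSeq). The selections ``"protein"``,
    ``"water_oxygen"`` and ``"ligand"`` are built from residue-name rules;
    the ligand residue-name set is configurable.
    """
    path = Path(path)
    ligand_resnames = {r.upper() for r in ligand_resnames}
    names, masses, res_seq, res_names, chains = [], [], [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                resname = line[17:21].strip()
                chain = line[21].strip() or "A"
                seq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78] if len(line) >= 78 else ""
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: unparseable {rec} record ({exc})"
                ) from None
            del x, y, z  # topology ignores coordinates
            try:
                mass = _mass_for(name, element)
            except FormatError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from None
            names.append(name)
            masses.append(mass)
            res_seq.append(seq)
            res_names.append(resname)
            chains.append(chain)
    if not names:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    n = len(names)
    water_oxygen, ligand, protein = [], [], []
    for i in range(n):
        rn = res_names[i].upper()
        if rn in _PROTEIN_RESNAMES:
            protein.append(i)
        if rn in ligand_resnames:
            ligand.append(i)
        if rn in _WATER_RESNAMES and names[i].upper() in {"OH2", "OW", "O"}:
            water_oxygen.append(i)
    return Topology(
        names=tuple(names),
        masses=np.array(masses),
        residue_seq=np.array(res_seq),
        residue_names=tuple(res_names),
        subunit_ids=tuple(chains),
        selections={
            "protein": np.array(protein, dtype=int),
            "water_oxygen": np.array(water_oxygen, dtype=int),
            "ligand": np.array(ligand, dtype=int),
        },
    )


def write_pdb(
    path: str | Path,
    top: Topology,
    positions: np.ndarray | None = None,
) -> None:
    """Write a topology (optionally with coordinates) as a PDB file."""
    positions = (
        np.zeros((top.n_atoms, 3)) if positions is None else np.asarray(positions)
    )
    lines = []
    for i in range(top.n_atoms):
        name = top.names[i]
        pad_name = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = positions[i]
        element = _guess_element(name, top.masses[i])
        lines.append(
            f"ATOM  {i + 1:5d} {pad_name:<4s} {top.residue_names[i]:<4s}"
            f"{top.subunit_ids[i]:1s}{int(top.residue_seq[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}\n"
        )
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def _guess_element(name: str, mass: float) -> str:
    best = min(ELEMENT_MASSES.items(), key=lambda kv: abs(kv[1] - mass))
    return best[0]


# ---------------------------------------------------------------------------
# plain frame archive (text)
# ---------------------------------------------------------------------------

_ARCHIVE_MAGIC = "FLOODFRAMES 1"


def write_frame_archive(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory to the plain text frame archive format.

    Layout (all ASCII, whitespace separated)::

        FLOODFRAMES 1
        natoms <N>
        nframes <M>
        frame <time_ns> <Lx> <Ly> <Lz>
        <x> <y> <z>          (N lines, 1e-4 Å precision)
        ... repeated per frame
    """
    with Path(path).open("w") as fh:
        fh.write(f"{_ARCHIVE_MAGIC}\n")
        fh.write(f"natoms {traj.topology.n_atoms}\n")
        fh.write(f"nframes {traj.n_frames}\n")
        for fr in traj.frames:
            fh.write(
                f"frame {fr.time:.6f} {fr.box[0]:.4f} {fr.box[1]:.4f} {fr.box[2]:.4f}\n"
            )
            np.savetxt(fh, fr.positions, fmt="%.4f")


def read_frame_archive(path: str | Path) -> Iterator[Frame]:
    """Yield frames from a plain frame archive."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if header != _ARCHIVE_MAGIC:
            raise FormatError(f"{path.name}:1: not a frame archive (got {header!r})")
        try:
            natoms = int(fh.readline().split()[1])
            nframes = int(fh.readline().split()[1])
        except (IndexError, ValueError):
            raise FormatError(f"{path.name}: malformed natoms/nframes header") from None
        for k in range(nframes):
            line = fh.readline().split()
            if not line or line[0] != "frame":
                raise FormatError(f"{path.name}: expected frame header {k}")
            time = float(line[1])
            box = np.array([float(v) for v in line[2:5]])
            pos = np.loadtxt(fh, max_rows=natoms, ndmin=2)
            if pos.shape != (natoms, 3):
                raise FormatError(
                    f"{path.name}: frame {k} has {pos.shape[0]} coordinate rows, "
                    f"expected {natoms}"
                )
            yield Frame(time=time, box=box, positions=pos)


# ---------------------------------------------------------------------------
# trajectory reading (archive + standard formats via MDAnalysis)
# ---------------------------------------------------------------------------

def _iter_mdanalysis(path: Path, n_atoms: int) -> Iterator[Frame]:
    import MDAnalysis as mda

    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.load_new(str(path))
    for ts in u.trajectory:
        if ts.dimensions is None:
            raise FormatError(f"{path.name}: frames carry no box information")
        dims = np.asarray(ts.dimensions, dtype=float)
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise FormatError(
                f"{path.name}: triclinic box (angles {dims[3:]}) is unsupported; "
                "only orthorhombic boxes are handled"
            )
        yield Frame(
            time=float(ts.time) / 1000.0,  # MDAnalysis time is ps; we use ns
            box=dims[:3].copy(),
            positions=np.asarray(ts.positions, dtype=float).copy(),
        )


def iter_frames(
    source: str | Path | Sequence[str | Path],
    top: Topology,
) -> Trajectory:
    """Load one or more trajectory files against a topology.

    DCD/XTC/GRO are read through MDAnalysis; ``.frames`` / ``.txt`` files
    are read as plain frame archives. Multiple files are concatenated in
    argument order; times must be strictly increasing across the result.
    """
    if isinstance(source, (str, Path)):
        source = [source]
    frames: list[Frame] = []
    last_time = -np.inf
    for item in source:
        path = Path(item)
        if path.suffix.lower() in (".frames", ".txt", ".arc"):
            reader: Iterable[Frame] = read_frame_archive(path)
        else:
            reader = _iter_mdanalysis(path, top.n_atoms)
        for fr in reader:
            if fr.positions.shape[0] != top.n_atoms:
                raise FormatError(
                    f"{path.name}: frame has {fr.positions.shape[0]} atoms but "
                    f"topology has {top.n_atoms}"
                )
            if fr.time <= last_time:
                raise FormatError(
                    f"{path.name}: non-monotone frame time {fr.time} ns after "
                    f"{last_time} ns (files must be passed in temporal order)"
                )
            last_time = fr.time
            frames.append(fr)
    return Trajectory(topology=top, frames=frames)
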