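"""Trajectory, topology and table I/O.

Trajectories are exchanged as multi-model PDB files (one MODEL per frame,
fixed-column records); everything tabular travels as delimited text with a
header row.  Residue numbering is taken verbatim from source files and is
1-based by PDB convention; frame indexing is 0-based internally.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "Selection",
    "TrajectoryFormatError",
    "ATOMIC_MASSES",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_table",
    "write_table",
]

#: Standard atomic masses (Da) for the elements this pipeline encounters.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    "BR": 79.904,
    "I": 126.904,
}


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates the multi-model PDB contract."""


@dataclasses.dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element.upper()]

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclasses.dataclass(frozen=True)
class Topology:
    """Ordered atom metadata; atom order defines the frame coordinate order."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in topology")
            seen.add(key)
            if a.element.upper() not in ATOMIC_MASSES:
                raise ValueError(
                    f"unknown element {a.element!r} for atom "
                    f"{a.name} {a.residue_name}{a.residue_index}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int)

    def select(self, name: str | None = None, chain: str | None = None,
               residue_indices: Sequence[int] | None = None) -> "Selection":
        """Simple attribute-based atom selection (e.g. ``name='CA'``)."""
        resset = set(residue_indices) if residue_indices is not None else None
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (name is None or a.name == name)
            and (chain is None or a.chain == chain)
            and (resset is None or a.residue_index in resset)
        ]
        return Selection(idx)

    def residue_label(self, atom_index: int) -> str:
        a = self.atoms[atom_index]
        return f"{a.residue_name}{a.residue_index}"


@dataclasses.dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free list of atom indices into a topology."""

    atom_indices: tuple[int, ...]

    def __init__(self, atom_indices: Sequence[int]):
        idx = tuple(int(i) for i in atom_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection contains duplicate atom indices")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)

    def validate(self, topology: Topology) -> None:
        n = len(topology)
        if any(i < 0 or i >= n for i in self.atom_indices):
            raise IndexError("selection index out of range for topology")


class Trajectory:
    """Frames x atoms x 3 Cartesian coordinates (Å) bound to a topology.

    Parameters
    ----------
    topology
        Atom metadata; its order is the coordinate order of every frame.
    coords
        Array of shape (F, A, 3) in Å.  F >= 1; all values finite.
    frame_spacing_ns
        Optional time between consecutive frames, in ns.
    """

    def __init__(self, topology: Topology, coords: np.ndarray,
                 frame_spacing_ns: float | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (F, A, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if coords.shape[1] != len(topology):
            raise ValueError(
                f"frame has {coords.shape[1]} atoms but topology has {len(topology)}"
            )
        if not np.isfinite(coords).all():
            raise ValueError("trajectory contains non-finite coordinates")
        self.topology = topology
        self.coords = coords
        self.frame_spacing_ns = frame_spacing_ns

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames


def _infer_element(raw_name: str, element_field: str) -> str:
    """PDB element column if present, else inferred from the atom-name field.

    Follows the fixed-column convention that two-letter element symbols
    (CL, FE, ZN, ...) start in the first name column, whereas names of
    one-letter-element atoms are indented (' CA ' is a Cα carbon, 'CA  '
    is calcium)."""
    el = element_field.strip()
    if el:
        return el.upper()
    raw = raw_name.ljust(4)
    if raw[0] not in " 0123456789":
        two = raw[:2].strip().upper()
        if len(two) == 2 and two in ATOMIC_MASSES:
            return two
    stripped = raw.strip().lstrip("0123456789")
    if not stripped:
        raise TrajectoryFormatError(f"cannot infer element for atom named {raw_name!r}")
    return stripped[0].upper()


def read_multimodel_pdb(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-model) PDB file into a topology and trajectory.

    One frame per MODEL record; a bare ATOM block yields a single frame.
    Atom order must be identical across models; residue indices are taken
    verbatim from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    frames: list[list[tuple[float, float, float]]] = []
    atom_keys: list[list[tuple]] = []
    atoms: list[Atom] = []
    current: list[tuple[float, float, float]] | None = None
    current_keys: list[tuple] = []
    in_model = False

    def _flush() -> None:
        nonlocal current, current_keys
        if current:
            frames.append(current)
            atom_keys.append(current_keys)
        current, current_keys = None, []

    with open(path) as fh:
        for line in fh:
            record = line[:6].strip()
            if record == "MODEL":
                _flush()
                current = []
                in_model = True
            elif record == "ENDMDL":
                _flush()
                in_model = False
            elif record in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                name = line[12:16].strip()
                resname = line[17:20].strip() or line[17:21].strip()
                chain = line[21].strip() or "A"
                try:
                    serial = int(line[6:11])
                    resindex = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError as exc:
                    raise TrajectoryFormatError(f"malformed ATOM record: {line.rstrip()!r}") from exc
                element = _infer_element(line[12:16], line[76:78] if len(line) >= 78 else "")
                if element not in ATOMIC_MASSES:
                    raise TrajectoryFormatError(
                        f"unknown element {element!r} for atom {name} {resname}{resindex}"
                    )
                if not frames:
                    atoms.append(Atom(serial, name, element, resname, resindex, chain))
                current.append(xyz)
                current_keys.append((name, resname, resindex, chain))
    _flush()

    if not frames:
        raise TrajectoryFormatError(f"no ATOM records found in {path}")

    first_keys = atom_keys[0]
    for m, keys in enumerate(atom_keys[1:], start=2):
        if len(keys) != len(first_keys):
            raise TrajectoryFormatError(
                f"MODEL {m} has {len(keys)} atoms, expected {len(first_keys)}"
            )
        if keys != first_keys:
            raise TrajectoryFormatError(f"MODEL {m} atom order differs from MODEL 1")

    topology = Topology(tuple(atoms))
    coords = np.array(frames, dtype=float)
    return topology, Trajectory(topology, coords)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a fixed-column multi-model PDB file."""
    if traj.n_frames < 1:
        raise ValueError("cannot write an empty trajectory")
    if np.abs(traj.coords).max() >= 10000.0:
        raise ValueError("coordinate magnitude overflows PDB %8.3f columns")
    multi = traj.n_frames > 1
    lines: list[str] = []
    for f in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for a, (x, y, z) in zip(traj.topology.atoms, traj.coords[f]):
            # one-letter-element atom names are indented per PDB convention
            name = a.name if len(a.name) >= 4 or len(a.element) == 2 else f" {a.name}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                f"{a.chain:1.1s}{a.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited (comma or tab) table with a header row.

    Columns that look numeric must parse fully; a stray non-numeric cell
    raises with the offending row and column named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty table file: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path))
    if df.shape[1] == 0:
        raise ValueError(f"table has no columns: {path}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            # a fully non-numeric column is treated as labels, a mixed one is an error
            if bad.any() and not bad.all():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric cell {df[col].iloc[row]!r} at row {row}, column {col!r}"
                )
            if not bad.any():
                df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(df).to_csv(path, sep=sep, index=False)
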