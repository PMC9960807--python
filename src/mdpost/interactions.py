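"""Hydrogen bonds, heavy-atom contacts, distance series and ligand descriptors.

Two kinds of objects live here.  Geometric operations (H-bond detection,
contact residues, donor-acceptor distance series) act on trajectory frames.
Topological descriptors (molecular weight, rotatable bonds, H-bond capacity,
a rule-of-five check) act on a :class:`MolecularGraph` — a minimal ligand
connection table with implicit hydrogens.

H-bond geometric criteria default to a 3.5 Å donor-acceptor heavy-atom
distance and a 135° D-H···A angle; both are configurable because published
occupancies are sensitive to the chosen cutoffs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import SeriesStats
from .trajio import ATOMIC_MASSES, Selection, Topology, Trajectory

__all__ = [
    "MolecularGraph",
    "HBondCriteria",
    "HBondRecord",
    "molecular_weight",
    "rotatable_bond_count",
    "hbond_capacity",
    "lipinski_check",
    "detect_hbonds",
    "hbond_count_series",
    "occupancy",
    "distance_series",
    "contact_residues",
    "read_molecular_graph",
    "write_molecular_graph",
    "resveratrol",
]

#: Covalent D-H bond length ceiling used to pair hydrogens with donors (Å).
_DH_COVALENT_MAX = 1.25


@dataclasses.dataclass(frozen=True)
class GraphAtom:
    element: str
    charge: int = 0
    n_hydrogens: int = 0


@dataclasses.dataclass(frozen=True)
class GraphBond:
    i: int
    j: int
    order: int = 1


class MolecularGraph:
    """Heavy-atom molecular graph with implicit hydrogens.

    Atoms carry ``(element, charge, n_hydrogens)``; bonds carry an integer
    order.  Ring membership is derived from the cycle structure (a bond is
    in a ring iff it is not a bridge of the graph).
    """

    def __init__(self, atoms: Sequence[GraphAtom | tuple], bonds: Sequence[GraphBond | tuple]):
        self.atoms = tuple(
            a if isinstance(a, GraphAtom) else GraphAtom(*a) for a in atoms
        )
        self.bonds = tuple(
            b if isinstance(b, GraphBond) else GraphBond(*b) for b in bonds
        )
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"invalid bond endpoints ({b.i}, {b.j})")
        for a in self.atoms:
            if a.element.upper() not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol {a.element!r}")
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        bridges = set(frozenset(e) for e in nx.bridges(g))
        self._graph = g
        self._ring_bonds = frozenset(
            frozenset((b.i, b.j)) for b in self.bonds
            if frozenset((b.i, b.j)) not in bridges
        )

    def __len__(self) -> int:
        return len(self.atoms)

    def bond_in_ring(self, bond: GraphBond) -> bool:
        return frozenset((bond.i, bond.j)) in self._ring_bonds

    def heavy_degree(self, i: int) -> int:
        return self._graph.degree[i]

    @property
    def formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            el = a.element.capitalize()
            counts[el] = counts.get(el, 0) + 1
            counts["H"] = counts.get("H", 0) + a.n_hydrogens
        if counts.get("H") == 0:
            del counts["H"]
        return counts


def _parse_formula(formula: str) -> dict[str, int]:
    import re

    if not formula:
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if m.start() != pos or not m.group(0):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse molecular formula {formula!r}")
    return counts


def molecular_weight(graph_or_formula: MolecularGraph | str) -> float:
    """Molecular weight in Da from standard atomic weights, to 2 decimals.

    Accepts either a :class:`MolecularGraph` (implicit hydrogens included)
    or a Hill-style formula string such as ``"C14H12O3"``.
    """
    if isinstance(graph_or_formula, MolecularGraph):
        counts = graph_or_formula.formula_counts
    else:
        counts = _parse_formula(graph_or_formula)
    total = 0.0
    for el, n in counts.items():
        key = el.upper()
        if key not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {el!r}")
        total += ATOMIC_MASSES[key] * n
    return round(total, 2)


def rotatable_bond_count(graph: MolecularGraph) -> int:
    """Count rotatable bonds: acyclic single bonds between two non-terminal
    heavy atoms (terminal = degree 1 in the heavy-atom graph).

    Hydroxyl C-O bonds are not rotatable under this convention because the
    oxygen is terminal among heavy atoms.
    """
    count = 0
    for b in graph.bonds:
        if b.order != 1 or graph.bond_in_ring(b):
            continue
        if graph.heavy_degree(b.i) > 1 and graph.heavy_degree(b.j) > 1:
            count += 1
    return count


def hbond_capacity(graph: MolecularGraph) -> tuple[int, int, int]:
    """(donors, acceptors, donors + acceptors) for a molecular graph.

    Every O-H or N-H counts one donor; every O or N heteroatom counts one
    acceptor.  The sum is the theoretical maximum number of simultaneous
    hydrogen bonds the molecule could form.
    """
    donors = sum(a.n_hydrogens for a in graph.atoms if a.element.upper() in ("O", "N"))
    acceptors = sum(1 for a in graph.atoms if a.element.upper() in ("O", "N"))
    return donors, acceptors, donors + acceptors


def lipinski_check(graph: MolecularGraph) -> tuple[bool, dict]:
    """Rule-of-five check on the three graph-computable rules.

    Evaluates MW <= 500 Da, H-bond donors <= 5 and acceptors <= 10; logP is
    not estimated, so the returned ``properties['rules_evaluated']`` lists
    exactly which rules the pass flag covers.
    """
    if len(graph) == 0:
        raise ValueError("cannot evaluate an empty molecular graph")
    mw = molecular_weight(graph)
    donors, acceptors, _ = hbond_capacity(graph)
    rules = {
        "mw_le_500": mw <= 500.0,
        "donors_le_5": donors <= 5,
        "acceptors_le_10": acceptors <= 10,
    }
    props = {
        "molecular_weight": mw,
        "hbond_donors": donors,
        "hbond_acceptors": acceptors,
        "rules_evaluated": sorted(rules),
        **rules,
    }
    return all(rules.values()), props


# ---------------------------------------------------------------------------
# geometric H-bond / contact analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond definition: heavy-atom D···A distance ceiling and
    D-H···A angle floor."""

    d_max: float = 3.5
    angle_min: float = 135.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.angle_min <= 180):
            raise ValueError("angle_min must lie in (0, 180]")


@dataclasses.dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    frame: int
    distance_ha: float

    def __post_init__(self) -> None:
        if self.distance_ha <= 0:
            raise ValueError("H···A distance must be positive")


def _attached_hydrogens(frame: np.ndarray, topology: Topology, donor: int) -> list[int]:
    donor_atom = topology.atoms[donor]
    out = []
    for i, a in enumerate(topology.atoms):
        if not a.is_hydrogen:
            continue
        if a.residue_index != donor_atom.residue_index or a.chain != donor_atom.chain:
            continue
        if np.linalg.norm(frame[i] - frame[donor]) <= _DH_COVALENT_MAX:
            out.append(i)
    return out


def detect_hbonds(frame: np.ndarray, topology: Topology, donors: Selection,
                  acceptors: Selection, criteria: HBondCriteria = HBondCriteria(),
                  frame_index: int = 0) -> list[HBondRecord]:
    """Detect hydrogen bonds in one frame.

    A record is emitted iff the donor-acceptor heavy-atom distance is at
    most ``criteria.d_max`` and the D-H···A angle is at least
    ``criteria.angle_min`` for some hydrogen covalently attached (<= 1.25 Å)
    to the donor.  A donor with no attached hydrogen is an error.
    """
    frame = np.asarray(frame, float)
    records: list[HBondRecord] = []
    for d in donors.indices:
        hydrogens = _attached_hydrogens(frame, topology, int(d))
        if not hydrogens:
            raise ValueError(
                f"donor atom {topology.atoms[d].name} "
                f"{topology.residue_label(int(d))} has no attached hydrogen"
            )
        for a in acceptors.indices:
            if a == d:
                continue
            d_da = float(np.linalg.norm(frame[a] - frame[d]))
            if d_da > criteria.d_max:
                continue
            for h in hydrogens:
                v1 = frame[d] - frame[h]
                v2 = frame[a] - frame[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle >= criteria.angle_min:
                    records.append(HBondRecord(
                        donor=int(d), hydrogen=int(h), acceptor=int(a),
                        frame=frame_index,
                        distance_ha=float(np.linalg.norm(frame[a] - frame[h])),
                    ))
                    break
    return records


def hbond_count_series(traj: Trajectory, donors: Selection, acceptors: Selection,
                       criteria: HBondCriteria = HBondCriteria(),
                       ) -> tuple[np.ndarray, list[HBondRecord]]:
    """Per-frame H-bond count plus the full record list."""
    counts = np.zeros(traj.n_frames, dtype=int)
    records: list[HBondRecord] = []
    for f in range(traj.n_frames):
        recs = detect_hbonds(traj.coords[f], traj.topology, donors, acceptors,
                             criteria, frame_index=f)
        counts[f] = len(recs)
        records.extend(recs)
    return counts, records


def occupancy(pair: tuple[int, int], records: Iterable[HBondRecord], n_frames: int) -> float:
    """Fraction of frames in which a specific (donor, acceptor) pair is bonded."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    donor, acceptor = pair
    frames = {r.frame for r in records if r.donor == donor and r.acceptor == acceptor}
    return len(frames) / n_frames


def distance_series(traj: Trajectory, atom_i: int, atom_j: int,
                    ) -> tuple[np.ndarray, SeriesStats]:
    """Euclidean distance (Å) between two atoms in every frame, with stats."""
    if atom_i == atom_j:
        raise ValueError("distance series needs two distinct atoms")
    series = np.linalg.norm(traj.coords[:, atom_i] - traj.coords[:, atom_j], axis=1)
    return series, SeriesStats.from_series(series)


def contact_residues(frame: np.ndarray, topology: Topology, ligand: Selection,
                     cutoff: float = 4.0) -> list[tuple[str, int, str]]:
    """Residues with a heavy atom within ``cutoff`` Å of any ligand heavy atom.

    The default 4.0 Å criterion is the common heavy-atom contact definition.
    Hydrogens are excluded on both sides; returns sorted unique
    ``(chain, residue_index, residue_name)`` tuples.
    """
    frame = np.asarray(frame, float)
    ligand_set = set(int(i) for i in ligand.indices)
    lig_heavy = [i for i in ligand_set if not topology.atoms[i].is_hydrogen]
    env_heavy = [
        i for i, a in enumerate(topology.atoms)
        if i not in ligand_set and not a.is_hydrogen
    ]
    if not lig_heavy or not env_heavy:
        return []
    tree = cKDTree(frame[env_heavy])
    hits: set[tuple[str, int, str]] = set()
    for pts in tree.query_ball_point(frame[lig_heavy], r=cutoff):
        for p in pts:
            a = topology.atoms[env_heavy[p]]
            hits.add((a.chain, a.residue_index, a.residue_name))
    return sorted(hits)


# ---------------------------------------------------------------------------
# connection-table text format + the resveratrol reference graph
# ---------------------------------------------------------------------------

def write_molecular_graph(graph: MolecularGraph, path: str | Path) -> None:
    """Write the minimal connection-table format::

        atoms <n>
        <element> <charge> <n_hydrogens>   (n lines)
        bonds <m>
        <i> <j> <order>                    (m lines)
    """
    lines = [f"atoms {len(graph.atoms)}"]
    lines += [f"{a.element} {a.charge} {a.n_hydrogens}" for a in graph.atoms]
    lines.append(f"bonds {len(graph.bonds)}")
    lines += [f"{b.i} {b.j} {b.order}" for b in graph.bonds]
    Path(path).write_text("\n".join(lines) + "\n")


def read_molecular_graph(path: str | Path) -> MolecularGraph:
    tokens = Path(path).read_text().split("\n")
    tokens = [t for t in (s.strip() for s in tokens) if t and not t.startswith("#")]
    if not tokens or not tokens[0].startswith("atoms"):
        raise ValueError("connection table must start with 'atoms <n>'")
    n_atoms = int(tokens[0].split()[1])
    atoms = []
    for line in tokens[1:1 + n_atoms]:
        el, charge, nh = line.split()
        atoms.append(GraphAtom(el, int(charge), int(nh)))
    bond_header = tokens[1 + n_atoms]
    if not bond_header.startswith("bonds"):
        raise ValueError("expected 'bonds <m>' after atom block")
    n_bonds = int(bond_header.split()[1])
    bonds = []
    for line in tokens[2 + n_atoms:2 + n_atoms + n_bonds]:
        i, j, order = line.split()
        bonds.append(GraphBond(int(i), int(j), int(order)))
    return MolecularGraph(atoms, bonds)


def resveratrol() -> MolecularGraph:
    """3,5,4'-trihydroxy-trans-stilbene (C14H12O3).

    Heavy-atom graph with Kekulé bond orders: a benzene-1,3-diol ring
    (atoms 0-5, hydroxyls at 2 and 4 via oxygens 14, 15), a trans vinyl
    bridge (6=7) and a 4-hydroxyphenyl ring (8-13, hydroxyl oxygen 16).
    """
    C, O = "C", "O"
    atoms = [
        GraphAtom(C, 0, 0),   # 0  ring-A C1 (vinyl attachment)
        GraphAtom(C, 0, 1),   # 1  ring-A C2
        GraphAtom(C, 0, 0),   # 2  ring-A C3 (OH)
        GraphAtom(C, 0, 1),   # 3  ring-A C4
        GraphAtom(C, 0, 0),   # 4  ring-A C5 (OH)
        GraphAtom(C, 0, 1),   # 5  ring-A C6
        GraphAtom(C, 0, 1),   # 6  vinyl Ca
        GraphAtom(C, 0, 1),   # 7  vinyl Cb
        GraphAtom(C, 0, 0),   # 8  ring-B C1' (vinyl attachment)
        GraphAtom(C, 0, 1),   # 9  ring-B C2'
        GraphAtom(C, 0, 1),   # 10 ring-B C3'
        GraphAtom(C, 0, 0),   # 11 ring-B C4' (OH)
        GraphAtom(C, 0, 1),   # 12 ring-B C5'
        GraphAtom(C, 0, 1),   # 13 ring-B C6'
        GraphAtom(O, 0, 1),   # 14 OH on C3
        GraphAtom(O, 0, 1),   # 15 OH on C5
        GraphAtom(O, 0, 1),   # 16 OH on C4'
    ]
    bonds = [
        # ring A, Kekulé alternation
        GraphBond(0, 1, 2), GraphBond(1, 2, 1), GraphBond(2, 3, 2),
        GraphBond(3, 4, 1), GraphBond(4, 5, 2), GraphBond(5, 0, 1),
        # vinyl bridge
        GraphBond(0, 6, 1), GraphBond(6, 7, 2), GraphBond(7, 8, 1),
        # ring B
        GraphBond(8, 9, 2), GraphBond(9, 10, 1), GraphBond(10, 11, 2),
        GraphBond(11, 12, 1), GraphBond(12, 13, 2), GraphBond(13, 8, 1),
        # hydroxyls
        GraphBond(2, 14, 1), GraphBond(4, 15, 1), GraphBond(11, 16, 1),
    ]
    return MolecularGraph(atoms, bonds)
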