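"""Seeded generators for every input the analysis pipeline consumes.

Each generator plants a known ground truth that the corresponding analysis
operation is expected to recover:

* :func:`make_trajectory` — a Cα trajectory that dwells in a small number
  of conformational states (reference structures plus isotropic Gaussian
  noise per residue, optionally wrapped in random rigid-body motion).  The
  default emulates a 263-residue receptor over 5000 frames with three
  states and transitions at 0.4% and 30% of the run, i.e. the shape of a
  1 μs simulation with conformational changes at ~4 ns and ~300 ns.
* :func:`make_hbond_series` — a donor-acceptor distance series switching
  between a bonded regime (~1.7-1.8 Å H···A) and an unbonded one (~6 Å).
* :func:`make_energy_tables` — per-frame MM/GBSA component tables with
  known component means, plus a per-residue decomposition constructed so
  that residue contributions sum to the interaction energy frame-wise.
* :func:`make_epm_cohort` — elevated-plus-maze records with planted group
  effects and a synthetic enzyme-activity covariate carrying a planted
  correlation with the anxiety index.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .behavior import EPMRecord, anxiety_index
from .trajio import Atom, Topology, Trajectory

__all__ = [
    "TrajectorySpec",
    "EnergySpec",
    "make_chain",
    "make_trajectory",
    "default_trajectory_spec",
    "make_hbond_series",
    "default_hbond_regimes",
    "make_energy_tables",
    "make_entropy_blocks",
    "default_energy_spec",
    "make_epm_cohort",
    "default_epm_groups",
]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrajectorySpec:
    """Recipe for a multi-state Cα trajectory.

    ``states`` are reference conformations of identical shape (N, 3);
    ``dwell_segments`` is an ordered list of (state_index, n_frames) whose
    frame counts sum to the trajectory length; ``sigma_per_residue`` is the
    isotropic per-coordinate noise SD in Å (scalar or length-N).
    """

    states: list[np.ndarray]
    dwell_segments: list[tuple[int, int]]
    sigma_per_residue: np.ndarray | float = 0.4
    global_rigid_motion: bool = False
    seed: int = 2023

    @property
    def n_residues(self) -> int:
        return int(np.asarray(self.states[0]).shape[0])

    @property
    def n_frames(self) -> int:
        return int(sum(n for _, n in self.dwell_segments))

    @property
    def frame_states(self) -> np.ndarray:
        """Planted state label per frame."""
        return np.concatenate([
            np.full(n, s, dtype=int) for s, n in self.dwell_segments
        ])


def make_chain(n_residues: int, seed: int, target_rg: float = 17.8) -> np.ndarray:
    """A smooth compact pseudo-Cα chain scaled to a target radius of
    gyration (Å).  Purely geometric: successive 3.8 Å steps with correlated
    directions, then isotropic rescaling to the requested compactness."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues - 1, 3))
    # correlate successive step directions for a chain-like, non-crumpled path
    for i in range(1, steps.shape[0]):
        steps[i] = 0.6 * steps[i - 1] + 0.4 * steps[i]
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
    coords -= coords.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum(coords ** 2, axis=1)))
    return coords * (target_rg / rg)


def _ca_topology(n_residues: int) -> Topology:
    atoms = tuple(
        Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
             residue_index=i + 1, chain="A")
        for i in range(n_residues)
    )
    return Topology(atoms)


def make_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Generate the trajectory described by a :class:`TrajectorySpec`.

    Each frame is its segment's state coordinates plus isotropic Gaussian
    noise (σ_i per residue); with ``global_rigid_motion`` every frame is
    additionally rotated and translated at random, which superposition-based
    analyses must remove.
    """
    states = [np.asarray(s, float) for s in spec.states]
    shapes = {s.shape for s in states}
    if len(shapes) != 1:
        raise ValueError(f"state conformations differ in shape: {shapes}")
    n_res = spec.n_residues
    sigma = np.broadcast_to(np.asarray(spec.sigma_per_residue, float), (n_res,))
    if np.any(sigma < 0):
        raise ValueError("sigma_per_residue must be >= 0")
    for s, _ in spec.dwell_segments:
        if not (0 <= s < len(states)):
            raise ValueError(f"dwell segment references unknown state {s}")

    rng = np.random.default_rng(spec.seed)
    coords = np.empty((spec.n_frames, n_res, 3))
    frame_states = spec.frame_states
    noise = rng.normal(size=(spec.n_frames, n_res, 3)) * sigma[None, :, None]
    for f in range(spec.n_frames):
        coords[f] = states[frame_states[f]] + noise[f]
    if spec.global_rigid_motion:
        rots = Rotation.random(spec.n_frames, random_state=rng)
        shifts = rng.uniform(-20.0, 20.0, size=(spec.n_frames, 3))
        for f in range(spec.n_frames):
            coords[f] = rots[f].apply(coords[f]) + shifts[f]
    return Trajectory(_ca_topology(n_res), coords)


def default_trajectory_spec(seed: int = 2023, n_residues: int = 263,
                            n_frames: int = 5000, sigma: float = 0.4,
                            displacement: float = 8.0,
                            initial_displacement: float = 20.0,
                            global_rigid_motion: bool = False) -> TrajectorySpec:
    """Three-state receptor trajectory with the default study shape.

    State 0 (late, 'closed') displaces a 20-residue loop around residue 131;
    state 2 (initial) displaces a C-terminal window; state 1 is the base
    conformation.  Dwell fractions are 0.4% / 29.6% / 70% of the run,
    mimicking conformational changes at ~4 ns and ~300 ns of a 1 μs
    trajectory.  Per-residue noise is ``sigma`` everywhere except the two
    mobile windows, which fluctuate three times harder.
    """
    base = make_chain(n_residues, seed=seed)
    rng = np.random.default_rng(seed + 1)

    def displaced(window: slice, amplitude: float) -> np.ndarray:
        state = base.copy()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        state[window] += amplitude * direction
        return state

    # mobile windows at fixed chain fractions: residues 124-143 and 223-242
    # for the default 263-residue receptor, scaled for smaller chains
    loop_window = slice(int(0.468 * n_residues), int(0.544 * n_residues))
    cterm_window = slice(int(0.844 * n_residues), int(0.920 * n_residues))
    # the initial state lies much farther out than the open/closed pair:
    # the first conformational change is a large-amplitude helix motion,
    # the later open->closed change a smaller loop rearrangement
    state_closed = displaced(loop_window, displacement)
    state_initial = displaced(cterm_window, initial_displacement)

    sigmas = np.full(n_residues, sigma)
    sigmas[int(0.487 * n_residues):int(0.510 * n_residues)] = 3 * sigma  # ~residue 131
    sigmas[int(0.859 * n_residues):int(0.886 * n_residues)] = 3 * sigma  # ~residue 230

    f_initial = max(1, round(0.004 * n_frames))
    f_open = round(0.30 * n_frames) - f_initial
    f_closed = n_frames - f_initial - f_open
    return TrajectorySpec(
        states=[state_closed, base, state_initial],
        dwell_segments=[(2, f_initial), (1, f_open), (0, f_closed)],
        sigma_per_residue=sigmas,
        global_rigid_motion=global_rigid_motion,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hydrogen-bond distance series
# ---------------------------------------------------------------------------

def make_hbond_series(regimes: Sequence[tuple[int, float, float]],
                      seed: int = 2023) -> np.ndarray:
    """Concatenated Gaussian distance regimes, truncated to stay positive.

    ``regimes`` is a list of (n_frames, mean Å, sd Å); zero-length regimes
    are skipped, non-positive means are an error.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for n, mean, sd in regimes:
        if mean <= 0:
            raise ValueError(f"regime mean must be positive, got {mean}")
        if sd < 0:
            raise ValueError("regime sd must be >= 0")
        if n <= 0:
            continue
        parts.append(np.clip(rng.normal(mean, sd, size=n), 1e-6, None))
    if not parts:
        raise ValueError("no frames generated: all regimes empty")
    return np.concatenate(parts)


def default_hbond_regimes(n_frames: int = 5000, bonded_fraction: float = 0.59,
                          ) -> list[tuple[int, float, float]]:
    """Unbonded regime around 6 Å followed by a bonded regime at
    1.77 ± 0.12 Å occupying ``bonded_fraction`` of the frames."""
    n_bonded = round(bonded_fraction * n_frames)
    return [(n_frames - n_bonded, 6.0, 1.0), (n_bonded, 1.77, 0.12)]


# ---------------------------------------------------------------------------
# MM/GBSA tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnergySpec:
    """Component means/SDs (kcal/mol) and per-residue contribution means.

    Residue means should sum to the interaction-energy mean (electrostatic
    + vdW + GB + SA) so that planted per-residue values are recovered
    exactly in expectation; the generator enforces frame-wise additivity by
    distributing each frame's interaction energy over residues in
    proportion to the planted means.
    """

    component_means: dict[str, float]
    component_sds: dict[str, float]
    residue_means: dict[str, float]
    n_frames: int = 2000
    seed: int = 2023


def default_energy_spec(seed: int = 2023, n_frames: int = 2000) -> EnergySpec:
    """Defaults emulating the studied complex: enthalpy mean −23.6 kcal/mol
    with key residues Leu126/Leu217/Leu171 below the −1.5 kcal/mol line."""
    named = {
        "Leu126": -2.2, "Leu217": -1.7, "Leu171": -1.6, "Thr124": -1.2,
        "Tyr183": -0.9, "Val231": -0.8, "Tyr177": -0.7, "Leu215": -0.5,
        "Ala223": -0.4, "Met233": -0.3, "Ser170": -0.2,
    }
    background_total = -23.6 - sum(named.values())  # -13.1
    background = {f"Gly{i}": background_total / 20 for i in range(1, 21)}
    return EnergySpec(
        component_means={"dE_internal": 0.0, "dE_electrostatic": -20.0,
                         "dE_vdW": -30.0, "dG_GB": 29.4, "dG_SA": -3.0},
        component_sds={"dE_internal": 0.0, "dE_electrostatic": 3.0,
                       "dE_vdW": 2.0, "dG_GB": 2.5, "dG_SA": 0.3},
        residue_means={**named, **background},
        n_frames=n_frames,
        seed=seed,
    )


def make_energy_tables(spec: EnergySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(component table, per-residue table) for the energetics module.

    Component columns are drawn independently per frame; residue
    contributions are each frame's interaction energy split in proportion
    to the planted residue means, so their frame-wise sum reproduces it
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    comp = {"frame": np.arange(spec.n_frames)}
    for col in ("dE_internal", "dE_electrostatic", "dE_vdW", "dG_GB", "dG_SA"):
        mean = spec.component_means.get(col, 0.0)
        sd = spec.component_sds.get(col, 0.0)
        comp[col] = rng.normal(mean, sd, size=spec.n_frames) if sd > 0 else np.full(
            spec.n_frames, mean)
    comp_df = pd.DataFrame(comp)

    interaction = (comp_df["dE_electrostatic"] + comp_df["dE_vdW"]
                   + comp_df["dG_GB"] + comp_df["dG_SA"]).to_numpy()
    residues = list(spec.residue_means)
    means = np.array([spec.residue_means[r] for r in residues])
    if means.sum() == 0:
        raise ValueError("residue means must not sum to zero")
    weights = means / means.sum()
    per_res = pd.DataFrame({
        "frame": np.repeat(np.arange(spec.n_frames), len(residues)),
        "residue_id": np.tile(residues, spec.n_frames),
        "dG_res": np.outer(interaction, weights).ravel(),
    })
    return comp_df, per_res


def make_entropy_blocks(mean: float = -19.0, sd: float = 1.9,
                        n_blocks: int = 20, snapshots_per_block: int = 5,
                        seed: int = 2023) -> list[np.ndarray]:
    """Per-snapshot TdS estimates (kcal/mol) grouped into blocks."""
    rng = np.random.default_rng(seed)
    return [rng.normal(mean, sd, size=snapshots_per_block) for _ in range(n_blocks)]


# ---------------------------------------------------------------------------
# elevated-plus-maze cohorts
# ---------------------------------------------------------------------------

def default_epm_groups() -> dict[str, dict[str, float]]:
    """Four-arm design: vehicle control, effective-dose treatment, stressed,
    and stressed+treated.  Values are per-group means/SDs of open-arm time
    (s), open-arm entries and total entries over a 600 s session."""
    return {
        "control":    {"T_op_mean": 90.0,  "T_op_sd": 30.0, "N_op_mean": 3.0,
                       "N_op_sd": 1.5, "N_mean": 12.0, "N_sd": 3.0},
        "res40":      {"T_op_mean": 210.0, "T_op_sd": 45.0, "N_op_mean": 6.0,
                       "N_op_sd": 2.0, "N_mean": 13.0, "N_sd": 3.0},
        "ptsd":       {"T_op_mean": 30.0,  "T_op_sd": 15.0, "N_op_mean": 1.0,
                       "N_op_sd": 1.0, "N_mean": 10.0, "N_sd": 2.5},
        "res40+ptsd": {"T_op_mean": 150.0, "T_op_sd": 40.0, "N_op_mean": 5.0,
                       "N_op_sd": 2.0, "N_mean": 12.0, "N_sd": 3.0},
    }


def make_epm_cohort(group_params: dict[str, dict[str, float]] | None = None,
                    T: float = 600.0, n_per_group: int = 10, seed: int = 2023,
                    activity_rho: float = 0.9,
                    ) -> tuple[list[EPMRecord], np.ndarray]:
    """EPM cohort with planted group effects plus a correlated covariate.

    Returns the records and a synthetic hepatic enzyme-activity series
    constructed to correlate with the per-animal anxiety index at the
    planted ρ (up to sampling noise).  Generated values are clipped to the
    record invariants (0 ≤ T_op ≤ T, 1 ≤ N, 0 ≤ N_op ≤ N).
    """
    params = group_params if group_params is not None else default_epm_groups()
    rng = np.random.default_rng(seed)
    records: list[EPMRecord] = []
    for group, p in params.items():
        if p["T_op_mean"] > T:
            raise ValueError(f"group {group!r}: mean open-arm time exceeds T={T}")
        for i in range(n_per_group):
            t_op = float(np.clip(rng.normal(p["T_op_mean"], p["T_op_sd"]), 0.0, T))
            n_total = int(np.clip(round(rng.normal(p["N_mean"], p["N_sd"])), 1, None))
            n_op = int(np.clip(round(rng.normal(p["N_op_mean"], p["N_op_sd"])), 0, n_total))
            records.append(EPMRecord(T_op=t_op, T=T, N_op=n_op, N=n_total,
                                     group=group, animal_id=f"{group}-{i + 1:02d}"))
    ai = np.array([anxiety_index(r) for r in records])
    noise = rng.normal(size=ai.size)
    noise = (noise - noise.mean()) / noise.std()
    if ai.std() == 0:
        latent = noise  # degenerate cohort: no AI variance to correlate with
    else:
        z = (ai - ai.mean()) / ai.std()
        latent = activity_rho * z + np.sqrt(max(0.0, 1 - activity_rho ** 2)) * noise
    activity = 100.0 + 15.0 * latent  # arbitrary enzyme-activity units
    return records, activity


def epm_table(records: Sequence[EPMRecord]) -> pd.DataFrame:
    """Records as the delimited-table schema the pipeline reads."""
    return pd.DataFrame([{
        "animal_id": r.animal_id, "group": r.group, "T_op": r.T_op,
        "T": r.T, "N_op": r.N_op, "N": r.N,
    } for r in records])
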