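"""Rigid-body superposition and trajectory geometry observables.

Implements the observables used to monitor a protein-ligand complex along a
molecular-dynamics trajectory: RMSD against a reference structure (after
optimal Kabsch superposition), the mass-weighted radius of gyration, the
per-residue root-mean-square fluctuation about the trajectory-average
structure, and mean/SD statistics over time segments of any per-frame series.

Conventions
-----------
* RMSD and RMSF default to Cα atoms; any :class:`~mdpost.trajio.Selection`
  may be supplied instead.
* The RMSF (and the DCCM/PCA modules) reference structure is the
  trajectory average after two superposition iterations.
* Standard deviations are sample SDs (ddof=1); n = 1 reports SD 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .trajio import Selection, Trajectory

__all__ = [
    "RigidTransform",
    "SeriesStats",
    "superpose",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "radius_of_gyration",
    "average_structure",
    "fit_trajectory",
    "rmsf",
    "segment_stats",
]


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> rotation @ x + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthogonal with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ np.asarray(self.rotation).T + np.asarray(self.translation)


@dataclasses.dataclass(frozen=True)
class SeriesStats:
    """Mean ± sample SD summary of a numeric series."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_series(cls, values: np.ndarray) -> "SeriesStats":
        values = np.asarray(values, dtype=float)
        n = values.size
        if n == 0:
            raise ValueError("cannot summarise an empty series")
        sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
        return cls(mean=float(np.mean(values)), sd=sd, n=n)


def _take(coords: np.ndarray, selection: Selection | None) -> np.ndarray:
    if selection is None:
        return coords
    return coords[..., selection.indices, :]


def _check_nondegenerate(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition atoms are collinear (degenerate geometry)")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: Selection | None = None) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Both inputs are (A, 3) coordinate arrays; if ``selection`` is given the
    fit uses only those atoms (the transform still applies to all).  Returns
    the minimizing proper rigid transform and the minimum RMSD in Å.
    """
    mob = _take(np.asarray(mobile, float), selection)
    ref = _take(np.asarray(reference, float), selection)
    if mob.shape != ref.shape:
        raise ValueError(f"selection shapes differ: {mob.shape} vs {ref.shape}")
    _check_nondegenerate(mob)
    _check_nondegenerate(ref)

    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    H = (mob - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    transform = RigidTransform(rotation=R, translation=rc - R @ mc)
    fitted = transform.apply(mob)
    value = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return transform, value


def apply_transform(coords: np.ndarray, transform: RigidTransform) -> np.ndarray:
    return transform.apply(coords)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between two equally shaped coordinate sets."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: Selection | None = None, fit: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference structure.

    With ``fit=True`` every frame is first superposed onto the reference
    over the selection, so the series is invariant under rigid motion of
    the whole trajectory.
    """
    if selection is not None and len(selection) == 0:
        raise ValueError("empty selection")
    reference = np.asarray(reference, float)
    ref_sel = _take(reference, selection)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame_sel = _take(traj.coords[f], selection)
        if fit:
            _, out[f] = superpose(frame_sel, ref_sel)
        else:
            out[f] = rmsd(frame_sel, ref_sel)
    return out


def radius_of_gyration(frame: np.ndarray, selection: Selection | None = None,
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (Å) of one frame.

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ).  Unit masses are
    used when ``masses`` is omitted.
    """
    pts = _take(np.asarray(frame, float), selection)
    if pts.shape[0] == 0:
        raise ValueError("empty selection")
    if masses is None:
        m = np.ones(pts.shape[0])
    else:
        m = np.asarray(masses, float)
        if selection is not None and m.shape[0] != pts.shape[0]:
            m = m[selection.indices]
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
    com = np.average(pts, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((pts - com) ** 2, axis=1), weights=m)))


def rog_series(traj: Trajectory, selection: Selection | None = None,
               mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration (Å)."""
    masses = traj.topology.masses if mass_weighted else None
    return np.array([
        radius_of_gyration(traj.coords[f], selection, masses)
        for f in range(traj.n_frames)
    ])


def fit_trajectory(traj_coords: np.ndarray, reference: np.ndarray,
                   fit_indices: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame of a coordinate array onto a reference."""
    out = np.empty_like(traj_coords)
    sel = None if fit_indices is None else Selection(list(fit_indices))
    for f in range(traj_coords.shape[0]):
        t, _ = superpose(traj_coords[f] if sel is None else traj_coords[f][sel.indices],
                         reference if sel is None else reference[sel.indices])
        out[f] = t.apply(traj_coords[f])
    return out


def average_structure(traj: Trajectory, selection: Selection | None = None,
                      n_iterations: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory-average structure over a selection, with iterated fitting.

    Frames are superposed onto a running reference (initially the first
    frame) and averaged; two iterations is the conventional essential-
    dynamics protocol.  Returns ``(average, fitted_coords)`` where
    ``fitted_coords`` has shape (F, A_sel, 3).
    """
    if traj.n_frames < 2:
        raise ValueError("average structure requires at least 2 frames")
    coords = _take(traj.coords, selection)
    reference = coords[0]
    fitted = coords
    for _ in range(n_iterations):
        fitted = fit_trajectory(coords, reference)
        reference = fitted.mean(axis=0)
    return reference, fitted


def rmsf(traj: Trajectory, selection: Selection | None = None) -> np.ndarray:
    """Per-atom RMSF (Å) about the average structure.

    RMSF_i = sqrt( <|r_i - <r_i>|^2> ) after superposing all frames onto
    the iterated trajectory average.  With a Cα selection this is the
    per-residue fluctuation profile.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    mean, fitted = average_structure(traj, selection)
    dev = fitted - mean
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


def segment_stats(series: np.ndarray, breakpoints: list[int] | None = None) -> list[SeriesStats]:
    """Mean ± SD over half-open segments ``[b_i, b_{i+1})`` of a series.

    ``breakpoints`` are interior frame indices, strictly increasing; with
    none given a single segment covering the whole series is returned.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    bps = list(breakpoints or [])
    if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if any(b <= 0 or b >= n for b in bps):
        raise ValueError("breakpoints must lie strictly inside the series")
    edges = [0] + bps + [n]
    out = []
    for lo, hi in zip(edges, edges[1:]):
        if hi <= lo:
            raise ValueError(f"empty segment [{lo}, {hi})")
        out.append(SeriesStats.from_series(series[lo:hi]))
    return out
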