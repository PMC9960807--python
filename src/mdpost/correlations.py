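"""Dynamics cross-correlation map and essential-dynamics PCA.

Both analyses act on Cα fluctuations about the trajectory-average
structure: frames are superposed onto the iterated average first (two
iterations, as in the geometry module), so rigid-body motion is removed
before any covariance is accumulated.

DCCM
    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

    where dr_i(t) is the displacement 3-vector of Cα atom i from its time
    average; entries lie in [-1, 1], the diagonal is identically 1, and
    +1/-1 indicate perfectly correlated/anti-correlated residue motion.

PCA
    Eigendecomposition of the 3N x 3N covariance matrix of flattened Cα
    fluctuations.  All 3N eigenvectors are returned (789 for a 263-residue
    selection); explained fractions are eigenvalues over their sum, and
    projections are the centered coordinates on each eigenvector.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import average_structure
from .trajio import Selection, Trajectory

__all__ = ["DCCMatrix", "PCAResult", "dccm", "pca", "variance_captured"]


@dataclasses.dataclass
class DCCMatrix:
    """Normalized Cα displacement cross-correlations with residue labels."""

    values: np.ndarray
    residue_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("DCCM must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("DCCM must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("DCCM diagonal must be 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("DCCM entries must lie in [-1, 1]")


@dataclasses.dataclass
class PCAResult:
    """Eigenvalues (descending), orthonormal eigenvectors (columns),
    per-component explained fractions and per-frame projections."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    explained_fraction: np.ndarray
    projections: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def _fitted_displacements(traj: Trajectory, selection: Selection | None,
                          fit: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(displacements (F, N, 3), mean structure) about the time average.

    With ``fit`` (the default) frames are first superposed onto the
    iterated trajectory average; ``fit=False`` uses raw coordinates, which
    is only meaningful when the input carries no rigid-body motion.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance analysis requires at least 2 frames")
    if fit:
        mean, fitted = average_structure(traj, selection)
    else:
        fitted = traj.coords if selection is None else traj.coords[:, selection.indices]
        mean = fitted.mean(axis=0)
    return fitted - mean, mean


def dccm(traj: Trajectory, selection: Selection | None = None,
         fit: bool = True) -> DCCMatrix:
    """Dynamics cross-correlation matrix over a (Cα) selection.

    Raises if any atom has zero fluctuation (its normalization is
    undefined), naming the offending residue.
    """
    disp, _ = _fitted_displacements(traj, selection, fit)
    indices = (selection.indices if selection is not None
               else np.arange(traj.n_atoms))
    # <dr_i . dr_j> as a single contraction over frames and xyz
    F = disp.shape[0]
    inner = np.einsum("fid,fjd->ij", disp, disp) / F
    auto = np.diag(inner).copy()
    zero = np.flatnonzero(auto <= 0)
    if zero.size:
        label = traj.topology.residue_label(int(indices[zero[0]]))
        raise ValueError(f"zero fluctuation at residue {label}: DCCM undefined")
    norm = np.sqrt(np.outer(auto, auto))
    values = inner / norm
    np.clip(values, -1.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2
    labels = tuple(traj.topology.residue_label(int(i)) for i in indices)
    return DCCMatrix(values=values, residue_ids=labels)


def pca(traj: Trajectory, selection: Selection | None = None,
        fit: bool = True) -> PCAResult:
    """Essential-dynamics PCA of Cα fluctuations.

    The covariance matrix of the flattened (3N) fluctuations is
    diagonalized exactly; eigenvalues are sorted descending and clipped at
    zero against round-off.  Covariance uses the 1/F normalization (time
    average), matching the DCCM convention.
    """
    disp, _ = _fitted_displacements(traj, selection, fit)
    F = disp.shape[0]
    X = disp.reshape(F, -1)
    if X.shape[1] == 0:
        raise ValueError("empty selection")
    X = X - X.mean(axis=0)
    cov = X.T @ X / F
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total == 0:
        raise ValueError("zero total variance: PCA undefined")
    return PCAResult(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        explained_fraction=eigvals / total,
        projections=X @ eigvecs,
    )


def variance_captured(result: PCAResult, n_components: int) -> float:
    """Cumulative explained-variance fraction of the first n components."""
    if not (1 <= n_components <= result.n_components):
        raise ValueError(
            f"n_components must lie in [1, {result.n_components}]"
        )
    return float(result.explained_fraction[:n_components].sum())
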