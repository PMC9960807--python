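"""MM/GBSA bookkeeping: component combination, block averaging, entropy
aggregation and per-residue decomposition.

The module consumes per-frame energy-component tables produced under the
single-trajectory convention (complex, receptor and ligand all extracted
from the complex trajectory, so internal-energy deltas cancel and may be
identically zero).  It never evaluates a force field or a GB model.

    dE_MM   = dE_internal + dE_electrostatic + dE_vdW
    dG_sol  = dG_GB + dG_SA
    dH      = dE_MM + dG_sol
    dG_bind = dH - TdS

Reported values follow the 20-block protocol: the trajectory is split into
equal contiguous blocks (50 ns each for a 1 us run), a fixed number of
snapshots is sampled at a regular stride within each block, and the
published number is the mean ± sample SD of the block means.  Entropy
estimates (TdS, kcal/mol) are supplied per snapshot in groups (5 per block
by default) and aggregated the same way.

Per-residue decomposition: the time-averaged residue contribution, with
"key" residues those at or below a -1.5 kcal/mol threshold (the <= rule at
the boundary is deliberate: equally favorable counts).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import SeriesStats

__all__ = [
    "EnergyComponents",
    "BindingFreeEnergy",
    "ResidueContribution",
    "COMPONENT_COLUMNS",
    "combine_components",
    "block_protocol",
    "entropy_mean",
    "binding_free_energy",
    "per_residue_decomposition",
    "key_residues",
    "DEFAULT_TEMPERATURE_K",
    "KEY_RESIDUE_THRESHOLD",
]

DEFAULT_TEMPERATURE_K = 310.0
KEY_RESIDUE_THRESHOLD = -1.5

COMPONENT_COLUMNS = ("dE_internal", "dE_electrostatic", "dE_vdW", "dG_GB", "dG_SA")


@dataclasses.dataclass(frozen=True)
class EnergyComponents:
    """Per-frame energy deltas (kcal/mol), single-trajectory convention."""

    dE_internal: np.ndarray
    dE_electrostatic: np.ndarray
    dE_vdW: np.ndarray
    dG_GB: np.ndarray
    dG_SA: np.ndarray

    def __post_init__(self) -> None:
        arrays = self.as_dict()
        lengths = {k: len(v) for k, v in arrays.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"component length mismatch: {lengths}")
        if next(iter(lengths.values())) < 1:
            raise ValueError("components must contain at least one frame")
        for k, v in arrays.items():
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite values in component {k}")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {c: np.asarray(getattr(self, c), dtype=float) for c in COMPONENT_COLUMNS}

    @property
    def n_frames(self) -> int:
        return len(np.asarray(self.dE_vdW))

    @property
    def internal_is_zero(self) -> bool:
        """True when internal deltas cancel exactly, as they must under the
        single-trajectory convention."""
        return bool(np.all(np.asarray(self.dE_internal) == 0.0))

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "EnergyComponents":
        missing = [c for c in COMPONENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing component column(s): {missing}")
        return cls(**{c: df[c].to_numpy(dtype=float) for c in COMPONENT_COLUMNS})


def combine_components(c: EnergyComponents) -> pd.DataFrame:
    """Per-frame dE_MM, dG_sol and dH = dE_MM + dG_sol."""
    d = c.as_dict()
    de_mm = d["dE_internal"] + d["dE_electrostatic"] + d["dE_vdW"]
    dg_sol = d["dG_GB"] + d["dG_SA"]
    return pd.DataFrame({"dE_MM": de_mm, "dG_sol": dg_sol, "dH": de_mm + dg_sol})


def block_protocol(series: np.ndarray, n_blocks: int = 20,
                   snapshots_per_block: int = 100) -> tuple[SeriesStats, np.ndarray]:
    """Block-averaged statistics of a per-frame series.

    Splits the series into ``n_blocks`` equal contiguous blocks, samples
    ``snapshots_per_block`` values at a regular stride within each, and
    returns the mean ± sample SD over block means (SD 0 when n_blocks=1)
    together with the block means themselves.
    """
    series = np.asarray(series, dtype=float)
    required = n_blocks * snapshots_per_block
    if series.size < required:
        raise ValueError(
            f"series has {series.size} frames; block protocol needs >= {required} "
            f"({n_blocks} blocks x {snapshots_per_block} snapshots)"
        )
    block_len = series.size // n_blocks
    stride = block_len // snapshots_per_block
    means = np.empty(n_blocks)
    for b in range(n_blocks):
        block = series[b * block_len:(b + 1) * block_len]
        means[b] = block[::stride][:snapshots_per_block].mean()
    return SeriesStats.from_series(means), means


def entropy_mean(blocks: Sequence[np.ndarray]) -> SeriesStats:
    """Aggregate per-snapshot TdS estimates grouped by block.

    Each block is averaged, then the mean ± sample SD across block means is
    returned.  Blocks must be non-empty and of equal size.
    """
    if len(blocks) == 0:
        raise ValueError("at least one entropy block is required")
    sizes = {len(np.atleast_1d(b)) for b in blocks}
    if 0 in sizes:
        raise ValueError("empty entropy block")
    if len(sizes) != 1:
        raise ValueError(f"ragged entropy blocks (sizes {sorted(sizes)})")
    means = np.array([float(np.mean(b)) for b in blocks])
    return SeriesStats.from_series(means)


@dataclasses.dataclass(frozen=True)
class BindingFreeEnergy:
    """End-point binding free energy summary (kcal/mol)."""

    dE_MM: SeriesStats
    dG_sol: SeriesStats
    dH: SeriesStats
    TdS: SeriesStats
    dG_bind: float
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if abs(self.dG_bind - (self.dH.mean - self.TdS.mean)) > 1e-9:
            raise ValueError("dG_bind must equal dH - TdS")


def binding_free_energy(dH: SeriesStats | float, TdS: SeriesStats | float,
                        temperature_K: float = DEFAULT_TEMPERATURE_K,
                        dE_MM: SeriesStats | None = None,
                        dG_sol: SeriesStats | None = None) -> BindingFreeEnergy:
    """Combine enthalpic and entropic terms: dG_bind = dH - TdS.

    Scalar inputs are wrapped as n=1 stats.  TdS is stored as the
    temperature-weighted entropy itself, so an unfavorable entropy of
    -19.0 kcal/mol raises a -23.6 kcal/mol enthalpy to -4.6 kcal/mol.
    """
    def _stats(x):
        return x if isinstance(x, SeriesStats) else SeriesStats(float(x), 0.0, 1)

    dh, tds = _stats(dH), _stats(TdS)
    return BindingFreeEnergy(
        dE_MM=_stats(dE_MM) if dE_MM is not None else SeriesStats(float("nan"), 0.0, 1),
        dG_sol=_stats(dG_sol) if dG_sol is not None else SeriesStats(float("nan"), 0.0, 1),
        dH=dh,
        TdS=tds,
        dG_bind=dh.mean - tds.mean,
        temperature_K=temperature_K,
    )


@dataclasses.dataclass(frozen=True)
class ResidueContribution:
    residue_id: str
    dG_res: float
    key: bool


def per_residue_decomposition(table: pd.DataFrame,
                              threshold: float = KEY_RESIDUE_THRESHOLD,
                              ) -> list[ResidueContribution]:
    """Time-average per-residue contributions from a long-format table.

    Expects columns ``frame``, ``residue_id``, ``dG_res``; every frame must
    report the same residue set.  Residues at or below ``threshold``
    (kcal/mol) are flagged as key binding residues.
    """
    if table.empty:
        return []
    required = {"frame", "residue_id", "dG_res"}
    if not required.issubset(table.columns):
        raise ValueError(f"decomposition table needs columns {sorted(required)}")
    per_frame = table.groupby("frame")["residue_id"].apply(frozenset)
    if per_frame.nunique() != 1:
        raise ValueError("inconsistent residue sets across frames")
    means = table.groupby("residue_id", sort=False)["dG_res"].mean()
    return [
        ResidueContribution(residue_id=str(r), dG_res=float(v), key=bool(v <= threshold))
        for r, v in means.items()
    ]


def key_residues(contribs: Sequence[ResidueContribution],
                 threshold: float = KEY_RESIDUE_THRESHOLD) -> list[str]:
    """Residues whose mean contribution is at or below the threshold,
    most favorable first."""
    hits = [c for c in contribs if c.dG_res <= threshold]
    return [c.residue_id for c in sorted(hits, key=lambda c: c.dG_res)]
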