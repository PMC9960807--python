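"""Elevated-plus-maze scoring: anxiety index, group summaries, correlations.

The anxiety index condenses a ten-minute elevated-plus-maze session into

    AI = 1 - 1/2 (T_op / T + N_op / N)

where T_op / T are open-arm and total time (s) and N_op / N open-arm and
total arm entries.  AI lies in [0, 1]; 0 is an animal that spent the whole
session in the open arms, 1 one that never entered them.  Correlations of
behavioral scores against covariates (e.g. hepatic enzyme activity) default
to Pearson's r, with Spearman available where monotone-only association is
preferred.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["EPMRecord", "anxiety_index", "pearson_r", "correlate", "group_summary"]


@dataclasses.dataclass(frozen=True)
class EPMRecord:
    """One animal's elevated-plus-maze session."""

    T_op: float
    T: float
    N_op: int
    N: int
    group: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("total time T must be positive")
        if not (0 <= self.T_op <= self.T):
            raise ValueError(f"open-arm time {self.T_op} outside [0, T={self.T}]")
        if self.N_op < 0 or self.N < 0 or self.N_op > self.N:
            raise ValueError(f"entries N_op={self.N_op}, N={self.N} violate 0 <= N_op <= N")


def anxiety_index(rec: EPMRecord) -> float:
    """AI = 1 - (T_op/T + N_op/N)/2, in [0, 1].

    Undefined for an animal with no arm entries at all (N = 0).
    """
    if rec.N == 0:
        raise ValueError("anxiety index undefined: animal never entered any arm (N=0)")
    return 1.0 - 0.5 * (rec.T_op / rec.T + rec.N_op / rec.N)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for a zero-variance series")
    return float(sps.pearsonr(x, y).statistic)


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Correlation with selectable method ('pearson' or 'spearman')."""
    if method == "pearson":
        return pearson_r(x, y)
    if method == "spearman":
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.size < 3:
            raise ValueError("spearman needs n >= 3")
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def records_from_table(df: pd.DataFrame) -> list[EPMRecord]:
    """Build records from a table with columns
    (animal_id, group, T_op, T, N_op, N)."""
    out = []
    for _, row in df.iterrows():
        out.append(EPMRecord(
            T_op=float(row["T_op"]), T=float(row["T"]),
            N_op=int(row["N_op"]), N=int(row["N"]),
            group=str(row.get("group", "")), animal_id=str(row.get("animal_id", "")),
        ))
    return out


def group_summary(records: Sequence[EPMRecord]) -> pd.DataFrame:
    """Per-group mean ± sample SD of every EPM measure and the AI.

    Returns one row per group with ``<measure>_mean``/``<measure>_sd``
    columns and ``n``; single-animal groups report SD 0 (flagged by n=1).
    """
    if not records:
        raise ValueError("no records supplied")
    rows = [{
        "group": r.group,
        "T_op": r.T_op,
        "T_closed": r.T - r.T_op,
        "N_op": r.N_op,
        "N_closed": r.N - r.N_op,
        "AI": anxiety_index(r),
    } for r in records]
    df = pd.DataFrame(rows)
    measures = ["T_op", "T_closed", "N_op", "N_closed", "AI"]
    out = []
    for group, sub in df.groupby("group", sort=False):
        row: dict = {"group": group, "n": len(sub)}
        for m in measures:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
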