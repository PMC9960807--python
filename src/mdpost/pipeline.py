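"""End-to-end orchestration: load inputs, run every analysis stage, write a
report bundle with a hashed MANIFEST.

The pipeline is driven by a flat key=value config file (see
:class:`RunConfig`).  Stages whose inputs are absent are skipped and logged;
any stage failure aborts the run with the stage named, leaving partial
outputs and a MANIFEST that marks completeness.  Frame indices are reported
1-based in output tables (0-based internally); residue numbering follows
the input files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, conformations, correlations, energetics, geometry
from .trajio import (Selection, Trajectory, read_multimodel_pdb, read_table,
                     write_multimodel_pdb, write_table)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("mdpost.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; defaults follow the reference study protocol."""

    trajectory: str | None = None
    energy_components: str | None = None
    per_residue: str | None = None
    entropy: str | None = None
    epm: str | None = None
    distance_series: str | None = None
    outdir: str = "mdpost_out"
    # analysis settings
    selection_name: str = "CA"
    rmsd_breakpoint_fraction: float = 0.30   # two-segment RMSD averaging split
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 135.0
    hbond_present_cutoff: float = 2.5        # H···A cutoff for occupancy of a distance series
    contact_cutoff: float = 4.0
    k_min: int = 2
    k_max: int = 10
    kmeans_max_iter: int = 1000
    sieve: int = 10
    seed: int = 2023
    n_blocks: int = 20
    snapshots_per_block: int = 100
    decomposition_threshold: float = energetics.KEY_RESIDUE_THRESHOLD
    temperature_K: float = energetics.DEFAULT_TEMPERATURE_K
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file ('#' comments allowed)."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Bundle:
    """Collects outputs and stage completion for the MANIFEST."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        outdir.mkdir(parents=True, exist_ok=True)
        self.stages: dict[str, str] = {}
        self.files: list[Path] = []
        self.summary: list[str] = []

    def add_table(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        write_table(df, path)
        self.files.append(path)
        return path

    def finish(self) -> Path:
        lines = ["# MANIFEST", "", "## stages"]
        lines += [f"{stage}: {status}" for stage, status in self.stages.items()]
        lines += ["", "## files (sha256)"]
        lines += [f"{p.name}: {_sha256(p)}" for p in sorted(self.files)]
        path = self.outdir / "MANIFEST"
        path.write_text("\n".join(lines) + "\n")
        (self.outdir / "summary.txt").write_text("\n".join(self.summary) + "\n")
        return path


def _stage(bundle: _Bundle, name: str):
    """Context manager marking stage status in the MANIFEST."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                bundle.stages[name] = "complete"
                logger.info("stage %s: complete", name)
                return False
            bundle.stages[name] = f"failed ({exc})"
            bundle.finish()
            raise PipelineError(name, exc) from exc
    return _Ctx()


def _geometry_stage(cfg: RunConfig, traj: Trajectory, sel: Selection, b: _Bundle) -> None:
    frames_1based = np.arange(1, traj.n_frames + 1)
    rmsd = geometry.rmsd_series(traj, traj.coords[0], sel, fit=True)
    b.add_table("rmsd.csv", pd.DataFrame({"frame": frames_1based, "rmsd_A": rmsd}))
    rog = geometry.rog_series(traj, sel)
    b.add_table("rog.csv", pd.DataFrame({"frame": frames_1based, "rog_A": rog}))
    bp = int(round(cfg.rmsd_breakpoint_fraction * traj.n_frames))
    breakpoints = [bp] if 0 < bp < traj.n_frames else []
    seg_rows = []
    for label, series in (("rmsd", rmsd), ("rog", rog)):
        full = geometry.segment_stats(series)[0]
        seg_rows.append({"series": label, "segment": "all", "mean": full.mean,
                         "sd": full.sd, "n": full.n})
        for i, st in enumerate(geometry.segment_stats(series, breakpoints)):
            seg_rows.append({"series": label, "segment": f"part{i + 1}",
                             "mean": st.mean, "sd": st.sd, "n": st.n})
    b.add_table("segment_stats.csv", pd.DataFrame(seg_rows))
    fluct = geometry.rmsf(traj, sel)
    res_ids = [traj.topology.atoms[i].residue_index for i in sel.indices]
    b.add_table("rmsf.csv", pd.DataFrame({"residue": res_ids, "rmsf_A": fluct}))
    b.summary += [
        f"RMSD (all frames): {np.mean(rmsd):.2f} ± {np.std(rmsd, ddof=1):.2f} Å",
        f"RoG  (all frames): {np.mean(rog):.2f} ± {np.std(rog, ddof=1):.2f} Å",
        f"RMSF: mean {fluct.mean():.2f} Å, max {fluct.max():.2f} Å "
        f"at residue {res_ids[int(np.argmax(fluct))]}",
    ]


def _cluster_stage(cfg: RunConfig, traj: Trajectory, sel: Selection, b: _Bundle) -> None:
    features = conformations.trajectory_features(traj, sel)
    k_best, table, models = conformations.select_k(
        features, range(cfg.k_min, cfg.k_max + 1), seed=cfg.seed,
        sieve=cfg.sieve, max_iter=cfg.kmeans_max_iter)
    b.add_table("cluster_indices.csv", table)
    model = models[k_best]
    b.add_table("cluster_labels.csv", pd.DataFrame({
        "frame": np.arange(1, traj.n_frames + 1), "cluster": model.labels}))
    reps = model.representative_frames
    rep_rows = []
    for c, f in enumerate(reps):
        rep_path = b.outdir / f"representative_cluster{c}.pdb"
        write_multimodel_pdb(
            Trajectory(traj.topology, traj.coords[f][None]), rep_path)
        b.files.append(rep_path)
        rep_rows.append({"cluster": c, "frame": int(f) + 1,
                         "population": int(model.populations[c])})
    b.add_table("representative_frames.csv", pd.DataFrame(rep_rows))
    b.summary += [
        f"Selected k = {k_best} "
        f"(DBI {model.dbi:.3f}, pSF {model.psf:.1f}, SSR/SST {model.ssr_sst:.3f})",
        "Cluster populations: " + ", ".join(
            f"{c}: {int(n)}" for c, n in enumerate(model.populations)),
    ]


def _correlation_stage(cfg: RunConfig, traj: Trajectory, sel: Selection, b: _Bundle) -> None:
    matrix = correlations.dccm(traj, sel)
    dccm_df = pd.DataFrame(matrix.values, columns=list(matrix.residue_ids))
    dccm_df.insert(0, "residue", list(matrix.residue_ids))
    b.add_table("dccm.csv", dccm_df)
    result = correlations.pca(traj, sel)
    b.add_table("pca_scree.csv", pd.DataFrame({
        "component": np.arange(1, result.n_components + 1),
        "eigenvalue": result.eigenvalues,
        "explained_fraction": result.explained_fraction,
    }))
    n_proj = min(10, result.n_components)
    b.add_table("pca_projections.csv", pd.DataFrame(
        result.projections[:, :n_proj],
        columns=[f"PC{i + 1}" for i in range(n_proj)]))
    b.summary += [
        f"PCA: {result.n_components} eigenvectors; "
        f"PC1-2 capture {100 * correlations.variance_captured(result, 2):.1f}%, "
        f"PC1-10 capture {100 * correlations.variance_captured(result, min(10, result.n_components)):.1f}%",
    ]


def _energetics_stage(cfg: RunConfig, b: _Bundle) -> None:
    comp = energetics.EnergyComponents.from_table(read_table(cfg.energy_components))
    per_frame = energetics.combine_components(comp)
    dh_stats, block_means = energetics.block_protocol(
        per_frame["dH"].to_numpy(), cfg.n_blocks, cfg.snapshots_per_block)
    mm_stats, _ = energetics.block_protocol(
        per_frame["dE_MM"].to_numpy(), cfg.n_blocks, cfg.snapshots_per_block)
    sol_stats, _ = energetics.block_protocol(
        per_frame["dG_sol"].to_numpy(), cfg.n_blocks, cfg.snapshots_per_block)
    b.add_table("gbsa_blocks.csv", pd.DataFrame({
        "block": np.arange(1, cfg.n_blocks + 1), "dH_mean": block_means}))
    tds_stats = None
    if cfg.entropy:
        ent = read_table(cfg.entropy)
        blocks = [g["TdS"].to_numpy() for _, g in ent.groupby("block", sort=True)]
        tds_stats = energetics.entropy_mean(blocks)
    result = energetics.binding_free_energy(
        dh_stats, tds_stats if tds_stats is not None else 0.0,
        cfg.temperature_K, dE_MM=mm_stats, dG_sol=sol_stats)
    rows = [
        {"quantity": "dE_MM", "mean": result.dE_MM.mean, "sd": result.dE_MM.sd, "n": result.dE_MM.n},
        {"quantity": "dG_sol", "mean": result.dG_sol.mean, "sd": result.dG_sol.sd, "n": result.dG_sol.n},
        {"quantity": "dH", "mean": result.dH.mean, "sd": result.dH.sd, "n": result.dH.n},
        {"quantity": "TdS", "mean": result.TdS.mean, "sd": result.TdS.sd, "n": result.TdS.n},
        {"quantity": "dG_bind", "mean": result.dG_bind, "sd": float("nan"), "n": result.dH.n},
    ]
    b.add_table("gbsa_summary.csv", pd.DataFrame(rows))
    entropy_note = "" if tds_stats is not None else " (no entropy table: TdS taken as 0)"
    b.summary.append(
        f"MM/GBSA: dH {result.dH.mean:.1f} ± {result.dH.sd:.1f}, "
        f"TdS {result.TdS.mean:.1f} ± {result.TdS.sd:.1f}, "
        f"dG_bind {result.dG_bind:.1f} kcal/mol at {cfg.temperature_K:.0f} K{entropy_note}")
    if cfg.per_residue:
        contribs = energetics.per_residue_decomposition(
            read_table(cfg.per_residue), cfg.decomposition_threshold)
        b.add_table("per_residue.csv", pd.DataFrame([
            {"residue_id": c.residue_id, "dG_res": c.dG_res, "key": c.key}
            for c in contribs]))
        keys = energetics.key_residues(contribs, cfg.decomposition_threshold)
        b.summary.append(
            f"Key residues (dG_res <= {cfg.decomposition_threshold} kcal/mol): "
            + (", ".join(keys) if keys else "none"))


def _distance_stage(cfg: RunConfig, b: _Bundle) -> None:
    table = read_table(cfg.distance_series)
    col = [c for c in table.columns if c != "frame"][0]
    series = table[col].to_numpy(dtype=float)
    stats = geometry.SeriesStats.from_series(series)
    present = series <= cfg.hbond_present_cutoff
    bonded = series[present]
    rows = [{
        "n_frames": stats.n, "mean_A": stats.mean, "sd_A": stats.sd,
        "occupancy": float(present.mean()),
        "bonded_mean_A": float(bonded.mean()) if present.any() else float("nan"),
        "bonded_sd_A": float(bonded.std(ddof=1)) if present.sum() > 1 else 0.0,
    }]
    b.add_table("hbond_distance_summary.csv", pd.DataFrame(rows))
    b.summary.append(
        f"H-bond distance series: occupancy {100 * present.mean():.0f}% "
        f"under {cfg.hbond_present_cutoff} Å; bonded mean "
        f"{bonded.mean():.2f} ± {bonded.std(ddof=1):.2f} Å" if present.any()
        else "H-bond distance series: never bonded")


def _epm_stage(cfg: RunConfig, b: _Bundle) -> None:
    df = read_table(cfg.epm)
    records = behavior.records_from_table(df)
    ai = [behavior.anxiety_index(r) for r in records]
    per_animal = df.assign(AI=ai)
    b.add_table("epm_ai.csv", per_animal)
    summary = behavior.group_summary(records)
    b.add_table("epm_groups.csv", summary)
    corr_note = ""
    if "activity" in df.columns:
        r = behavior.correlate(df["activity"], ai, cfg.correlation_method)
        b.add_table("epm_correlation.csv", pd.DataFrame(
            [{"x": "activity", "y": "AI", "method": cfg.correlation_method, "r": r}]))
        corr_note = f"; activity-AI {cfg.correlation_method} r = {r:.2f}"
    b.summary.append(
        "EPM groups: " + ", ".join(
            f"{row['group']} AI {row['AI_mean']:.2f} ± {row['AI_sd']:.2f} (n={row['n']})"
            for _, row in summary.iterrows()) + corr_note)


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the MANIFEST path.

    Stage order: trajectory load, geometry, clustering, DCCM/PCA,
    H-bond distance series, energetics, EPM.  Missing optional inputs skip
    their stage; the MANIFEST records per-stage completeness and a sha256
    for every emitted file.
    """
    b = _Bundle(Path(config.outdir))
    b.summary.append("mdpost pipeline report")
    b.summary.append("frame indices are 1-based; residue numbering follows input files")

    traj = sel = None
    if config.trajectory:
        with _stage(b, "trajectory_io"):
            _, traj = read_multimodel_pdb(config.trajectory)
            sel = traj.topology.select(name=config.selection_name)
            if len(sel) == 0:
                raise ValueError(f"no atoms named {config.selection_name!r}")
            logger.info("loaded %d frames, %d atoms, %d selected",
                        traj.n_frames, traj.n_atoms, len(sel))
    else:
        b.stages["trajectory_io"] = "skipped (no trajectory)"

    for name, fn, enabled in (
        ("geometry", _geometry_stage, traj is not None),
        ("conformations", _cluster_stage, traj is not None),
        ("correlations", _correlation_stage, traj is not None),
    ):
        if enabled:
            with _stage(b, name):
                fn(config, traj, sel, b)
        else:
            b.stages[name] = "skipped (no trajectory)"

    if config.distance_series:
        with _stage(b, "interactions"):
            _distance_stage(config, b)
    else:
        b.stages["interactions"] = "skipped (no distance series)"

    if config.energy_components:
        with _stage(b, "energetics"):
            _energetics_stage(config, b)
    else:
        b.stages["energetics"] = "skipped (no energy tables)"
        logger.info("energetics stage skipped: no energy tables configured")

    if config.epm:
        with _stage(b, "behavior"):
            _epm_stage(config, b)
    else:
        b.stages["behavior"] = "skipped (no EPM table)"

    return b.finish()
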