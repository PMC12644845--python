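"""End-to-end orchestration: simulate -> estimate -> metrics -> fit ->
peaks / cluster / gradient / stats, with seeds, resume, and provenance.

Every stage reads and writes plain delimited text under one output
directory, so any intermediate can be inspected, replaced, or deleted
to force recomputation (a stage is skipped when its outputs already
exist).  One master seed drives everything; per-stage seeds are derived
as ``(master_seed * 1000 + stage_index) mod 2**31`` and recorded, so
identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lifespan_ec import io as lio
from lifespan_ec import metrics as lmetrics
from lifespan_ec import patterns, peaks, stats, synth, trajectory
from lifespan_ec.rdcm import RdcmConfig, estimate_ec

logger = logging.getLogger("lifespan_ec.pipeline")

STAGES = ("simulate", "estimate", "metrics", "fit", "peaks", "cluster", "gradient", "stats")

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "simulate": {
        "n_subjects": 60,
        "n_regions": 20,
        "networks": {"VIS": 5, "SM": 5, "FPC": 5, "DMN": 5},
        "tr": 0.8,
        "n_timepoints": 400,
        "snr": 3.0,
        "age_min": 0.05,
        "age_max": 95.0,
    },
    "estimate": {"nyquist_fraction": 1.0},
    "metrics": {"include_diagonal": False},
    "fit": {"metric": "global_ec", "k_min": 5, "k_max": 14, "grid": 512,
            "nodal_k_min": 5, "nodal_k_max": 8},
    "peaks": {"n_draws": 2000, "alpha": 0.05},
    "cluster": {"k": 5, "n_init": 50},
    "gradient": {},
    "stats": {"early_cutoff": 12.0, "late_cutoff": 20.0},
}


def validate_config(config: dict) -> dict:
    """Merge with defaults; unknown keys anywhere are a hard error."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in merged:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(value, dict):
            for sub, sv in value.items():
                if sub not in merged[key]:
                    raise ValueError(f"unknown config key {key}.{sub}")
                merged[key][sub] = sv
        else:
            merged[key] = value
    return merged


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) * 1000 + STAGES.index(stage)) % 2**31


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunRecord:
    config: dict
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path], elapsed: float, skipped: bool) -> None:
        self.stages[stage] = {
            "skipped": skipped,
            "seconds": round(elapsed, 3),
            "outputs": {p.name: _digest(p) for p in outputs if p.is_file()},
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds,
             "stages": self.stages, "warnings": self.warnings},
            indent=1, sort_keys=True,
        ))


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run") -> RunRecord:
    """Execute all stages in dependency order; resumable and seeded."""
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=cfg)
    record.seeds = {s: stage_seed(cfg["master_seed"], s) for s in STAGES}

    parcellation = _stage_simulate(cfg, out, record)
    _stage_estimate(cfg, out, record, parcellation)
    _stage_metrics(cfg, out, record, parcellation)
    fit_global = _stage_fit(cfg, out, record, parcellation)
    _stage_peaks(cfg, out, record, fit_global)
    tm = _load_trajectories(out)
    _stage_cluster(cfg, out, record, tm, parcellation)
    _stage_gradient(cfg, out, record, tm, parcellation)
    _stage_stats(cfg, out, record, tm, parcellation)
    record.save(out / "run_record.json")
    return record


def _stage_simulate(cfg, out: Path, record: RunRecord) -> lio.Parcellation:
    t0 = time.time()
    sim = cfg["simulate"]
    parc_path = out / "parcellation.tsv"
    manifest_path = out / "manifest.tsv"
    if parc_path.exists() and manifest_path.exists():
        record.record("simulate", [parc_path, manifest_path], 0.0, skipped=True)
        return lio.read_parcellation(parc_path)
    parcellation = lio.reference_parcellation(sim["networks"])
    lio.write_parcellation(parcellation, parc_path)
    spec = synth.SimulationSpec(
        n_regions=sim["n_regions"], tr=sim["tr"],
        n_timepoints=sim["n_timepoints"], snr=sim["snr"],
        parcellation=parcellation,
    )
    synth.generate_cohort(
        n_subjects=sim["n_subjects"], spec=spec,
        seed=stage_seed(cfg["master_seed"], "simulate"), out_dir=out,
        age_range=(sim["age_min"], sim["age_max"]),
    )
    record.record("simulate", [parc_path, manifest_path, out / "truth.json"],
                  time.time() - t0, skipped=False)
    return parcellation


def _stage_estimate(cfg, out: Path, record: RunRecord, parcellation) -> None:
    t0 = time.time()
    ec_dir = out / "ec"
    log_path = out / "estimate_log.tsv"
    if log_path.exists():
        record.record("estimate", [log_path], 0.0, skipped=True)
        return
    ec_dir.mkdir(exist_ok=True)
    manifest = lio.read_manifest(out / "manifest.tsv")
    rcfg = RdcmConfig(nyquist_fraction=cfg["estimate"]["nyquist_fraction"])
    log_rows = []
    for row in manifest.rows():
        run = lio.read_bold_run(out / row["series_path"], row, parcellation)
        ec, summaries, _ = estimate_ec(run, parcellation, rcfg)
        name = Path(row["series_path"]).stem
        lio.write_ec_matrix(ec, ec_dir / f"{name}_ec.tsv")
        log_rows.append({
            "scan": name,
            "n_converged": sum(s.converged for s in summaries),
            "n_regions": len(summaries),
        })
    pd.DataFrame(log_rows).to_csv(log_path, sep="\t", index=False)
    record.record("estimate", [log_path], time.time() - t0, skipped=False)


def _stage_metrics(cfg, out: Path, record: RunRecord, parcellation) -> None:
    t0 = time.time()
    metrics_path = out / "metrics.tsv"
    nodal_path = out / "nodal.tsv"
    if metrics_path.exists() and nodal_path.exists():
        record.record("metrics", [metrics_path, nodal_path], 0.0, skipped=True)
        return
    manifest = lio.read_manifest(out / "manifest.tsv")
    include_diag = cfg["metrics"]["include_diagonal"]
    scans = []
    for row in manifest.rows():
        name = Path(row["series_path"]).stem
        ec = lio.read_ec_matrix(out / "ec" / f"{name}_ec.tsv", parcellation)
        scans.append(lmetrics.scan_metrics(
            ec, parcellation, subject_id=row["subject_id"], age=row["age"],
            sex=int(row["sex"]), site=row["site"], include_diagonal=include_diag,
        ))
    lmetrics.metrics_table(scans).to_csv(metrics_path, sep="\t", index=False, float_format="%.12g")
    lmetrics.nodal_table(scans).to_csv(nodal_path, sep="\t", index=False, float_format="%.12g")
    record.record("metrics", [metrics_path, nodal_path], time.time() - t0, skipped=False)


def _stage_fit(cfg, out: Path, record: RunRecord, parcellation):
    t0 = time.time()
    fcfg = cfg["fit"]
    fit_path = out / "fit_global.tsv"
    traj_path = out / "trajectories.tsv"
    metrics_df = pd.read_csv(out / "metrics.tsv", sep="\t")
    sub = metrics_df[metrics_df["metric"] == fcfg["metric"]].rename(columns={"value": "y"})
    samples = sub[["y", "age", "sex", "subject_id", "site"]].rename(columns={"y": "value"})
    fit = trajectory.fit_trajectory(
        samples, k_range=range(fcfg["k_min"], fcfg["k_max"] + 1), grid_size=fcfg["grid"]
    )
    if fit_path.exists() and traj_path.exists():
        record.record("fit", [fit_path, traj_path], 0.0, skipped=True)
        return fit
    frames = [fit.predict(sex_value=s) for s in (0.0, 1.0, -1.0)]
    pd.concat(frames).to_csv(fit_path, sep="\t", index=False, float_format="%.12g")

    nodal = pd.read_csv(out / "nodal.tsv", sep="\t")
    tm_df, grid_t = trajectory.fit_nodal_trajectories(
        nodal, value_column="ecs",
        k_range=range(fcfg["nodal_k_min"], fcfg["nodal_k_max"] + 1),
        grid_size=fcfg["grid"],
    )
    tm_df.columns = [f"{t:.10g}" for t in grid_t]
    tm_df.to_csv(traj_path, sep="\t", float_format="%.12g")
    record.record("fit", [fit_path, traj_path], time.time() - t0, skipped=False)
    return fit


def _stage_peaks(cfg, out: Path, record: RunRecord, fit) -> None:
    t0 = time.time()
    path = out / "peaks.tsv"
    if path.exists():
        record.record("peaks", [path], 0.0, skipped=True)
        return
    pk = peaks.bootstrap_peak_ci(
        fit, n_draws=cfg["peaks"]["n_draws"], alpha=cfg["peaks"]["alpha"],
        seed=stage_seed(cfg["master_seed"], "peaks"),
    )
    pd.DataFrame([asdict(pk)]).to_csv(path, sep="\t", index=False, float_format="%.12g")
    record.record("peaks", [path], time.time() - t0, skipped=False)


def _load_trajectories(out: Path) -> patterns.TrajectoryMatrix:
    df = pd.read_csv(out / "trajectories.tsv", sep="\t", index_col=0)
    return patterns.TrajectoryMatrix(
        values=df.to_numpy(dtype=float),
        region_ids=tuple(df.index),
        grid_t=np.array([float(c) for c in df.columns]),
    )


def _stage_cluster(cfg, out: Path, record: RunRecord, tm, parcellation) -> None:
    t0 = time.time()
    path = out / "clusters.tsv"
    if path.exists():
        record.record("cluster", [path], 0.0, skipped=True)
        return
    res = patterns.cluster_trajectories(
        tm, k=cfg["cluster"]["k"], n_init=cfg["cluster"]["n_init"],
        seed=stage_seed(cfg["master_seed"], "cluster"), parcellation=parcellation,
    )
    pd.DataFrame({"region": list(tm.region_ids), "cluster": res.labels}).to_csv(
        path, sep="\t", index=False
    )
    if res.composition is not None:
        res.composition.to_csv(out / "cluster_composition.tsv", sep="\t", float_format="%.6g")
    record.record("cluster", [path], time.time() - t0, skipped=False)


def _stage_gradient(cfg, out: Path, record: RunRecord, tm, parcellation) -> None:
    t0 = time.time()
    path = out / "gradient.tsv"
    if path.exists():
        record.record("gradient", [path], 0.0, skipped=True)
        return
    grad = patterns.pca_gradient(tm, parcellation)
    pd.DataFrame(
        {"region": list(tm.region_ids), "loading": grad.loadings}
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
    record.record("gradient", [path], time.time() - t0, skipped=False)


def _stage_stats(cfg, out: Path, record: RunRecord, tm, parcellation) -> None:
    t0 = time.time()
    path = out / "stats.tsv"
    if path.exists():
        record.record("stats", [path], 0.0, skipped=True)
        return
    sd = patterns.early_late_sd(
        tm, cfg["stats"]["early_cutoff"], cfg["stats"]["late_cutoff"]
    )
    rows = []
    by_net: dict = {}
    for net in parcellation.networks:
        regions = [r for r in tm.region_ids if parcellation.network_of[r] == net]
        sub = sd.loc[regions]
        by_net[net] = (sub["sd_early"].to_numpy(), sub["sd_late"].to_numpy())
    results = stats.pairwise_network_tests(by_net, test="signedrank")
    for net, res in zip(parcellation.networks, results):
        rows.append({
            "comparison": f"{net}: sd_early vs sd_late", "test": res.test,
            "statistic": res.statistic, "p_value": res.p_value,
            "p_adjusted": res.p_adjusted, "cohens_d": res.effect_size,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")
    record.record("stats", [path], time.time() - t0, skipped=False)


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------


def recovery_report(out_dir: str | Path, tolerances: dict | None = None) -> pd.DataFrame:
    """Planted vs recovered quantities for a synthetic pipeline run.

    Reports the mean off-diagonal correlation between each scan's
    generating matrix and its estimated EC, and the planted vs fitted
    global peak age.  A missing truth file is a hard error.
    """
    out = Path(out_dir)
    truth_path = out / "truth.json"
    if not truth_path.exists():
        raise FileNotFoundError("truth.json not found: recovery reports need a synthetic run")
    # loose sanity floors for desk-scale synthetic runs; override per study
    tol = {"ec_corr_min": 0.4, "peak_age_tol": 3.0}
    tol.update(tolerances or {})
    truth = synth.load_truth(truth_path)
    manifest = lio.read_manifest(out / "manifest.tsv")
    parcellation = lio.read_parcellation(out / "parcellation.tsv")

    corrs = []
    r = parcellation.n_regions
    off = ~np.eye(r, dtype=bool)
    for row in manifest.rows():
        A, _ = synth.make_lifespan_ec(
            row["age"], int(row["sex"]), row["site"],
            truth.subject_effects[str(row["subject_id"])], truth, r,
        )
        name = Path(row["series_path"]).stem
        ec = lio.read_ec_matrix(out / "ec" / f"{name}_ec.tsv", parcellation)
        corrs.append(np.corrcoef(A[off], ec.values[off])[0, 1])
    mean_corr = float(np.mean(corrs))

    peaks_df = pd.read_csv(out / "peaks.tsv", sep="\t")
    fitted_peak = float(peaks_df["peak_age"].iloc[0])
    planted_peak = truth.planted_global_peak_age

    rows = [
        {"quantity": "ec_offdiag_corr", "planted": 1.0, "recovered": mean_corr,
         "error": 1.0 - mean_corr, "passed": mean_corr >= tol["ec_corr_min"]},
        {"quantity": "global_peak_age", "planted": planted_peak, "recovered": fitted_peak,
         "error": abs(fitted_peak - planted_peak),
         "passed": abs(fitted_peak - planted_peak) <= tol["peak_age_tol"]},
    ]
    report = pd.DataFrame(rows)
    report.to_csv(out / "recovery_report.tsv", sep="\t", index=False, float_format="%.12g")
    return report
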