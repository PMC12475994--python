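"""End-to-end orchestration: simulate -> networks -> metrics -> stats ->
report.

Each stage persists its outputs under the run directory and is skipped on
rerun when its inputs (config section + upstream artifacts) are unchanged,
tracked by content hashes in ``manifest.json``. Any stage failure halts the
run with the stage name (and subject id where applicable); partial outputs
are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import StageError
from .metrics import (
    GLOBAL_METRICS,
    NODAL_METRICS,
    SMALL_WORLD_METRICS,
    MetricCurves,
    NullModelConfig,
    SparsityGrid,
    metric_curves,
)
from .network import SimilarityMatrix, build_network
from .samples import ROISampleSet
from .stats import (
    adjusted_correlation,
    ancova_group_test,
    anova_from_summary,
    bonferroni_posthoc,
    chi_square_test,
    nodal_group_screen,
    ttest_from_summary,
)
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("gmnet")


@dataclass
class StatsOptions:
    covariates: tuple = ("age", "gender", "education", "TIV")
    alpha: float = 0.05
    correlation_subset: str = "patients"  # "patients" | "DKD" | "all"
    correlation_variables: tuple = ("eGFR", "Scr", "NCT_A")
    max_correlation_nodes: int = 10


@dataclass
class RunConfig:
    out_dir: str = "gmnet-run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grid_size: int = 128
    bandwidth_rule: str = "silverman"
    pair_eval: str = "interp"
    sparsity: SparsityGrid = field(default_factory=SparsityGrid)
    mode: str = "weighted"
    null_config: NullModelConfig = field(default_factory=NullModelConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in obj.__dict__.items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return convert(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "cohort" in data and isinstance(data["cohort"], dict):
            c = dict(data["cohort"])
            for key in ("voxels_per_roi", "affected_rois"):
                if key in c:
                    c[key] = tuple(c[key])
            if "clinical_params" in c:
                c["clinical_params"] = {
                    var: {g: tuple(ms) for g, ms in per.items()}
                    for var, per in c["clinical_params"].items()
                }
            data["cohort"] = CohortConfig(**c)
        if "sparsity" in data and isinstance(data["sparsity"], dict):
            data["sparsity"] = SparsityGrid(**data["sparsity"])
        if "null_config" in data:
            nc = data["null_config"]
            data["null_config"] = NullModelConfig(**nc) if isinstance(nc, dict) else nc
        if "stats" in data and isinstance(data["stats"], dict):
            s = dict(data["stats"])
            for key in ("covariates", "correlation_variables"):
                if key in s:
                    s[key] = tuple(s[key])
            data["stats"] = StatsOptions(**s)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    """Per-run record of config, seeds and stage input/output hashes."""

    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = {"stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def stage_unchanged(self, stage: str, input_hash: str, outputs) -> bool:
        rec = self.data["stages"].get(stage)
        return (
            rec is not None
            and rec["input_hash"] == input_hash
            and all(Path(p).exists() for p in rec["outputs"])
            and set(map(str, outputs)) <= set(rec["outputs"])
        )

    def record(self, stage: str, input_hash: str, outputs) -> None:
        self.data["stages"][stage] = {
            "input_hash": input_hash,
            "outputs": sorted(str(p) for p in outputs),
            "output_hashes": {str(p): _hash_file(Path(p)) for p in outputs},
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _timed(stage):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            out = fn(*args, **kwargs)
            log.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)
            return out

        return inner

    return wrap


@_timed("simulate")
def stage_simulate(config: RunConfig, out_dir: Path, manifest: _Manifest):
    cohort_path = out_dir / "cohort.csv"
    samples_dir = out_dir / "samples"
    input_hash = _hash_obj(config.to_dict()["cohort"])
    if manifest.stage_unchanged("simulate", input_hash, [cohort_path]):
        log.info("stage=simulate skipped (unchanged)")
        return cohort_path, samples_dir
    try:
        cohort, subjects = generate_cohort(config.cohort)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    samples_dir.mkdir(parents=True, exist_ok=True)
    outputs = [cohort_path]
    cohort.to_csv(cohort_path, index=False)
    for subject in subjects:
        p = samples_dir / f"{subject.subject_id}.tsv"
        subject.to_tsv(p)
        outputs.append(p)
    manifest.record("simulate", input_hash, outputs)
    return cohort_path, samples_dir


@_timed("network")
def stage_network(config: RunConfig, out_dir: Path, manifest: _Manifest,
                  samples_dir: Path):
    net_dir = out_dir / "networks"
    sample_files = sorted(samples_dir.glob("*.tsv"))
    input_hash = _hash_obj(
        {
            "grid_size": config.grid_size,
            "bandwidth_rule": config.bandwidth_rule,
            "pair_eval": config.pair_eval,
            "inputs": [_hash_file(p) for p in sample_files],
        }
    )
    expected = [net_dir / p.name for p in sample_files]
    if manifest.stage_unchanged("network", input_hash, expected):
        log.info("stage=network skipped (unchanged)")
        return net_dir
    net_dir.mkdir(parents=True, exist_ok=True)
    for p in sample_files:
        sid = p.stem
        try:
            samples = ROISampleSet.from_tsv(p, subject_id=sid,
                                            atlas_name=config.cohort.atlas_name)
            matrix = build_network(
                samples, grid_size=config.grid_size,
                bandwidth_rule=config.bandwidth_rule,
                pair_eval=config.pair_eval,
            )
        except Exception as exc:
            raise StageError("network", str(exc), subject_id=sid) from exc
        matrix.to_tsv(net_dir / p.name)
        log.info("stage=network subject=%s done", sid)
    manifest.record("network", input_hash, expected)
    return net_dir


@_timed("metrics")
def stage_metrics(config: RunConfig, out_dir: Path, manifest: _Manifest,
                  net_dir: Path):
    metrics_dir = out_dir / "metrics"
    auc_path = metrics_dir / "auc.tsv"
    curves_path = metrics_dir / "curves.tsv"
    net_files = sorted(net_dir.glob("*.tsv"))
    null_cfg = config.null_config
    input_hash = _hash_obj(
        {
            "sparsity": config.to_dict()["sparsity"],
            "mode": config.mode,
            "null": None if null_cfg is None else dataclasses.asdict(null_cfg),
            "seed": config.seed,
            "inputs": [_hash_file(p) for p in net_files],
        }
    )
    if manifest.stage_unchanged("metrics", input_hash, [auc_path, curves_path]):
        log.info("stage=metrics skipped (unchanged)")
        return auc_path, curves_path
    metrics_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    auc_frames, curve_frames = [], []
    for p in net_files:
        sid = p.stem
        try:
            matrix = SimilarityMatrix.from_tsv(p, subject_id=sid)
            curves = metric_curves(
                matrix, grid=config.sparsity, mode=config.mode,
                null_config=null_cfg, seed=int(rng.integers(2**31 - 1)),
                subject_id=sid,
            )
        except Exception as exc:
            raise StageError("metrics", str(exc), subject_id=sid) from exc
        auc_frames.append(curves.auc_frame())
        curve_frames.append(curves.to_long_frame())
        log.info("stage=metrics subject=%s done", sid)
    pd.concat(auc_frames, ignore_index=True).to_csv(auc_path, sep="\t", index=False)
    pd.concat(curve_frames, ignore_index=True).to_csv(curves_path, sep="\t",
                                                      index=False)
    manifest.record("metrics", input_hash, [auc_path, curves_path])
    return auc_path, curves_path


def _demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style demographic/clinical comparisons from the cohort."""
    rows = []
    groups = [g for g in ("HC", "DM", "DKD") if g in set(cohort["group"])]
    if "gender" in cohort and len(groups) > 1:
        table = [
            [int((cohort.loc[cohort.group == g, "gender"] == v).sum())
             for g in groups]
            for v in (1, 0)
        ]
        res = chi_square_test(table)
        rows.append({"variable": "gender", "test": res.test,
                     "statistic": res.statistic, "p": res.p})
    numeric = [c for c in cohort.columns
               if c not in ("subject_id", "group", "gender", "severity")]
    for var in numeric:
        per = [cohort.loc[cohort.group == g, var].dropna() for g in groups]
        per = [(v.mean(), v.std(ddof=1), len(v)) for v in per if len(v) >= 2]
        if len(per) >= 3:
            res = anova_from_summary(*zip(*per))
        elif len(per) == 2:
            (m1, s1, n1), (m2, s2, n2) = per
            res = ttest_from_summary(m1, s1, n1, m2, s2, n2)
        else:
            continue
        rows.append({"variable": var, "test": res.test,
                     "statistic": res.statistic, "p": res.p})
    return pd.DataFrame(rows)


@_timed("stats")
def stage_stats(config: RunConfig, out_dir: Path, manifest: _Manifest,
                cohort_path: Path, auc_path: Path):
    stats_dir = out_dir / "stats"
    opts = config.stats
    outputs = {
        "demographics": stats_dir / "demographics.tsv",
        "global": stats_dir / "global_ancova.tsv",
        "correlations": stats_dir / "correlations.tsv",
        "bundle": stats_dir / "results.json",
    }
    input_hash = _hash_obj(
        {
            "stats": dataclasses.asdict(opts),
            "inputs": [_hash_file(cohort_path), _hash_file(auc_path)],
        }
    )
    nodal_paths = [stats_dir / f"nodal_screen_{m}.tsv" for m in NODAL_METRICS]
    all_outputs = list(outputs.values()) + nodal_paths
    if manifest.stage_unchanged("stats", input_hash, all_outputs):
        log.info("stage=stats skipped (unchanged)")
        return stats_dir
    stats_dir.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(cohort_path).set_index("subject_id", drop=False)
    auc = pd.read_csv(auc_path, sep="\t")
    subjects = sorted(auc["subject"].unique())
    cohort = cohort.loc[subjects].reset_index(drop=True)

    _demographics_table(cohort).to_csv(outputs["demographics"], sep="\t",
                                       index=False)

    # Global metric ANCOVA (Table-2-shaped).
    glob = auc[auc["node_or_global"] == "global"]
    settings = config.to_dict()
    settings.pop("out_dir", None)  # keep the bundle location-independent
    bundle = {"settings": settings, "global": {}, "nodal": {},
              "correlations": []}
    global_rows = []
    for metric in glob["metric"].unique():
        sub = glob[glob["metric"] == metric].set_index("subject")
        y = sub.loc[subjects, "auc"].to_numpy(float)
        try:
            overall = ancova_group_test(y, cohort, opts.covariates)
        except Exception as exc:
            raise StageError("stats", f"global metric {metric}: {exc}") from exc
        row = {"metric": metric, "f": overall.statistic,
               "df1": overall.df[0], "df2": overall.df[1], "p": overall.p}
        for g in ("HC", "DM", "DKD"):
            sel = cohort["group"] == g
            if sel.any():
                row[f"mean_{g}"] = float(y[sel.to_numpy()].mean())
                row[f"sd_{g}"] = float(y[sel.to_numpy()].std(ddof=1))
        if overall.p < opts.alpha:
            for c in bonferroni_posthoc(y, cohort, opts.covariates):
                key = c.contrast.replace(" ", "")
                row[f"{key}_p_raw"] = c.p
                row[f"{key}_p_bonf"] = c.p_adjusted
                row[f"{key}_direction"] = c.effect_direction
        global_rows.append(row)
        bundle["global"][metric] = {"f": overall.statistic, "p": overall.p}
    pd.DataFrame(global_rows).to_csv(outputs["global"], sep="\t", index=False)

    # Per-node screens.
    screens = {}
    nodal = auc[auc["node_or_global"] != "global"]
    for metric in NODAL_METRICS:
        sub = nodal[nodal["metric"] == metric]
        if sub.empty:
            pd.DataFrame().to_csv(stats_dir / f"nodal_screen_{metric}.tsv",
                                  sep="\t", index=False)
            continue
        wide = sub.pivot(index="subject", columns="node_or_global",
                         values="auc").loc[subjects]
        screen = nodal_group_screen(wide, cohort, opts.covariates, opts.alpha)
        screen.to_csv(stats_dir / f"nodal_screen_{metric}.tsv", sep="\t",
                      index=False)
        screens[metric] = (screen, wide)
        bundle["nodal"][metric] = {
            "n_significant": int(screen["significant"].sum()),
            "significant_nodes": screen.loc[screen["significant"], "node"]
            .tolist(),
        }

    # Adjusted correlations in the configured cohort subset.
    corr_rows = []
    if opts.correlation_subset == "patients":
        mask = cohort["group"].isin(["DM", "DKD"])
    elif opts.correlation_subset == "DKD":
        mask = cohort["group"] == "DKD"
    else:
        mask = pd.Series(True, index=cohort.index)
    sub_cohort = cohort[mask].reset_index(drop=True)
    if "degree" in screens and len(sub_cohort) > len(opts.covariates) + 3:
        screen, wide = screens["degree"]
        hits = screen[screen["significant"]].sort_values("f", ascending=False)
        for node in hits["node"].head(opts.max_correlation_nodes):
            y = wide[node].to_numpy(float)[mask.to_numpy()]
            for var in opts.correlation_variables:
                if var not in sub_cohort:
                    continue
                res = adjusted_correlation(sub_cohort[var].to_numpy(float), y,
                                           sub_cohort, opts.covariates)
                corr_rows.append({
                    "node": node, "metric": "degree", "variable": var,
                    "r": res.estimate, "p": res.p, "df": res.df[0],
                    "direction": res.effect_direction,
                })
    corr_frame = pd.DataFrame(
        corr_rows, columns=["node", "metric", "variable", "r", "p", "df",
                            "direction"]
    )
    corr_frame.to_csv(outputs["correlations"], sep="\t", index=False)
    bundle["correlations"] = corr_rows

    with open(outputs["bundle"], "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
    manifest.record("stats", input_hash, all_outputs)
    return stats_dir


@_timed("report")
def stage_report(config: RunConfig, out_dir: Path, manifest: _Manifest,
                 cohort_path: Path, auc_path: Path, stats_dir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "gmnet"

    report_dir = out_dir / "report"
    for needed, stage in ((cohort_path, "simulate"), (auc_path, "metrics"),
                          (stats_dir / "global_ancova.tsv", "stats")):
        if not Path(needed).exists():
            raise StageError("report", f"missing output of stage {stage!r}")
    input_hash = _hash_obj(
        {"inputs": [_hash_file(cohort_path), _hash_file(auc_path),
                    _hash_file(stats_dir / "global_ancova.tsv")]}
    )
    report_dir.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(cohort_path)
    auc = pd.read_csv(auc_path, sep="\t")
    glob = auc[auc["node_or_global"] == "global"].merge(
        cohort[["subject_id", "group"]], left_on="subject",
        right_on="subject_id",
    )
    outputs = []
    order = [g for g in ("HC", "DM", "DKD") if g in set(cohort["group"])]
    for metric in sorted(glob["metric"].unique()):
        fig, ax = plt.subplots(figsize=(4, 3))
        data = [glob.loc[(glob.metric == metric) & (glob.group == g), "auc"]
                for g in order]
        ax.violinplot([d.to_numpy() for d in data], showmedians=True)
        ax.set_xticks(range(1, len(order) + 1), order)
        ax.set_ylabel(f"{metric} AUC")
        fig.tight_layout()
        p = report_dir / f"violin_{metric}.svg"
        fig.savefig(p, metadata={"Date": None})
        plt.close(fig)
        outputs.append(p)

    corr = pd.read_csv(stats_dir / "correlations.tsv", sep="\t")
    nodal_degree_path = stats_dir / "nodal_screen_degree.tsv"
    if not corr.empty and nodal_degree_path.exists():
        fig, axes = plt.subplots(
            1, min(len(corr), 4), figsize=(3 * min(len(corr), 4), 3),
            squeeze=False,
        )
        for ax, (_, row) in zip(axes.ravel(), corr.iterrows()):
            ax.set_title(f"node {row['node']} vs {row['variable']}\n"
                         f"r={row['r']:.2f}, p={row['p']:.3g}")
            ax.set_xlabel(row["variable"])
            ax.set_ylabel("degree AUC")
        fig.tight_layout()
        p = report_dir / "correlations.svg"
        fig.savefig(p, metadata={"Date": None})
        plt.close(fig)
        outputs.append(p)

    manifest.record("report", input_hash, outputs)
    return report_dir


def run_all(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO, format="%(asctime)s %(name)s %(message)s"
    )
    import networkx
    import scipy

    log.info("gmnet run seed=%s numpy=%s scipy=%s networkx=%s",
             config.seed, np.__version__, scipy.__version__,
             networkx.__version__)
    config.to_yaml(out_dir / "config.yaml")
    manifest = _Manifest(out_dir)
    cohort_path, samples_dir = stage_simulate(config, out_dir, manifest)
    net_dir = stage_network(config, out_dir, manifest, samples_dir)
    auc_path, _ = stage_metrics(config, out_dir, manifest, net_dir)
    stats_dir = stage_stats(config, out_dir, manifest, cohort_path, auc_path)
    stage_report(config, out_dir, manifest, cohort_path, auc_path, stats_dir)
    return out_dir
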