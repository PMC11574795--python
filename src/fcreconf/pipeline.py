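"""End-to-end analysis: ingest -> FC -> reconfiguration -> group stats ->
heterogeneity -> brain-behavior, from a single run configuration.

Stage order mirrors the analysis being reproduced: per-state FC estimation
(optionally preceded by temporal filtering), z-scale averaging of the two
task runs, edge-wise reconfiguration, accuracy subgrouping, edge-wise
group t-tests with FDR, distribution-level contrasts (rank-sum + KS) of
group-averaged edges per state, similarity/typicality with label-permutation
tests, and covariate-adjusted behavior correlations with distribution
contrasts.  Every stochastic stage is seeded from the run seed, so a rerun
with identical inputs and config reproduces the summary exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brain_behavior, cohort_io, connectivity, group_stats, heterogeneity
from .exceptions import PipelineStageError

logger = logging.getLogger("fcreconf")

#: full-group and subgroup contrasts, in reporting order (A, B); z and d are A vs B
CONTRASTS = (
    ("ASD", "TD"),
    ("LP-ASD", "TDs"),
    ("TP-ASD", "TDs"),
    ("LP-ASD", "TP-ASD"),
)
#: typicality is only defined against a typically-developing reference
TYPICALITY_CONTRASTS = (("ASD", "TD"), ("LP-ASD", "TDs"), ("TP-ASD", "TDs"))
STATES = ("rest", "task", "reconfiguration")
MEASURES = ("accuracy", "rt", "brief_gec", "celf_wc")


@dataclass
class RunConfig:
    """Everything one analysis run needs; every default is echoed into the summary."""

    manifest: str
    phenotypes: str
    mode: str = "matrix"  # "matrix" (FC tables on disk) | "timeseries"
    filter_enabled: bool = False
    rest_band: tuple = (0.008, 0.08)  # Hz
    task_highpass: float = 0.01  # Hz
    filter_order: int = 4
    tr: float = 1.25  # seconds; used when filtering time series
    subgroup_threshold: float = 0.90
    fdr_q: float = 0.05
    permutation_B: int = 10_000
    seed: int = 0
    covariates: tuple = ("age", "motion")
    motion_summary: str = "mean"  # "mean" | "rest" | "task"
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("manifest", "phenotypes"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        if self.mode not in ("matrix", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.permutation_B < 99:
            raise ValueError("permutation_B must be >= 99")
        if self.motion_summary not in ("mean", "rest", "task"):
            raise ValueError(f"unknown motion_summary {self.motion_summary!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("rest_band", "covariates"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _load_edges(config: RunConfig):
    """Stage 'fc': read scans, estimate FC, average runs, reconfigure."""
    manifest = cohort_io.read_manifest(config.manifest)
    records = cohort_io.read_phenotypes(config.phenotypes)
    by_id = {r.subject_id: r for r in records}
    missing = [s for s in manifest.subjects() if s not in by_id]
    if missing:
        raise ValueError(f"subjects missing from phenotype table: {missing}")

    roi_labels = None
    tables = {"rest": [], "task": [], "reconfiguration": []}
    subject_order = []
    for sid in manifest.subjects():
        files = manifest.files_for(sid)
        per_state = {}
        for state, path in files.items():
            if config.mode == "matrix":
                values, labels = cohort_io.read_fc_matrix(path)
                fcm = connectivity.FCMatrix(
                    values=values, subject_id=sid, state=state, roi_labels=labels
                )
            else:
                data, labels = cohort_io.read_timeseries(path)
                if config.filter_enabled:
                    if state == "rest":
                        data = connectivity.bandpass_filter(
                            data, *config.rest_band, tr=config.tr, order=config.filter_order
                        )
                    else:
                        data = connectivity.highpass_filter(
                            data, config.task_highpass, tr=config.tr, order=config.filter_order
                        )
                fcm = connectivity.fc_from_timeseries(
                    data, subject_id=sid, state=state, roi_labels=labels
                )
            per_state[state] = fcm
            if roi_labels is None:
                roi_labels = fcm.roi_labels
            elif fcm.roi_labels != roi_labels:
                raise ValueError(f"{sid}/{state}: ROI labels differ across the cohort")
        task = connectivity.average_fc(
            [per_state[s] for s in ("task_run1", "task_run2") if s in per_state]
        )
        recon = connectivity.reconfiguration(per_state["rest"], task)
        tables["rest"].append(connectivity.vectorize_upper(per_state["rest"]))
        tables["task"].append(connectivity.vectorize_upper(task))
        tables["reconfiguration"].append(recon.values)
        subject_order.append(sid)

    edges = {k: np.vstack(v) for k, v in tables.items()}
    logger.info(
        "fc: %d subjects, %d ROIs, %d edges",
        len(subject_order),
        len(roi_labels),
        edges["rest"].shape[1],
    )
    return manifest, records, subject_order, edges, roi_labels


def _sample_masks(records, subject_order):
    """Boolean row masks for the two groups and three performance subgroups."""
    by_id = {r.subject_id: r for r in records}
    group = np.array([by_id[s].group for s in subject_order])
    subgroup = np.array([by_id[s].subgroup for s in subject_order])
    return {
        "ASD": group == "ASD",
        "TD": group == "TD",
        "TDs": subgroup == "TDs",
        "TP-ASD": subgroup == "TP-ASD",
        "LP-ASD": subgroup == "LP-ASD",
    }


def _labels_for_contrast(masks, a, b):
    keep = masks[a] | masks[b]
    labels = np.where(masks[a], a, b)
    return keep, labels


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, stages=("fc", "group", "heterogeneity", "behavior")) -> dict:
    """Execute the pipeline and return (and optionally write) the run summary.

    The summary carries the config echo, per-stage shapes, every statistic
    and p-value of every output table, and all derived seeds — enough to
    re-derive each result table without rereading intermediate files.
    """
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    summary: dict = {
        "package": _package_version(),
        "config": _jsonable(asdict(config)),
        "stages": list(stages),
        "warnings": [],
        "tables": {},
    }
    caught: list[str] = []

    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            result = _run_stages(config, stages, summary, out_dir)
            caught = [str(w.message) for w in wlist]
    finally:
        if out_dir:
            logger.removeHandler(fh)
            fh.close()
    summary["warnings"] = caught
    for msg in caught:
        logger.warning(msg)
    summary.update(result)
    if out_dir:
        with open(out_dir / "run_summary.json", "w") as fp:
            json.dump(_jsonable(summary), fp, sort_keys=True, indent=1)
    return summary


def _run_stages(config, stages, summary, out_dir):
    out: dict = {}

    try:
        manifest, records, subject_order, edges, roi_labels = _load_edges(config)
    except Exception as exc:
        raise PipelineStageError("fc", str(exc)) from exc
    edge_labels = connectivity.edge_pair_labels(roi_labels)
    out["n_subjects"] = len(subject_order)
    out["n_edges"] = int(edges["rest"].shape[1])
    out["states"] = list(STATES)
    if "fc" in stages and out_dir:
        for state, table in edges.items():
            df = pd.DataFrame(table, index=subject_order, columns=edge_labels)
            df.rename_axis("subject_id").to_csv(out_dir / f"edges_{state}.csv")
    if set(stages) == {"fc"}:
        return out

    try:
        assignment = group_stats.assign_subgroups(records, config.subgroup_threshold)
        masks = _sample_masks(records, subject_order)
        out["subgroup_counts"] = {
            k: int(v.sum()) for k, v in masks.items()
        }
        edge_tests = []
        for state in STATES:
            table = group_stats.edge_ttest(
                edges[state][masks["ASD"]],
                edges[state][masks["TD"]],
                q=config.fdr_q,
                edge_labels=edge_labels,
            )
            table.insert(0, "state", state)
            edge_tests.append(table)
        edge_tests = pd.concat(edge_tests, ignore_index=True)

        dist_rows = []
        means = {
            name: {state: group_stats.group_edge_means(edges[state][mask]) for state in STATES}
            for name, mask in masks.items()
            if mask.sum() >= 1
        }
        for state in STATES:
            for a, b in CONTRASTS:
                cmp_ = group_stats.compare_distributions(means[a][state], means[b][state])
                dist_rows.append(
                    {
                        "state": state,
                        "contrast": f"{a} vs {b}",
                        "median_a": float(np.median(means[a][state])),
                        "spread_a": float(np.std(means[a][state], ddof=1)),
                        "median_b": float(np.median(means[b][state])),
                        "spread_b": float(np.std(means[b][state], ddof=1)),
                        "ranksum_z": cmp_.ranksum_z,
                        "ranksum_p": cmp_.ranksum_p,
                        "ks_D": cmp_.ks_D,
                        "ks_p": cmp_.ks_p,
                    }
                )
        dist_tests = pd.DataFrame(dist_rows)
        for col in ("ranksum", "ks"):
            adj, rej = group_stats.bh_fdr(dist_tests[f"{col}_p"], q=config.fdr_q)
            dist_tests[f"{col}_p_adj"] = adj
            dist_tests[f"{col}_reject"] = rej
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("group", str(exc)) from exc

    out["n_contrasts"] = len(CONTRASTS)
    summary["tables"]["edge_tests"] = {
        "n_rows": len(edge_tests),
        "n_reject": int(edge_tests["reject"].sum()),
    }
    summary["tables"]["distribution_tests"] = dist_tests.to_dict(orient="records")
    if out_dir and "group" in stages:
        edge_tests.to_csv(out_dir / "edge_tests.csv", index=False)
        dist_tests.to_csv(out_dir / "distribution_tests.csv", index=False)
        assignment.to_csv(out_dir / "subgroups.csv", index=False)

    if "heterogeneity" in stages:
        try:
            out.update(
                _heterogeneity_stage(
                    config, edges, masks, subject_order, summary, out_dir
                )
            )
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("heterogeneity", str(exc)) from exc

    if "behavior" in stages:
        try:
            out.update(
                _behavior_stage(
                    config, edges, masks, records, subject_order, edge_labels, summary, out_dir
                )
            )
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("behavior", str(exc)) from exc
    return out


def _heterogeneity_stage(config, edges, masks, subject_order, summary, out_dir):
    S = {state: heterogeneity.intersubject_correlation(edges[state]) for state in STATES}
    group_labels = np.where(masks["ASD"], "ASD", "TD")

    sim_rows = []
    typ_rows = []
    for state in STATES:
        sim = heterogeneity.similarity_scores(S[state], group_labels)
        typ = heterogeneity.typicality_scores(S[state], group_labels, "TD")
        for i, sid in enumerate(subject_order):
            sim_rows.append(
                {"subject_id": sid, "state": state, "group": group_labels[i],
                 "similarity": float(sim[i])}
            )
            typ_rows.append(
                {"subject_id": sid, "state": state, "group": group_labels[i],
                 "typicality": float(typ[i])}
            )
    sim_df = pd.DataFrame(sim_rows)
    typ_df = pd.DataFrame(typ_rows)

    perm_rows = []
    for mi, (metric, contrasts) in enumerate(
        (("similarity", CONTRASTS), ("typicality", TYPICALITY_CONTRASTS))
    ):
        for si, state in enumerate(STATES):
            for ci, (a, b) in enumerate(contrasts):
                keep, labels = _labels_for_contrast(masks, a, b)
                res = heterogeneity.permutation_group_test(
                    S[state][np.ix_(keep, keep)],
                    labels[keep],
                    metric=metric,
                    B=config.permutation_B,
                    seed=np.random.SeedSequence(
                        config.seed, spawn_key=(mi, si, ci)
                    ),
                    groups=(a, b),
                )
                perm_rows.append(
                    {
                        "metric": metric,
                        "state": state,
                        "contrast": f"{a} vs {b}",
                        "cohens_d": res.observed_d,
                        "p": res.p,
                        "B": res.B,
                        "method": res.method,
                        "seed": config.seed,
                    }
                )
    perm_df = pd.DataFrame(perm_rows)
    adj = np.full(len(perm_df), np.nan)
    rej = np.zeros(len(perm_df), dtype=bool)
    for metric in ("similarity", "typicality"):  # table-level FDR families
        m = perm_df["metric"] == metric
        adj[m], rej[m] = group_stats.bh_fdr(perm_df.loc[m, "p"], q=config.fdr_q)
    perm_df["p_adj"] = adj
    perm_df["reject"] = rej

    summary["tables"]["permutation_tests"] = perm_df.to_dict(orient="records")
    gm = sim_df.groupby(["state", "group"])["similarity"].mean().round(6)
    summary["tables"]["similarity_group_means"] = {
        f"{state}/{group}": v for (state, group), v in gm.items()
    }
    if out_dir:
        sim_df.to_csv(out_dir / "similarity.csv", index=False)
        typ_df.to_csv(out_dir / "typicality.csv", index=False)
        perm_df.to_csv(out_dir / "permutation_tests.csv", index=False)
    return {"n_permutation_tests": len(perm_df)}


def _behavior_values(records, subject_order, measure):
    by_id = {r.subject_id: r for r in records}
    vals = []
    for sid in subject_order:
        r = by_id[sid]
        if measure == "accuracy":
            vals.append((r.acc_sw + r.acc_aw) / 2.0)
        elif measure == "rt":
            vals.append((r.rt_sw + r.rt_aw) / 2.0)
        else:
            vals.append(getattr(r, measure))
    return np.asarray(vals, dtype=float)


def _covariate_table(config, records, subject_order):
    by_id = {r.subject_id: r for r in records}
    cols = []
    for name in config.covariates:
        if name == "age":
            cols.append([by_id[s].age for s in subject_order])
        elif name == "motion":
            if config.motion_summary == "rest":
                cols.append([by_id[s].rmsd_rest for s in subject_order])
            elif config.motion_summary == "task":
                cols.append([by_id[s].rmsd_task for s in subject_order])
            else:
                cols.append(
                    [(by_id[s].rmsd_rest + by_id[s].rmsd_task) / 2.0 for s in subject_order]
                )
        else:
            raise ValueError(f"unknown covariate {name!r}")
    if not cols:
        return None
    return np.column_stack(cols)


def _behavior_stage(config, edges, masks, records, subject_order, edge_labels, summary, out_dir):
    recon = edges["reconfiguration"]
    cov = _covariate_table(config, records, subject_order)
    coeff_rows = []
    coeffs = {}
    for name, mask in masks.items():
        if mask.sum() < (0 if cov is None else cov.shape[1]) + 4:
            continue
        for measure in MEASURES:
            vals = _behavior_values(records, subject_order, measure)
            r, n_used = brain_behavior.edgewise_behavior_correlations(
                recon[mask], vals[mask], None if cov is None else cov[mask]
            )
            coeffs[(name, measure)] = r
            finite = r[np.isfinite(r)]
            coeff_rows.append(
                {
                    "sample": name,
                    "measure": measure,
                    "n_used": n_used,
                    "median_r": float(np.median(finite)),
                    "spread_r": float(np.std(finite, ddof=1)),
                }
            )
    coeff_summary = pd.DataFrame(coeff_rows)

    long_rows = []
    for (name, measure), r in coeffs.items():
        for e, val in enumerate(r):
            long_rows.append(
                {"sample": name, "measure": measure, "edge": e,
                 "edge_label": edge_labels[e], "r": float(val)}
            )
    coeff_long = pd.DataFrame(long_rows)

    dist_rows = []
    for measure in MEASURES:
        for a, b in CONTRASTS:
            if (a, measure) not in coeffs or (b, measure) not in coeffs:
                continue
            cmp_ = brain_behavior.compare_correlation_distributions(
                coeffs[(a, measure)], coeffs[(b, measure)]
            )
            dist_rows.append(
                {
                    "measure": measure,
                    "contrast": f"{a} vs {b}",
                    "ranksum_z": cmp_.ranksum_z,
                    "ranksum_p": cmp_.ranksum_p,
                    "ks_D": cmp_.ks_D,
                    "ks_p": cmp_.ks_p,
                }
            )
    dist_df = pd.DataFrame(dist_rows)
    if len(dist_df):
        adj, rej = group_stats.bh_fdr(dist_df["ranksum_p"], q=config.fdr_q)
        dist_df["ranksum_p_adj"] = adj
        dist_df["ranksum_reject"] = rej

    summary["tables"]["behavior_correlation_summary"] = coeff_summary.to_dict(
        orient="records"
    )
    summary["tables"]["behavior_distribution_tests"] = dist_df.to_dict(orient="records")
    if out_dir:
        coeff_long.to_csv(out_dir / "behavior_correlations.csv", index=False)
        coeff_summary.to_csv(out_dir / "behavior_correlation_summary.csv", index=False)
        dist_df.to_csv(out_dir / "behavior_distribution_tests.csv", index=False)
    return {"n_behavior_measures": len(MEASURES)}


def _package_version() -> str:
    try:
        return version("fcreconf")
    except PackageNotFoundError:
        return "unknown"


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
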