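"""End-to-end pipeline orchestration.

Stages: cohort -> feature table -> multi-view clustering -> LOOCV consensus
-> survival statistics -> metabolite comparison.  Every run writes its
resolved configuration next to the artifacts, and identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, features, mrs, survival, synthetic, validation

logger = logging.getLogger(__name__)

RESECTION_CODES = {"complete": 0, "partial": 1, "biopsy": 2}
BASELINE_COVARIATES = [
    "age_ge_60",
    "sex_male",
    "resection_code",
    "mgmt_methylated",
    "idh1_mutant",
    "ce_volume",
]


@dataclass
class PipelineConfig:
    """Single-JSON configuration of a full run."""

    input_dir: str | None = None  # cohort on disk; None -> synthetic
    out_dir: str = "mvhist_out"
    seed: int = 0
    n_bins: int = 100
    feature_k_range: tuple[int, int] = (2, 10)
    patient_k_range: tuple[int, int] = (2, 10)
    final_k: int = 2
    integration: str = "ward"
    cutpoint_min_prop: float = 0.1
    n_boot: int = 2000
    mrs_occupancy_threshold: float = 0.5
    mrs_sd_threshold: float = 20.0
    mrs_summary: str = "median"
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key in ("feature_k_range", "patient_k_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cohort = d.get("cohort") or {}
        for key, val in cohort.items():
            if isinstance(val, list):
                cohort[key] = tuple(val)
        return cls(**d)

    def mvda_config(self) -> clustering.MVDAConfig:
        return clustering.MVDAConfig(
            feature_k_candidates=range(self.feature_k_range[0], self.feature_k_range[1] + 1),
            patient_k_candidates=range(self.patient_k_range[0], self.patient_k_range[1] + 1),
            final_k=self.final_k,
            integration=self.integration,
        )

    def cohort_config(self) -> synthetic.CohortConfig:
        return synthetic.CohortConfig(seed=self.seed, **self.cohort)


def _stage(name: str):
    logger.info("stage: %s", name)


def load_cohort(config: PipelineConfig) -> synthetic.SyntheticCohort:
    if config.input_dir is None:
        return synthetic.generate_cohort(config.cohort_config())
    indir = Path(config.input_dir)
    if not (indir / "manifest.json").exists():
        raise FileNotFoundError(f"no cohort manifest at {indir / 'manifest.json'}")
    return synthetic.read_cohort(indir)


def compute_features(
    cohort: synthetic.SyntheticCohort, config: PipelineConfig
) -> features.FeatureTable:
    return features.build_feature_table(
        cohort.feature_inputs(), n_bins=config.n_bins, on_error="raise"
    )


def view_frames(table: features.FeatureTable) -> dict[str, pd.DataFrame]:
    return {v: table.view_matrix(v) for v in features.VIEW_NAMES}


def _survival_frame(cohort: synthetic.SyntheticCohort) -> pd.DataFrame:
    df = cohort.covariate_table().copy()
    df["resection_code"] = df["resection"].map(RESECTION_CODES)
    return df


def survival_stage(
    cohort: synthetic.SyntheticCohort,
    table: features.FeatureTable,
    result: clustering.MVDAResult,
    config: PipelineConfig,
) -> dict:
    """Feature ranking, cluster/feature survival models, and 12-month ROC."""
    df = _survival_frame(cohort)
    labels = result.final_labels
    centroid_cols = result.centroid_features()
    ranked = survival.rank_features(table.data[centroid_cols], labels)
    selected = [r.name for r in ranked if r.selected]

    out: dict = {
        "ranked_features": [dataclasses.asdict(r) for r in ranked],
        "selected_features": selected,
        "cluster_sizes": {int(c): int(n) for c, n in
                          zip(*np.unique(labels, return_counts=True))},
    }

    df = df.assign(cluster2=(labels == 2).astype(int))
    for endpoint in ("os", "pfs"):
        t = df[f"{endpoint}_days"].to_numpy()
        e = df[f"{endpoint}_event"].to_numpy().astype(bool)
        stat, p = survival.log_rank_test(labels, t, e)
        km = survival.kaplan_meier(t, e, labels)
        cox_df = df[BASELINE_COVARIATES + ["cluster2", f"{endpoint}_days", f"{endpoint}_event"]]
        cox = survival.cox_ph_fit(cox_df, f"{endpoint}_days", f"{endpoint}_event")
        out[endpoint] = {
            "logrank_statistic": stat,
            "logrank_p": p,
            "km_median": {str(g): km[g]["median"] for g in km},
            "cox_cluster2_hr": cox.hr("cluster2"),
            "cox_cluster2_p": cox.p("cluster2"),
            "cox_summary": cox.summary.to_dict(orient="index"),
        }
        # per selected feature: optimal cutpoint + log-rank + adjusted Cox
        per_feature = {}
        for name in selected:
            vals = table.data[name].to_numpy()
            try:
                cut = survival.optimal_cutpoint(
                    vals, t, e, min_prop=config.cutpoint_min_prop
                )
                _, p_feat = survival.log_rank_test(cut.groups, t, e)
            except ValueError as exc:
                per_feature[name] = {"error": str(exc)}
                continue
            fdf = df[BASELINE_COVARIATES + [f"{endpoint}_days", f"{endpoint}_event"]].copy()
            fdf[name] = (vals - vals.mean()) / vals.std(ddof=0)
            fcox = survival.cox_ph_fit(fdf, f"{endpoint}_days", f"{endpoint}_event")
            per_feature[name] = {
                "cutoff": cut.cutoff,
                "logrank_p": p_feat,
                "cox_hr": fcox.hr(name),
                "cox_p": fcox.p(name),
            }
        out[endpoint]["features"] = per_feature
        # 12-month incremental ROC comparison
        outcome, n_excluded = survival.twelve_month_outcome(t, e)
        try:
            auc = survival.incremental_auc(
                df[BASELINE_COVARIATES],
                table.data[selected] if selected else table.data[centroid_cols],
                outcome,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            out[endpoint]["auc"] = dataclasses.asdict(auc)
        except ValueError as exc:
            out[endpoint]["auc"] = {"error": str(exc)}
        out[endpoint]["n_excluded_12mo"] = n_excluded
    return out


def mrs_stage(
    cohort: synthetic.SyntheticCohort,
    final_labels: np.ndarray,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-patient metabolite summaries over retained NE voxels, compared
    between final clusters."""
    rows = {}
    for p in cohort.patients:
        fractions = mrs.tumor_fraction_per_csi_voxel(p.masks.ne, p.csi)
        included = mrs.filter_csi_voxels(
            p.csi,
            fractions,
            occupancy_threshold=config.mrs_occupancy_threshold,
            sd_threshold=config.mrs_sd_threshold,
        )
        summary = mrs.summarize_patient(p.csi, included, how=config.mrs_summary)
        rows[p.patient_id] = {f"{k}-NE": v for k, v in summary.items()}
    summaries = pd.DataFrame.from_dict(rows, orient="index")
    return mrs.compare_metabolites(summaries, final_labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifacts; returns them in memory too."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())

    _stage("cohort")
    cohort = load_cohort(config)

    _stage("features")
    table = compute_features(cohort, config)
    table.data.to_csv(outdir / "features.csv")

    _stage("clustering")
    frames = view_frames(table)
    result = clustering.run_mvda(frames, config.mvda_config())
    labels = result.final_labels
    pd.DataFrame(
        {"patient_id": table.patient_ids, "final_cluster": labels}
    ).set_index("patient_id").to_csv(outdir / "final_labels.csv")
    (outdir / "centroids.json").write_text(
        json.dumps(
            {
                v: {
                    "centroids": cs.centroids,
                    "memberships": cs.memberships,
                    "patient_k": result.clustering.per_view_k[v],
                }
                for v, cs in result.centroid_sets.items()
            },
            indent=2,
            sort_keys=True,
        )
    )

    _stage("loocv")
    partitions = validation.loocv_clusterings(frames, config.mvda_config())
    consensus = validation.consensus_matrix(partitions, table.patient_ids)
    consensus.to_frame().to_csv(outdir / "consensus.csv")
    consensus_means = validation.cluster_consensus_means(consensus, labels)

    _stage("survival")
    surv = survival_stage(cohort, table, result, config)
    ranked = pd.DataFrame(surv["ranked_features"]).set_index("name")
    ranked.to_csv(outdir / "ranked_features.csv")
    surv["consensus_means"] = {str(k): v for k, v in consensus_means.items()}
    (outdir / "survival.json").write_text(json.dumps(surv, indent=2, sort_keys=True, default=float))

    _stage("mrs")
    mrs_table = mrs_stage(cohort, labels, config)
    mrs_table.to_csv(outdir / "mrs.csv")

    logger.info("pipeline complete: %s", outdir)
    return {
        "cohort": cohort,
        "feature_table": table,
        "mvda": result,
        "partitions": partitions,
        "consensus": consensus,
        "consensus_means": consensus_means,
        "survival": surv,
        "mrs": mrs_table,
        "out_dir": outdir,
    }
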