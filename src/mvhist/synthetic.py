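"""Synthetic cohort generator.

Builds cohorts with the statistical structure the downstream analysis
assumes: five co-registered parametric maps per patient, CE/FLAIR/NAWM
masks, a coarse CSI metabolite grid, clinical covariates, and censored
OS/PFS times generated under a proportional-hazards model with a
cluster-dependent hazard ratio.

Voxel intensities are log-normal (positive, right-skewed).  Each patient
carries a latent cluster label; the cluster shifts the patient-level
log-mean of every modality by ``effect_size * patient_sd / 2`` (sign by
cluster), with effect sizes configured per view and concentrated in the
non-enhancing views by default.  NAWM intensities are cluster-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import MODALITIES, ParametricMapSet, ROIMaskSet, view_of
from .mrs import CSIGrid, METABOLITES
from .survival import SurvivalRecord


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


DEFAULT_EFFECT_SIZES = {
    "CE-diffusion": 0.5,
    "NE-diffusion": 5.0,
    "CE-perfusion": 0.5,
    "NE-perfusion": 5.0,
}

# Marginal covariate frequencies of the emulated 80-patient cohort.
COVARIATE_MARGINALS = {
    "age_ge_60": 45 / 80,
    "sex_male": 58 / 80,
    "resection": {"complete": 56 / 80, "partial": 22 / 80, "biopsy": 2 / 80},
    "mgmt_methylated": 37 / 78,
    "idh1_mutant": 7 / 80,
}

# Arbitrary positive units per modality before NAWM normalization.
_NAWM_BASELINE = {"p": 1.0, "q": 1.2, "rCBV": 100.0, "MTT": 5.0, "rCBF": 50.0}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 80
    cluster_proportions: tuple[float, float] = (53 / 80, 27 / 80)
    map_names: tuple[str, ...] = MODALITIES
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    hr_cluster2_os: float = 0.32
    hr_cluster2_pfs: float = 0.33
    censoring_rate: float = 0.2
    seed: int = 0
    # intensity model
    patient_sd: float = 0.15  # sd of the patient-level log-mean
    voxel_sigma: float = 0.25  # within-patient log-scale voxel spread
    tumor_contrast: float = 0.35  # log-mean elevation of tumor over NAWM
    ne_volume_factor: float = 1.5  # FLAIR linear enlargement for cluster 2
    # survival model (exponential baselines, cluster-1 medians in days)
    baseline_median_os: float = 424.0
    baseline_median_pfs: float = 248.0
    # CSI model
    csi_shape: tuple[int, int] = (8, 8)
    csi_naa_shift: float = 0.3  # log-scale NAA/Cr drop in cluster 2 NE voxels
    csi_sd_range: tuple[float, float] = (5.0, 35.0)  # quality SD percent

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.shape != (2,) or (props < 0).any() or abs(props.sum() - 1) > 1e-9:
            raise ConfigurationError("cluster_proportions must be two non-negative values summing to 1")
        if len(self.grid_shape) != 3 or any(int(d) <= 0 for d in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(d < 8 for d in self.grid_shape[:2]) or self.grid_shape[2] < 4:
            raise ConfigurationError("grid too small to place CE/FLAIR/NAWM regions")
        if not all(np.isfinite(list(self.effect_sizes.values()))):
            raise ConfigurationError("effect sizes must be finite")
        if self.hr_cluster2_os <= 0 or self.hr_cluster2_pfs <= 0:
            raise ConfigurationError("hazard ratios must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")


@dataclass
class PatientBundle:
    """Everything generated for one synthetic patient."""

    patient_id: str
    maps: ParametricMapSet
    masks: ROIMaskSet
    csi: CSIGrid
    covariates: dict
    survival: SurvivalRecord
    true_cluster: int


@dataclass
class SyntheticCohort:
    patients: list[PatientBundle]
    config: CohortConfig

    @property
    def true_clusters(self) -> np.ndarray:
        return np.array([p.true_cluster for p in self.patients])

    def covariate_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "true_cluster": p.true_cluster}
            row.update(p.covariates)
            row.update(
                os_days=p.survival.os_days,
                os_event=int(p.survival.os_event),
                pfs_days=p.survival.pfs_days,
                pfs_event=int(p.survival.pfs_event),
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("patient_id")

    def feature_inputs(self):
        """Yield (patient_id, maps, masks) for the feature stage."""
        for p in self.patients:
            yield p.patient_id, p.maps, p.masks


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # per-patient child streams are keyed by (seed, index) so cohorts are
    # stable when n_patients changes
    return np.random.default_rng(np.random.SeedSequence((seed, 7919, index)))


def _cluster_sizes(n: int, proportions: Sequence[float]) -> tuple[int, int]:
    n1 = int(round(n * float(proportions[0])))
    n1 = min(max(n1, 1), n - 1)
    return n1, n - n1


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_masks(
    rng: np.random.Generator, config: CohortConfig, true_cluster: int
) -> ROIMaskSet:
    """Geometric CE/FLAIR/NAWM masks with CE strictly inside FLAIR.

    Cluster 2 gets a linearly enlarged FLAIR (larger non-enhancing volume);
    NAWM sits in the contralateral half, disjoint from FLAIR by construction.
    """
    nx, ny, nz = config.grid_shape
    center = np.array([0.28 * nx, 0.5 * ny, 0.5 * nz]) + rng.uniform(-0.5, 0.5, 3)
    base = np.array([0.16 * nx, 0.28 * ny, 0.30 * nz]) * rng.uniform(0.9, 1.1)
    scale = config.ne_volume_factor ** (1 / 3) if true_cluster == 2 else 1.0
    flair_r = np.minimum(base * scale, [0.24 * nx, 0.42 * ny, 0.45 * nz])
    flair = _ellipsoid((nx, ny, nz), center, flair_r)
    ce = _ellipsoid((nx, ny, nz), center, flair_r * 0.55)
    ce &= flair
    nawm = np.zeros((nx, ny, nz), dtype=bool)
    nawm[
        int(0.70 * nx) : int(0.92 * nx),
        int(0.30 * ny) : int(0.70 * ny),
        int(0.30 * nz) : int(0.70 * nz),
    ] = True
    nawm &= ~flair
    masks = ROIMaskSet(ce=ce, flair=flair, nawm=nawm)
    ne = masks.ne
    if ce.sum() < 2 or ne.sum() < 2 or nawm.sum() < 2:
        raise ConfigurationError(
            f"degenerate masks on grid {config.grid_shape}: "
            f"|CE|={int(ce.sum())}, |NE|={int(ne.sum())}, |NAWM|={int(nawm.sum())}"
        )
    return masks


def generate_maps(
    rng: np.random.Generator,
    config: CohortConfig,
    masks: ROIMaskSet,
    true_cluster: int,
) -> ParametricMapSet:
    """Five log-normal voxel maps with cluster-conditional tumor means."""
    shape = masks.shape
    sign = +0.5 if true_cluster == 1 else -0.5
    maps = {}
    ne = masks.ne
    for m in config.map_names:
        mu_nawm = np.log(_NAWM_BASELINE[m])
        vol = rng.lognormal(mu_nawm - 0.3, config.voxel_sigma, size=shape)
        vol[masks.nawm] = rng.lognormal(
            mu_nawm, config.voxel_sigma, size=int(masks.nawm.sum())
        )
        for region, mask in (("CE", masks.ce), ("NE", ne)):
            eff = float(config.effect_sizes.get(view_of(m, region), 0.0))
            # patient-level log-mean: cluster shift of eff*patient_sd plus noise
            b = rng.normal(sign * eff * config.patient_sd, config.patient_sd)
            mu = mu_nawm + config.tumor_contrast + b
            vol[mask] = rng.lognormal(mu, config.voxel_sigma, size=int(mask.sum()))
        maps[m] = vol
    return ParametricMapSet(maps)


def generate_survival(
    true_cluster: int,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> SurvivalRecord:
    """Censored OS/PFS times under exponential proportional hazards.

    The cluster-1 hazard matches the configured baseline medians; cluster 2's
    hazard is multiplied by the configured hazard ratio.  Censoring is an
    independent exponential race tuned so the expected censoring probability
    equals ``censoring_rate``.
    """
    if true_cluster not in (1, 2):
        raise ValueError(f"true_cluster must be 1 or 2, got {true_cluster}")
    if config.hr_cluster2_os <= 0 or config.hr_cluster2_pfs <= 0:
        raise ConfigurationError("hazard ratios must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = {}
    for endpoint, median, hr in (
        ("os", config.baseline_median_os, config.hr_cluster2_os),
        ("pfs", config.baseline_median_pfs, config.hr_cluster2_pfs),
    ):
        rate = np.log(2) / median * (hr if true_cluster == 2 else 1.0)
        t_event = rng.exponential(1.0 / rate)
        if config.censoring_rate > 0:
            c_rate = rate * config.censoring_rate / (1 - config.censoring_rate)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = np.inf
        out[f"{endpoint}_days"] = float(max(min(t_event, t_cens), 1e-6))
        out[f"{endpoint}_event"] = bool(t_event <= t_cens)
    return SurvivalRecord(**out)


def generate_covariates(rng: np.random.Generator, masks: ROIMaskSet) -> dict:
    """Clinical covariates from the emulated marginal frequencies.

    Categorical covariates are independent of the cluster label; the volumes
    are read off the generated masks (so the NE-volume difference follows
    from the FLAIR enlargement).
    """
    m = COVARIATE_MARGINALS
    res_cats = list(m["resection"])
    res_probs = np.array(list(m["resection"].values()))
    return {
        "age_ge_60": int(rng.random() < m["age_ge_60"]),
        "sex_male": int(rng.random() < m["sex_male"]),
        "resection": res_cats[rng.choice(len(res_cats), p=res_probs / res_probs.sum())],
        "mgmt_methylated": int(rng.random() < m["mgmt_methylated"]),
        "idh1_mutant": int(rng.random() < m["idh1_mutant"]),
        "ce_volume": int(masks.ce.sum()),
        "ne_volume": int(masks.ne.sum()),
    }


def csi_footprints(grid_shape: tuple[int, int, int], n_rows: int = 8, n_cols: int = 8) -> np.ndarray:
    """Partition the central axial slab into an n_rows × n_cols footprint map."""
    nx, ny, nz = grid_shape
    labels = np.full(grid_shape, -1, dtype=int)
    z0, z1 = nz // 3, max(nz // 3 + 1, 2 * nz // 3)
    x_edges = np.linspace(0, nx, n_rows + 1).astype(int)
    y_edges = np.linspace(0, ny, n_cols + 1).astype(int)
    for r in range(n_rows):
        for c in range(n_cols):
            labels[x_edges[r] : x_edges[r + 1], y_edges[c] : y_edges[c + 1], z0:z1] = (
                r * n_cols + c
            )
    return labels


def generate_csi_grid(
    masks: ROIMaskSet,
    true_cluster: int,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> CSIGrid:
    """Metabolite-ratio grid with a cluster shift in NE-dominant voxels.

    NAA/Cr is lowered (by ``csi_naa_shift`` on the log scale) in cluster-2
    voxels whose footprint is more than half non-enhancing tumor; quality SDs
    are uniform over ``csi_sd_range`` so a realistic share of voxels fails
    the downstream SD filter.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_rows, n_cols = config.csi_shape
    labels = csi_footprints(masks.shape, n_rows, n_cols)
    # NE occupancy per CSI voxel, used to place the cluster-conditional shift
    inside = labels >= 0
    totals = np.bincount(labels[inside], minlength=n_rows * n_cols)
    ne_counts = np.bincount(labels[inside & masks.ne], minlength=n_rows * n_cols)
    ne_frac = np.divide(
        ne_counts, totals, out=np.zeros_like(ne_counts, dtype=float), where=totals > 0
    ).reshape(n_rows, n_cols)
    shift = np.where(
        (ne_frac > 0.5) & (true_cluster == 2), -config.csi_naa_shift, 0.0
    )
    ratios = {
        "NAA/Cr": rng.lognormal(np.log(1.2) + shift, 0.2, size=(n_rows, n_cols)),
        "Cho/Cr": rng.lognormal(np.log(0.8), 0.2, size=(n_rows, n_cols)),
    }
    lo, hi = config.csi_sd_range
    quality = {
        met: rng.uniform(lo, hi, size=(n_rows, n_cols)) for met in METABOLITES
    }
    return CSIGrid(
        ratios=ratios,
        quality_sd=quality,
        footprint_labels=labels,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config = config if config is not None else CohortConfig()
    config.validate()
    n = config.n_patients
    n1, _ = _cluster_sizes(n, config.cluster_proportions)
    labels = np.array([1] * n1 + [2] * (n - n1))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 104729)))
    shuffle_rng.shuffle(labels)
    patients = []
    for i in range(n):
        rng = _patient_rng(config.seed, i)
        cluster = int(labels[i])
        masks = generate_masks(rng, config, cluster)
        maps = generate_maps(rng, config, masks, cluster)
        covariates = generate_covariates(rng, masks)
        survival = generate_survival(cluster, config, rng=rng)
        survival.covariates = dict(covariates)
        csi = generate_csi_grid(masks, cluster, config, rng=rng)
        patients.append(
            PatientBundle(
                patient_id=f"P{i:03d}",
                maps=maps,
                masks=masks,
                csi=csi,
                covariates=covariates,
                survival=survival,
                true_cluster=cluster,
            )
        )
    return SyntheticCohort(patients=patients, config=config)


# ---------------------------------------------------------------------------
# disk round-trip (NIfTI volumes + cohort CSV + JSON manifest)

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: per-patient NIfTI files, covariate CSV, manifest."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    manifest = {"config": _config_to_json(cohort.config), "patients": {}}
    for p in cohort.patients:
        pdir = outdir / p.patient_id
        pdir.mkdir(exist_ok=True)
        entry = {"maps": {}, "masks": {}, "csi": str(Path(p.patient_id) / "csi.json")}
        for m, vol in p.maps.maps.items():
            fn = pdir / f"map_{m}.nii"
            nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), fn)
            entry["maps"][m] = str(Path(p.patient_id) / fn.name)
        for name, mask in (("ce", p.masks.ce), ("flair", p.masks.flair), ("nawm", p.masks.nawm)):
            fn = pdir / f"mask_{name}.nii"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), fn)
            entry["masks"][name] = str(Path(p.patient_id) / fn.name)
        with open(pdir / "csi.json", "w") as fh:
            json.dump(
                {
                    "ratios": {k: v.tolist() for k, v in p.csi.ratios.items()},
                    "quality_sd": {k: v.tolist() for k, v in p.csi.quality_sd.items()},
                    "footprint_labels": p.csi.footprint_labels.tolist(),
                    "n_rows": p.csi.n_rows,
                    "n_cols": p.csi.n_cols,
                },
                fh,
            )
        manifest["patients"][p.patient_id] = entry
    cohort.covariate_table().to_csv(outdir / "cohort.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def read_cohort(indir: str | Path) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    import nibabel as nib

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    config = _config_from_json(manifest["config"])
    table = pd.read_csv(indir / "cohort.csv", index_col="patient_id")
    patients = []
    for pid, entry in sorted(manifest["patients"].items()):
        maps = ParametricMapSet(
            {m: np.asarray(nib.load(indir / rel).dataobj, dtype=float)
             for m, rel in entry["maps"].items()}
        )
        masks = ROIMaskSet(
            ce=np.asarray(nib.load(indir / entry["masks"]["ce"]).dataobj) > 0,
            flair=np.asarray(nib.load(indir / entry["masks"]["flair"]).dataobj) > 0,
            nawm=np.asarray(nib.load(indir / entry["masks"]["nawm"]).dataobj) > 0,
        )
        with open(indir / entry["csi"]) as fh:
            c = json.load(fh)
        csi = CSIGrid(
            ratios={k: np.asarray(v) for k, v in c["ratios"].items()},
            quality_sd={k: np.asarray(v) for k, v in c["quality_sd"].items()},
            footprint_labels=np.asarray(c["footprint_labels"]),
            n_rows=c["n_rows"],
            n_cols=c["n_cols"],
        )
        row = table.loc[pid]
        survival = SurvivalRecord(
            os_days=float(row["os_days"]),
            os_event=bool(row["os_event"]),
            pfs_days=float(row["pfs_days"]),
            pfs_event=bool(row["pfs_event"]),
        )
        cov_cols = [
            c for c in table.columns
            if c not in ("true_cluster", "os_days", "os_event", "pfs_days", "pfs_event")
        ]
        covariates = {c: row[c] for c in cov_cols}
        survival.covariates = dict(covariates)
        patients.append(
            PatientBundle(
                patient_id=pid,
                maps=maps,
                masks=masks,
                csi=csi,
                covariates=covariates,
                survival=survival,
                true_cluster=int(row["true_cluster"]),
            )
        )
    return SyntheticCohort(patients=patients, config=config)


def _config_to_json(config: CohortConfig) -> dict:
    return asdict(config)


def _config_from_json(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("cluster_proportions", "map_names", "grid_shape", "csi_shape", "csi_sd_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortConfig(**d)
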