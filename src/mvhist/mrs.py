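"""CSI voxel filtering and metabolite comparison between patient clusters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

METABOLITES = ("NAA/Cr", "Cho/Cr")


@dataclass
class CSIGrid:
    """A coarse spectroscopy grid of metabolite ratios over the map volume.

    ``ratios`` and ``quality_sd`` map each metabolite to an
    ``(n_rows, n_cols)`` array (quality SDs in percent).  ``footprint_labels``
    is an integer volume on the map grid: ``-1`` outside the CSI slab,
    otherwise ``row * n_cols + col`` of the covering CSI voxel.
    """

    ratios: Mapping[str, np.ndarray]
    quality_sd: Mapping[str, np.ndarray]
    footprint_labels: np.ndarray
    n_rows: int = 8
    n_cols: int = 8

    def __post_init__(self):
        for met in METABOLITES:
            if met not in self.ratios or met not in self.quality_sd:
                raise ValueError(f"missing metabolite {met!r}")
        shape = (self.n_rows, self.n_cols)
        for met in METABOLITES:
            r = np.asarray(self.ratios[met], dtype=float)
            s = np.asarray(self.quality_sd[met], dtype=float)
            if r.shape != shape or s.shape != shape:
                raise ValueError(f"{met}: grids must be {shape}")
            if np.nanmin(r) < 0:
                raise ValueError(f"{met}: negative metabolite ratio")
        self.footprint_labels = np.asarray(self.footprint_labels)

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col


def tumor_fraction_per_csi_voxel(
    tumor_mask: np.ndarray, grid: CSIGrid
) -> np.ndarray:
    """Fraction of each CSI voxel's footprint occupied by tumor voxels."""
    tumor_mask = np.asarray(tumor_mask).astype(bool)
    if tumor_mask.shape != grid.footprint_labels.shape:
        raise ValueError(
            f"grid mismatch: mask {tumor_mask.shape} vs "
            f"footprints {grid.footprint_labels.shape}"
        )
    labels = grid.footprint_labels
    n_cells = grid.n_rows * grid.n_cols
    inside = labels >= 0
    totals = np.bincount(labels[inside], minlength=n_cells)
    if (totals == 0).any():
        empty = np.nonzero(totals == 0)[0]
        raise ValueError(f"CSI voxels with empty footprint: {empty.tolist()}")
    tumor = np.bincount(labels[inside & tumor_mask], minlength=n_cells)
    return (tumor / totals).reshape(grid.n_rows, grid.n_cols)


def filter_csi_voxels(
    grid: CSIGrid,
    fractions: np.ndarray,
    occupancy_threshold: float = 0.5,
    sd_threshold: float = 20.0,
) -> dict[str, np.ndarray]:
    """Included-voxel masks per metabolite.

    A voxel is kept when its tumor fraction is strictly greater than
    ``occupancy_threshold`` and its quality SD does not exceed
    ``sd_threshold`` percent (values with SD strictly above the threshold are
    discarded).
    """
    fractions = np.asarray(fractions, dtype=float)
    occupied = fractions > occupancy_threshold
    out = {}
    for met in METABOLITES:
        ok_quality = np.asarray(grid.quality_sd[met], dtype=float) <= sd_threshold
        out[met] = occupied & ok_quality
    return out


def summarize_patient(
    grid: CSIGrid, included: Mapping[str, np.ndarray], how: str = "median"
) -> dict[str, float]:
    """Per-patient metabolite summary over the retained voxels (NaN if none)."""
    if how not in ("median", "mean"):
        raise ValueError(f"unknown summary {how!r}")
    reduce = np.median if how == "median" else np.mean
    out = {}
    for met in METABOLITES:
        mask = np.asarray(included[met], dtype=bool)
        vals = np.asarray(grid.ratios[met], dtype=float)[mask]
        out[met] = float(reduce(vals)) if vals.size else float("nan")
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (bounded by 1, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def compare_metabolites(
    summaries: pd.DataFrame, cluster_labels: Sequence
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per metabolite column, BH-adjusted.

    ``summaries`` is patients × measures (e.g. ``NAA/Cr``, ``Cho/Cr`` per
    region); NaN rows are dropped per measure.  All comparisons form one BH
    family.  Returns a frame indexed by measure with ``statistic``, ``p`` and
    ``p_adj``.
    """
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two clusters, got {len(uniq)}")
    rows = {}
    for col in summaries.columns:
        vals = summaries[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        a = vals[ok & (labels == uniq[0])]
        b = vals[ok & (labels == uniq[1])]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"{col}: a cluster has no finite values")
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            warnings.warn(f"{col}: all values tied; p set to 1", stacklevel=2)
            rows[col] = (0.0, 1.0)
        else:
            res = mannwhitneyu(a, b, alternative="two-sided")
            rows[col] = (float(res.statistic), float(res.pvalue))
    out = pd.DataFrame(rows, index=["statistic", "p"]).T
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
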