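"""Mask algebra, NAWM normalization and histogram feature extraction.

Feature columns are named ``<Statistic>-<modality>-<region>`` (e.g.
``Mean-q-NE``) and partition into four views:

* ``CE-diffusion`` / ``NE-diffusion`` — p and q maps, 10 statistics each (20 features)
* ``CE-perfusion`` / ``NE-perfusion`` — rCBV, MTT, rCBF maps (30 features)

for a total of 100 columns per patient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

MODALITIES = ("p", "q", "rCBV", "MTT", "rCBF")
DIFFUSION_MODALITIES = ("p", "q")
PERFUSION_MODALITIES = ("rCBV", "MTT", "rCBF")
REGIONS = ("CE", "NE")
STATISTICS = (
    "Mean",
    "SD",
    "Median",
    "Mode",
    "Skewness",
    "Kurtosis",
    "Prc5",
    "Prc25",
    "Prc75",
    "Prc95",
)
VIEW_NAMES = ("CE-diffusion", "NE-diffusion", "CE-perfusion", "NE-perfusion")


class InsufficientDataError(ValueError):
    """Raised when a region holds too few voxels to summarize."""


class DegenerateControlError(ValueError):
    """Raised when the NAWM control region cannot normalize a map."""


def _as_bool(volume: np.ndarray) -> np.ndarray:
    return np.asarray(volume).astype(bool)


@dataclass(frozen=True)
class ROIMaskSet:
    """Binary CE / FLAIR / NAWM masks on a common grid; NE is derived."""

    ce: np.ndarray
    flair: np.ndarray
    nawm: np.ndarray

    def __post_init__(self):
        ce, flair, nawm = map(_as_bool, (self.ce, self.flair, self.nawm))
        if not (ce.shape == flair.shape == nawm.shape):
            raise ValueError(
                f"mask grids differ: ce {ce.shape}, flair {flair.shape}, nawm {nawm.shape}"
            )
        object.__setattr__(self, "ce", ce)
        object.__setattr__(self, "flair", flair)
        object.__setattr__(self, "nawm", nawm)

    @property
    def ne(self) -> np.ndarray:
        return derive_ne_mask(self.flair, self.ce)

    @property
    def shape(self) -> tuple:
        return self.ce.shape

    def region(self, name: str) -> np.ndarray:
        name = name.upper()
        if name == "CE":
            return self.ce
        if name == "NE":
            return self.ne
        if name == "FLAIR":
            return self.flair
        if name == "NAWM":
            return self.nawm
        raise KeyError(name)


@dataclass
class ParametricMapSet:
    """The five co-registered parametric maps of one patient."""

    maps: Mapping[str, np.ndarray]

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.maps]
        if missing:
            raise ValueError(f"missing modalities: {missing}")
        shapes = {m: np.asarray(v).shape for m, v in self.maps.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"map grids differ: {shapes}")
        self.maps = {m: np.asarray(self.maps[m], dtype=float) for m in MODALITIES}

    @property
    def shape(self) -> tuple:
        return next(iter(self.maps.values())).shape

    def normalized(self, nawm: np.ndarray) -> "ParametricMapSet":
        """NAWM-normalize every map (ratio to the patient's NAWM mean)."""
        return ParametricMapSet({m: normalize_map(v, nawm) for m, v in self.maps.items()})


def derive_ne_mask(flair: np.ndarray, ce: np.ndarray) -> np.ndarray:
    """Non-enhancing region: voxels inside FLAIR but outside CE."""
    flair = _as_bool(flair)
    ce = _as_bool(ce)
    if flair.shape != ce.shape:
        raise ValueError(f"grid mismatch: flair {flair.shape} vs ce {ce.shape}")
    return flair & ~ce


def normalize_map(volume: np.ndarray, nawm: np.ndarray) -> np.ndarray:
    """Divide every voxel by the mean value inside the NAWM control region."""
    volume = np.asarray(volume, dtype=float)
    nawm = _as_bool(nawm)
    if volume.shape != nawm.shape:
        raise ValueError(f"grid mismatch: map {volume.shape} vs nawm {nawm.shape}")
    if not nawm.any():
        raise DegenerateControlError("empty NAWM mask")
    ref = float(volume[nawm].mean())
    if ref == 0.0 or not np.isfinite(ref):
        raise DegenerateControlError(f"NAWM mean is degenerate: {ref}")
    return volume / ref


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity: 2|A∩B| / (|A| + |B|)."""
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass(frozen=True)
class HistogramFeatureVector:
    """Ten histogram statistics of one modality within one region."""

    mean: float
    sd: float
    median: float
    mode: float
    skewness: float
    kurtosis: float
    prc5: float
    prc25: float
    prc75: float
    prc95: float

    _FIELD_BY_STAT = {
        "Mean": "mean",
        "SD": "sd",
        "Median": "median",
        "Mode": "mode",
        "Skewness": "skewness",
        "Kurtosis": "kurtosis",
        "Prc5": "prc5",
        "Prc25": "prc25",
        "Prc75": "prc75",
        "Prc95": "prc95",
    }

    def as_dict(self) -> dict:
        return {stat: getattr(self, f) for stat, f in self._FIELD_BY_STAT.items()}


def histogram_mode(values: np.ndarray, n_bins: int = 100) -> float:
    """Center of the most populated of ``n_bins`` equal-width bins on [min, max].

    Ties are broken toward the lowest bin.  A zero-width range returns the
    common value.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def compute_histogram_features(values, n_bins: int = 100) -> HistogramFeatureVector:
    """Compute the ten histogram statistics of one region's voxel values.

    Statistics other than the mode are computed on the raw values; the mode
    comes from the ``n_bins``-bin histogram.  Percentiles use linear
    interpolation between order statistics; skewness and excess kurtosis use
    population (biased) moment definitions.  Non-finite voxels are dropped
    with a logged count; a constant region yields sd = 0 and
    skewness = kurtosis = 0 by convention.
    """
    values = np.asarray(values, dtype=float).ravel()
    finite = np.isfinite(values)
    if not finite.all():
        logger.warning("dropping %d non-finite voxels", int((~finite).sum()))
        values = values[finite]
    if values.size < 2:
        raise InsufficientDataError(
            f"need at least 2 finite voxels, got {values.size}"
        )
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        warnings.warn("constant region: skewness/kurtosis set to 0", stacklevel=2)
        skewness = kurt = 0.0
    else:
        skewness = float(_stats.skew(values, bias=True))
        kurt = float(_stats.kurtosis(values, fisher=True, bias=True))
    prc = np.percentile(values, [5, 25, 50, 75, 95])
    return HistogramFeatureVector(
        mean=float(values.mean()),
        sd=sd,
        median=float(prc[2]),
        mode=histogram_mode(values, n_bins=n_bins),
        skewness=skewness,
        kurtosis=kurt,
        prc5=float(prc[0]),
        prc25=float(prc[1]),
        prc75=float(prc[3]),
        prc95=float(prc[4]),
    )


def feature_name(statistic: str, modality: str, region: str) -> str:
    return f"{statistic}-{modality}-{region}"


def view_of(modality: str, region: str) -> str:
    kind = "diffusion" if modality in DIFFUSION_MODALITIES else "perfusion"
    return f"{region}-{kind}"


def feature_columns() -> list[str]:
    """The 100 feature names in deterministic (view-major) order."""
    cols = []
    for region in REGIONS:
        for group in (DIFFUSION_MODALITIES, PERFUSION_MODALITIES):
            for modality in group:
                for stat in STATISTICS:
                    cols.append(feature_name(stat, modality, region))
    return cols


def view_assignment() -> dict[str, list[str]]:
    """Mapping view name -> its feature columns (sizes 20/20/30/30)."""
    views: dict[str, list[str]] = {v: [] for v in VIEW_NAMES}
    for col in feature_columns():
        stat, modality, region = col.split("-")
        views[view_of(modality, region)].append(col)
    return views


@dataclass
class FeatureTable:
    """Patients × 100 histogram features with their view partition."""

    data: pd.DataFrame
    views: dict[str, list[str]] = field(default_factory=view_assignment)
    failed_patients: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        expected = feature_columns()
        got = list(self.data.columns)
        if got != expected:
            raise ValueError(
                "feature table columns do not match the canonical 100-column layout"
            )

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    def view_matrix(self, view: str) -> pd.DataFrame:
        return self.data[self.views[view]]


def extract_patient_features(
    maps: ParametricMapSet,
    masks: ROIMaskSet,
    n_bins: int = 100,
    normalize: bool = True,
) -> dict[str, float]:
    """One patient's 100 named features from its five maps and two regions."""
    if maps.shape != masks.shape:
        raise ValueError(f"map grid {maps.shape} differs from mask grid {masks.shape}")
    working = maps.normalized(masks.nawm) if normalize else maps
    regions = {"CE": masks.ce, "NE": masks.ne}
    out: dict[str, float] = {}
    for region, mask in regions.items():
        for modality in MODALITIES:
            vec = working.maps[modality][mask]
            fv = compute_histogram_features(vec, n_bins=n_bins)
            for stat, value in fv.as_dict().items():
                out[feature_name(stat, modality, region)] = value
    return out


def build_feature_table(
    patients: Iterable[tuple[str, ParametricMapSet, ROIMaskSet]],
    n_bins: int = 100,
    normalize: bool = True,
    on_error: str = "raise",
) -> FeatureTable:
    """Assemble the patients × 100 feature table.

    ``patients`` yields ``(patient_id, maps, masks)``.  ``on_error`` controls
    per-patient failures (empty region, missing data): ``"raise"`` aborts,
    ``"drop"`` excludes the patient, ``"na"`` keeps an all-NA row; failures
    are recorded per patient id either way.
    """
    if on_error not in ("raise", "drop", "na"):
        raise ValueError(f"on_error must be raise/drop/na, got {on_error!r}")
    rows: dict[str, dict[str, float]] = {}
    failed: dict[str, str] = {}
    for pid, maps, masks in patients:
        try:
            rows[pid] = extract_patient_features(
                maps, masks, n_bins=n_bins, normalize=normalize
            )
        except (InsufficientDataError, DegenerateControlError, ValueError) as exc:
            if on_error == "raise":
                raise type(exc)(f"patient {pid!r}: {exc}") from exc
            failed[str(pid)] = str(exc)
            if on_error == "na":
                rows[pid] = {c: np.nan for c in feature_columns()}
            logger.warning("patient %r failed feature extraction: %s", pid, exc)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=feature_columns())
    return FeatureTable(data=data, failed_patients=failed)
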