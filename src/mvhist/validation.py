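"""Leave-one-out cross-validation and consensus co-occurrence analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import MVDAConfig, run_mvda

logger = logging.getLogger(__name__)


@dataclass
class LoocvPartition:
    """One leave-one-out repetition: the held-out patient and the labels."""

    left_out: object
    labels: dict  # patient_id -> cluster label over the retained patients


@dataclass
class ConsensusMatrix:
    """Pairwise co-occurrence fractions over the LOOCV repetitions.

    ``M[i, j]`` is the fraction of repetitions containing both patients in
    which they shared a cluster (diagonal fixed at 1); the denominator counts
    only repetitions where both are present.
    """

    M: np.ndarray
    patient_ids: list

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("consensus matrix must be square")
        if not np.allclose(M, M.T):
            raise ValueError("consensus matrix must be symmetric")
        if (M < -1e-12).any() or (M > 1 + 1e-12).any():
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(M), 1.0):
            raise ValueError("consensus diagonal must be 1")
        self.M = M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.patient_ids, columns=self.patient_ids)


def loocv_clusterings(
    view_frames: Mapping[str, pd.DataFrame],
    config: MVDAConfig | None = None,
) -> list[LoocvPartition]:
    """Rerun the full multi-view pipeline once per held-out patient.

    Every repetition refits feature clustering, centroid selection, patient
    clustering and integration from scratch on the remaining patients.
    Failures are recorded against the held-out patient and re-raised; nothing
    is silently dropped.
    """
    ids = list(next(iter(view_frames.values())).index)
    if len(ids) < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    partitions = []
    for pid in ids:
        reduced = {v: f.drop(index=pid) for v, f in view_frames.items()}
        try:
            result = run_mvda(reduced, config)
        except Exception as exc:
            logger.error("LOOCV repetition leaving out %r failed: %s", pid, exc)
            raise RuntimeError(f"LOOCV repetition leaving out {pid!r} failed") from exc
        kept = [i for i in ids if i != pid]
        labels = dict(zip(kept, result.final_labels))
        partitions.append(LoocvPartition(left_out=pid, labels=labels))
    return partitions


def consensus_matrix(
    partitions: Sequence[LoocvPartition], patient_ids: Sequence
) -> ConsensusMatrix:
    """Co-occurrence fractions over the repetitions containing each pair."""
    ids = list(patient_ids)
    n = len(ids)
    pos = {pid: i for i, pid in enumerate(ids)}
    together = np.zeros((n, n))
    both = np.zeros((n, n))
    for part in partitions:
        members = list(part.labels)
        idx = np.array([pos[m] for m in members])
        lab = np.array([part.labels[m] for m in members])
        same = lab[:, None] == lab[None, :]
        both[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += same
    off = ~np.eye(n, dtype=bool)
    if (both[off] == 0).any():
        raise ValueError("some patient pair is never co-present in any repetition")
    M = np.ones((n, n))
    M[off] = together[off] / both[off]
    M = 0.5 * (M + M.T)
    return ConsensusMatrix(M=M, patient_ids=ids)


def cluster_consensus_means(
    consensus: ConsensusMatrix, final_labels: Sequence
) -> dict:
    """Mean off-diagonal co-occurrence within each final cluster.

    Singleton clusters have no within-cluster pair and report NaN.
    """
    labels = np.asarray(final_labels)
    if len(labels) != len(consensus.patient_ids):
        raise ValueError("labels do not match the consensus matrix")
    out = {}
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if len(idx) == 0:
            raise ValueError(f"cluster {c} is empty")
        if len(idx) == 1:
            out[int(c)] = float("nan")
            continue
        sub = consensus.M[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        out[int(c)] = float(sub[off].mean())
    return out
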