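"""Set-theoretic variance partitioning of encoding-model performance.

Decomposes the joint (separate-model) explained variance into components
unique to production, unique to comprehension, and shared between them, from
the cross-validated prediction correlations of the joint and the two
single-modality models:

    unique_production    = R2_joint - R2_comprehension
    unique_comprehension = R2_joint - R2_production
    shared               = R2_production + R2_comprehension - R2_joint

with R2 = max(r, 0)^2. The three components sum to R2_joint exactly before
clipping; negative components (a CV sampling artifact) are clipped to zero
independently afterwards, and components are reported on the square-root
scale to stay commensurate with correlation-based accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABELS = ("production", "comprehension", "bimodal", "none")
DEFAULT_THRESHOLD_R = 0.05


@dataclass
class PartitionMap:
    """Per-voxel variance partition and best-partition labels."""

    r2_joint: np.ndarray
    r2_production: np.ndarray
    r2_comprehension: np.ndarray
    unique_production: np.ndarray  # clipped, R^2 scale
    unique_comprehension: np.ndarray
    shared: np.ndarray
    raw_unique_production: np.ndarray  # pre-clip, satisfy additivity exactly
    raw_unique_comprehension: np.ndarray
    raw_shared: np.ndarray
    labels: np.ndarray | None = None

    @property
    def sqrt_unique_production(self) -> np.ndarray:
        return np.sqrt(self.unique_production)

    @property
    def sqrt_unique_comprehension(self) -> np.ndarray:
        return np.sqrt(self.unique_comprehension)

    @property
    def sqrt_shared(self) -> np.ndarray:
        return np.sqrt(self.shared)

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sqrt_unique_production": self.sqrt_unique_production,
                "sqrt_unique_comprehension": self.sqrt_unique_comprehension,
                "sqrt_shared": self.sqrt_shared,
            }
        )
        if self.labels is not None:
            out["label"] = self.labels
        out.index.name = "voxel"
        return out


def compute_partition(r_joint: np.ndarray, r_prod: np.ndarray, r_comp: np.ndarray) -> PartitionMap:
    """Partition CV prediction accuracy into unique and shared components."""
    r_joint = np.asarray(r_joint, dtype=float)
    r_prod = np.asarray(r_prod, dtype=float)
    r_comp = np.asarray(r_comp, dtype=float)
    if not (r_joint.shape == r_prod.shape == r_comp.shape):
        raise ValueError("per-voxel correlation vectors must have matching shapes")
    R2j = np.maximum(r_joint, 0.0) ** 2
    R2p = np.maximum(r_prod, 0.0) ** 2
    R2c = np.maximum(r_comp, 0.0) ** 2
    up = R2j - R2c
    uc = R2j - R2p
    sh = R2p + R2c - R2j
    return PartitionMap(
        r2_joint=R2j,
        r2_production=R2p,
        r2_comprehension=R2c,
        unique_production=np.maximum(up, 0.0),
        unique_comprehension=np.maximum(uc, 0.0),
        shared=np.maximum(sh, 0.0),
        raw_unique_production=up,
        raw_unique_comprehension=uc,
        raw_shared=sh,
    )


def best_partition_label(
    pmap: PartitionMap,
    r_separate: np.ndarray,
    threshold_r: float = DEFAULT_THRESHOLD_R,
) -> np.ndarray:
    """Label each voxel by its largest partition component.

    Voxels whose separate-model accuracy does not exceed ``threshold_r`` are
    labelled "none". Ties break toward shared ("bimodal"), then production —
    a fixed, documented order so labelling is deterministic.
    """
    if threshold_r < 0:
        raise ValueError("threshold must be nonnegative")
    comps = np.stack([pmap.shared, pmap.unique_production, pmap.unique_comprehension])
    names = np.array(["bimodal", "production", "comprehension"])
    labels = names[np.argmax(comps, axis=0)]  # argmax ties -> first (shared, then production)
    labels = labels.astype(object)
    labels[np.asarray(r_separate, dtype=float) <= threshold_r] = "none"
    pmap.labels = labels.astype(str)
    return pmap.labels


def select_voxels(
    scores: pd.DataFrame,
    rule: str,
    q_alpha: float = 0.05,
    threshold_r: float = DEFAULT_THRESHOLD_R,
) -> np.ndarray:
    """Select voxel index sets used throughout the analysis.

    rule="linguistic": voxels with significant separate-model accuracy
    (FDR q < ``q_alpha`` on the Fisher-combined permutation p).
    rule="cross_modal": voxels with r > ``threshold_r`` in both same- and
    cross-modality scoring.
    ``scores`` columns: "q" for linguistic; "r_same" and "r_cross" for
    cross_modal.
    """
    if rule == "linguistic":
        if "q" not in scores:
            raise ValueError("linguistic selection needs a 'q' column")
        return np.flatnonzero(scores["q"].to_numpy() < q_alpha)
    if rule == "cross_modal":
        missing = {"r_same", "r_cross"} - set(scores.columns)
        if missing:
            raise ValueError(f"cross_modal selection needs columns {sorted(missing)}")
        mask = (scores["r_same"].to_numpy() > threshold_r) & (scores["r_cross"].to_numpy() > threshold_r)
        return np.flatnonzero(mask)
    raise ValueError(f"unknown selection rule {rule!r}")
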