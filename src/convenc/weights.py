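"""Weight-space analyses: delay averaging and per-voxel tuning correlations."""

from __future__ import annotations

import numpy as np

from .encoding import EncodingResult
from .features import DesignMatrix


def delay_average(weights: np.ndarray, design: DesignMatrix) -> dict[str, np.ndarray]:
    """Average FIR weights over the six delay copies of each feature.

    Returns one [D x V] matrix per band: the mean tuning of each voxel to each
    feature, collapsing the hemodynamic delay axis (e.g. 33,792 delayed
    weights -> 5,632 mean weights for the two-band model).
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float).T).T
    if W.shape[0] != design.n_columns:
        raise ValueError("weight rows must match design columns")
    out: dict[str, np.ndarray] = {}
    delays = np.unique(design.delay)
    n_d = delays.size
    for band in design.bands:
        cols = design.band_columns(band)
        order = np.lexsort((design.delay[cols], design.feature[cols]))
        cols = cols[order]
        if cols.size % n_d:
            raise ValueError(f"band {band!r} columns are not a whole number of delay groups")
        feat_grid = design.feature[cols].reshape(-1, n_d)
        delay_grid = design.delay[cols].reshape(-1, n_d)
        if np.any(feat_grid != feat_grid[:, :1]) or np.any(delay_grid != delays):
            raise ValueError(f"band {band!r} is missing delay copies for some feature")
        out[band] = W[cols].reshape(-1, n_d, W.shape[1]).mean(axis=1)
    return out


def weight_correlation(map_a: np.ndarray, map_b: np.ndarray, voxel_set: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel Pearson correlation between two [D x V] tuning maps.

    Computed across the D feature dimensions for each voxel in ``voxel_set``
    (all voxels when None). Zero-variance tuning vectors get r = 0, keeping
    silent voxels from producing NaNs in group summaries.
    """
    A = np.asarray(map_a, dtype=float)
    B = np.asarray(map_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("tuning maps must have identical shapes")
    if voxel_set is not None:
        A = A[:, voxel_set]
        B = B[:, voxel_set]
    a = A - A.mean(axis=0)
    b = B - B.mean(axis=0)
    na = np.sqrt(np.sum(a**2, axis=0))
    nb = np.sqrt(np.sum(b**2, axis=0))
    denom = na * nb
    r = np.zeros(A.shape[1])
    ok = denom > 0
    r[ok] = np.sum(a[:, ok] * b[:, ok], axis=0) / denom[ok]
    return np.clip(r, -1.0, 1.0)


def cross_modal_tuning_correlation(result: EncodingResult, design: DesignMatrix, voxel_set: np.ndarray | None = None) -> np.ndarray:
    """Production-vs-comprehension tuning correlation from a separate model."""
    maps = delay_average(result.weights, design)
    if "production" not in maps or "comprehension" not in maps:
        raise ValueError("cross-modal tuning correlation needs a separate model")
    return weight_correlation(maps["production"], maps["comprehension"], voxel_set)
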