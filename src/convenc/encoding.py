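"""Voxel-wise banded ridge FIR encoding models.

Fits a separate ridge penalty per feature band (production vs comprehension),
selecting the per-voxel penalty pair on an exhaustive 10x10 grid by
contiguous-in-time 5-fold inner cross-validation, scores held-out predictions
with Pearson correlation, exchanges weight blocks between bands for
cross-modality generalization, and tests accuracy with a 20-TR
block-permutation null combined across folds by Fisher's method with
Benjamini-Hochberg FDR.

Banded ridge with penalty alpha_b on band b is solved by rescaling band
columns by 1/sqrt(alpha_b) and solving an ordinary ridge with unit penalty;
the solver switches between the primal normal equations (P <= T) and the dual
kernel form (P > T), so designs far wider than the number of TRs are handled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from .features import DesignMatrix

#: Ten log-spaced ridge penalties between 1e-2 and 1e7.
ALPHA_GRID = np.logspace(-2, 7, 10)


def _contiguous_folds(n: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """k contiguous temporal blocks as (train_idx, val_idx) pairs."""
    bounds = np.linspace(0, n, k + 1).astype(int)
    folds = []
    idx = np.arange(n)
    for i in range(k):
        val = idx[bounds[i] : bounds[i + 1]]
        train = np.concatenate([idx[: bounds[i]], idx[bounds[i + 1] :]])
        folds.append((train, val))
    return folds


def _solve_unit_ridge(Xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Ridge solution with penalty 1 on a (column-scaled) design.

    Primal when P <= T, dual (kernel) otherwise; the two agree on problems
    where both are feasible.
    """
    T, P = Xs.shape
    if P <= T:
        A = Xs.T @ Xs
        A[np.diag_indices_from(A)] += 1.0
        return linalg.solve(A, Xs.T @ Y, assume_a="pos")
    K = Xs @ Xs.T
    K[np.diag_indices_from(K)] += 1.0
    return Xs.T @ linalg.solve(K, Y, assume_a="pos")


@dataclass
class EncodingResult:
    """Fitted voxel-wise encoding model and its evaluation."""

    weights: np.ndarray  # [P x V] (fold-averaged if LOSO)
    alphas: np.ndarray  # [n_bands x V]
    bands: tuple[str, ...]
    band_columns: dict[str, np.ndarray]
    fold_r: np.ndarray | None = None  # [n_folds x V]
    mean_r: np.ndarray | None = None  # [V]
    fold_weights: np.ndarray | None = None  # [n_folds x P x V]
    fold_p: np.ndarray | None = None  # [n_folds x V]
    combined_p: np.ndarray | None = None  # [V]
    q: np.ndarray | None = None  # [V]
    config: dict = field(default_factory=dict)


class BandedRidgeCV(BaseEstimator, RegressorMixin):
    """Multi-target banded ridge with per-voxel, per-band penalty selection.

    Parameters
    ----------
    bands
        Mapping band name -> column indices; the groups must partition the
        columns of X.
    alphas
        Candidate penalties; the grid searched is the Cartesian product over
        bands (10 x 10 for the two-band conversational model).
    n_inner_folds
        Inner CV folds; splits are contiguous temporal blocks because the
        regressors and targets are autocorrelated time series.

    Attributes
    ----------
    coef_ : ndarray [P x V]
        Weights refit on all rows at the selected penalty pair.
    alpha_ : ndarray [n_bands x V]
        Selected penalty per band per voxel.
    """

    def __init__(self, bands: dict[str, np.ndarray], alphas: np.ndarray = ALPHA_GRID, n_inner_folds: int = 5):
        self.bands = bands
        self.alphas = alphas
        self.n_inner_folds = n_inner_folds

    def _check_bands(self, P: int) -> list[np.ndarray]:
        cols = [np.asarray(self.bands[b], dtype=int) for b in self.bands]
        allc = np.sort(np.concatenate(cols))
        if not np.array_equal(allc, np.arange(P)):
            raise ValueError("bands must partition the design columns")
        return cols

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        T, P = X.shape
        V = Y.shape[1]
        band_cols = self._check_bands(P)
        alphas = np.asarray(self.alphas, dtype=float)
        self.band_names_ = tuple(self.bands)

        if not np.any(X):
            warnings.warn("all-zero design; returning zero weights at the maximal penalty", stacklevel=2)
            self.coef_ = np.zeros((P, V))
            self.alpha_ = np.full((len(band_cols), V), alphas.max())
            return self

        combos = list(product(range(alphas.size), repeat=len(band_cols)))
        folds = _contiguous_folds(T, self.n_inner_folds)
        mse = np.zeros((len(combos), V))
        for train, val in folds:
            Xt, Xv, Yt, Yv = X[train], X[val], Y[train], Y[val]
            if P <= Xt.shape[0]:  # primal: Gram over features, scaled per combo
                G = Xt.T @ Xt
                C = Xt.T @ Yt
                for ci, combo in enumerate(combos):
                    s = np.empty(P)
                    for cols, ai in zip(band_cols, combo):
                        s[cols] = 1.0 / np.sqrt(alphas[ai])
                    A = G * np.outer(s, s)
                    A[np.diag_indices_from(A)] += 1.0
                    W = linalg.solve(A, C * s[:, None], assume_a="pos")
                    resid = Yv - (Xv * s) @ W
                    mse[ci] += np.mean(resid**2, axis=0)
            else:  # dual: per-band kernels over TRs
                Kt = [Xt[:, cols] @ Xt[:, cols].T for cols in band_cols]
                Kv = [Xv[:, cols] @ Xt[:, cols].T for cols in band_cols]
                for ci, combo in enumerate(combos):
                    K = sum(Kb / alphas[ai] for Kb, ai in zip(Kt, combo))
                    K[np.diag_indices_from(K)] += 1.0
                    dual = linalg.solve(K, Yt, assume_a="pos")
                    pred = sum(Kb / alphas[ai] for Kb, ai in zip(Kv, combo)) @ dual
                    mse[ci] += np.mean((Yv - pred) ** 2, axis=0)
        best = np.argmin(mse, axis=0)  # ties -> first combo in grid order

        self.coef_ = np.empty((P, V))
        self.alpha_ = np.empty((len(band_cols), V))
        G_full = X.T @ X if P <= T else None
        C_full = X.T @ Y if P <= T else None
        K_full = [X[:, cols] @ X[:, cols].T for cols in band_cols] if P > T else None
        for ci in np.unique(best):
            voxels = np.flatnonzero(best == ci)
            combo = combos[ci]
            s = np.empty(P)
            for cols, ai in zip(band_cols, combo):
                s[cols] = 1.0 / np.sqrt(alphas[ai])
            if P <= T:
                A = G_full * np.outer(s, s)
                A[np.diag_indices_from(A)] += 1.0
                W = linalg.solve(A, C_full[:, voxels] * s[:, None], assume_a="pos")
            else:
                K = sum(Kb / alphas[ai] for Kb, ai in zip(K_full, combo))
                K[np.diag_indices_from(K)] += 1.0
                dual = linalg.solve(K, Y[:, voxels], assume_a="pos")
                W = (X * s).T @ dual
            self.coef_[:, voxels] = W * s[:, None]
            self.alpha_[:, voxels] = alphas[np.array(combo)][:, None]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_


def pearson_scores(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; constant prediction or target scores 0.

    The zero convention (rather than NaN) keeps downstream thresholding and
    averaging well defined for silent voxels and all-zero weight vectors.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float).T).T
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float).T).T
    if y_true.shape != y_pred.shape:
        raise ValueError("observed and predicted shapes differ")
    a = y_true - y_true.mean(axis=0)
    b = y_pred - y_pred.mean(axis=0)
    na = np.sqrt(np.sum(a**2, axis=0))
    nb = np.sqrt(np.sum(b**2, axis=0))
    denom = na * nb
    ok = denom > 0
    r = np.zeros(y_true.shape[1])
    r[ok] = np.sum(a[:, ok] * b[:, ok], axis=0) / denom[ok]
    return np.clip(r, -1.0, 1.0)


def predict_and_score(weights: np.ndarray, X_test: np.ndarray, y_test: np.ndarray) -> np.ndarray:
    """Per-voxel Pearson r of the linear prediction ``X_test @ weights``."""
    if X_test.shape[0] != np.atleast_2d(y_test.T).T.shape[0]:
        raise ValueError("test design and targets have different lengths")
    return pearson_scores(y_test, X_test @ weights)


MIN_SESSION_TR = 20


def run_loso(
    design: DesignMatrix,
    y: np.ndarray,
    alphas: np.ndarray = ALPHA_GRID,
    n_inner_folds: int = 5,
    n_perm: int = 0,
    block_tr: int = 20,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> EncodingResult:
    """Leave-one-session-out evaluation of the banded ridge model.

    Each session is held out once; the model (including the inner penalty
    search) is refit on the remaining sessions and scored on the held-out
    session. Weights are stored per fold and fold-averaged for the weight
    analyses. With ``n_perm > 0``, per-fold block-permutation p values are
    combined by Fisher's method and FDR-corrected across voxels.
    """
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    sessions = np.unique(design.session_index)
    usable = []
    for s in sessions:
        if np.sum(design.session_index == s) < MIN_SESSION_TR:
            warnings.warn(f"session {s} has < {MIN_SESSION_TR} TRs; excluded from LOSO", stacklevel=2)
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError("leave-one-session-out needs at least 2 usable sessions")

    bands = {b: design.band_columns(b) for b in design.bands}
    P, V = design.n_columns, Y.shape[1]
    fold_w = np.empty((len(usable), P, V))
    fold_alpha = np.empty((len(usable), len(bands), V))
    fold_r = np.empty((len(usable), V))
    fold_p = np.empty((len(usable), V)) if n_perm > 0 else None

    for i, s in enumerate(usable):
        test = design.session_index == s
        train = ~test & np.isin(design.session_index, usable)
        model = BandedRidgeCV(bands=bands, alphas=alphas, n_inner_folds=n_inner_folds)
        model.fit(design.values[train], Y[train])
        pred = model.predict(design.values[test])
        fold_w[i] = model.coef_
        fold_alpha[i] = model.alpha_
        fold_r[i] = pearson_scores(Y[test], pred)
        if n_perm > 0:
            fold_p[i] = block_permutation_p(Y[test], pred, block_tr=block_tr, n_perm=n_perm, seed=seed + i)

    combined = q = None
    if n_perm > 0:
        combined = fisher_combine(fold_p)
        q = bh_fdr(combined)
    return EncodingResult(
        weights=fold_w.mean(axis=0),
        alphas=fold_alpha.mean(axis=0),
        bands=tuple(bands),
        band_columns=bands,
        fold_r=fold_r,
        mean_r=fold_r.mean(axis=0),
        fold_weights=fold_w,
        fold_p=fold_p,
        combined_p=combined,
        q=q,
        config={"alphas": np.asarray(alphas).tolist(), "n_perm": n_perm, "block_tr": block_tr, "seed": seed},
    )


def swap_band_weights(result: EncodingResult) -> EncodingResult:
    """Exchange the production and comprehension weight blocks of each voxel.

    Requires a two-band separate model whose bands share an identical
    (feature, delay) column layout; applying the swap twice restores the
    original weights bit-exactly.
    """
    if set(result.bands) != {"production", "comprehension"}:
        raise ValueError("weight swapping requires a separate model with production and comprehension bands")
    cp = result.band_columns["production"]
    cc = result.band_columns["comprehension"]
    if cp.size != cc.size:
        raise ValueError("band column blocks differ in size; cannot swap")
    swapped = result.weights.copy()
    swapped[cp], swapped[cc] = result.weights[cc], result.weights[cp]
    fold_sw = None
    if result.fold_weights is not None:
        fold_sw = result.fold_weights.copy()
        fold_sw[:, cp], fold_sw[:, cc] = result.fold_weights[:, cc], result.fold_weights[:, cp]
    return EncodingResult(
        weights=swapped,
        alphas=result.alphas[::-1] if result.alphas.shape[0] == 2 else result.alphas,
        bands=result.bands,
        band_columns=result.band_columns,
        fold_weights=fold_sw,
        config={**result.config, "swapped": True},
    )


def score_loso(design: DesignMatrix, y: np.ndarray, result: EncodingResult) -> np.ndarray:
    """Per-voxel mean r over sessions using per-fold weights (e.g. swapped)."""
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    sessions = [s for s in np.unique(design.session_index) if np.sum(design.session_index == s) >= MIN_SESSION_TR]
    if result.fold_weights is None or result.fold_weights.shape[0] != len(sessions):
        raise ValueError("result lacks per-fold weights matching the session structure")
    rs = np.empty((len(sessions), Y.shape[1]))
    for i, s in enumerate(sessions):
        test = design.session_index == s
        rs[i] = predict_and_score(result.fold_weights[i], design.values[test], Y[test])
    return rs.mean(axis=0)


def _block_slices(n: int, block: int) -> list[np.ndarray]:
    """Contiguous blocks of ``block`` TRs; a partial tail block stays intact."""
    return [np.arange(i, min(i + block, n)) for i in range(0, n, block)]


def block_permutation_p(
    y_test: np.ndarray,
    y_pred: np.ndarray,
    block_tr: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """One-sided p for positive prediction accuracy under block permutation.

    The observed time series is cut into contiguous 20-TR blocks (kept intact
    to preserve autocorrelation) whose order is shuffled n_perm times; the
    null is the distribution of Pearson r between the shuffled observations
    and the unchanged predictions. p = (1 + #{null >= observed}) / (n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.atleast_2d(np.asarray(y_test, dtype=float).T).T
    Yp = np.atleast_2d(np.asarray(y_pred, dtype=float).T).T
    T = Y.shape[0]
    if T <= block_tr:
        # single block: every shuffle is the identity, the null is degenerate
        warnings.warn("test segment spans a single permutation block; p is 1 by construction", stacklevel=2)
    blocks = _block_slices(T, block_tr)
    observed = pearson_scores(Y, Yp)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[1])
    for _ in range(n_perm):
        order = rng.permutation(len(blocks))
        idx = np.concatenate([blocks[i] for i in order])
        null_r = pearson_scores(Y[idx], Yp)
        exceed += null_r >= observed
    return (1.0 + exceed) / (n_perm + 1.0)


def fisher_combine(fold_p: np.ndarray, clamp: float | None = None) -> np.ndarray:
    """Fisher's method across folds: -2 sum(ln p) ~ chi^2 with 2k df.

    Zero p values (impossible under the add-one permutation rule, but
    possible for externally supplied p) are clamped with a warning.
    """
    P = np.asarray(fold_p, dtype=float)
    if np.any(P > 1) or np.any(P < 0):
        raise ValueError("p values must lie in [0, 1]")
    if np.any(P == 0):
        clamp = clamp if clamp is not None else np.finfo(float).tiny
        warnings.warn("zero p values clamped before Fisher combination", stacklevel=2)
        P = np.maximum(P, clamp)
    stat = -2.0 * np.sum(np.log(P), axis=0)
    return stats.chi2.sf(stat, df=2 * P.shape[0])


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values across voxels."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
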