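"""Design-matrix construction and minimal BOLD preprocessing.

Turns TR-aligned transcript segments and per-TR contextual embeddings into
FIR-expanded, band-labelled predictor matrices, and applies the minimal BOLD
preprocessing the encoding analysis assumes (120-s running-median detrend,
per-run unit-variance normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import DELAYS, EmbeddingStore

MODES = ("separate", "unified", "production_only", "comprehension_only")


def assign_segments_to_tr(segments: pd.DataFrame, tr_ms: float = 1000.0) -> pd.DataFrame:
    """Assign each transcript segment to the TR containing its midpoint.

    ``segments`` needs columns onset_ms, offset_ms, modality and (optionally)
    run and tokens. TR index = floor(midpoint / tr_ms) on half-open bins, so a
    midpoint exactly on a boundary goes to the later TR. Row order within a TR
    is preserved.
    """
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    onset = segments["onset_ms"].to_numpy(dtype=float)
    offset = segments["offset_ms"].to_numpy(dtype=float)
    if np.any(onset < 0):
        raise ValueError("segment onsets must be nonnegative")
    if np.any(onset >= offset):
        raise ValueError("segment onsets must precede offsets")
    out = segments.copy()
    out["tr"] = np.floor((onset + offset) / 2.0 / tr_ms).astype(int)
    return out


def build_context_window(table: pd.DataFrame, tr: int, modality: str, context_s: int, run: int | None = None) -> list:
    """Concatenate a modality's tokens over the trailing context window.

    Collects tokens from TRs ``tr - context_s + 1 .. tr`` (clipped at the run
    start, i.e. TR 0 of the run), in temporal order. Returns an empty list if
    the window holds no tokens.
    """
    sel = table
    if run is not None:
        sel = sel[sel["run"] == run]
    max_tr = int(sel["tr"].max()) if len(sel) else -1
    if tr < 0 or tr > max_tr:
        raise IndexError(f"tr {tr} out of range for table with max tr {max_tr}")
    lo = max(0, tr - int(context_s) + 1)
    rows = sel[(sel["modality"] == modality) & (sel["tr"] >= lo) & (sel["tr"] <= tr)]
    rows = rows.sort_values("tr", kind="stable")
    tokens: list = []
    for toks in rows["tokens"]:
        tokens.extend(toks)
    return tokens


def pool_token_embeddings(token_embeddings: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """Mean-pool token embeddings into one per-TR vector.

    Returns ``(vector, True)``, or ``(None, False)`` for an empty token set
    (the TR is flagged absent rather than given a fabricated vector).
    """
    arr = np.asarray(token_embeddings, dtype=float)
    if arr.size == 0:
        return None, False
    return arr.mean(axis=0), True


@dataclass
class DesignMatrix:
    """Predictor matrix with per-column provenance and per-row run labels.

    ``band`` / ``feature`` / ``delay`` are per-column arrays; ``delay`` is 0
    before FIR expansion and in {2..7} afterwards.
    """

    values: np.ndarray  # [T x P]
    band: np.ndarray  # str [P]
    feature: np.ndarray  # int [P]
    delay: np.ndarray  # int [P]
    run_index: np.ndarray  # [T]
    session_index: np.ndarray  # [T]

    @property
    def n_columns(self) -> int:
        return int(self.values.shape[1])

    @property
    def bands(self) -> tuple[str, ...]:
        # preserve first-appearance order
        seen: dict[str, None] = {}
        for b in self.band:
            seen.setdefault(b, None)
        return tuple(seen)

    def band_columns(self, band: str) -> np.ndarray:
        return np.flatnonzero(self.band == band)

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"band": self.band, "feature": self.feature, "delay": self.delay})


def assemble_design(store: EmbeddingStore, mode: str, layer: int, context_s: int) -> DesignMatrix:
    """Assemble the pre-FIR design for one (mode, layer, context) cell.

    separate        -> [T x 2D]: production block then comprehension block,
                       zero rows where the modality is absent;
    production_only / comprehension_only -> [T x D] single band;
    unified         -> [T x D]: mean of the two modalities' embeddings where
                       both are present, falling back to the single present
                       modality's embedding otherwise.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    D = store.dim
    if mode == "separate":
        Xp = store.matrix("production", layer, context_s)
        Xc = store.matrix("comprehension", layer, context_s)
        values = np.concatenate([Xp, Xc], axis=1)
        band = np.array(["production"] * D + ["comprehension"] * D)
        feature = np.concatenate([np.arange(D), np.arange(D)])
    elif mode in ("production_only", "comprehension_only"):
        m = "production" if mode == "production_only" else "comprehension"
        values = store.matrix(m, layer, context_s).copy()
        band = np.array([m] * D)
        feature = np.arange(D)
    else:  # unified
        Xp = store.matrix("production", layer, context_s)
        Xc = store.matrix("comprehension", layer, context_s)
        pp = store.presence["production"].astype(float)[:, None]
        pc = store.presence["comprehension"].astype(float)[:, None]
        denom = np.maximum(pp + pc, 1.0)
        values = (Xp * pp + Xc * pc) / denom
        band = np.array(["unified"] * D)
        feature = np.arange(D)
    return DesignMatrix(
        values=values,
        band=band,
        feature=feature,
        delay=np.zeros(values.shape[1], dtype=int),
        run_index=store.run_index.copy(),
        session_index=store.session_index.copy(),
    )


class FIRDelayTransformer(BaseEstimator, TransformerMixin):
    """FIR expansion: delayed copies of each column at lags 2..7 TRs.

    Column (band, feature, d) at row t equals the source column at row t - d
    of the same run, and zero where the lag crosses a run boundary. A
    scikit-learn transformer over raw arrays; :func:`fir_expand` applies it to
    a :class:`DesignMatrix` with provenance bookkeeping.
    """

    def __init__(self, delays: Sequence[int] = DELAYS):
        self.delays = delays

    def fit(self, X, y=None):
        delays = tuple(int(d) for d in self.delays)
        if len(delays) == 0 or any(d < 1 for d in delays):
            raise ValueError("delays must be positive integers in TR units")
        self.delays_ = delays
        return self

    def transform(self, X, runs=None):
        X = np.asarray(X, dtype=float)
        T, P = X.shape
        if runs is None:
            runs = np.zeros(T, dtype=int)
        out = np.zeros((T, P * len(self.delays_)))
        run_lengths = {int(r): int(np.sum(runs == r)) for r in np.unique(runs)}
        if any(d >= n for d in self.delays_ for n in run_lengths.values()):
            warnings.warn("a delay is >= a run length; the affected columns are all zero", stacklevel=2)
        for j, d in enumerate(self.delays_):
            block = out[:, j * P : (j + 1) * P]
            for r in np.unique(runs):
                sel = np.flatnonzero(runs == r)
                if d < sel.size:
                    block[sel[d:]] = X[sel[:-d]]
        return out


def fir_expand(design: DesignMatrix, delays: Sequence[int] = DELAYS) -> DesignMatrix:
    """FIR-expand a pre-FIR design, multiplying its width by ``len(delays)``.

    Output columns are ordered band-major, then feature, then delay, so each
    band block keeps an identical (feature, delay) inner layout — the property
    that makes cross-modality weight swapping well defined.
    """
    tf = FIRDelayTransformer(delays=delays).fit(design.values)
    dl = tf.delays_
    cols = []
    band_out, feat_out, delay_out = [], [], []
    expanded = tf.transform(design.values, runs=design.run_index)
    P = design.n_columns
    # reorder from delay-major blocks to band/feature-major with delay fastest
    for b in design.bands:
        for j in design.band_columns(b):
            for k, d in enumerate(dl):
                cols.append(expanded[:, k * P + j])
                band_out.append(design.band[j])
                feat_out.append(design.feature[j])
                delay_out.append(d)
    return DesignMatrix(
        values=np.column_stack(cols),
        band=np.array(band_out),
        feature=np.array(feat_out, dtype=int),
        delay=np.array(delay_out, dtype=int),
        run_index=design.run_index.copy(),
        session_index=design.session_index.copy(),
    )


class BoldPreprocessor(BaseEstimator, TransformerMixin):
    """Detrend and normalize BOLD: per voxel per run, subtract a centred
    120-s running median (edge-truncated window), then scale to zero mean and
    unit variance. Voxels with zero variance after detrending are flagged and
    set to zeros.
    """

    def __init__(self, window_s: int = 120, tr_s: float = 1.0):
        self.window_s = window_s
        self.tr_s = tr_s

    def fit(self, X, y=None):
        self.window_tr_ = max(1, int(round(self.window_s / self.tr_s)))
        return self

    def transform(self, X, runs=None):
        X = np.asarray(X, dtype=float)
        T, V = X.shape
        if runs is None:
            runs = np.zeros(T, dtype=int)
        out = np.empty_like(X)
        flagged = np.zeros(V, dtype=bool)
        for r in np.unique(runs):
            sel = np.flatnonzero(runs == r)
            if sel.size < 2:
                raise ValueError("each run must contain more than one TR")
            block = pd.DataFrame(X[sel])
            med = block.rolling(self.window_tr_, center=True, min_periods=1).median().to_numpy()
            resid = X[sel] - med
            resid -= resid.mean(axis=0)
            sd = resid.std(axis=0)
            zero = sd < 1e-12
            flagged |= zero
            sd[zero] = 1.0
            resid /= sd
            resid[:, zero] = 0.0
            out[sel] = resid
        self.flagged_ = flagged
        return out


def preprocess_bold(values: np.ndarray, run_index: np.ndarray, window_s: int = 120, tr_s: float = 1.0):
    """Functional wrapper over :class:`BoldPreprocessor`.

    Returns ``(preprocessed [T x V], flagged [V])``.
    """
    pp = BoldPreprocessor(window_s=window_s, tr_s=tr_s).fit(values)
    out = pp.transform(values, runs=run_index)
    return out, pp.flagged_
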