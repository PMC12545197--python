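"""Low-dimensional structure of encoding weights.

PCA of accuracy-scaled voxel tuning maps, a parallel "stimulus PCA" of the
embedding features themselves as a null reference, Gale-Shapley stable
matching between the two PC sets, bootstrap significance of matched pairs,
and ranked most-correlated utterances per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA


def scale_weights(weights: np.ndarray, accuracy: np.ndarray) -> np.ndarray:
    """Scale each voxel's tuning column by its prediction accuracy.

    Down-weights poorly predicted voxels before PCA; negative accuracies are
    clipped to zero so they zero the column rather than flip its sign.
    """
    W = np.asarray(weights, dtype=float)
    r = np.asarray(accuracy, dtype=float)
    if W.shape[1] != r.size:
        raise ValueError("accuracy vector must have one entry per voxel column")
    return W * np.maximum(r, 0.0)[None, :]


class WeightSpacePCA(BaseEstimator):
    """Mean-centred PCA over observations (voxels or TR utterances).

    Thin estimator over :class:`sklearn.decomposition.PCA` exposing loadings
    as [D x K] columns in feature space plus variance-explained fractions.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 observations")
        if np.allclose(X, X[0]):
            raise ValueError("constant data matrix has no principal components")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(X)
        self.loadings_ = self._pca.components_.T  # [D x K]
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.n_components_ = self._pca.n_components_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float))


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson r| between columns of A [D x n] and columns of B [D x m]."""
    a = A - A.mean(axis=0)
    b = B - B.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return np.abs((a / na).T @ (b / nb))


def gale_shapley(proposer_prefs: np.ndarray, acceptor_prefs: np.ndarray) -> list[tuple[int, int]]:
    """Proposer-optimal stable matching from score matrices.

    ``proposer_prefs[i, j]`` is proposer i's score for acceptor j (higher is
    preferred) and ``acceptor_prefs[j, i]`` acceptor j's score for proposer i.
    Ties are broken by lower index, making the outcome deterministic.
    """
    n, m = proposer_prefs.shape
    # preference orders, stable sort so equal scores keep index order
    order = [list(np.argsort(-proposer_prefs[i], kind="stable")) for i in range(n)]
    rank = np.empty((m, n), dtype=int)
    for j in range(m):
        rank[j, np.argsort(-acceptor_prefs[j], kind="stable")] = np.arange(n)
    next_choice = [0] * n
    engaged_to: dict[int, int] = {}  # acceptor -> proposer
    free = list(range(n))
    while free:
        i = free.pop(0)
        if next_choice[i] >= m:
            continue  # proposer exhausted (only when n > m)
        j = order[i][next_choice[i]]
        next_choice[i] += 1
        if j not in engaged_to:
            engaged_to[j] = i
        elif rank[j, i] < rank[j, engaged_to[j]]:
            free.append(engaged_to[j])
            engaged_to[j] = i
        else:
            free.append(i)
    return sorted((i, j) for j, i in engaged_to.items())


def stable_match(weight_loadings: np.ndarray, stimulus_loadings: np.ndarray) -> list[tuple[int, int]]:
    """Match weight PCs to stimulus PCs by loading similarity.

    Both sides rank the other by absolute Pearson correlation between loading
    vectors; the weight side proposes, yielding the weight-optimal stable
    matching. Returns (weight PC index, stimulus PC index) pairs.
    """
    Wl = np.asarray(weight_loadings, dtype=float)
    Sl = np.asarray(stimulus_loadings, dtype=float)
    if Wl.shape[0] != Sl.shape[0]:
        raise ValueError("loading vectors must live in the same feature space")
    C = _abs_corr_matrix(Wl, Sl)
    return gale_shapley(C, C.T)


def is_stable(matches: list[tuple[int, int]], prefs: np.ndarray) -> bool:
    """Exhaustive blocking-pair check for a matching under symmetric scores."""
    matched_w = {i: j for i, j in matches}
    matched_s = {j: i for i, j in matches}
    n, m = prefs.shape
    for i in range(n):
        for j in range(m):
            if matched_w.get(i) == j:
                continue
            cur_w = prefs[i, matched_w[i]] if i in matched_w else -np.inf
            cur_s = prefs[matched_s[j], j] if j in matched_s else -np.inf
            if prefs[i, j] > cur_w and prefs[i, j] > cur_s:
                return False
    return True


def _projected_variance_fraction(X: np.ndarray, loading: np.ndarray) -> float:
    """Fraction of total variance of mean-centred X along one unit loading."""
    Xc = X - X.mean(axis=0)
    total = np.sum(Xc**2)
    if total == 0:
        return 0.0
    proj = Xc @ (loading / np.linalg.norm(loading))
    return float(np.sum(proj**2) / total)


@dataclass
class BootstrapOutcome:
    """Per matched pair: bootstrap variance distributions and significance."""

    matches: list[tuple[int, int]]
    weight_var: np.ndarray  # [n_pairs] point estimates
    stimulus_var: np.ndarray
    weight_boot: np.ndarray  # [n_boot x n_pairs]
    stimulus_boot: np.ndarray
    significant: np.ndarray  # bool [n_pairs]
    n_boot: int


def bootstrap_significance(
    weight_data: np.ndarray,
    stimulus_data: np.ndarray,
    weight_loadings: np.ndarray,
    stimulus_loadings: np.ndarray,
    matches: list[tuple[int, int]],
    n_boot: int = 1000,
    seed: int = 0,
    refit: bool = False,
) -> BootstrapOutcome:
    """Bootstrap test of weight PCs against their matched stimulus PCs.

    Observations (voxels for the weight side, TR utterances for the stimulus
    side) are resampled with replacement; in each resample the variance
    explained by each matched pair is recomputed by projecting the resampled
    data onto the original loadings (component identity is fixed, avoiding
    order switching; ``refit=True`` refits a PCA per resample instead and
    compares sorted top components). A pair is significant iff the stimulus
    PC explains more variance than the weight PC in zero of the ``n_boot``
    resamples — an exceedance p below 1/n_boot.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    Wd = np.asarray(weight_data, dtype=float)
    Sd = np.asarray(stimulus_data, dtype=float)
    rng = np.random.default_rng(seed)
    n_pairs = len(matches)
    wb = np.empty((n_boot, n_pairs))
    sb = np.empty((n_boot, n_pairs))
    # unit-norm loading matrices restricted to the matched components
    Lw = weight_loadings[:, [i for i, _ in matches]]
    Ls = stimulus_loadings[:, [j for _, j in matches]]
    Lw = Lw / np.linalg.norm(Lw, axis=0)
    Ls = Ls / np.linalg.norm(Ls, axis=0)

    def _proj_fracs(X: np.ndarray, L: np.ndarray) -> np.ndarray:
        Xc = X - X.mean(axis=0)
        total = np.sum(Xc**2)
        if total == 0:
            return np.zeros(L.shape[1])
        return np.sum((Xc @ L) ** 2, axis=0) / total

    for t in range(n_boot):
        wi = rng.integers(0, Wd.shape[0], Wd.shape[0])
        si = rng.integers(0, Sd.shape[0], Sd.shape[0])
        Wres, Sres = Wd[wi], Sd[si]
        if refit:
            k = max(i for i, _ in matches) + 1
            wv = WeightSpacePCA(n_components=min(k, *Wres.shape)).fit(Wres).explained_variance_ratio_
            kj = max(j for _, j in matches) + 1
            sv = WeightSpacePCA(n_components=min(kj, *Sres.shape)).fit(Sres).explained_variance_ratio_
            for p, (i, j) in enumerate(matches):
                wb[t, p] = wv[i]
                sb[t, p] = sv[j]
        else:
            wb[t] = _proj_fracs(Wres, Lw)
            sb[t] = _proj_fracs(Sres, Ls)
    point_w = np.array([_projected_variance_fraction(Wd, weight_loadings[:, i]) for i, _ in matches])
    point_s = np.array([_projected_variance_fraction(Sd, stimulus_loadings[:, j]) for _, j in matches])
    significant = np.all(sb <= wb, axis=0)
    return BootstrapOutcome(
        matches=matches,
        weight_var=point_w,
        stimulus_var=point_s,
        weight_boot=wb,
        stimulus_boot=sb,
        significant=significant,
        n_boot=n_boot,
    )


def rank_utterances(
    pc_loading: np.ndarray,
    utterance_embeddings: np.ndarray,
    top_n: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Utterances whose embeddings correlate most with a PC loading.

    Correlation is Pearson across the D embedding dimensions. Returns the
    top-n most positively and most negatively correlated utterances; ties go
    to the earlier utterance, zero-variance embeddings are excluded.
    """
    v = np.asarray(pc_loading, dtype=float)
    E = np.asarray(utterance_embeddings, dtype=float)
    if top_n > E.shape[0]:
        raise ValueError("top_n exceeds the number of utterances")
    vc = v - v.mean()
    Ec = E - E.mean(axis=1, keepdims=True)
    nv = np.linalg.norm(vc)
    ne = np.linalg.norm(Ec, axis=1)
    valid = ne > 0
    r = np.full(E.shape[0], np.nan)
    r[valid] = (Ec[valid] @ vc) / (ne[valid] * nv)
    idx = np.flatnonzero(valid)
    # stable sort => earlier utterance wins ties
    pos = idx[np.argsort(-r[idx], kind="stable")][:top_n]
    neg = idx[np.argsort(r[idx], kind="stable")][:top_n]
    top_pos = pd.DataFrame({"utterance": pos, "correlation": r[pos]})
    top_neg = pd.DataFrame({"utterance": neg, "correlation": r[neg]})
    return top_pos, top_neg
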