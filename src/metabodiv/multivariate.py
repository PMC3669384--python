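"""Multivariate modeling and discriminative-feature selection.

Unsupervised views (PCA, hierarchical clustering) and supervised two-class
models (PLS-DA and OPLS-DA) of the aligned intensity matrix, plus the three
feature-selection rules used to call a metabolite "discriminative":

* **VIP >= 1** — variable importance in the projection,
  ``VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a)`` (mean VIP^2 = 1).
* **S-plot rule** — |cov(t1, x_j)| and |corr(t1, x_j)| each scaled so their
  maximum is 100%; a feature is a candidate when *both* scaled values exceed
  50%.
* **Wilcoxon** — two-sided rank-sum test per feature at raw p < 0.05
  (Benjamini-Hochberg q-values are reported alongside but selection follows
  the raw-p convention).

The PLS core is a NIPALS PLS1 on a ±1 class vector; OPLS-DA removes
``n_orth`` Y-orthogonal components from X (orthogonal-signal-correction
deflation) before the single predictive PLS component, so OPLS-DA with
``n_orth = 0`` reproduces 1-component PLS-DA exactly.

Preprocessing defaults to mean centering + Pareto scaling (divide by the
square root of the feature standard deviation), the common choice for FT-MS
intensity data; unit-variance scaling is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

from .alignment import FeatureMatrix

__all__ = [
    "Preprocessing", "LatentModel", "PCAResult",
    "preprocess", "log_transform", "filter_prevalence", "impute_half_min",
    "pca", "pls_da", "opls_da", "vip",
    "select_candidates", "wilcoxon_select", "hca", "cluster_support",
    "discriminative_features",
]

_LINKAGES = ("single", "complete", "average", "ward", "centroid", "median",
             "weighted")


@dataclass(frozen=True)
class Preprocessing:
    """Column preprocessing: centering plus 'pareto' | 'uv' | 'none' scaling."""

    center: bool = True
    scaling: str = "pareto"

    def __post_init__(self) -> None:
        if self.scaling not in ("pareto", "uv", "none"):
            raise ValueError("scaling must be 'pareto', 'uv' or 'none'")


def _as_X(matrix) -> tuple[np.ndarray, list[str] | None]:
    """Accept a FeatureMatrix (features x samples) or array (samples x features)."""
    if isinstance(matrix, FeatureMatrix):
        return matrix.values.T.copy(), list(matrix.sample_ids)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D samples x features array")
    return x.copy(), None


def log_transform(matrix):
    """log10(1 + x) intensity transform (zeros map to zero).

    Ion counts are log-normal, so the multivariate stages model
    log-intensities; this stabilizes per-feature variance across the several
    orders of magnitude an FT-ICR intensity scale spans.  Accepts and returns
    the same container type as the modeling functions.
    """
    if isinstance(matrix, FeatureMatrix):
        out = FeatureMatrix(feature_mzs=matrix.feature_mzs.copy(),
                            sample_ids=list(matrix.sample_ids),
                            values=np.log10(1.0 + matrix.values),
                            provenance=matrix.provenance,
                            sample_meta=matrix.sample_meta)
        return out
    return np.log10(1.0 + np.asarray(matrix, dtype=float))


def filter_prevalence(matrix: FeatureMatrix, min_prevalence: float = 0.5
                      ) -> tuple[FeatureMatrix, np.ndarray]:
    """Drop features present (> 0) in fewer than ``min_prevalence`` of samples.

    Direct-infusion datasets carry many single-sample peaks (chemical noise);
    multivariate modeling considers only features observed in a majority of
    profiles.  Returns the filtered matrix and the kept feature indices.
    """
    prev = (matrix.values > 0).mean(axis=1)
    keep = np.nonzero(prev >= min_prevalence)[0]
    drop = np.nonzero(prev < min_prevalence)[0]
    return matrix.drop_features(drop), keep


def impute_half_min(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace zeros by half the feature's minimum positive intensity.

    The conventional missing-value treatment for peak intensities below the
    detection limit; features that are all-zero stay zero.
    """
    values = matrix.values.copy()
    for i in range(values.shape[0]):
        row = values[i]
        pos = row[row > 0]
        if len(pos) and (row == 0).any():
            row[row == 0] = pos.min() / 2.0
    return FeatureMatrix(feature_mzs=matrix.feature_mzs.copy(),
                         sample_ids=list(matrix.sample_ids), values=values,
                         provenance=matrix.provenance,
                         sample_meta=matrix.sample_meta)


def preprocess(X: np.ndarray, prep: Preprocessing = Preprocessing()
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns; returns (X_scaled, means, scales)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0) if prep.center else np.zeros(X.shape[1])
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    if prep.scaling == "pareto":
        scales = np.sqrt(np.where(sd > 0, sd, 1.0))
    elif prep.scaling == "uv":
        scales = np.where(sd > 0, sd, 1.0)
    else:
        scales = np.ones(X.shape[1])
    return (X - means) / scales, means, scales


@dataclass
class PCAResult:
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # features x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    sample_ids: list[str] | None = None


def pca(matrix, n_components: int = 2,
        prep: Preprocessing = Preprocessing()) -> PCAResult:
    """Principal component analysis of the preprocessed intensity matrix."""
    X, sample_ids = _as_X(matrix)
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    Xs, _, _ = preprocess(X, prep)
    rank = min(Xs.shape)
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; "
                      "truncated", stacklevel=2)
        n_components = rank
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(Xs)
    return PCAResult(scores=scores, loadings=sk.components_.T,
                     explained_variance=sk.explained_variance_,
                     explained_variance_ratio=sk.explained_variance_ratio_,
                     sample_ids=sample_ids)


@dataclass
class LatentModel:
    """A fitted PLS-DA / OPLS-DA model (two classes, y in {-1, +1})."""

    prep: Preprocessing
    classes: tuple    # (negative class, positive class)
    y: np.ndarray
    scores: np.ndarray        # samples x A (predictive)
    loadings: np.ndarray      # features x A
    weights: np.ndarray       # features x A, each column unit-norm
    y_loadings: np.ndarray    # (A,)
    ssy: np.ndarray           # per-component explained Y variance
    orth_scores: np.ndarray | None = None    # samples x n_orth
    orth_loadings: np.ndarray | None = None  # features x n_orth
    orth_weights: np.ndarray | None = None
    cov_t1: np.ndarray | None = None   # per-feature cov(t1, x_j)
    corr_t1: np.ndarray | None = None  # per-feature corr(t1, x_j)
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None
    sample_ids: list[str] | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def _encode_labels(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    if (y == 1).all() or (y == -1).all():
        raise ValueError("both classes must be non-empty")
    return y, tuple(classes)


def _pls1(Xs: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1: returns (T, P, W, c, ssy) on the already-scaled X."""
    n, p = Xs.shape
    A = min(n_components, min(n - 1, p) if n > 1 else 1)
    X = Xs.copy()
    yd = y.astype(float).copy()
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    W = np.zeros((p, A))
    c = np.zeros(A)
    ssy = np.zeros(A)
    for a in range(A):
        w = X.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            A = a
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt == 0:
            A = a
            break
        pvec = X.T @ t / tt
        ca = (yd @ t) / tt
        X = X - np.outer(t, pvec)
        yd = yd - ca * t
        T[:, a], P[:, a], W[:, a], c[a] = t, pvec, w, ca
        ssy[a] = ca ** 2 * tt
    return T[:, :A], P[:, :A], W[:, :A], c[:A], ssy[:A]


def pls_da(matrix, labels, n_components: int = 1,
           prep: Preprocessing = Preprocessing()) -> LatentModel:
    """Partial least squares discriminant analysis (two classes)."""
    X, sample_ids = _as_X(matrix)
    y, classes = _encode_labels(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match number of samples")
    Xs, means, scales = preprocess(X, prep)
    T, P, W, c, ssy = _pls1(Xs, y, n_components)
    t1 = T[:, 0]
    model = LatentModel(prep=prep, classes=classes, y=y, scores=T, loadings=P,
                        weights=W, y_loadings=c, ssy=ssy,
                        cov_t1=_cov_profile(Xs, t1),
                        corr_t1=_corr_profile(Xs, t1),
                        feature_means=means, feature_scales=scales,
                        sample_ids=sample_ids)
    return model


def opls_da(matrix, labels, n_orth: int = 1,
            prep: Preprocessing = Preprocessing()) -> LatentModel:
    """Orthogonal PLS-DA: strip ``n_orth`` Y-orthogonal components, then fit
    one predictive PLS component.

    The S-plot profiles (``cov_t1``, ``corr_t1``) relate the predictive score
    to the *preprocessed* X (before orthogonal deflation), matching the usual
    S-plot presentation.
    """
    X, sample_ids = _as_X(matrix)
    y, classes = _encode_labels(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match number of samples")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    Xs, means, scales = preprocess(X, prep)
    n, p = Xs.shape

    w = Xs.T @ y
    w /= np.linalg.norm(w)
    Xd = Xs.copy()
    To = np.zeros((n, n_orth))
    Po = np.zeros((p, n_orth))
    Wo = np.zeros((p, n_orth))
    k = 0
    for _ in range(n_orth):
        t = Xd @ w
        pvec = Xd.T @ t / (t @ t)
        w_o = pvec - (w @ pvec) * w
        nw = np.linalg.norm(w_o)
        if nw < 1e-12:
            warnings.warn("no orthogonal variation left; fewer orthogonal "
                          "components fitted", stacklevel=2)
            break
        w_o /= nw
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        To[:, k], Po[:, k], Wo[:, k] = t_o, p_o, w_o
        k += 1

    T, P, W, c, ssy = _pls1(Xd, y, 1)
    t1 = T[:, 0]
    return LatentModel(prep=prep, classes=classes, y=y, scores=T, loadings=P,
                       weights=W, y_loadings=c, ssy=ssy,
                       orth_scores=To[:, :k] if k else None,
                       orth_loadings=Po[:, :k] if k else None,
                       orth_weights=Wo[:, :k] if k else None,
                       cov_t1=_cov_profile(Xs, t1),
                       corr_t1=_corr_profile(Xs, t1),
                       feature_means=means, feature_scales=scales,
                       sample_ids=sample_ids)


def _cov_profile(Xs: np.ndarray, t: np.ndarray) -> np.ndarray:
    n = len(t)
    tc = t - t.mean()
    return (Xs - Xs.mean(axis=0)).T @ tc / (n - 1)


def _corr_profile(Xs: np.ndarray, t: np.ndarray) -> np.ndarray:
    cov = _cov_profile(Xs, t)
    sx = Xs.std(axis=0, ddof=1)
    st = t.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sx * st)
    return np.where(np.isfinite(r), r, 0.0)


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in the projection; satisfies sum(VIP^2) = p."""
    W, ssy = model.weights, model.ssy
    p = model.n_features
    denom = ssy.sum()
    if denom == 0:
        return np.zeros(p)
    return np.sqrt(p * (W ** 2 @ ssy) / denom)


def select_candidates(model: LatentModel, pct_cutoff: float = 50.0
                      ) -> np.ndarray:
    """S-plot candidate rule: both scaled |cov| and |corr| strictly above
    ``pct_cutoff`` percent of their respective maxima.

    Returns the selected feature indices (empty when covariance is all zero).
    """
    cov = np.abs(model.cov_t1)
    corr = np.abs(model.corr_t1)
    if cov.max() == 0:
        return np.array([], dtype=int)
    cov_pct = cov / cov.max() * 100.0
    corr_pct = corr / corr.max() * 100.0 if corr.max() > 0 else corr
    return np.nonzero((cov_pct > pct_cutoff) & (corr_pct > pct_cutoff))[0]


def wilcoxon_select(matrix, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature two-sided rank-sum test between the two groups.

    Exact p-values for small untied samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).  Returns a DataFrame
    with ``p``, BH ``q`` and the ``selected`` flag (raw p < alpha).
    """
    X, _ = _as_X(matrix)
    labels = np.asarray(labels)
    y, classes = _encode_labels(labels)
    a_idx, b_idx = y < 0, y > 0
    if a_idx.sum() < 3 or b_idx.sum() < 3:
        warnings.warn("group size < 3: rank-sum test has essentially no power",
                      stacklevel=2)
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        a, b = X[a_idx, j], X[b_idx, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[j] = 1.0
            continue
        pvals[j] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"p": pvals, "q": q, "selected": pvals < alpha})


def hca(matrix, method: str = "ward", metric: str = "euclidean",
        prep: Preprocessing | None = Preprocessing()) -> np.ndarray:
    """Agglomerative clustering of samples; returns a scipy linkage matrix."""
    X, _ = _as_X(matrix)
    if X.shape[0] < 2:
        raise ValueError("HCA needs >= 2 samples")
    if method not in _LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {_LINKAGES}")
    if prep is not None:
        X, _, _ = preprocess(X, prep)
    return _scipy_linkage(X, method=method, metric=metric)


def discriminative_features(matrix, labels, n_orth: int = 1,
                            vip_threshold: float = 1.0,
                            pct_cutoff: float = 50.0, alpha: float = 0.05,
                            prep: Preprocessing = Preprocessing(),
                            log: bool = True,
                            min_prevalence: float = 0.5,
                            impute: bool = True) -> dict:
    """The full discriminative-metabolite call for a two-class contrast.

    Pipeline: prevalence filter (features in >= ``min_prevalence`` of
    samples), half-minimum imputation of remaining zeros, log10 transform,
    then an OPLS-DA fit; the three selection rules — VIP >=
    ``vip_threshold``, both scaled |cov| and |corr| above ``pct_cutoff``%,
    and Wilcoxon raw p < ``alpha`` — are intersected.  Returns the model, the
    three individual sets and their intersection (all as indices into the
    *input* matrix), plus the per-group split (which class each selected
    feature is elevated in, from the sign of its covariance with the
    predictive score).
    """
    kept = None
    if isinstance(matrix, FeatureMatrix):
        if min_prevalence > 0:
            matrix, kept = filter_prevalence(matrix, min_prevalence)
        if impute:
            matrix = impute_half_min(matrix)
    data = log_transform(matrix) if log else matrix
    model = opls_da(data, labels, n_orth=n_orth, prep=prep)
    vips = vip(model)
    vip_set = set(np.nonzero(vips >= vip_threshold)[0].tolist())
    splot_set = set(select_candidates(model, pct_cutoff=pct_cutoff).tolist())
    wtab = wilcoxon_select(data, labels, alpha=alpha)
    wilcoxon_set = set(np.nonzero(wtab["selected"].to_numpy())[0].tolist())
    selected = sorted(vip_set & splot_set & wilcoxon_set)
    # positive covariance with t1 -> elevated where y = +1 (classes[1])
    neg_cls, pos_cls = model.classes
    sign_to_class = {True: pos_cls, False: neg_cls}
    # orient t1 so that it correlates positively with y
    t1 = model.scores[:, 0]
    flip = np.corrcoef(t1, model.y)[0, 1] < 0
    per_group = {neg_cls: [], pos_cls: []}
    for j in selected:
        up = model.cov_t1[j] > 0
        if flip:
            up = not up
        per_group[sign_to_class[bool(up)]].append(j)
    if kept is not None:
        remap = {local: int(orig) for local, orig in enumerate(kept)}
        vip_set = {remap[j] for j in vip_set}
        splot_set = {remap[j] for j in splot_set}
        wilcoxon_set = {remap[j] for j in wilcoxon_set}
        selected = sorted(remap[j] for j in selected)
        per_group = {g: [remap[j] for j in js] for g, js in per_group.items()}
    return {"model": model, "vip": vips, "vip_set": vip_set,
            "splot_set": splot_set, "wilcoxon": wtab,
            "wilcoxon_set": wilcoxon_set, "selected": selected,
            "per_group": per_group, "kept_features": kept}


def _cv_q2(Xs: np.ndarray, y: np.ndarray, n_folds: int, rng) -> float:
    """Cross-validated Q2 of a 1-component PLS-DA (predict held-out y)."""
    n = len(y)
    n_folds = min(n_folds, n)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    press, ssy_tot = 0.0, float(((y - y.mean()) ** 2).sum())
    for fold in folds:
        train = np.setdiff1d(idx, fold)
        if len(np.unique(y[train])) < 2:
            return -np.inf
        T, P, W, c, _ = _pls1(Xs[train], y[train], 1)
        if W.shape[1] == 0:
            return -np.inf
        t_new = Xs[fold] @ W[:, 0]
        y_hat = c[0] * t_new
        press += float(((y[fold] - y_hat) ** 2).sum())
    return 1.0 - press / ssy_tot


def cluster_support(matrix, labels, q2_threshold: float = 0.4,
                    n_permutations: int = 200, n_folds: int = 7,
                    alpha: float = 0.05, seed: int = 0,
                    prep: Preprocessing = Preprocessing()) -> dict:
    """Statistical support for a sample partition via cross-validated PLS-DA.

    A partition is *supported* when the 7-fold cross-validated Q2 of a
    1-component PLS-DA predicting the cluster labels reaches
    ``q2_threshold`` and a label-permutation test (Q2 of permuted labels
    >= observed, with the +1 rule) gives p < ``alpha``.  Multi-cluster
    partitions are assessed one-vs-rest; the worst (lowest Q2 / highest p)
    cluster decides.
    """
    X, _ = _as_X(matrix)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 clusters to assess support")
    Xs, _, _ = preprocess(X, prep)
    rng = np.random.default_rng(seed)

    contrasts = []
    if len(classes) == 2:
        contrasts.append(np.where(labels == classes[1], 1.0, -1.0))
    else:
        for cl in classes:
            yy = np.where(labels == cl, 1.0, -1.0)
            if 0 < (yy == 1).sum() < len(yy):
                contrasts.append(yy)

    q2s, pvals = [], []
    for y in contrasts:
        q2 = _cv_q2(Xs, y, n_folds, rng)
        n_ge = 0
        for _ in range(n_permutations):
            q2p = _cv_q2(Xs, rng.permutation(y), n_folds, rng)
            if q2p >= q2:
                n_ge += 1
        q2s.append(q2)
        pvals.append((n_ge + 1) / (n_permutations + 1))
    q2_min, p_max = float(min(q2s)), float(max(pvals))
    return {"q2": q2_min, "p_permutation": p_max,
            "per_contrast_q2": [float(v) for v in q2s],
            "per_contrast_p": [float(v) for v in pvals],
            "supported": bool(q2_min >= q2_threshold and p_max < alpha)}
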