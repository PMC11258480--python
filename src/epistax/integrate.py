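"""Cross-dataset normalization, unwanted-variation removal and global comparisons.

Counts are upper-quartile normalized and log-transformed (a regularized-log
stand-in, log2(normalized + 1)); unwanted variation is estimated from in-silico
empirical negative-control features (nominal p above threshold in every
contrast) by SVD and regressed out, RUVg-style.  Corrected panels feed a
classical (Torgerson) MDS of the most variable features, Pearson correlation
panels ordered by hierarchical clustering, and exclusive-intersection (UpSet)
overlap counts of DEG sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .diffexpr import ContrastResult, estimate_size_factors
from .simulate import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressionPanel:
    """Regularized-log expression values with correction bookkeeping."""

    values: pd.DataFrame  # features x samples, log2 scale
    sample_meta: pd.DataFrame | None = None
    k_removed: int = 0
    control_features: set = field(default_factory=set)


@dataclass
class ComparisonMatrix:
    """Symmetric Pearson correlation matrix with a clustering display order."""

    labels: list[str]
    r: pd.DataFrame
    order: list[str]


def empirical_controls(contrasts: list[ContrastResult], p_threshold: float = 0.1) -> set:
    """Features with nominal p > p_threshold in every supplied contrast.

    These act as in-silico empirical negative controls for unwanted-variation
    estimation: features no contrast moved are assumed to vary only with
    nuisance factors.
    """
    if not contrasts:
        raise ValueError("need at least one contrast")
    controls: set | None = None
    for res in contrasts:
        ok = {f for f, p in zip(res.feature_ids, res.p) if p > p_threshold}
        controls = ok if controls is None else controls & ok
    if not controls:
        raise ValueError(
            f"empty control set at p > {p_threshold}; loosen the threshold"
        )
    return controls


class RUVCorrector(BaseEstimator, TransformerMixin):
    """Remove k unwanted-variation factors estimated from control features.

    Factors are the top-k right singular vectors of the centered control-gene
    submatrix of the log expression panel (samples in columns); every
    feature's log expression is regressed on them and the fitted component is
    subtracted.  Follows the sklearn transformer contract on arrays shaped
    (n_samples, n_features).

    Parameters
    ----------
    k : int, default 1
        Number of unwanted factors to remove.  ``k=0`` is the identity.
    control_idx : array-like of int, optional
        Column indices (features) used as negative controls.  Required when
        ``k > 0``.

    Attributes
    ----------
    factors_ : ndarray of shape (n_samples, k)
        Estimated unwanted-variation factors.
    """

    def __init__(self, k: int = 1, control_idx=None):
        self.k = k
        self.control_idx = control_idx

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.k == 0:
            self.factors_ = np.zeros((X.shape[0], 0))
            return self
        if self.control_idx is None or len(self.control_idx) == 0:
            raise ValueError("control_idx required when k > 0")
        ctrl = X[:, np.asarray(self.control_idx, int)]
        if self.k > min(ctrl.shape):
            raise ValueError(
                f"k={self.k} exceeds min(n_samples, n_controls)={min(ctrl.shape)}"
            )
        centered = ctrl - ctrl.mean(axis=0, keepdims=True)
        if not np.any(centered):
            self.factors_ = np.zeros((X.shape[0], self.k))
            return self
        # SVD of samples x controls: left singular vectors span sample-space
        # nuisance directions (the "right" vectors of the controls-x-samples
        # orientation)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        self.factors_ = u[:, : self.k] * s[: self.k]
        return self

    def transform(self, X):
        check_is_fitted(self, "factors_")
        X = np.asarray(X, float)
        w = self.factors_
        if w.shape[1] == 0 or not np.any(w):
            return X.copy()
        centered = X - X.mean(axis=0, keepdims=True)
        coef, *_ = np.linalg.lstsq(w, centered, rcond=None)
        return X - w @ coef


def regularized_log(counts: CountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(upper-quartile-normalized count + 1): the monotone rlog stand-in."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    return np.log2(counts.counts / size_factors + 1.0)


def remove_unwanted_variation(
    counts: CountMatrix, controls, k: int = 1
) -> ExpressionPanel:
    """Upper-quartile normalize, log-transform and remove k nuisance factors.

    ``controls`` is the identifier set of empirical negative-control
    features; ``k=0`` returns the normalized log panel unchanged.
    """
    log_panel = regularized_log(counts)
    controls = set(controls) if controls is not None else set()
    if k > 0 and not controls:
        raise ValueError("controls must be nonempty when k > 0")
    ctrl_idx = [i for i, f in enumerate(log_panel.index) if f in controls]
    corrector = RUVCorrector(k=k, control_idx=ctrl_idx)
    corrected = corrector.fit_transform(log_panel.to_numpy().T).T
    return ExpressionPanel(
        values=pd.DataFrame(corrected, index=log_panel.index, columns=log_panel.columns),
        sample_meta=counts.sample_meta,
        k_removed=k,
        control_features=controls,
    )


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared Euclidean distance matrix and embeds samples
    on the top eigenvectors; exact for distance matrices of Euclidean origin.

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimensionality.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_samples, n_components)
        Origin-centered coordinates.
    eigenvalues_ : ndarray
        Eigenvalues of the doubly centered Gram matrix, descending.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None, dissimilarity: str = "euclidean"):
        X = np.asarray(X, float)
        n = X.shape[0]
        if self.n_components >= n:
            raise ValueError("n_components must be < number of samples")
        if dissimilarity == "precomputed":
            d = X
        else:
            d = squareform(pdist(X, metric="euclidean"))
        j = np.eye(n) - np.ones((n, n)) / n
        gram = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh(gram)
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]
        lam = np.clip(evals[: self.n_components], 0.0, None)
        self.eigenvalues_ = evals
        self.embedding_ = evecs[:, : self.n_components] * np.sqrt(lam)
        return self

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).embedding_


def mds_embed(panel: ExpressionPanel, n_top: int = 500, dims: int = 2) -> pd.DataFrame:
    """Embed samples by classical MDS on the most variable features.

    The ``n_top`` features with the largest across-sample variance of the
    transformed values are kept (all features, with a logged notice, if fewer
    exist); coordinates are centered at the origin.
    """
    values = panel.values
    if values.shape[0] < n_top:
        logger.info(
            "only %d features available for MDS (requested top %d); using all",
            values.shape[0], n_top,
        )
        top = values
    else:
        variances = values.var(axis=1)
        top = values.loc[variances.sort_values(ascending=False).index[:n_top]]
    coords = ClassicalMDS(n_components=dims).fit_transform(top.to_numpy().T)
    return pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )


def correlation_panel(profiles: pd.DataFrame | dict) -> ComparisonMatrix:
    """Pairwise Pearson correlation of perturbation effect profiles.

    ``profiles`` maps perturbation name -> beta vector on a shared feature
    universe (or a features x perturbations DataFrame).  Correlations use the
    intersection of finite entries per pair; hierarchical clustering (average
    linkage on 1 - r) supplies the display order.
    """
    if isinstance(profiles, dict):
        profiles = pd.DataFrame(profiles)
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    for name in profiles.columns:
        col = profiles[name].to_numpy(float)
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.var(finite) == 0:
            raise ValueError(f"profile {name!r} has zero variance")

    labels = list(profiles.columns)
    k = len(labels)
    r = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        a = profiles.iloc[:, i].to_numpy(float)
        b = profiles.iloc[:, j].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        r[i, j] = r[j, i] = np.corrcoef(a[ok], b[ok])[0, 1]
    rdf = pd.DataFrame(r, index=labels, columns=labels)

    condensed = squareform(1.0 - r, checks=False)
    order = [labels[i] for i in leaves_list(average(condensed))]
    return ComparisonMatrix(labels=labels, r=rdf, order=order)


def overlap_counts(deg_sets: dict) -> pd.DataFrame:
    """Exclusive-intersection (UpSet) counts over a family of DEG sets.

    For every nonempty combination of set names, counts the features that
    belong to exactly that combination; the counts sum to the union size.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(deg_sets)
    membership: dict[str, tuple] = {}
    for feat in set().union(*deg_sets.values()):
        membership[feat] = tuple(n for n in names if feat in deg_sets[n])
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            count = sum(1 for m in membership.values() if m == combo)
            rows.append({"combination": "&".join(combo), "degree": r, "count": count})
    return pd.DataFrame(rows)
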