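"""Motif-class separation of RTK interactomes via neighborhood component
analysis (NCA) and a permutation-calibrated relative-distance statistic.

Given a baits x preys feature matrix and a binary motif-class label per
bait, NCA learns a linear transform that favours same-class nearest
neighbours.  Cluster separation is summarised by the ratio of the mean
within-class pairwise distance to the mean between-class pairwise distance
(< 1 means classes are tighter than their surroundings).  Significance
comes from re-running the full pipeline on label permutations and reading
the lower tail of an Epanechnikov-KDE fit to the null ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NeighborhoodComponentsAnalysis
from sklearn.preprocessing import StandardScaler

from ._stats import EpanechnikovKDE


@dataclass
class PermutationTestResult:
    observed_ratio: float
    null_ratios: np.ndarray
    p: float
    seed: int
    n_perm: int


def _validate(matrix, labels):
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("matrix rows must match labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    return X, y


def nca_transform(matrix, labels, n_components: int = 2, seed: int = 0,
                  standardize: bool = True, max_iter: int = 50):
    """Supervised linear embedding by neighborhood component analysis.

    Missing values are zero-filled (zero = not detected) and features are
    scaled to unit variance before fitting, so high-abundance preys do not
    dominate.  Degenerate input for which the fit fails falls back to an
    identity (truncated) projection with a warning.
    """
    X, y = _validate(matrix, labels)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    X = np.nan_to_num(X, nan=0.0)
    if standardize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns
            X = StandardScaler(with_mean=True).fit_transform(X)
        X = np.nan_to_num(X, nan=0.0)
    nca = NeighborhoodComponentsAnalysis(
        n_components=n_components, init="pca", random_state=seed,
        max_iter=max_iter,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return nca.fit_transform(X, y)
    except Exception:
        warnings.warn("NCA fit failed; falling back to identity transform")
        return X[:, :n_components]


def relative_distance(embedded, labels) -> float:
    """Mean within-class / mean between-class pairwise Euclidean distance.

    Scale-invariant; defined as 1.0 when all points coincide (no structure).
    """
    X = np.asarray(embedded, dtype=float)
    y = np.asarray(labels)
    for c in np.unique(y):
        if np.sum(y == c) < 2:
            raise ValueError("each class needs >= 2 members for within-distance")
    d = squareform(pdist(X))
    same = y[:, None] == y[None, :]
    iu = np.triu_indices_from(d, k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if between.size == 0 or between.mean() == 0:
        return 1.0
    return float(within.mean() / between.mean())


def permutation_pvalue(matrix, labels, n_perm: int = 1000, seed: int = 0,
                       n_components: int = 2, refit: bool = True,
                       max_iter: int = 50) -> PermutationTestResult:
    """Permutation test of motif-class separation in interactome space.

    Class labels are shuffled preserving class sizes; for each permutation
    the full pipeline (NCA fit, then relative distance) is re-run by default
    (``refit=False`` keeps the transform fitted on the true labels and only
    re-scores).  The observed ratio's lower-tail probability is read from an
    Epanechnikov-KDE CDF over the null ratios and floored at 1/(n_perm+1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X, y = _validate(matrix, labels)
    rng = np.random.default_rng(seed)

    def _ratio(labs, fit_seed, transform=None):
        if transform is None:
            emb = nca_transform(X, labs, n_components, seed=fit_seed,
                                max_iter=max_iter)
        else:
            emb = transform
        return relative_distance(emb, labs)

    observed_emb = nca_transform(X, y, n_components, seed=seed,
                                 max_iter=max_iter)
    observed = relative_distance(observed_emb, y)

    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y)
        if refit:
            null[b] = _ratio(perm, fit_seed=int(rng.integers(2**31 - 1)))
        else:
            null[b] = relative_distance(observed_emb, perm)
    kde = EpanechnikovKDE(null, bandwidth="auto")
    p = max(float(kde.cdf(observed)), 1.0 / (n_perm + 1))
    return PermutationTestResult(
        observed_ratio=observed, null_ratios=null, p=p, seed=seed,
        n_perm=n_perm,
    )
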