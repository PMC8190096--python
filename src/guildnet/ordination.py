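"""Hellinger transform, Bray-Curtis distances, PCoA and PERMANOVA.

Community matrices here follow the vegan convention: rows are plots
(samples), columns taxa. The Hellinger transform (square root of relative
abundances) tempers the influence of dominant taxa before Bray-Curtis
dissimilarity; principal coordinate analysis embeds the distance matrix via
eigendecomposition of the Gower-centered squared distances; PERMANOVA tests
group differences with a pseudo-F statistic under label permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import InsufficientDesignError

logger = logging.getLogger(__name__)


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Square root of row-relative abundances; zero-total rows are dropped.

    Each retained row's squared entries sum to one.
    """
    totals = counts.sum(axis=1)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("hellinger: dropping %d zero-total plots: %s", len(zero), list(zero))
        counts = counts.drop(index=zero)
        totals = totals.drop(index=zero)
    return np.sqrt(counts.div(totals, axis=0))


@dataclass
class DistanceMatrix:
    """Symmetric plot-by-plot distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        finite = v[np.isfinite(v)]
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (finite < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis(X: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = sum|x_a - x_b| / sum(x_a + x_b).

    Entries lie in [0, 1] for non-negative data; a pair of all-zero rows has
    an undefined distance (NaN, recorded in ``undefined_pairs``).
    """
    arr = X.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    d = squareform(pdist(arr, metric="braycurtis"))
    ids = list(X.index)
    undefined = []
    zero_rows = np.nonzero(arr.sum(axis=1) == 0)[0]
    for a in zero_rows:
        for b in zero_rows:
            if a < b:
                d[a, b] = d[b, a] = np.nan
                undefined.append((ids[a], ids[b]))
    if undefined:
        logger.warning("bray_curtis: %d all-zero row pairs have undefined distance",
                       len(undefined))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, values=d, undefined_pairs=undefined)


@dataclass
class OrdinationResult:
    """Principal coordinates with eigenvalue bookkeeping."""

    coordinates: pd.DataFrame  # plots x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def pcoa(D: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Gower double-centering ``B = -1/2 J D^2 J`` with ``J = I - 11'/n``, then
    eigendecomposition; coordinates are eigenvectors scaled by the square
    root of the positive eigenvalues (negative eigenvalues, which arise for
    non-Euclidean dissimilarities like Bray-Curtis, are discarded and
    counted). Proportions explained are relative to the positive-eigenvalue
    total.
    """
    d = D.values
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    n_neg = int((eigval < -tol).sum())
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    if k is not None:
        if k > coords.shape[1]:
            logger.warning("pcoa: requested %d axes, only %d positive; truncating",
                           k, coords.shape[1])
        coords = coords[:, :k]
        lam_out = lam[: coords.shape[1]]
    else:
        lam_out = lam
    frame = pd.DataFrame(
        coords, index=D.ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(
        coordinates=frame,
        eigenvalues=lam_out,
        proportion_explained=lam_out / lam.sum() if lam.sum() > 0 else lam_out,
        n_negative_eigenvalues=n_neg,
    )


class PCoA(BaseEstimator, TransformerMixin):
    """Sklearn-style principal coordinate analysis.

    ``fit_transform`` takes a :class:`DistanceMatrix` (or square ndarray) and
    returns the coordinate array; fitted attributes mirror
    :class:`OrdinationResult`.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "PCoA":
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        if not isinstance(X, DistanceMatrix):
            X = np.asarray(X, dtype=float)
            X = DistanceMatrix(ids=[str(i) for i in range(X.shape[0])], values=X)
        res = pcoa(X, k=self.n_components)
        self.coordinates_ = res.coordinates
        self.eigenvalues_ = res.eigenvalues
        self.proportion_explained_ = res.proportion_explained
        self.n_negative_eigenvalues_ = res.n_negative_eigenvalues
        return res.coordinates.to_numpy()


@dataclass
class PermanovaResult:
    """Single-factor PERMANOVA outcome."""

    factor: str
    pseudo_f: float
    r2: float
    p_value: float
    n_perm: int
    seed: int
    n_groups: int
    n: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_among / ss_total
    return f, r2


def permanova(
    D: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    factor: str = "factor",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F partitions the sum of squared distances into among- and
    within-group components; the p-value is the add-one-corrected share of
    label permutations with F at least the observed value.
    """
    labels = pd.Series(list(labels))
    codes, groups = labels.factorize()
    n_groups = len(groups)
    if n_groups < 2:
        raise InsufficientDesignError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(groups[i]) for i in np.nonzero(sizes < 2)[0]]
        raise InsufficientDesignError(f"groups with < 2 members: {small}")
    d2 = D.values**2
    if np.isnan(d2).any():
        raise ValueError("distance matrix contains undefined entries")
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(codes), n_groups)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return PermanovaResult(
        factor=factor,
        pseudo_f=float(f_obs),
        r2=float(r2),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        n_groups=n_groups,
        n=len(labels),
    )
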