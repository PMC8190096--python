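"""Compositional correlation estimation (SparCC) with bootstrap significance.

Sequence counts are compositional: only relative abundances are observed, so
naive correlations of proportions are biased. SparCC works from the variances
of pairwise log-ratios, which are invariant to each sample's total. Writing
``t_ij = Var(log(x_i/x_j))`` and assuming most pairs of taxa are effectively
uncorrelated (sparsity), the per-taxon basis variances ``omega`` solve the
linear system

    [(p - 2) I + 1 1'] omega = rowsums(T)

and correlations follow as ``rho_ij = (omega_i + omega_j - t_ij) /
(2 sqrt(omega_i omega_j))``. Pairs whose estimated |rho| exceeds a threshold
violate the sparsity assumption and are iteratively excluded from the system
(their t_ij removed, the system re-solved), up to a maximum number of
exclusions. Significance comes from bootstrap resampling of plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import GenusGuildConflictError, MethodAssumptionError, SolverError
from .guilds import TARGET_CLASSES

logger = logging.getLogger(__name__)

OMEGA_FLOOR = 1e-10


@dataclass
class GenusTable:
    """Genus x plot counts, each genus tagged with its guild class."""

    counts: pd.DataFrame
    guilds: pd.Series  # genus -> guild class

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.guilds.index):
            self.guilds = self.guilds.reindex(self.counts.index)
        if self.counts.index.duplicated().any():
            raise ValueError("genus names must be unique")


def aggregate_by_genus(counts: pd.DataFrame, assignments: pd.DataFrame) -> GenusTable:
    """Sum taxon counts to genus level, keeping only guild-assigned genera.

    Only taxa with class AMF / PATHOGEN / SAPROTROPH are retained; a genus
    whose taxa map to two different guild classes raises
    :class:`GenusGuildConflictError`.
    """
    ass = assignments.set_index("taxon_id")
    keep = ass[ass["guild_class"].isin(TARGET_CLASSES)]
    keep = keep[keep.index.isin(counts.index)]
    if keep.empty:
        logger.warning("aggregate_by_genus: no guild-assigned taxa; empty table")
        return GenusTable(
            counts=pd.DataFrame(index=pd.Index([], name="genus"), columns=counts.columns),
            guilds=pd.Series(dtype=object),
        )
    per_genus = keep.groupby("genus")["guild_class"].nunique()
    conflicts = per_genus[per_genus > 1].index.tolist()
    if conflicts:
        raise GenusGuildConflictError(f"genera mapped to multiple guilds: {conflicts}")
    sub = counts.loc[keep.index]
    agg = sub.groupby(keep["genus"]).sum()
    agg.index.name = "genus"
    guilds = keep.groupby("genus")["guild_class"].first().reindex(agg.index)
    return GenusTable(counts=agg, guilds=guilds)


def estimate_fractions(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Posterior-mean relative abundances per plot.

    ``fraction_ij = (count_ij + pseudocount) / (total_j + p * pseudocount)``
    so each plot's fractions sum to one and zeros stay strictly positive.
    Requires at least 4 genera and 4 plots (the sparsity argument behind the
    basis-variance system needs p >= 4).
    """
    counts = np.asarray(counts, dtype=float)
    p, n = counts.shape
    if p < 4:
        raise MethodAssumptionError(f"need >= 4 genera for SparCC, have {p}")
    if n < 4:
        raise MethodAssumptionError(f"need >= 4 plots for SparCC, have {n}")
    totals = counts.sum(axis=0)
    return (counts + pseudocount) / (totals + p * pseudocount)


def logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix of pairwise log-ratio variances t_ij = Var(log f_i - log f_j).

    Sample variance over plots (denominator n-1); symmetric with zero diagonal.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[1] < 2:
        raise MethodAssumptionError("need >= 2 plots for a variance")
    logf = np.log(fractions)
    cov = np.cov(logf, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_variances(
    t_matrix: np.ndarray, excluded_pairs: tuple[tuple[int, int], ...] = ()
) -> np.ndarray:
    """Solve the SparCC basis-variance system, honoring excluded pairs.

    For each excluded pair (i, j): t_ij is removed from rows i and j of the
    right-hand side, M_ij = M_ji = 0, and M_ii, M_jj drop by one. Solutions
    are floored at a small positive value (logged when clipping occurs).
    """
    t = np.asarray(t_matrix, dtype=float)
    p = t.shape[0]
    m = np.full((p, p), 1.0) + (p - 2.0) * np.eye(p)
    rhs = t.sum(axis=1)
    for i, j in excluded_pairs:
        rhs[i] -= t[i, j]
        rhs[j] -= t[i, j]
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
    try:
        omega = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise SolverError(
            "basis-variance system is singular; try fewer exclusions"
        ) from exc
    n_clip = int((omega < OMEGA_FLOOR).sum())
    if n_clip:
        logger.debug("basis_variances: %d variances clipped to floor", n_clip)
    return np.maximum(omega, OMEGA_FLOOR)


def _rho_from(omega: np.ndarray, t: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class SparccResult:
    """Output of a SparCC correlation run."""

    genera: list[str]
    rho: np.ndarray
    omega: np.ndarray
    t_matrix: np.ndarray
    excluded_pairs: list[tuple[int, int]]
    p_values: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.genera, columns=self.genera)

    def pvalue_frame(self) -> pd.DataFrame:
        if self.p_values is None:
            raise ValueError("p-values not computed (n_boot=0)")
        return pd.DataFrame(self.p_values, index=self.genera, columns=self.genera)


def _correlations_from_counts(
    counts: np.ndarray,
    pseudocount: float,
    exclusion_threshold: float,
    max_exclusions: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    frac = estimate_fractions(counts, pseudocount)
    t = logratio_variances(frac)
    excluded: list[tuple[int, int]] = []
    frozen_rho: dict[tuple[int, int], float] = {}
    omega = basis_variances(t)
    rho = _rho_from(omega, t)
    while len(excluded) < max_exclusions:
        mask = np.abs(rho.copy())
        np.fill_diagonal(mask, 0.0)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(mask), mask.shape)
        if mask[i, j] <= exclusion_threshold:
            break
        pair = (min(i, j), max(i, j))
        excluded.append(pair)
        try:
            omega_new = basis_variances(t, tuple(excluded))
        except SolverError:
            # one more exclusion would degenerate the system; stop here
            excluded.pop()
            logger.debug("exclusion of pair %s would make the system singular; stopping", pair)
            break
        frozen_rho[pair] = rho[i, j]  # excluded pairs keep their last estimate
        omega = omega_new
        rho = _rho_from(omega, t)
    for (i, j), r in frozen_rho.items():
        rho[i, j] = rho[j, i] = r
    return rho, omega, t, excluded


def sparcc_correlations(
    gt: GenusTable | pd.DataFrame,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> SparccResult:
    """SparCC correlations with iterative strong-pair exclusion (no p-values)."""
    counts = gt.counts if isinstance(gt, GenusTable) else gt
    rho, omega, t, excluded = _correlations_from_counts(
        counts.to_numpy(), pseudocount, exclusion_threshold, max_exclusions
    )
    return SparccResult(
        genera=list(counts.index),
        rho=rho,
        omega=omega,
        t_matrix=t,
        excluded_pairs=excluded,
        params={
            "pseudocount": pseudocount,
            "exclusion_threshold": exclusion_threshold,
            "max_exclusions": max_exclusions,
        },
    )


def bootstrap_pvalues(
    gt: GenusTable | pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> np.ndarray:
    """Two-sided bootstrap p-values for SparCC correlations.

    Plots are resampled with replacement ``n_boot`` times and the full
    correlation estimate recomputed each time. With ``q- = (1 + #{rho <= 0}) /
    (n_boot + 1)`` and ``q+ = (1 + #{rho >= 0}) / (n_boot + 1)``, the p-value
    is ``min(1, 2 min(q-, q+))``; the add-one correction keeps p strictly
    positive on either tail. Deterministic given ``seed``.
    """
    if n_boot < 20:
        raise MethodAssumptionError("n_boot must be >= 20")
    counts = (gt.counts if isinstance(gt, GenusTable) else gt).to_numpy()
    p, n = counts.shape
    rng = np.random.default_rng(seed)
    n_le = np.zeros((p, p))
    n_ge = np.zeros((p, p))
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rho_b, _, _, _ = _correlations_from_counts(
            counts[:, idx], pseudocount, exclusion_threshold, max_exclusions
        )
        n_le += rho_b <= 0
        n_ge += rho_b >= 0
    q_neg = (1.0 + n_le) / (n_boot + 1.0)
    q_pos = (1.0 + n_ge) / (n_boot + 1.0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(q_neg, q_pos))
    pvals = (pvals + pvals.T) / 2.0  # symmetric by construction; guard rounding
    np.fill_diagonal(pvals, 1.0)
    return pvals


class SparCC(BaseEstimator):
    """Sklearn-style SparCC estimator.

    ``fit`` expects ``X`` with plots as rows and genera as columns (the
    sklearn samples-by-features convention; :class:`GenusTable` and other
    genus-by-plot frames are transposed internally when passed directly).

    Parameters
    ----------
    pseudocount : float, default 1.0
        Added to every count before forming fractions.
    exclusion_threshold : float, default 0.1
        |rho| above which the strongest pair is excluded from the
        basis-variance system and the system re-solved.
    max_exclusions : int, default 10
        Cap on iterative exclusions.
    n_boot : int, default 100
        Bootstrap resamples for p-values; 0 skips them.
    random_state : int, default 0
        Bootstrap seed.

    Attributes
    ----------
    rho_ : ndarray — estimated correlation matrix (diag 1, entries in [-1, 1])
    omega_ : ndarray — basis variances
    t_matrix_ : ndarray — pairwise log-ratio variances
    excluded_pairs_ : list of index pairs removed by the sparsity filter
    pvalues_ : ndarray or None — bootstrap two-sided p-values
    genera_ : list of column names
    """

    def __init__(
        self,
        pseudocount: float = 1.0,
        exclusion_threshold: float = 0.1,
        max_exclusions: int = 10,
        n_boot: int = 100,
        random_state: int = 0,
    ):
        self.pseudocount = pseudocount
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusions = max_exclusions
        self.n_boot = n_boot
        self.random_state = random_state

    def _as_genus_by_plot(self, X) -> pd.DataFrame:
        if isinstance(X, GenusTable):
            return X.counts
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X)
        return pd.DataFrame(X.T, index=[f"g{i}" for i in range(X.shape[1])])

    def fit(self, X, y=None) -> "SparCC":
        table = self._as_genus_by_plot(X)
        res = sparcc_correlations(
            table,
            pseudocount=self.pseudocount,
            exclusion_threshold=self.exclusion_threshold,
            max_exclusions=self.max_exclusions,
        )
        self.genera_ = res.genera
        self.rho_ = res.rho
        self.omega_ = res.omega
        self.t_matrix_ = res.t_matrix
        self.excluded_pairs_ = res.excluded_pairs
        if self.n_boot:
            self.pvalues_ = bootstrap_pvalues(
                table,
                n_boot=self.n_boot,
                seed=self.random_state,
                pseudocount=self.pseudocount,
                exclusion_threshold=self.exclusion_threshold,
                max_exclusions=self.max_exclusions,
            )
        else:
            self.pvalues_ = None
        return self

    def result_(self) -> SparccResult:
        return SparccResult(
            genera=self.genera_,
            rho=self.rho_,
            omega=self.omega_,
            t_matrix=self.t_matrix_,
            excluded_pairs=self.excluded_pairs_,
            p_values=self.pvalues_,
            params=self.get_params(),
        )
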