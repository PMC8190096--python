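"""Rarefaction, per-plot guild counts, ratio statistics, and treatment effects.

The ratio statistics summarize guild balance at a fixed rarefaction depth:
``P/(P + A_s)`` tracks the pathogen-to-mutualist balance and
``S/(S + P + A_s)`` the share of decomposers among guild-assigned reads
(A_s = soil AMF, P = plant pathogens, S = saprotrophs).

Treatment effects are estimated two ways, per guild and treatment:

* a site-stratified linear model on log(count + 1) with a treatment contrast
  (fixed site effects; two-sided t-test on the contrast), and
* a raw percent change: per site, the relative-abundance contrast of
  treatment vs control plot means, averaged over sites having both arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from ._exceptions import ConsistencyError, InsufficientDesignError
from .guilds import AMF, PATHOGEN, SAPROTROPH

logger = logging.getLogger(__name__)

GUILD_COLUMNS = {AMF: "A_s", PATHOGEN: "P", SAPROTROPH: "S"}


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Randomly subsample each plot to exactly ``depth`` reads without replacement.

    Plots with fewer than ``depth`` total reads are dropped (logged). Sampling
    is multivariate hypergeometric per plot, so a plot with exactly ``depth``
    reads is returned unchanged. Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.info("rarefy: dropping %d plots below depth %d: %s",
                    len(dropped), depth, list(dropped))
    out = {}
    for plot in keep:
        col = counts[plot].to_numpy(dtype=np.int64)
        out[plot] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=counts.index)
    rarefied.columns.name = counts.columns.name
    return rarefied


def guild_counts(rarefied: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-plot guild read totals A_s (AMF), P (pathogens), S (saprotrophs).

    OTHER/UNASSIGNED taxa are excluded; ``depth`` is the per-plot total of the
    rarefied table.
    """
    cls = assignments.set_index("taxon_id")["guild_class"]
    missing = rarefied.index.difference(cls.index)
    if len(missing):
        raise ConsistencyError(f"taxa in counts without assignments: {list(missing)[:5]}")
    cls = cls.reindex(rarefied.index)
    out = pd.DataFrame(index=rarefied.columns)
    out.index.name = "plot_id"
    for guild, col in GUILD_COLUMNS.items():
        out[col] = rarefied.loc[cls == guild].sum(axis=0).astype(int)
    out["depth"] = rarefied.sum(axis=0).astype(int)
    return out


def guild_ratios(gc: pd.DataFrame) -> pd.DataFrame:
    """Ratio statistics P/(P+A_s) and S/(S+P+A_s) with defined-ness flags.

    A zero denominator yields NaN with the corresponding flag set False,
    never a silent 0.
    """
    out = gc.copy()
    pm_den = out["P"] + out["A_s"]
    sap_den = out["S"] + out["P"] + out["A_s"]
    out["pm_ratio"] = np.where(pm_den > 0, out["P"] / pm_den.replace(0, np.nan), np.nan)
    out["sap_share"] = np.where(sap_den > 0, out["S"] / sap_den.replace(0, np.nan), np.nan)
    out["pm_defined"] = pm_den > 0
    out["sap_defined"] = sap_den > 0
    return out


@dataclass
class TreatmentEffect:
    """Estimated effect of one treatment on one guild, versus control."""

    guild: str
    treatment: str
    pct_change: float  # site-averaged % change in relative abundance
    log_estimate: float  # treatment contrast on log(count+1)
    ci_low: float
    ci_high: float
    p_value: float  # two-sided t on the contrast
    n_treatment: int
    n_control: int
    n_sites: int
    excluded_sites: list[str]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def treatment_effects(
    gc: pd.DataFrame,
    meta: pd.DataFrame,
    guild: str,
    treatment: str,
    control: str = "CTRL",
) -> TreatmentEffect:
    """Site-stratified treatment effect on one guild's abundance.

    ``gc`` is the per-plot guild count table (from :func:`guild_counts`),
    ``meta`` the plot metadata (plot_id, site, treatment). Requires at least
    two sites containing plots of both arms. Sites whose control mean
    relative abundance is zero are excluded from the percent-change average
    (logged), but still inform the log-scale model.
    """
    col = GUILD_COLUMNS[guild]
    df = gc.reset_index().merge(meta, on="plot_id", how="left")
    df = df[df["treatment"].isin([control, treatment])].copy()
    df["rel"] = df[col] / df["depth"]
    df["is_treat"] = (df["treatment"] == treatment).astype(int)

    both = [
        s
        for s, grp in df.groupby("site")
        if {control, treatment} <= set(grp["treatment"])
    ]
    if len(both) < 2:
        raise InsufficientDesignError(
            f"need >= 2 sites with both {control} and {treatment} arms, have {len(both)}"
        )
    df = df[df["site"].isin(both)]

    fit = smf.ols(f"np.log1p({col}) ~ C(site) + is_treat", data=df).fit()
    est = fit.params["is_treat"]
    ci = fit.conf_int().loc["is_treat"]
    pval = fit.pvalues["is_treat"]

    pct, excluded = [], []
    for site, grp in df.groupby("site"):
        mc = grp.loc[grp["is_treat"] == 0, "rel"].mean()
        mt = grp.loc[grp["is_treat"] == 1, "rel"].mean()
        if mc == 0:
            excluded.append(site)
            continue
        pct.append((mt - mc) / mc * 100.0)
    if excluded:
        logger.info("treatment_effects(%s, %s): %d sites with zero control mean excluded",
                    guild, treatment, len(excluded))
    if not pct:
        raise InsufficientDesignError("no site has a nonzero control mean")
    return TreatmentEffect(
        guild=guild,
        treatment=treatment,
        pct_change=float(np.mean(pct)),
        log_estimate=float(est),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(pval),
        n_treatment=int(df["is_treat"].sum()),
        n_control=int((1 - df["is_treat"]).sum()),
        n_sites=len(pct),
        excluded_sites=excluded,
    )
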