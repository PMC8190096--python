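"""Synthetic NutNet-like fungal community generator with planted ground truth.

Emulates the sampling design of a globally replicated grassland
nutrient-addition experiment: sites divided into blocks, one plot per
block x treatment (control, N, P, N+P), amplicon read counts per plot.
Each downstream stage of the pipeline (guild assignment, rarefaction,
treatment effects, SparCC networks, ordination) therefore has a known truth
to recover:

* a taxon -> guild map (a configurable fraction of taxa is absent from the
  guild database, mimicking the unassignable share of real ITS data),
* multiplicative treatment effects on expected per-guild relative abundance,
* a planted genus-genus correlation structure on the log scale.

Counts are drawn by sampling genus log-abundances from a multivariate normal
whose correlation is the planted block matrix, adding site- and plot-level
noise, converting to expected relative abundances, scaling guild shares by
the treatment multipliers (the "other" pool absorbs the renormalization, so
planted guild effects are exactly recoverable despite compositional closure),
splitting genera into taxa, and multinomial sampling at the raw read depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import CorrelationBlockError, InvalidDesignError
from ._seeds import stage_rng
from .guilds import AMF, OTHER, PATHOGEN, SAPROTROPH, GuildDatabase

logger = logging.getLogger(__name__)

GUILD_POOLS = (AMF, PATHOGEN, SAPROTROPH, OTHER)
TREATMENTS = ("CTRL", "N", "P", "NP")

#: multiplicative treatment effects on expected relative abundance, calibrated
#: to the headline effect sizes the pipeline should recover: pathogens x2.40
#: (+140%) and AMF x0.67 (-33%) under N+P, pathogens x1.8 under N or P alone,
#: saprotrophs unaffected.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "CTRL": {},
    "N": {PATHOGEN: 1.8},
    "P": {PATHOGEN: 1.8},
    "NP": {PATHOGEN: 2.40, AMF: 0.67, SAPROTROPH: 1.00},
}

#: expected control-plot share of reads per guild pool; "other" includes both
#: assignable non-target guilds and database-absent taxa.
DEFAULT_BASELINE_SHARES = {AMF: 0.05, PATHOGEN: 0.06, SAPROTROPH: 0.17, OTHER: 0.72}

DEFAULT_N_GENERA = {AMF: 12, PATHOGEN: 18, SAPROTROPH: 25, OTHER: 45}

_POOL_PREFIX = {AMF: "Amf", PATHOGEN: "Pat", SAPROTROPH: "Sap", OTHER: "Oth"}
_POOL_PHYLUM = {
    AMF: "Glomeromycota",
    PATHOGEN: "Ascomycota",
    SAPROTROPH: "Basidiomycota",
    OTHER: "Ascomycota",
}
_POOL_GUILD_STRINGS = {
    AMF: [("Arbuscular Mycorrhizal", "Symbiotroph")],
    PATHOGEN: [("Plant Pathogen", "Pathotroph")],
    SAPROTROPH: [("Soil Saprotroph", "Saprotroph"), ("Undefined Saprotroph", "Saprotroph")],
    OTHER: [
        ("Wood Saprotroph", "Saprotroph"),
        ("Dung Saprotroph", "Saprotroph"),
        ("Ectomycorrhizal", "Symbiotroph"),
        ("Animal Pathogen", "Pathotroph"),
        ("Fungal Parasite", "Pathotroph"),
        ("Epiphyte", "Symbiotroph"),
    ],
}


def compound_block_correlation(n: int, blocks: list[tuple[int, int, float]]) -> np.ndarray:
    """Block correlation matrix: identity plus compound-symmetric blocks.

    ``blocks`` is a list of ``(start, size, rho)``; blocks must not overlap.
    """
    corr = np.eye(n)
    used = np.zeros(n, dtype=bool)
    for start, size, rho in blocks:
        idx = np.arange(start, start + size)
        if idx[-1] >= n or used[idx].any():
            raise InvalidDesignError(f"correlation block {(start, size)} overlaps or exceeds matrix")
        used[idx] = True
        corr[np.ix_(idx, idx)] = rho
        corr[idx, idx] = 1.0
    return corr


def validate_correlation(corr: np.ndarray) -> None:
    """Check symmetry, unit diagonal and positive definiteness per block.

    Blocks are the connected components of the off-diagonal sparsity pattern;
    a non-PD block raises :class:`CorrelationBlockError` naming its indices.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise CorrelationBlockError("correlation matrix must be square")
    if not np.allclose(corr, corr.T):
        raise CorrelationBlockError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise CorrelationBlockError("correlation matrix must have unit diagonal")
    # connected components of |corr| > 0 off-diagonal
    n = corr.shape[0]
    seen = np.zeros(n, dtype=bool)
    for i in range(n):
        if seen[i]:
            continue
        comp = [i]
        stack = [i]
        seen[i] = True
        while stack:
            j = stack.pop()
            nbrs = np.nonzero((np.abs(corr[j]) > 0) & ~seen)[0]
            for k in nbrs:
                if k != j:
                    seen[k] = True
                    comp.append(k)
                    stack.append(k)
        idx = np.array(sorted(comp))
        eigs = np.linalg.eigvalsh(corr[np.ix_(idx, idx)])
        if eigs.min() <= 1e-10:
            raise CorrelationBlockError(
                f"correlation block over genera indices {idx.tolist()} is not "
                f"positive definite (min eigenvalue {eigs.min():.3g})"
            )


def default_correlation(n_genera: dict[str, int]) -> np.ndarray:
    """Planted block correlation over genera ordered (AMF, pathogen, saprotroph, other).

    Within-guild compound blocks of 4 at rho=0.6, one cross-guild block of 4
    spanning the pathogen/saprotroph boundary at rho=0.4, one negative
    saprotroph pair at rho=-0.45, and moderate blocks in the "other" pool.
    """
    offs = {}
    pos = 0
    for pool in GUILD_POOLS:
        offs[pool] = pos
        pos += n_genera[pool]
    n = pos
    blocks: list[tuple[int, int, float]] = []

    def add_within(pool: str, start_rel: int, size: int, rho: float) -> None:
        if n_genera[pool] >= start_rel + size:
            blocks.append((offs[pool] + start_rel, size, rho))

    add_within(AMF, 0, 4, 0.6)
    add_within(PATHOGEN, 0, 4, 0.6)
    add_within(PATHOGEN, 4, 4, 0.6)
    # cross-guild block: last 2 pathogen + first 2 saprotroph genera
    if n_genera[PATHOGEN] >= 10 and n_genera[SAPROTROPH] >= 2:
        blocks.append((offs[SAPROTROPH] - 2, 4, 0.4))
    add_within(SAPROTROPH, 2, 5, 0.6)
    add_within(SAPROTROPH, 7, 2, -0.45)
    add_within(OTHER, 0, 5, 0.5)
    add_within(OTHER, 5, 5, 0.5)
    corr = compound_block_correlation(n, blocks)
    validate_correlation(corr)
    return corr


@dataclass
class SimDesign:
    """Parameters of the synthetic NutNet-like experiment.

    Defaults reproduce the study conditions the pipeline is validated
    against: 25 sites x 3 blocks x 4 treatments, 2000 raw reads per plot
    (comfortably above the 485-read rarefaction depth), ~40% of taxa absent
    from the guild database, and the calibrated effect preset in
    :data:`DEFAULT_EFFECTS`.
    """

    n_sites: int = 25
    n_blocks_per_site: int = 3
    treatments: tuple[str, ...] = TREATMENTS
    raw_depth: int = 2000
    n_genera: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_GENERA))
    taxa_per_genus: int = 2
    frac_unassignable: float = 0.40
    baseline_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SHARES)
    )
    effect_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(m) for t, m in DEFAULT_EFFECTS.items()}
    )
    corr_blocks: np.ndarray | None = None  # None -> default_correlation
    genus_sd: float = 0.6
    site_sd: float = 0.5
    plot_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_sites", "n_blocks_per_site", "raw_depth", "taxa_per_genus"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be positive")
        if any(v <= 0 for v in self.n_genera.values()):
            raise InvalidDesignError("n_genera entries must be positive")
        if not 0.0 <= self.frac_unassignable < 1.0:
            raise InvalidDesignError("frac_unassignable must be in [0, 1)")
        for trt, eff in self.effect_multipliers.items():
            if any(m <= 0 for m in eff.values()):
                raise InvalidDesignError(f"multipliers for {trt} must be > 0")
        if abs(sum(self.baseline_shares.values()) - 1.0) > 1e-9:
            raise InvalidDesignError("baseline_shares must sum to 1")
        if self.corr_blocks is not None:
            validate_correlation(np.asarray(self.corr_blocks))

    @property
    def n_total_genera(self) -> int:
        return sum(self.n_genera[p] for p in GUILD_POOLS)

    @property
    def n_taxa(self) -> int:
        return self.n_total_genera * self.taxa_per_genus

    def correlation(self) -> np.ndarray:
        if self.corr_blocks is not None:
            return np.asarray(self.corr_blocks, dtype=float)
        return default_correlation(self.n_genera)

    def genus_names(self) -> tuple[list[str], list[str]]:
        """(names, pool labels) for all genera, ordered by guild pool."""
        names, pools = [], []
        for pool in GUILD_POOLS:
            for i in range(self.n_genera[pool]):
                names.append(f"{_POOL_PREFIX[pool]}gen{i + 1:02d}")
                pools.append(pool)
        return names, pools


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated count table."""

    guild_shares: pd.DataFrame  # treatment x guild expected relative abundance
    corr: np.ndarray  # planted genus correlation
    genera: list[str]
    genus_guild: pd.Series  # genus -> guild pool
    taxon_guild: pd.Series  # taxon_id -> guild pool
    expected_fractions: pd.DataFrame  # taxa x plots expected relative abundances

    def to_json(self, path) -> None:
        payload = {
            "guild_shares": {t: dict(row) for t, row in self.guild_shares.iterrows()},
            "genera": self.genera,
            "genus_guild": self.genus_guild.to_dict(),
            "taxon_guild": self.taxon_guild.to_dict(),
            "corr": np.asarray(self.corr).round(6).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _unassignable_genera(design: SimDesign, rng: np.random.Generator) -> set[str]:
    """Pick ``frac_unassignable`` of each pool's genera to omit from the database.

    Stratified per pool so the expected unassigned read share matches the
    taxon fraction; counts round to the nearest integer per pool.
    """
    names, pools = design.genus_names()
    out: set[str] = set()
    for pool in GUILD_POOLS:
        pool_names = [n for n, p in zip(names, pools) if p == pool]
        k = int(round(design.frac_unassignable * len(pool_names)))
        if k:
            out.update(rng.choice(pool_names, size=k, replace=False))
    return out


def _taxon_records(design: SimDesign) -> pd.DataFrame:
    """Taxon table: taxon_id, genus, family, pool, lineage."""
    names, pools = design.genus_names()
    rows = []
    otu = 0
    for gi, (genus, pool) in enumerate(zip(names, pools)):
        fam = f"{_POOL_PREFIX[pool]}fam{gi // 3 + 1:02d}"
        for t in range(design.taxa_per_genus):
            otu += 1
            lineage = (
                f"k__Fungi;p__{_POOL_PHYLUM[pool]};c__{_POOL_PREFIX[pool]}class;"
                f"o__{_POOL_PREFIX[pool]}ales;f__{fam};g__{genus};s__{genus}_sp{t + 1}"
            )
            rows.append(
                {
                    "taxon_id": f"OTU{otu:04d}",
                    "genus": genus,
                    "family": fam,
                    "pool": pool,
                    "lineage": lineage,
                }
            )
    return pd.DataFrame(rows)


def generate_guild_db(design: SimDesign) -> tuple[GuildDatabase, pd.DataFrame]:
    """Synthetic guild database and taxonomy table for a design.

    Every assignable genus gets exactly one record, at genus level except for
    one saprotroph family demoted to a family-level record (exercising the
    most-specific-rank matching rule). Unassignable genera appear in the
    taxonomy but not in the database. A couple of "other"-pool records carry
    the AMF guild string at Possible confidence, which the confidence filter
    must demote.
    """
    rng = stage_rng(design.seed, "guild_db")
    taxa = _taxon_records(design)
    unassignable = _unassignable_genera(design, rng)
    genus_rows = taxa.drop_duplicates("genus")

    records = []
    family_level_fams: set[str] = set()
    # demote one fully-assignable saprotroph family to a family-level record
    sap = genus_rows[genus_rows["pool"] == SAPROTROPH]
    for fam, grp in sap.groupby("family"):
        if not set(grp["genus"]) & unassignable and len(grp) > 1:
            family_level_fams.add(fam)
            break

    conf_cycle = {AMF: ["Highly Probable", "Probable"], OTHER: ["Probable", "Possible"]}
    for i, row in enumerate(genus_rows.itertuples(index=False)):
        if row.genus in unassignable:
            continue
        pool = row.pool
        strings = _POOL_GUILD_STRINGS[pool]
        guild, trophic = strings[i % len(strings)]
        confs = conf_cycle.get(pool, ["Highly Probable", "Probable", "Possible"])
        conf = confs[i % len(confs)]
        if pool == OTHER and i % 11 == 0:
            # Possible-confidence AMF annotation: must classify as OTHER
            guild, trophic, conf = "Arbuscular Mycorrhizal", "Symbiotroph", "Possible"
        if row.family in family_level_fams:
            name, level = row.family, "family"
            if any(r["taxon"] == name for r in records):
                continue
        else:
            name, level = row.genus, "genus"
        records.append(
            {
                "taxon": name,
                "taxonomicLevel": level,
                "trophicMode": trophic,
                "guild": guild,
                "confidenceRanking": conf,
            }
        )
    db = GuildDatabase(pd.DataFrame(records))
    taxonomy = taxa[["taxon_id", "lineage"]].copy()
    return db, taxonomy


def _plot_frame(design: SimDesign) -> pd.DataFrame:
    rows = []
    for s in range(1, design.n_sites + 1):
        for b in range(1, design.n_blocks_per_site + 1):
            for trt in design.treatments:
                rows.append(
                    {
                        "plot_id": f"S{s:02d}B{b}_{trt}",
                        "site": f"S{s:02d}",
                        "block": b,
                        "treatment": trt,
                    }
                )
    return pd.DataFrame(rows)


def generate_counts(design: SimDesign) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a taxa x plots count table with metadata and planted truth.

    Returns ``(counts, metadata, truth)``; identical designs (including seed)
    yield identical tables.
    """
    corr = design.correlation()
    validate_correlation(corr)
    rng = stage_rng(design.seed, "counts")
    taxa = _taxon_records(design)
    names, pools = design.genus_names()
    n_g = len(names)
    pools_arr = np.array(pools)
    meta = _plot_frame(design)
    n_plots = len(meta)

    # baseline mean log-abundance per genus: equal within a pool, set so pool
    # shares match baseline_shares on the exp scale before noise
    mu = np.empty(n_g)
    for pool in GUILD_POOLS:
        m = pools_arr == pool
        mu[m] = np.log(design.baseline_shares[pool] / design.n_genera[pool])

    chol = np.linalg.cholesky(corr)
    site_eff = rng.normal(0.0, design.site_sd, size=(design.n_sites, n_g))
    site_index = meta["site"].factorize()[0]

    # fixed within-genus taxon split (drawn once per design)
    if design.taxa_per_genus == 1:
        split = np.ones((n_g, 1))
    else:
        split = rng.dirichlet(np.full(design.taxa_per_genus, 5.0), size=n_g)

    mult_by_pool = {
        trt: np.array([design.effect_multipliers.get(trt, {}).get(p, 1.0) for p in GUILD_POOLS])
        for trt in design.treatments
    }
    pool_index = {p: i for i, p in enumerate(GUILD_POOLS)}
    pool_of_genus = np.array([pool_index[p] for p in pools])

    counts = np.zeros((design.n_taxa, n_plots), dtype=np.int64)
    expected = np.zeros_like(counts, dtype=float)
    z = rng.standard_normal((n_plots, n_g))
    plot_noise = rng.normal(0.0, design.plot_sd, size=(n_plots, n_g))
    for j in range(n_plots):
        logab = (
            mu
            + design.genus_sd * (chol @ z[j])
            + site_eff[site_index[j]]
            + plot_noise[j]
        )
        w = np.exp(logab - logab.max())
        f = w / w.sum()
        shares = np.bincount(pool_of_genus, weights=f, minlength=len(GUILD_POOLS))
        m = mult_by_pool[meta["treatment"].iloc[j]].copy()
        # the OTHER pool absorbs renormalization so target-guild shares scale
        # exactly by their multipliers (no closure bias)
        target_mass = sum(
            m[pool_index[p]] * shares[pool_index[p]] for p in (AMF, PATHOGEN, SAPROTROPH)
        )
        if target_mass >= 1.0:
            raise InvalidDesignError(
                "effect multipliers push target-guild share past 1; "
                "reduce multipliers or baseline shares"
            )
        m[pool_index[OTHER]] = (1.0 - target_mass) / shares[pool_index[OTHER]]
        f = f * m[pool_of_genus]
        f_taxa = (f[:, None] * split).ravel()
        expected[:, j] = f_taxa
        counts[:, j] = rng.multinomial(design.raw_depth, f_taxa / f_taxa.sum())

    taxon_ids = taxa["taxon_id"].tolist()
    counts_df = pd.DataFrame(counts, index=pd.Index(taxon_ids, name="taxon_id"),
                             columns=meta["plot_id"])
    expected_df = pd.DataFrame(expected, index=counts_df.index, columns=meta["plot_id"])

    shares_rows = {}
    for trt in design.treatments:
        m = mult_by_pool[trt]
        shares_rows[trt] = {
            p: design.baseline_shares[p] * m[pool_index[p]] for p in (AMF, PATHOGEN, SAPROTROPH)
        }
    guild_shares = pd.DataFrame(shares_rows).T
    truth = SimTruth(
        guild_shares=guild_shares,
        corr=corr,
        genera=names,
        genus_guild=pd.Series(pools, index=names, name="guild"),
        taxon_guild=pd.Series(taxa["pool"].to_numpy(), index=taxa["taxon_id"], name="guild"),
        expected_fractions=expected_df,
    )
    return counts_df, meta, truth


def simulate_genus_table(
    n_genera: int,
    n_plots: int,
    corr: np.ndarray | None = None,
    depth: int = 2000,
    genus_sd: float = 1.0,
    mu_sd: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Direct genus x plot count table with a planted log-scale correlation.

    A lighter-weight generator than :func:`generate_counts` for exercising the
    compositional correlation estimator: genus log-abundances are multivariate
    normal with the given correlation, then multinomially sampled per plot.
    Returns ``(table, correlation)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))
    if corr is None:
        corr = np.eye(n_genera)
    else:
        corr = np.asarray(corr, dtype=float)
        validate_correlation(corr)
    chol = np.linalg.cholesky(corr)
    mu = rng.normal(0.0, mu_sd, size=n_genera)
    counts = np.zeros((n_genera, n_plots), dtype=np.int64)
    for j in range(n_plots):
        logab = mu + genus_sd * (chol @ rng.standard_normal(n_genera))
        w = np.exp(logab - logab.max())
        counts[:, j] = rng.multinomial(depth, w / w.sum())
    genera = [f"gen{i + 1:03d}" for i in range(n_genera)]
    table = pd.DataFrame(counts, index=pd.Index(genera, name="genus"),
                         columns=[f"plot{j + 1:03d}" for j in range(n_plots)])
    return table, corr


def write_simulation(outdir, design: SimDesign) -> dict[str, Path]:
    """Run both generators and write TSV/JSON artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db, taxonomy = generate_guild_db(design)
    counts, meta, truth = generate_counts(design)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "guild_db": outdir / "guild_db.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    db.to_tsv(paths["guild_db"])
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    logger.info("simulation written to %s (%d taxa x %d plots)", outdir, *counts.shape)
    return paths
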