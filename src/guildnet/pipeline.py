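"""End-to-end pipeline: simulate/load -> assign -> rarefy -> effects ->
SparCC networks per treatment -> cross-treatment permutation tests ->
ordination + PERMANOVA, with one master seed and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._exceptions import GuildnetError, StageFailureError
from ._seeds import stage_seed_sequence
from .abundance import guild_counts, guild_ratios, rarefy, treatment_effects
from .guilds import (
    AMF,
    PATHOGEN,
    SAPROTROPH,
    TARGET_CLASSES,
    GuildDatabase,
    assign_guilds,
    assignment_summary,
)
from .networks import build_network, permtest_metric
from .ordination import bray_curtis, hellinger, pcoa, permanova
from .simulate import SimDesign, generate_counts, generate_guild_db
from .sparcc import aggregate_by_genus, bootstrap_pvalues, sparcc_correlations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either the four input paths or a ``simulate`` block must be provided.
    Defaults are the study's procedural constants: 485-read rarefaction,
    alpha 0.05, 100 bootstrap resamples, 10,000 network permutations.
    """

    out_dir: Path
    counts: Path | None = None
    taxonomy: Path | None = None
    guild_db: Path | None = None
    metadata: Path | None = None
    simulate: dict | None = None
    depth: int = 485
    alpha: float = 0.05
    n_boot: int = 100
    n_perm: int = 10_000
    n_perm_permanova: int = 999
    metrics: tuple[str, ...] = ("n_edges", "connectance", "mean_degree")
    control: str = "CTRL"
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise GuildnetError("depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise GuildnetError("alpha must be in (0, 1)")
        paths = (self.counts, self.taxonomy, self.guild_db, self.metadata)
        if self.simulate is None:
            if any(p is None for p in paths):
                raise GuildnetError(
                    "config needs either a [simulate] block or all of "
                    "counts/taxonomy/guild_db/metadata paths"
                )
            for p in paths:
                if not Path(p).exists():
                    raise GuildnetError(f"input path does not exist: {p}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs = {}
        for key in ("depth", "alpha", "n_boot", "n_perm", "n_perm_permanova",
                    "control", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "metrics" in raw:
            kwargs["metrics"] = tuple(raw["metrics"])
        for key in ("counts", "taxonomy", "guild_db", "metadata"):
            if key in raw.get("paths", {}):
                kwargs[key] = Path(raw["paths"][key])
        if "simulate" in raw:
            kwargs["simulate"] = dict(raw["simulate"])
        return cls(out_dir=Path(raw["out_dir"]), **kwargs)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _seed_int(master: int, stage: str) -> int:
    return int(stage_seed_sequence(master, stage).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    On a stage failure the output directory keeps partial outputs plus a
    ``failed/`` marker naming the stage, and :class:`StageFailureError` is
    raised.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "guildnet_version": __version__,
        "parameters": {
            "depth": cfg.depth,
            "alpha": cfg.alpha,
            "n_boot": cfg.n_boot,
            "n_perm": cfg.n_perm,
            "n_perm_permanova": cfg.n_perm_permanova,
            "seed": cfg.seed,
        },
        "seeds": {},
        "stages": {},
        "files": {},
    }
    stage = "setup"
    try:
        # --- inputs -------------------------------------------------------
        if cfg.simulate is not None:
            stage = "simulate"
            design = SimDesign(seed=cfg.simulate.get("seed", cfg.seed),
                               **{k: v for k, v in cfg.simulate.items() if k != "seed"})
            db, taxonomy = generate_guild_db(design)
            counts, meta, _truth = generate_counts(design)
            manifest["stages"]["simulate"] = {
                "n_taxa": int(counts.shape[0]), "n_plots": int(counts.shape[1])
            }
        else:
            stage = "load"
            counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
            taxonomy = pd.read_csv(cfg.taxonomy, sep="\t", dtype=str)
            db = GuildDatabase.from_tsv(cfg.guild_db)
            meta = pd.read_csv(cfg.metadata, sep="\t")
            manifest["stages"]["load"] = {
                "n_taxa": int(counts.shape[0]), "n_plots": int(counts.shape[1])
            }

        stage = "assign"
        assignments = assign_guilds(taxonomy, db)
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        summary = assignment_summary(assignments, counts)
        summary.to_csv(out / "assignment_summary.tsv", sep="\t", header=["read_fraction"])
        manifest["stages"]["assign"] = {
            "read_fraction": {k: float(v) for k, v in summary.items()}
        }

        stage = "rarefy"
        seed_r = _seed_int(cfg.seed, "rarefy")
        manifest["seeds"]["rarefy"] = seed_r
        rarefied = rarefy(counts, cfg.depth, seed=seed_r)
        manifest["stages"]["rarefy"] = {
            "depth": cfg.depth,
            "plots_in": int(counts.shape[1]),
            "plots_kept": int(rarefied.shape[1]),
        }

        stage = "guild_counts"
        gc = guild_ratios(guild_counts(rarefied, assignments))
        gc.to_csv(out / "guild_counts.tsv", sep="\t")

        stage = "effects"
        effects = []
        for guild in TARGET_CLASSES:
            for trt in sorted(set(meta["treatment"]) - {cfg.control}):
                eff = treatment_effects(gc, meta, guild, trt, control=cfg.control)
                effects.append(eff.to_dict())
        (out / "effects.json").write_text(json.dumps(effects, indent=1))
        manifest["stages"]["effects"] = {"n_contrasts": len(effects)}

        stage = "sparcc"
        seed_b = _seed_int(cfg.seed, "sparcc_boot")
        manifest["seeds"]["sparcc_boot"] = seed_b
        nets = {}
        treatments = sorted(set(meta["treatment"]))
        plot_trt = meta.set_index("plot_id")["treatment"]
        for trt in treatments:
            plots = [p for p in rarefied.columns if plot_trt.get(p) == trt]
            gt = aggregate_by_genus(rarefied[plots], assignments)
            res = sparcc_correlations(gt)
            pvals = bootstrap_pvalues(gt.counts, n_boot=cfg.n_boot, seed=seed_b)
            rho = res.rho_frame()
            pv = pd.DataFrame(pvals, index=rho.index, columns=rho.columns)
            rho.to_csv(out / f"sparcc_rho_{trt}.tsv", sep="\t")
            pv.to_csv(out / f"sparcc_p_{trt}.tsv", sep="\t")
            net = build_network(rho, pv, alpha=cfg.alpha, treatment=trt, guilds=gt.guilds)
            net.edge_frame().to_csv(out / f"network_edges_{trt}.tsv", sep="\t", index=False)
            nets[trt] = net
            manifest["stages"].setdefault("networks", {})[trt] = net.metrics()

        stage = "permtest"
        seed_p = _seed_int(cfg.seed, "permtest")
        manifest["seeds"]["permtest"] = seed_p
        union = sorted(set().union(*(n.graph.nodes for n in nets.values())))
        permtests = []
        for (ta, tb), metric in itertools.product(
            itertools.combinations(treatments, 2), cfg.metrics
        ):
            res = permtest_metric(
                nets[ta], nets[tb], metric,
                n_perm=cfg.n_perm, seed=seed_p, union_genera=union,
            )
            permtests.append(res.to_dict())
        (out / "permtests.json").write_text(json.dumps(permtests, indent=1))
        manifest["stages"]["permtest"] = {"n_tests": len(permtests)}

        stage = "ordination"
        seed_o = _seed_int(cfg.seed, "permanova")
        manifest["seeds"]["permanova"] = seed_o
        cls = assignments.set_index("taxon_id")["guild_class"]
        ordinations = {}
        for guild in TARGET_CLASSES:
            taxa = cls[cls == guild].index.intersection(rarefied.index)
            community = rarefied.loc[taxa].T  # plots x taxa
            community = community.loc[community.sum(axis=1) > 0]
            if community.shape[0] < 8 or community.shape[1] < 2:
                logger.warning("ordination: skipping %s (too few plots/taxa)", guild)
                continue
            hel = hellinger(community)
            dm = bray_curtis(hel)
            ord_res = pcoa(dm, k=2)
            ord_res.coordinates.to_csv(out / f"pcoa_{guild}.tsv", sep="\t")
            labels = plot_trt.reindex(ord_res.coordinates.index)
            perm = permanova(dm, labels, n_perm=cfg.n_perm_permanova,
                             seed=seed_o, factor="treatment")
            ordinations[guild] = {
                "pseudo_f": perm.pseudo_f,
                "r2": perm.r2,
                "p_value": perm.p_value,
                "n_plots": perm.n,
                "prop_explained_pc12": [float(x) for x in ord_res.proportion_explained[:2]],
            }
        (out / "permanova.json").write_text(json.dumps(ordinations, indent=1))
        manifest["stages"]["ordination"] = ordinations

        stage = "manifest"
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = _digest(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:
        marker = out / "failed"
        marker.mkdir(exist_ok=True)
        (marker / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise StageFailureError(stage, exc) from exc


def effects_over_sims(
    contrasts: list[tuple[str, str]],
    seeds,
    depth: int = 485,
    design_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Percent-change estimates over replicate simulations, one row per seed.

    Each seed drives one full simulate -> assign -> rarefy -> guild counts ->
    treatment effect chain under the default study design; all requested
    ``(guild, treatment)`` contrasts are estimated from the same simulated
    run. Columns are named ``"{guild}:{treatment}"``.
    """
    design_kwargs = design_kwargs or {}
    rows = []
    for s in seeds:
        design = SimDesign(seed=int(s), **design_kwargs)
        db, taxonomy = generate_guild_db(design)
        counts, meta, _ = generate_counts(design)
        assignments = assign_guilds(taxonomy, db)
        rarefied = rarefy(counts, depth, seed=_seed_int(int(s), "rarefy"))
        gc = guild_counts(rarefied, assignments)
        rows.append(
            {
                f"{g}:{trt}": treatment_effects(gc, meta, g, trt).pct_change
                for g, trt in contrasts
            }
        )
    return pd.DataFrame(rows, index=pd.Index(list(seeds), name="seed"))


def effect_recovery(
    guild: str,
    treatment: str,
    seeds,
    depth: int = 485,
    design_kwargs: dict | None = None,
) -> list[float]:
    """Percent-change estimates for one guild/treatment over replicate simulations."""
    df = effects_over_sims([(guild, treatment)], seeds, depth, design_kwargs)
    return df[f"{guild}:{treatment}"].tolist()
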