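# guildnet

Nutrient enrichment (nitrogen and phosphorus) reshapes grassland soil fungal
communities: it tends to promote plant pathogens, suppress arbuscular
mycorrhizal fungi (AMF, putative mutualists), and leave saprotrophs largely
unchanged. `guildnet` is a tested, reusable implementation of the analysis
chain behind that kind of multi-site amplicon study, aimed at microbial
ecologists working with NutNet-style block designs (sites divided into
blocks, with control, N, P and N+P plots):

1. **Guild assignment** — FUNGuild-style matching of taxon lineages to guilds
   at the most specific shared rank, with the AMF confidence filter
   (Highly Probable / Probable only) and the soil/undefined-saprotroph
   subsetting rule.
2. **Rarefaction** — multivariate-hypergeometric subsampling of each plot to
   a fixed depth (default 485 reads); per-plot guild counts `A_s`, `P`, `S`
   and the ratio statistics `P/(P + A_s)` (pathogen:mutualist balance) and
   `S/(S + P + A_s)` (decomposer share).
3. **Treatment effects** — a site-stratified estimator: log(count + 1) linear
   model with fixed site effects and a treatment contrast (two-sided t test),
   plus the raw site-averaged percent change in relative abundance.
4. **SparCC** — from-scratch compositional correlation estimation on
   genus-aggregated counts. With `t_ij = Var(log(x_i/x_j))`, basis variances
   `ω` solve `[(p−2)I + 11ᵀ] ω = rowsums(T)` under a sparsity assumption
   (strongly correlated pairs iteratively excluded), and
   `ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_i ω_j))`, with bootstrap p-values
   (default 100 resamples).
5. **Networks** — per-treatment graphs of significant (p < 0.05)
   correlations; connectance `E/N²`, mean degree `2E/N`; and a paired
   permutation test that swaps each genus pair's edge indicators between two
   treatments (10,000 permutations by default) to compare network metrics.
6. **Ordination** — Hellinger transform, Bray–Curtis distances, principal
   coordinate analysis, and single-factor PERMANOVA with a seeded
   permutation scheme.
7. **Synthetic data** — a NutNet-like generator with planted guild
   membership, multiplicative treatment effects on expected relative
   abundance, and a planted genus–genus log-scale correlation structure, so
   every stage can be validated against a known truth.

Fit/transform-shaped pieces (`SparCC`, `PCoA`, `GuildAssigner`) follow the
scikit-learn estimator protocol and compose with sklearn tooling; the
hypothesis tests and the pipeline are plain functions.

## Worked example

```python
from guildnet import (SimDesign, generate_guild_db, generate_counts, assign_guilds,
                      assignment_summary, rarefy, guild_counts, guild_ratios,
                      treatment_effects, PATHOGEN, AMF)

design = SimDesign(seed=1)                 # 25 sites x 3 blocks x 4 treatments
db, taxonomy = generate_guild_db(design)
counts, meta, truth = generate_counts(design)

assignments = assign_guilds(taxonomy, db)
print("assigned read fraction:",
      round(1 - assignment_summary(assignments, counts)["UNASSIGNED"], 3))

rarefied = rarefy(counts, 485, seed=1)
gc = guild_ratios(guild_counts(rarefied, assignments))
for guild in (PATHOGEN, AMF):
    eff = treatment_effects(gc, meta, guild, "NP")
    print(f"{guild} NP vs CTRL: pct_change={eff.pct_change:+.1f}%  p={eff.p_value:.2e}")
```

prints

```
assigned read fraction: 0.599
PATHOGEN NP vs CTRL: pct_change=+171.3%  p=3.84e-35
AMF NP vs CTRL: pct_change=-30.8%  p=1.12e-08
```

About 60% of reads belong to database-covered taxa (the generator plants 40%
of taxa as unassignable). The single-replicate pathogen estimate (+171%) is
noisy around the planted +140%; averaging over replicate simulations
converges to it (see below). The AMF suppression (−31% vs planted −33%) and
the tiny contrast p-values reflect the strong planted N+P effects.

The same stages are available from the shell:

```bash
guildnet simulate --seed 1 --out sim/
guildnet assign --taxonomy sim/taxonomy.tsv --db sim/guild_db.tsv \
    --counts sim/counts.tsv --out assign.tsv
guildnet run --config run.toml       # full pipeline with a manifest
```

## Layout

- `src/guildnet/simulate.py` — synthetic-data generator and planted truth
- `src/guildnet/guilds.py` — lineage parsing and guild assignment
- `src/guildnet/abundance.py` — rarefaction, guild counts/ratios, effects
- `src/guildnet/sparcc.py` — compositional correlations and bootstrap
- `src/guildnet/networks.py` — networks, metrics, permutation comparison
- `src/guildnet/ordination.py` — Hellinger / Bray–Curtis / PCoA / PERMANOVA
- `src/guildnet/pipeline.py`, `cli.py` — orchestration and `guildnet` CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
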