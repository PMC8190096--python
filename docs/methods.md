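# Methods

This note documents the models and procedures `guildnet` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## The study design being emulated

The target setting is a globally replicated grassland nutrient-addition
experiment: `n_sites` grasslands (default 25), each divided into
`n_blocks_per_site` blocks (default 3), each block containing one plot per
treatment — control (CTRL), nitrogen (N), phosphorus (P), and both (NP).
Soil fungal communities are characterized by amplicon sequencing, giving a
taxa × plots count table, a taxonomy table of rank-prefixed lineages, and a
curated guild database in a FUNGuild-like schema.

## Guild assignment

Lineages are parsed from `k__…;p__…;…;g__…;s__…` strings; matching against
the database proceeds from the most specific rank shared by lineage and
database (species, then genus, family, order, …) and is case-insensitive
and exact (no fuzzy matching — curated databases are name-keyed). The
matched record's guild string is classified:

- contains "Arbuscular Mycorrhizal" **and** confidence is Highly Probable or
  Probable → `AMF`; at Possible confidence the match is demoted to `OTHER`.
  The confidence filter deliberately applies only to AMF; pathogen and
  saprotroph assignments accept all confidence levels.
- contains "Plant Pathogen" → `PATHOGEN`.
- guild or trophic mode contains "Soil Saprotroph" or "Undefined Saprotroph"
  → `SAPROTROPH`. Substrate specialists (wood, dung, litter) are *not*
  counted as saprotrophs here, because their substrates are not
  representative of bulk grassland soil; they fall through to `OTHER`.
- any other database match → `OTHER`; no match → `UNASSIGNED`.

Multi-guild annotations (e.g. "Plant Pathogen|Undefined Saprotroph") resolve
by the priority AMF > PATHOGEN > SAPROTROPH and are logged as ambiguous;
databases do not document a canonical tie rule, and this ordering prefers the
ecologically narrower claims.

## Rarefaction and guild statistics

Each plot is subsampled **without replacement** (multivariate
hypergeometric) to a fixed depth, default 485 reads — a common compromise
between retaining plots and characterizing abundant taxa. Plots below the
depth are dropped and logged. Sampling is unbiased: the expected rarefied
fraction of a taxon equals its pre-rarefaction fraction (verified by Monte
Carlo in the tests). Rarefaction is performed once per seed.

Per plot, `A_s`, `P`, `S` are the rarefied read totals of AMF, pathogen and
saprotroph taxa (OTHER/UNASSIGNED excluded). Two ratios summarize guild
balance: `P/(P + A_s)` (pathogen-to-mutualist) and `S/(S + P + A_s)`
(decomposer share among guild-assigned reads). Zero denominators yield a
flagged *undefined* value, never a silent zero.

## Treatment effects

For a guild and treatment, two complementary estimates versus control:

- **Log-scale contrast.** OLS of `log(count + 1)` on site indicator
  variables plus a treatment dummy, restricted to sites containing both
  arms; the two-sided t-test on the dummy is the reported p-value. Site
  fixed effects stratify out the large between-site differences. A
  random-effects (site, block-within-site) model would be the textbook
  choice for this design; the fixed-effect stratification is used instead
  because the quantity of interest here is recovery of the treatment effect,
  not variance components, and it is exact at small site counts.
- **Percent change.** Per site, `(mean treated − mean control)/mean control
  × 100` on relative abundances (counts/depth; identical to count-based
  change at fixed depth), averaged over sites with both arms. Sites with a
  zero control mean are excluded and logged. This is a ratio-of-means
  estimator: with few control plots per site it carries a small positive
  Jensen bias that vanishes as plot-level variability shrinks (a property
  the tests check explicitly).

No multiple-testing correction is applied across guilds; p-values are
reported unadjusted.

## SparCC compositional correlations

Counts are aggregated to genus within guild-assigned taxa (a genus mapping
to two guild classes is an error, surfaced by name). Fractions use a
posterior-mean estimate with pseudocount 1:
`f_i = (x_i + 1)/(total + p)` — a single deterministic estimate rather than
averaging Dirichlet draws, which keeps the whole chain reproducible from one
seed. The estimator requires at least 4 genera and 4 plots.

From `t_ij = Var(log(f_i/f_j))` (sample variance, n−1), basis variances
solve `[(p−2)I + 11ᵀ] ω = rowsums(T)`. Pairs violating the sparsity
assumption are excluded iteratively: while any non-excluded `|ρ| > 0.1` and
fewer than 10 exclusions have been made, the largest-|ρ| pair is removed
from the system (its `t_ij` dropped from both rows, the matrix adjusted)
and the system re-solved; excluded pairs keep their last computed ρ. If a
further exclusion would make the system singular (possible at small p), the
iteration stops there rather than failing — direct calls to
`basis_variances` still raise on a singular system. Basis variances are
floored at 1e−10 (logged); correlations are clipped to [−1, 1].

Bootstrap p-values resample plots with replacement (default 100 resamples,
matching common practice for these networks) and recompute the full
estimate each time. With `q⁻ = (1 + #{ρ* ≤ 0})/(B + 1)` and
`q⁺ = (1 + #{ρ* ≥ 0})/(B + 1)`, the two-sided p-value is
`min(1, 2·min(q⁻, q⁺))`. The add-one correction keeps p strictly positive
on **both** tails (the one-sided variant `2·min(q⁻, 1−q⁻)` collapses to 0
when every resample has the same sign).

## Networks and the cross-treatment permutation test

Per treatment, the network keeps genus pairs with `p < α` (default 0.05);
nodes are genera incident to at least one edge, signed by ρ. Metrics follow
the conventions of the target analyses: **connectance = E/N²** (note: not
the undirected-graph maximum `N(N−1)/2`) and **mean degree = 2E/N**. Empty
networks report zero metrics with an `empty` flag.

Two treatments are compared on a metric by a paired permutation test over
the union genus set: each unordered genus pair carries a 0/1 edge indicator
per treatment; a permutation independently swaps the two indicators with
probability 1/2 per pair, both networks are reformed (nodes = genera with
≥ 1 edge after the swap), and the metric difference recomputed. This
per-pair swap is the most conservative scheme that keeps the node universe
fixed and preserves each pair's edge multiset exactly; a pooled reshuffle
(`shuffle="global"`) is available as an alternative null. The p-value is
two-sided on |difference| with the add-one correction,
`p = (1 + #{|Δ*| ≥ |Δ|})/(n_perm + 1)`; one-sided is available by flag.
Default `n_perm = 10,000`.

## Ordination

Guild community tables are Hellinger-transformed (square root of row
relative abundances), Bray–Curtis distances computed
(`Σ|x_a − x_b| / Σ(x_a + x_b)`, via scipy), and PCoA performed by Gower
double-centering `B = −½·J·D²·J` and eigendecomposition; negative
eigenvalues (expected for Bray–Curtis) are discarded and counted, and
proportions explained are relative to the positive-eigenvalue total.
PERMANOVA is single-factor: `SS_total = Σ_{i<j} d²_ij/n`, within-group sums
analogously per group, pseudo-F with (g−1, n−g) degrees of freedom, and a
seeded label-permutation p-value with the add-one correction (default 999
permutations). No restricted/strata permutations are implemented. The
implementation is checked in the tests against scikit-bio's PCoA and
PERMANOVA on shared inputs, and against hand-computed partitions.

## The synthetic-data generator

The generator plants a known truth for every downstream stage:

- **Taxa and guilds.** Four genus pools (defaults: 12 AMF, 18 pathogen, 25
  saprotroph, 45 other; 2 taxa per genus). 40% of each pool's genera are
  omitted from the guild database, so ~40% of reads are unassignable —
  matching the assignable share typical of ITS surveys. Baseline expected
  read shares are AMF 0.05, pathogen 0.06, saprotroph 0.17, other 0.72,
  chosen from the guild read totals such surveys report.
- **Abundances.** Per plot, genus log-abundances are multivariate normal:
  a planted block correlation matrix (within- and cross-guild compound
  blocks, including a negative pair) scaled by `genus_sd` (0.6), plus
  independent site effects (`site_sd` 0.5, shared across a site's plots) and
  plot noise (`plot_sd` 0.3). `genus_sd` 0.6 keeps per-plot guild-share
  coefficients of variation near 0.3, small enough that the site-averaged
  percent-change estimator's Jensen bias stays at a few percent of the
  effect — i.e. the planted effects are recoverable at the design's sample
  sizes, as they evidently were in the real studies this emulates.
- **Treatment effects.** Multiplicative on expected relative abundance:
  pathogens ×2.40 and AMF ×0.67 under NP (the +140% / −33% headline
  effects), pathogens ×1.8 under N or P alone, saprotrophs ×1.00. Target
  guild shares are scaled exactly per plot and the "other" pool absorbs the
  renormalization, so compositional closure introduces no bias into the
  planted guild effects.
- **Counts.** Multinomial at `raw_depth` (2000) per plot, so every column
  sums exactly to the raw depth and rarefaction to 485 always retains all
  plots. One master seed drives fixed-offset child streams per stage;
  identical designs give byte-identical outputs.

A lighter generator (`simulate_genus_table`) produces genus × plot tables
with a planted correlation directly, for validating the compositional
estimator in isolation.

**What the generator does not emulate:** sequencing-level artifacts (PCR
bias, chimeras, variable read depth per plot), unbalanced designs (real
studies lose plots to quality filtering; the generator is balanced by
default, though rarefaction handles shortfall plots), taxonomic
misannotation, overdispersion beyond lognormal-multinomial, and any direct
link between guild abundance and plant or soil covariates. Passing tests
therefore demonstrate that the estimators recover planted truths under a
clean lognormal-multinomial world — not that real data meet those
assumptions.

## Validation problem sizes

The test suite validates effect recovery on 20 replicate simulations of the
full default design (seeds 1–20); SparCC recovery on 50 genera × 120 plots
with six planted ρ = 0.7 blocks (Pearson r ≥ 0.7 planted vs estimated) and
a 200-plot null (mean |ρ| < 0.1); permutation-test calibration on 200
simulated network pairs at 1,000 permutations (type-I error within
[0.02, 0.09]) plus exhaustive enumeration on 3-pair toys; and PERMANOVA
calibration on 500 null simulations of 16 plots at 199 permutations. These
sizes give stable Monte-Carlo estimates while keeping the default test run
fast.

## Known limitations

- The fixed-effect treatment model ignores block-within-site structure;
  p-values are anti-conservative if blocks are strongly autocorrelated.
- The percent-change estimator's ratio bias, while small at the default
  noise levels, grows with plot-level variability and few control plots.
- SparCC assumes sparsity of strong correlations; with densely correlated
  communities the exclusion cap (10) leaves residual bias in ω.
- Connectance uses the E/N² convention; comparisons with sources using
  E/(N(N−1)/2) require rescaling.
- PERMANOVA is single-factor and unrestricted; site effects inflate
  within-group heterogeneity when testing treatment across pooled sites.
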