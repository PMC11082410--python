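# Methods

## The metabolic map

The map is a bipartite factor graph: metabolite pools on one side, reaction
modules on the other, with directed consume/produce edges. Flux balance is
penalised only on the pools listed in `balanced_set`; terminal products
(hydroxyl radical, hydroxide, stored Fe³⁺, heme, Fe–S clusters, exported
Fe²⁺, O₂) are free. The bundled cytosolic iron/ROS map has 15 modules:

- **Fe²⁺ sources (3):** ferrous ion import; ferric ion import and
  reduction; heme import and reduction.
- **Fe²⁺ sinks (4):** Fe–S cluster synthesis; heme synthesis; Fe²⁺ export;
  the Fenton reaction.
- **Ferritin synthesis (1):** consumes the cytosolic Fe³⁺ produced by the
  Fenton reaction. Together with the four Fe²⁺ sinks it forms the five
  "iron outflux" modules whose summed flux is the denominator of the
  relative Fenton level.
- **ROS modules (7):** two superoxide sources (NADPH oxidase,
  mitochondrial leak), superoxide dismutation, a peroxisomal H₂O₂ source,
  and three H₂O₂ sinks (catalase, glutathione peroxidase, peroxiredoxin).
  The Fenton module itself also consumes superoxide and H₂O₂, making eight
  modules that touch the ROS pools.

Default `balanced_set` = {cytosolic Fe²⁺, cytosolic Fe³⁺, superoxide,
hydrogen peroxide} — exactly the pools that have both a producer and a
consumer in this topology. Gene memberships are representative HGNC
symbols per branch, stored in the bundled JSON and meant to be edited;
nothing is hard-coded, so a user with a curated supplementary gene list can
swap it in without touching code.

## Flux estimation

Each module m carries a fully connected network `i_m → 8 → 4 → 1` with
tanh hidden activations and an absolute-value output (nonnegativity by
construction). Inputs are `log1p(TPM)` per gene, standardised over
samples. The joint loss is the squared flux imbalance over balanced pools
and samples plus `λ Σ_j (Σ_m Flux_{m,j} − TA_j)²`, where the
total-activity surrogate TA_j is the summed expression of all map genes in
sample j, rescaled to cohort mean 1 (a constant TA is also supported). λ
defaults to 1 on that scale. The anchor is essential: the all-zero flux
field satisfies balance exactly, so without it the minimiser is trivial.

Optimisation is full-batch Adam, default learning rate 3 × 10⁻² with a
cosine decay to 1% of the initial rate over the epoch budget (a constant
small rate converges too slowly for the tail samples; a constant large
rate oscillates near the optimum), default 1000 epochs with early stopping
when the relative loss change over 50 epochs drops below 10⁻⁶. Training
is deterministic given the seed. Genes missing from the matrix are imputed
as zero rows with a logged warning, since real matrices drop symbols.

Reported fluxes are relative levels: predictions are multiplied by a scale
fixed at training time so the training cohort's mean total flux equals the
mean total activity. Identifiability caveat: sample-wise balance pins each
sink's dependence on its own genes (rank recovery is strong), but the
per-module absolute scale within a pool is only weakly identified, so
cross-module flux shares should be read as indicative rather than
calibrated.

## Synthetic cohorts

The generator emulates what the estimator assumes: (1) balance — source
modules draw LogNormal(0, 0.5²) fluxes and each balanced pool's influx is
apportioned to its remaining consumers by Dirichlet(2) shares (a consumer
shared between pools, like the Fenton module, is assigned once, at the
first pool processed; when its committed draw exceeds a later pool's
provisional influx, that pool's dedicated sources are scaled up to cover
it); a `slack` parameter jitters consumer fluxes by a Uniform(−s, s)
factor so residuals stay within s × influx. (2) monotone expression —
each module gene is `loading × flux × exp(N(0, σ))` with loadings
Uniform(0.5, 2); σ defaults to 0.2 for the standard study conditions,
`genes_per_module` can pad memberships with synthetic symbols. The RM
generator draws standard-normal scores and a Fenton vector that is a fixed
linear combination of a planted support plus Gaussian noise. The shuffling
perturbation permutes each gene's values within a randomly chosen fraction
of samples, preserving per-gene marginals while destroying the
gene–module dependency there.

What the simulations do *not* emulate: TCGA batch structure, library-size
composition effects, dropout, correlated gene modules outside the map, or
any real iron biology. Passing the recovery tests shows the estimation
machinery is sound under its own assumptions, not that real-cohort flux
estimates are accurate.

Standard problem sizes used by the recovery checks (chosen to keep the
default suite fast while leaving clear margins): n = 500, noise 0.2 for
the 15-module recovery run (3000 epochs; loss falls ≥ 100×, per-module
Spearman ρ ≥ 0.8); n = 200 noiseless for the 2-module chain (10 000
epochs; per-sample |R1 − R2|/max ≤ 0.05); n = 300, 800 epochs, 5 seeds for
the shuffling robustness curve over fractions {0, 0.2, 0.4} (median final
loss non-decreasing in the shuffled fraction).

## Enrichment scores

ssGSEA running-sum convention: rank genes by descending expression (ties
broken by gene symbol, so scores are deterministic), then
`ES = Σ_{i=1..G} [P_hit(i) − P_miss(i)]` where P_hit is the cumulative
`|expr|^α`-weighted fraction of set genes at or above rank i and P_miss
the cumulative fraction of non-set genes. This is the integral of the
running difference, not the KS extremum. α defaults to 0.75. At α = 0 the
score depends on ranks only, hence is invariant under strictly monotone
transforms. Scores are reported unnormalised by default; an optional
normalisation divides each set's scores by (max − min) across samples.
A set with no gene in the matrix yields NaN plus a warning; the pipeline
drops such sets before the association stage.

## Proton and transport bookkeeping

The ledger stores integer net H⁺ and CO₂ yields per product unit for the
positively associated RMs (e.g. +4 H⁺ per phosphatidylserine, +2 per
sialic acid, +1 CO₂ per proline); conditional "0 or +1" entries carry both
values and a flag. ATP bookkeeping: fermentative production is pH-neutral
per ATP, respiration consumes one H⁺ per ATP, each hydrolysis releases one
— so Warburg + hydrolysis nets +1 H⁺ and respiration + hydrolysis nets 0.

Transport free energy is `ΔG = ZFV + RT ln(c_dest/c_origin)` with
F = 96 485.3 C/mol and R = 8.31 J/(mol·K); for H⁺ the ratio is
`10^(−pH_dest)/10^(−pH_origin)`. In the 1:1 Na⁺/H⁺ antiport the two
electrical terms cancel exactly (verified over a potential grid), leaving
`RT[ln(Na ratio) + ln(H ratio)]`. The two-compartment sodium model takes
extracellular : intracellular volume 20 : 80, ESC 140 mmol/l, normal ISC
12 mmol/l, and solves `k·TSC_N = 0.2·ESC + 0.8·ISC_C` for the tumour ISC
given the cancer-to-normal total-sodium ratio k ∈ [2, 3] (values outside
that range warn). T defaults to 310 K — the value the energy figures
require — and is an explicit parameter. ΔG values quoted as single
numbers are rounded to the nearest joule. Positive ΔG ⇒ the transport is
infeasible, negative ⇒ feasible, zero ⇒ marginal.

## Association analysis

Per cancer type, the Fenton flux is regressed on the RM enrichment matrix
with an L1 penalty. Predictors are z-scored per RM (default on). The
penalty comes from seeded 10-fold cross-validation on a geometric grid
(100 points down from the critical penalty), taking the sparsest model
within one standard error of the minimum CV error; `lam` can pin the
penalty directly, and `lam = 0` falls back to ordinary least squares. The
cross-type summary counts, for each RM, the fraction of types with a
positive coefficient (rate of contribution) and averages those positive
coefficients over the selecting types only (contribution score); a flag
includes negative coefficients, and the default report keeps RMs selected
in at least 40% of types. The metastasis model is a no-intercept
two-term OLS with t-test P values; rank-deficient designs fall back to the
pseudo-inverse with a warning. Pearson correlations use the t
distribution with n − 2 degrees of freedom.

## Phenotype statistics

Relative Fenton level = Fenton flux / Σ(five iron outfluxes), scale
invariant, NaN when all outfluxes vanish. Growth rate = 365/doubling-days
(per year); the bundled table carries the 11 subtype median doubling times
(metastasis rates must be user-supplied — their source units are not
bundled). Quantile stratification takes the top and bottom ⌊q·n⌋ samples
with label-ordered tie-breaking. Mann–Whitney uses midranks; P values are
exact (full enumeration over rank assignments, two-sided as twice the
smaller tail) for pooled sizes ≤ 16, else the normal approximation with
tie and continuity corrections. No multiple-testing correction is applied
by default; a Benjamini–Hochberg helper exists for many-test panels.

## Numerical and design notes

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every generator and the trainer are
  bit-reproducible.
- Training aborts with the epoch index if the loss becomes non-finite.
- Expression tables collapse duplicate gene symbols by sum with a warning;
  FPKM→TPM rescales each column to sum to 10⁶.
- The pipeline writes a manifest (seed, config echo, loss-trace head/tail)
  and is bit-identical under rerun with the same config.

## Known limitations

- Per-module flux scales are only weakly identified (see above); absolute
  flux shares between modules within one pool are indicative.
- The bundled gene memberships of the iron map are representative, not a
  curated supplementary list; results on real data depend on editing them.
- The lasso summary reports no post-selection inference.
- Compartment-specific Fenton variants (mitochondrial, extracellular) are
  representable as alternative maps but none are bundled.
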