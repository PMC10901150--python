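# Methods

This note documents the statistical models, parameter defaults, and design
decisions behind `toxmodnet`, and states what the synthetic-data generator
does and does not emulate.

## Processing model

### QC and fold changes

Samples are filtered on raw library size (strictly below 500,000 counts is
excluded) and, after CPM normalization, on replicate concordance: each
sample's Pearson correlation on log2(CPM+1) — over the 5,000 most variable
probes — against the mean profile of its (compound, dose, time, batch)
condition must reach 0.95. The condition mean includes the candidate
sample itself (a literal reading of "correlation toward the mean of the
same condition"); a leave-one-out mode is available. Conditions left with
a single replicate are passed through with a warning, and a filter that
empties a condition raises rather than silently dropping a cell of the
design.

Log2 fold changes contrast the mean treated CPM with the mean CPM of the
matched vehicle from the same time point and batch, with a +1 pseudocount
inside the ratio (configurable). The pipeline does not name a canonical
differential-expression test for targeted counts, so adjusted p-values
come from a two-sided Welch t-test per gene on log2(CPM+1) replicate
values, BH-adjusted within each time point across all genes × conditions.
This is deterministic and adequate at n = 3 for threshold-style DEG
calling; it is not a dispersion-shrinkage method and will be conservative
for weakly expressed genes. Probe-to-gene collapse keeps the probe with
the smallest minimum adjusted p across conditions; ties fall back to the
larger mean raw count and then to the lexicographically smaller probe id.

### Network construction

The network is unsigned: `a_ij = |cor|^β`, so co-induced and co-repressed
genes cluster together. β is selected as the smallest power whose degree
distribution fits a power law with signed R² ≥ 0.85 (10 equal-width
connectivity bins; signed R² = −sign(slope)·R², requiring a falling
distribution). Two guards apply: powers whose mean connectivity falls
below 1 are ineligible — at extreme powers even noise yields a
power-law-shaped degree distribution because the network has dissolved —
and a target of 0 is treated as no requirement. When no eligible power
reaches the target the argmax is returned with a warning.

Module detection is average-linkage hierarchical clustering on 1 − TOM,
cut at 0.99 of the maximum merge height; clusters below `min_module_size`
(default 20) fall to module 0. A rescue step ("hybrid" mode, default)
then assigns each unassigned gene to the module with the highest mean TOM
to its members, provided that mean reaches half the module's internal mean
TOM — a TOM-space analogue of PAM-style borderline assignment. A plain
fixed-height cut ("static") is available.

Eigengenes are the first principal component over conditions of the
module's z-scored member matrix, sign-oriented so the correlation with the
module's mean z-profile is non-negative (PCA sign is arbitrary), then
divided by their standard deviation across conditions so every eigengene
column has SD exactly 1. Throughout the package, standard deviations are
sample SDs (ddof = 1). Merging is transitive: modules whose eigengene
correlations chain at ≥ 0.8 (signed by default; absolute-value mode
available) are unioned, eigengenes recomputed, and the process repeated to
a fixpoint. `corEG` is computed only against the parent module; hub ties
break on the lexicographically smaller gene id. Enrichment is a
hypergeometric upper tail per (module, gene set) with BH adjustment across
all pairs.

### Preservation

The composite follows the density + connectivity logic of published
module-preservation statistics with a minimal defensible subset: one
density statistic (mean within-module adjacency in the test system at the
reference β) and two connectivity statistics (correlation of intramodular
connectivity vectors between systems and correlation of the vectorized
within-module correlation matrices). The null permutes module identity —
random same-size gene sets drawn from the genes shared by both systems —
which preserves each system's global correlation structure; 200
permutations by default, seeded. `Zsummary = (Zdensity + Zconnectivity)/2`
with the 2/10 interpretation thresholds; medianRank is the median of the
per-statistic ordinal ranks of the observed values (rank 1 strongest).
Modules with fewer than 10 shared genes are skipped and recorded.

### Trait screen and candidate genes

Eigengene/death pairing is by shared (compound, concentration); each
correlation pools all transcriptomic time points against death at a single
measurement time, with 58 h as the headline choice (early module activity
versus late outcome). At least 3 paired points are required for a
p-value. BH adjustment runs within each (death type, death time) family by
default; a global mode exists because the original family definition is
not documented. "Eigengene > 2" is the signed score (activation);
absolute-value mode available. The hit rule and gene thresholds use
strict inequalities throughout: a pair passing at exactly r = 0.5 or a
gene at exactly log2FC = 2 does not qualify, and exactly 4 passing DILI
compounds is not a hit.

### RNAi scoring

σ is the sample standard deviation and the population includes the mock
and scrambled control records (both configurable). Replicates are averaged
per siRNA before standardization, so each siRNA contributes one value per
population. The hit rule (z beyond ±1 in ≥ 2 strata) considers only
challenge-compound strata — the vehicle condition produces no injury, so
its z-scores are noise — and a gene satisfying both directions is flagged
as a conflict and left unclassed. Ward clustering of z profiles into two
groups is available as an alternative mode, mirroring heatmap-style
grouping.

## Synthetic-data generator

The generator emulates a targeted-sequencing dose/time course in a
hepatocyte line and plants every structure the pipeline must find.

* **Design** — compounds per category (DILI, stress reference,
  cytokine/growth factor, negative), up to 6 strictly ordered
  concentrations, time points {4, 8, 24} h, ≥ 2 replicates, batches
  assigned round-robin with per-batch vehicle wells. Vehicle replication
  is configurable separately: the standard datasets use 12 solvent wells
  per batch and time point, as plates typically carry many DMSO wells.
  With only 3 vehicle wells the shared fold-change denominator induces a
  visible (batch × time)-factor correlation among all genes — a real
  artifact of sparse controls that otherwise dominates the background
  correlation structure.
* **Counts** — negative binomial with gene-wise dispersion drawn
  log-normally (median size 10), baseline log2 means N(5, 2.5²), and
  library sizes uniform in (1–3)·10⁶. Module genes start 2 log2 units
  below the background baseline: stress transcripts are induced from
  low/mid expression, and the offset keeps the planted genes' share of the
  library small so their induction does not compositionally distort every
  other gene's CPM.
* **Module activation** — `amplitude × responsiveness(compound) ×
  Hill(dose) × timeweight(time)`. Narrow (compound-specific) modules
  respond to a random subset of non-negative compounds with mid-range Hill
  midpoints and one of three archetypal time profiles. Broad
  (DILI-general) modules respond to every DILI compound with steep Hill
  slopes (3.5–4.5), midpoints at 55–75 % of the dose range, and a late
  time profile — general cytotoxic stress engages near cytotoxic doses and
  late in time, which also gives the right-skewed activation distribution
  that makes per-compound eigengene peaks exceed 2 after unit-variance
  normalization. Loadings lie in [0.3, 1] with a fraction of negative
  signs (anti-correlated members, exercising the unsigned network).
* **QC defects** — a configurable fraction of treated samples is
  corrupted, at most one per condition: half get library sizes of
  100–400 k (failing the 500 k filter), half get a partially decorrelated
  profile — the log2 mean blended at weight 0.85 with a permuted baseline
  profile. Full profile replacement would drag the *siblings'* correlation
  to the contaminated condition mean below 0.95 as well; the 0.85 blend
  puts the corrupted sample near r ≈ 0.92 and its siblings near 0.97, so
  the set of failing samples equals the set of flagged samples exactly.
* **Reference system** — a second log2FC matrix sharing gene ids, with
  per-condition module activations drawn afresh; preserved modules share
  one activation per condition (attenuation configurable), non-preserved
  modules get independent per-gene activations of the same marginal scale,
  destroying co-expression but not variance.
* **Cell death** — a saturating hazard of the linked modules' late-time
  activation: `fraction(t) = baseline + (1 − baseline)(1 − exp(−drive·t/58))`
  with `drive = max(0, rate·Σ w_m·activation_m + noise)`. Death is
  monotone in measurement time by construction, zero-coupling with zero
  noise returns the baseline everywhere, and dose dependence is inherited
  from the activation.
* **RNAi screen** — baseline death ≈ 0.35–0.45 under challenge compounds
  (0.05 under vehicle), Gaussian noise (sd 0.05), protective/enhancing
  shifts of ±effect_size·noise_sd under challenge compounds only, mock and
  scrambled controls in every stratum, values clipped to [0, 1].

What the generator does **not** emulate: probe-level multi-mapping and
alignment artifacts, count overdispersion that depends on expression
level, batch effects beyond vehicle matching, compound kinetics beyond a
three-point time profile, partial module preservation (a module is either
preserved or scrambled), and death-type-specific biology beyond a scale
factor. Passing the recovery suite therefore shows the pipeline's
statistics are implemented correctly and identifiable under the assumed
noise family — not that the thresholds are optimal for any real assay.

## Standard experiment sizes

Chosen to exercise every stage at full statistical fidelity while staying
desk-scale: module recovery uses 2,000 genes (8 modules of 50–120 genes
plus background), 240 treated conditions (20 compounds × 4 doses × 3
times), 3 replicates, 2 batches; the recovery analysis runs at a fixed
reference power β = 6 (automatic selection is validated separately — on
strongly modular data smaller powers can already satisfy the scale-free
criterion while being less discriminative for clustering). Preservation
uses 500 genes, 10 modules (5 preserved, 5 scrambled), 80 + 60 conditions,
200 permutations. The trait screen uses 800 genes, 12 modules (2
death-linked), 8 DILI + 4 negative compounds at 6 doses. The RNAi screen
uses 60 targets with 6 + 6 planted effects at effect size 3.

## Known limitations

* The Welch-on-log2CPM test is a stand-in for a provider-grade DE
  pipeline; absolute DEG counts on real data would differ.
* The dynamic tree cut is a simplified hybrid (static cut + TOM-space
  rescue), not a full reimplementation of branch-shape-based cutting;
  on weakly separated modules it will behave differently.
* Preservation implements three core statistics, not the full published
  battery (no separability or cluster-coefficient terms).
* Cross-species or cross-platform gene mapping is out of scope: the two
  systems must already share gene identifiers.
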