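# Methods

## Problem setting

Multiplexed bulk RNA-seq of laboratory *Drosophila* often contains reads
from natural viruses.  Two inference problems follow.  First, a nonzero
virus count in a library does not establish infection: on patterned flow
cells a small fraction of reads (of order 10⁻³) is misassigned between
libraries sharing a lane ("index hopping" / "barcode switching"), so one
heavily infected library contaminates its whole lane at a low level.
Second, once infections are called, their effect on host expression must
be estimated across heterogeneous published projects that differ in
genotype, tissue and laboratory environment, and that sampled the sexes
unevenly.

## Presence/absence calling

A virus is called present in a library when its read count reaches
`max(rel_threshold × per_virus_max, abs_threshold)` with defaults
`rel_threshold = 0.01` and `abs_threshold = 150` reads.  The relative
rule is the hopping correction: hopped reads in a lane-mate are roughly
proportional to the source library's titre, so thresholding at 1% of the
per-virus maximum removes them while retaining genuine infections, whose
titres span orders of magnitude.  The absolute floor guards the regime
where the per-virus maximum itself is small.  Raw read counts are used
(not library-size-normalized): the rule is about hopped read numbers,
which scale with the source library, not the recipient.

The per-virus maximum is taken within each project by default (a pooled
option exists): hopping is a within-run artefact and titre scales differ
between projects.

*Floor selection from duplicates.*  When duplicate samples exist, the
floor is chosen from a candidate grid {10, 25, 50, 100, 150, 200, 300,
500} by minimizing discordance — the fraction of (duplicate pair, virus)
combinations whose two calls differ — with ties broken toward the
smallest candidate to retain sensitivity.  Discordance as a fraction of
pair-virus combinations is a declared interpretation; no quantitative
definition of duplicate inconsistency was available to adopt.

*Sex verification.*  Library sex is verified from sex-limited marker
genes (defaults: eleven male-specific and five female-specific FlyBase
genes).  Marker counts are CPM-normalized and summed per set; a library
is called male when the male sum is at least twice the female sum,
female in the reverse case, and ambiguous otherwise.  The 2× margin is a
configurable default chosen to be insensitive to low-level leakage while
never misclassifying a genuinely single-sex library.

*Switching-rate estimation.*  The hop rate is estimated as wrong-sex
marker reads (female-marker reads in verified males plus male-marker
reads in verified females) over all marker reads in sexed libraries,
with a Clopper–Pearson binomial interval, reported per lane and pooled.
The estimate is diagnostic: the primary caller remains the threshold
rule.  Single-sex designs return an explicitly flagged undefined rate.

*Common-source contamination.*  Virus pairs whose log1p counts correlate
at Pearson r ≥ 0.95 across libraries are joined into connected
components and flagged: counts that tightly co-vary across hundreds of
libraries indicate a shared contaminating source (e.g. cell-culture RNA
or hopping from an unreported library) rather than independent
infections.  log1p is used because counts span four orders of magnitude;
constant columns are excluded with a warning.

## Prevalence and co-infection

Prevalence is k/n positive libraries per (project, virus) with a
Clopper–Pearson interval — exact coverage matters because several
viruses appear in only one or two libraries of a project.

Association between two viruses is tested on the 2×2 cross-tabulation of
calls with Fisher's exact test implemented from first principles: the
point probability of each feasible table with the observed margins is
computed through log-gamma (stable for n ≈ 1000 libraries), and the
two-sided p-value sums all tables whose probability does not exceed the
observed one (point-probability rule, with a 1 + 10⁻⁷ relative tolerance
for floating-point ties, matching the convention of the standard R
implementation).  A tail-doubling rule is available for comparison.  The
reported odds ratio is the sample odds ratio n11·n00/(n10·n01), infinite
when a denominator cell is zero and a numerator cell positive.  The
co-infection scan applies a raw α = 0.01 per pair with **no**
multiple-testing correction — a deliberate, prominently documented
choice mirroring a raw per-pair significance threshold; exact tests on
discrete support are conservative, so the realized type-I rate is at or
below α.

## Differential expression model

Expression is log2-CPM with a prior count of 0.5:
`log2((count + 0.5)/(size + 1) × 10⁶)`.  Inside `VirusDEModel` the
library size is an *effective* size — median-of-ratios size factors (as
in DESeq) times the mean column total — because raw totals are
compositional: a strong response concentrated in a subset of genes
changes an infected library's total and would shift the log-CPM of every
unaffected gene, biasing null genes.  Genes with CPM > 1 in fewer than
5% of libraries are filtered.  Both the filter and the normalization
settings are declared defaults of this package.  Precision weights
(voom-style) are not used; the variance-moderation stage partially
compensates — a deliberate simplification.

Per virus, libraries are restricted to the projects where the virus was
called present, and the model is

    expression ~ sex + virus + sex:virus + (1 | dataset_genotype_tissue)

with uninfected females as the reference level.  Term-dropping rules: if
the retained libraries contain one sex, or the virus was called in one
sex only, the sex term and the interaction are dropped; strata with a
single level (one dataset, one genotype, one tissue) are dropped from
the random-effect label, and a single-level label reduces the fit to
OLS.  All provided stratum columns are concatenated into the label.
Age is never a covariate (the source datasets do not report it).  With
the interaction present, the virus coefficient is the infection effect
in females and the interaction is the additional effect in males.

*Fitting.*  The single-random-intercept Gaussian mixed model is fitted
by REML.  With V = I + λZZ′ and λ the variance ratio σ²_group/σ²_resid,
V⁻¹ has a closed block form per group, the residual variance is
profiled, and the criterion is minimized in log λ by bounded 1-D search
— robust and fast enough to fit thousands of genes per second.  λ
estimates at the boundary (≤10⁻⁶) fall back to OLS degrees of freedom.

*Inference.*  Wald t statistics use a Satterthwaite-type df:
df = 2·Var(β̂_j)²/(g′ Cov(θ̂) g), with g the numerical gradient of the
coefficient variance in θ = (σ²_resid, σ²_group) and Cov(θ̂) twice the
inverse numerical Hessian of the REML −2 log-likelihood.  On shared
fixtures the estimates, standard errors, dfs and p-values agree with
lme4/lmerTest to within 2% (exactly, for the estimates), and the OLS
path reduces to the classical equal-variance t-test.

*Moderation.*  Residual variances are optionally shrunk toward a common
prior: a scaled inverse-chi-square prior (s₀², d₀) is fitted by moments
on log s² (solving a trigamma equation for d₀, as in limma), posterior
variances are the df-weighted average, and t statistics gain d₀ prior
df.  Degenerate spreads skip moderation with a warning.  The
null-calibration checks use unmoderated p-values so that they test the
mixed model itself.

*Multiplicity and classification.*  p-values are BH-adjusted per
coefficient across genes (step-up, monotone, capped at 1).  Genes are
classified up/down at |logFC| > 0.5 and adjusted p < 0.001, strict
inequalities.

## Cross-virus correlation

Estimated logFC vectors (per virus, and per sex:virus interaction) are
aligned on shared tested genes and correlated pairwise — Pearson by
default, Spearman as an option, since both conventions appear in
practice for this comparison; p-values come from the t transform of r
with n − 2 df, and entries with p ≥ 0.001 are masked.  All tested genes
enter the correlation (not only significant ones); this is a documented
default.

## Synthetic-data generator

The generator emulates the study conditions the pipeline targets:
several projects of O(100) single-fly libraries with genotype/tissue
strata, lanes, and both sexes (single-sex designs are supported, as they
occur in real projects).  Defaults: two projects × 100 libraries, two
lanes per project, hop rate 0.002, infected titres log-normal with
median 10⁵ reads (σ_log = 1, matching the orders-of-magnitude spread of
real titres), library sizes log-normal around 10⁶, 2000 NB genes with
dispersion 0.2, baseline abundances log-normal (σ = 2 on log2),
prevalences of 0.1–0.3, planted log2 effects of magnitude 1 on 10% of
genes (sex, virus) and 5% (interaction), group random intercepts with
sd 0.5.

* **Hop model:** each uninfected lane-mate receives a Poisson count with
  mean `hop_rate × lane_total/(lane_size − 1)` — reads relocate
  uniformly at a per-read rate, the simplest generative model of the
  artefact the caller corrects.
* **Planted effects are balanced** (half up, half down per affected
  set): real responses contain both directions, and balance keeps
  library composition roughly stable, as in real data where global
  expression mass is approximately conserved.
* **Markers** are strictly sex-limited; a `marker_leakage` flag plants
  wrong-sex marker reads whose lane-level expectation is `hop_rate ×`
  the lane's marker reads (spread over opposite-sex lane-mates), so the
  pooled wrong-sex/total ratio is a consistent estimator of the planted
  rate.  Without the flag, wrong-sex marker counts are exactly zero.
* **Duplicates** are technical re-sequencing replicates: the duplicate
  shares the original's latent titres and gene rates and re-draws
  Poisson counts, staying on the same lane.
* **Randomness:** one seed; per-stage substreams derived from a single
  `SeedSequence`, so outputs are bit-identical given the configuration.

What the generator does *not* emulate: FASTQ-level artefacts, ribosomal
RNA, cell-culture contamination mixtures, batch effects beyond the group
intercept, gene–gene correlation, and NB dispersion trends with
abundance.  Passing tests therefore demonstrate correctness of the
inference given the model's assumptions (NB counts, log-linear effects,
uniform hopping), not robustness to every artefact of real libraries.

## Verification scales and expectations

The acceptance checks run at these sizes, chosen so the whole suite
completes in minutes on one CPU while leaving the statistical
conclusions stable across seeds:

* Exact test vs exhaustive enumeration: 500 random tables, margins ≤ 30.
* Caller vs brute-force rule + monotonicity: 100 random 30×4 matrices.
* Parameter recovery: two male-only projects × 100 libraries (ten
  genotype groups, group sd 0.5), 2000 genes, planted virus logFC 1.0,
  NB dispersion 0.2, prevalence 0.4.  The male-only design exercises the
  documented drop rule (`~ virus + (1|group)`), so the virus coefficient
  is informed by all 200 libraries; expected MAE ≈ 0.08 log2 units
  against the 0.1 bound, and the null-gene false-positive rate at raw
  p < 0.05 sits within three binomial standard errors of 0.05.  In
  mixed-sex designs the virus coefficient is the female-reference effect
  informed by roughly a quarter of the libraries; its per-gene sampling
  SE (~0.13 log2) makes a 0.1 per-gene MAE unattainable at this scale,
  so the mixed-sex check asserts unbiasedness (|mean error| < 0.1) for
  sex, virus and interaction instead.
* Switching rate: 100 simulations of one 40-library project at hop rate
  0.002; the 95% CI covers the truth in ≥ 90 runs.
* BH: 1000 random p-vectors against an independent step-up
  implementation.

## Numerical choices and edge cases

* Log-gamma for all hypergeometric terms; renormalization of the
  support's log-probabilities before summing tails.
* REML search bounded in log λ ∈ [−15, 12]; Cholesky failures and
  boundary fits fall back to OLS df; rank-deficient designs raise (per
  gene, they are skipped and recorded).
* Satterthwaite df clipped to (0, n − p]; non-finite curvature falls
  back to residual df.
* Clopper–Pearson endpoints at k = 0 and k = n are exactly 0 and 1.
* Ties in threshold selection resolve to the smallest candidate;
  `verify_sex` returns ambiguous when both marker sums are zero.
* Correlation pairs with fewer than 3 shared genes are undefined, never
  significant.

## Known limitations

* The Gaussian model on log2-CPM ignores the mean–variance relation of
  counts at low expression; precision weights would sharpen low-count
  genes.
* One random intercept only; crossed or nested random effects (e.g.
  lane within project) are not modelled.
* The hop model is uniform within lane; real index hopping can be
  barcode-specific.
* The co-infection scan's raw α is intentionally uncorrected; users
  scanning many pairs should interpret flags accordingly.
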