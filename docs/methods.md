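# Methods

## The problem

Quantitative RT–PCR of circular RNAs asks a proportion question: did the
fraction of a gene's transcripts that end up in the circular form (or that
include a circRNA-enriched alternative exon) change between genotypes? The
classical 2^ΔΔCt workflow answers a related but different question — the
change in a single transcript's abundance relative to a housekeeping gene —
and it quantifies uncertainty poorly when the measurements are correlated,
as they are here: technical triplicates share an animal, animals share
litters, and plates of wells share a qPCR run. This package implements both
the classical workflow and a hierarchical Bayesian treatment of the raw
threshold-cycle (Ct) values whose headline output is the cross-genotype
**ratio of ratios** with posterior credible intervals.

## The hierarchical Ct model

For a detected well `i` with primer `p`, genotype `g`, sex `s`, run `r`,
litter `l`, animal `a`:

    Ct_i ~ Normal(alpha_p + beta_{p,g} + gamma_{p,s} + u_r + v_l + w_a,
                  sigma_{p,r})

    u_r ~ Normal(0, tau_run),  v_l ~ Normal(0, tau_litter),
    w_a ~ Normal(0, tau_animal)
    log sigma_{p,r} = eta0 + eta_p + eta_r

- Fixed effects: per-primer intercept, full primer×genotype and primer×sex
  interactions. Corner (reference-level) coding: `beta_{p,wt} = 0` and
  `gamma_{p,F} = 0`, so `beta_{p,g}` is the Ct shift of genotype `g`
  relative to wild type for primer `p`, in cycles.
- A Normal observation model on the Ct scale is the natural choice here:
  Ct is a log-scale quantity (one cycle ≈ one doubling), so additive
  effects on Ct are multiplicative on expression and all ΔΔCt arithmetic
  is linear.
- Technical replicates enter as raw observations; the animal intercept
  absorbs the within-animal correlation, which is precisely why pre-
  averaging is unnecessary and wasteful of variance information.
- Residual SD varies by primer and run through a log-linear decomposition
  (`eta0 + eta_p + eta_r`), the most parsimonious structure that lets both
  factors act multiplicatively.

Priors (weakly informative on the plausible qPCR range, overridable via
`ModelSpec.priors`): `alpha ~ Normal(20, 10)` cycles, `beta, gamma ~
Normal(0, 5)`, `tau ~ half-Normal(0, 5)`, `eta ~ Normal(0, 1)`. The eta
scale bounds the residual SD roughly within e^±2 of its baseline, wide for
a well-behaved assay.

Non-detects (no threshold crossing by the plate ceiling, default cycle 40)
are excluded by default; `nondetect_policy="censor"` instead treats them as
upper-censored at the ceiling via truncated-Normal data augmentation.
Detected values above Ct 30 are flagged low-confidence by the simulator,
mirroring the variance inflation seen for physiologically scarce targets.

### Sampling

The sampler is a blocked Gibbs scheme written for this model:

1. **Scales.** Each `tau` is updated by univariate slice sampling on
   `log tau` against the *marginal* likelihood in which all varying
   intercepts are integrated out analytically (a Woodbury identity through
   the `(R+L+A)`-dimensional capacitance matrix). Collapsing removes the
   funnel-shaped coupling between scales and effects — including the
   litter–animal ridge that arises because litters are small groups of
   animals — and is the difference between effective sample sizes of ~60
   and ~600 per 800 draws on the cohort-sized fixtures.
2. **Locations.** All location parameters (`alpha, beta, gamma, u, v, w`)
   are then drawn jointly from their exact multivariate-Normal full
   conditional (one Cholesky of a K×K precision matrix, K ≈ 20–50).
3. **Residual SDs.** `eta0`, each `eta_p`, each `eta_r` by univariate slice
   sampling, followed by an exact Gaussian recentring move between `eta0`
   and the offsets (the likelihood constrains only their sums).

Chains are seeded through `numpy.random.SeedSequence.spawn`, so a given
`(seed, chains, draws)` is bit-reproducible. Convergence is gated on split
R-hat < 1.01 and bulk ESS ≥ 100 per chain (arviz) over the population-level
parameters (`alpha, beta, gamma, tau, eta0`); group-level offsets are
reported but not gated, matching how mixed-model software summarizes them.
When the gate fails, varying intercepts are dropped in the order **litter,
then run** and the model is refitted; the animal intercept and all fixed
effects are never dropped, and every fallback is recorded in the result's
warnings. The drop order is a policy choice: the litter scale is typically
the least identified (fewest groups) and litter effects cancel from the
ratio estimands anyway.

Defaults: 4 chains × 500 post-warmup draws (300 warmup); at least 400
post-warmup draws in total are required. The test-suite and acceptance
fixtures use 2 chains × 400 draws, which passes the same gate on the
cohort-sized problems they fit — problem sizes chosen as representative of
the designs this package targets (tens of animals, a handful of primers).

## Estimands

With expression inferred from the quantification identity
`E = eff^(-Ct)` (`eff` = amplification efficiency, fold per cycle, in
(1, 2]), the population-level mean Ct of primer `p` in genotype `g` is

    ct(p, g) = alpha_p + beta_{p,g} + mean_s gamma_{p,s}

(varying intercepts at zero, sexes averaged with equal weight — the
population summary; the data's sex composition does not reweight it).
The ratio of the target:canonical expression ratio between genotypes is,
per posterior draw,

    Q = eff_t^-(ΔΔCt_t) * eff_c^+(ΔΔCt_c),
    ΔΔCt_x = ct(x, g_num) - ct(x, g_den)

Everything shared between the two species cancels: the reference gene, run,
litter and animal offsets, the sex marginal. Reference-gene independence is
therefore structural, and the tests assert it is bit-exact. `Q < 1` means a
smaller circular (or alternative-exon) proportion in the numerator
genotype.

Summaries: posterior mean of Q (the reported point estimate; the geometric
mean `exp(mean(log Q))` is also exposed since the posterior of a ratio is
right-skewed), equal-tailed 50% and 95% credible intervals (order-statistic
reproducible, unlike HPD), and the significance call "the 95% interval
excludes 1". The absolute-expression estimand replaces the canonical primer
with the reference gene — same closed form, but no longer
reference-independent by construction (that is its point).

Efficiency sensitivity recomputes Q over a grid of efficiency assumptions
(default {1.8, 1.9, 2.0} applied jointly) and reports whether the sign of
log Q and the excludes-one verdict survive. Equal efficiencies act as a
monotone transform of a fixed ΔΔCt contrast, so sign stability under joint
variation is exact; unequal target/canonical efficiencies can genuinely
move Q, which is why the grid accepts pairs. Default efficiency is 2.0 for
all primers (results reported assuming equal efficiency).

## The 2^ΔΔCt baseline

Triplicates are averaged over detected replicates (all-non-detect wells
propagate the flag, partial wells warn); ΔCt = Ct_target − Ct_reference
within animal, using the same-run reference when available (run offsets
then cancel exactly, mirroring the model's run intercept) and the pooled
per-animal reference otherwise; FC = 2^(mean ΔCt of control − ΔCt of
animal), so the control group's geometric mean FC is exactly 1. Group
summaries are Tukey box-plot statistics with type-7 (linear interpolation)
quartiles and 1.5×IQR whiskers — the convention is stated because the
fences are not reproducible without it. Tests: Student, Welch (default —
safest under unequal variances, and the sources describing this workflow
are ambiguous about the variant used), paired, and Mann–Whitney; stars at
p < 0.05/0.01/0.001. Constant nonzero paired differences make the paired t
statistic unbounded; the implementation warns and reports p → 0 rather than
failing.

## circRNA count comparison

BSJ count tables (CIRI2/CIRIquant-like TSV dialect, ids `chrom:start|end`,
1-based inclusive) are normalized to counts-per-median-library; in the
pipeline the host-gene table's column sums serve as library sizes for both
tables, the closest desk-scale stand-in for the depth normalization the
upstream quantifiers perform (flagged as such in output metadata).
circRNAs with mean normalized BSJ < 3 across all samples are excluded
(boundary inclusive). log2 fold changes use pseudocount 0.5 (avoids
infinities at zero counts). Significance uses a two-sided label-permutation
test on |log2FC| — a distribution-free stand-in for the negative-binomial
DE machinery, defensible at these group sizes — with Benjamini–Hochberg
FDR. All `C(n, n_b)` relabelings are enumerated when there are ≤ 10,000;
the exhaustive p is `#{splits with |lfc| ≥ observed}/n_splits` (the
observed split counts itself), which is exactly the limit of the add-one
Monte-Carlo estimator `(1 + #exceed)/(1 + n_perm)` used otherwise. Designs
admitting fewer than 20 splits are rejected.

Significant circRNAs (|log2FC| > 1, FDR < 0.05) are classified against
their host gene in this precedence order:

1. `circ_only` — host gene shows no reliable change (host FDR ≥ threshold;
   the magnitude criterion is deliberately not applied to the host, so a
   reliably detected sub-twofold host shift still counts as a host
   response);
2. `inverse` — host changed significantly in the opposite direction;
3. `circ_amplified` — same direction, circRNA shifted by the larger factor;
4. `concordant` — otherwise.

Filtered rows keep `filtered`; kept-but-non-significant rows get
`not_significant`, so the classification is total. Counts past a plain
twofold criterion (log2FC beyond ±1) are also reported.

## The synthetic-data generator

The Ct generator reproduces the nested cohort structure of a two-genotype
mouse study: by default 6 homozygous mutants (4 male, 2 female) versus 4
wild types (2/2), 3 litters, 2 qPCR runs, technical triplicates, with a
larger ~10-vs-10, 4-litter variant for validation-cohort layouts. Animals
are assigned to litters and runs round-robin within genotype, so genotype
is never confounded with run or litter, and each animal's wells sit in one
run. Each record is the sum of the fixed effects, one draw per
run/litter/animal, and replicate noise; values past cycle 40 become
non-detects.

Default magnitudes (real variance components differ between assays and
facilities; these are fixed, representative choices): baseline Ct 18 (reference), 22
(linear), 24 (circular/alt-exon) — an abundant housekeeper and mid-range
targets; sd_run 0.5, sd_litter 0.3, sd_animal 0.5 cycles and residual SD
0.25 cycles — run-to-run shifts of about half a cycle and sub-half-cycle
technical noise are typical of careful SYBR assays; a +1-cycle shift of the
circular/alt-exon primers in the mutant (true Q = 0.5 at efficiency 2, the
twofold deficit of interest); a +0.1-cycle male offset so the sex terms are
exercised. The true Q is available in closed form from the shifts and
efficiencies, which is what the calibration tests check coverage against.

The count generator draws negative-binomial counts (dispersion 0.1,
`var = mu + 0.1 mu^2`) with log-normal library sizes (CV 0.2 around 2×10^7)
for ~30 circRNAs spanning the abundance range, a fifth of them shifted by
|log2FC| 1.5–2.5 against essentially flat host genes — the discordant
pattern the classifier is meant to find.

What the generators do **not** emulate: amplification curves or efficiency
drift within a plate, non-Normal heavy-tailed well failures,
between-primer residual correlation, count overdispersion that varies by
feature, and any read-level structure (junction discovery is out of
scope). Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to assay pathologies the
model excludes.

## Numerical and design notes

- Slice sampling uses stepping-out with shrinkage, width 1.0 (log-scale
  scales) or 0.5 (etas), capped step-outs; `log tau` is bounded in
  [log 1e-4, log 1e3] cycles — a floor of a ten-thousandth of a cycle is
  numerically zero variance.
- The location draw adds the prior precision to the diagonal before one
  Cholesky factorization; no matrix is ever inverted explicitly.
- Equal-tailed intervals come from `numpy.quantile` (type-7), so every
  interval is reproducible from the stored draws file.
- Ct CSVs store non-detects as `Undetermined` and parse `NA`/empty as
  non-detects too; decimal points only (no locale-dependent parsing).
- Posterior draws persist as a long CSV (chain, draw, parameter, value)
  with the factor levels in a `# coords:` header line, so estimands can be
  recomputed from the file alone.

## Known limitations

- The permutation test has coarse p-value granularity at small group sizes
  (minimum p = 1/20 at 3-vs-3), so FDR thresholds near that floor are
  blunt; this matches its role as a small-cohort stand-in.
- The fallback order (litter, then run) is a fixed policy, not a data-driven
  model search; with very small designs the full model will often reduce.
- PPC statistics (per-primer SD, per-run SD, min, max) target variance
  calibration; they have little power against mean-structure errors, which
  the recovery tests cover instead.
- Efficiency is an assumption, not estimated: there is no dilution-series
  (standard-curve) module.
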