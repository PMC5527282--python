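# Methods

## Polarization factor ratio

The PFR summarises a strain's macrophage polarization state as

    ratio_s = E[numerator, s] / E[Arg1, s]          (RMA scale)
    PFR_s   = ratio_s / mean_s(baseline ratio_s)

with `Il12b` as the default numerator and `Nos2` as the alternative.
Three conventions deserve comment:

* **The ratio is taken on RMA (log2) values directly**, not as a
  difference of logs. This follows the printed definition of the
  statistic faithfully even though a ratio of logarithms is an unusual
  quantity; because RMA intensities are strictly positive and bounded
  (roughly 2–14), the ratio is well defined and monotone in the
  underlying polarization contrast. The package deliberately does not
  "correct" this to `2**(num − den)`.
* **Both conditions are normalized by the baseline population mean**, so
  `pfr_base` averages to exactly 1 across strains and `pfr_lps`
  measures the shift relative to the untreated population state.
* **Replicates are averaged on the RMA scale before the ratio.** The
  alternative order (ratio first, then average) is nearly identical for
  tight replicates; one order had to be fixed and this one is it.

The normalizing mean is the arithmetic mean of per-strain ratios.
Strain ranking is ascending in PFR with lexicographic tie-break on the
strain id, making the rank a deterministic permutation.

## Signature extraction

Each gene's replicate-averaged LPS expression is Pearson-correlated
with the LPS-condition PFR across strains. P-values come from the
two-sided t test `t = r·sqrt((n−2)/(1−r²))` on n−2 df; within numerical
resolution of collinearity (1 − r² < 1e-14) p is reported as 0.
Benjamini–Hochberg adjustment is computed in one family over all
non-constant genes. A gene enters a signature only if it passes **both**
P < 1e-4 and FDR < 5% (defaults; both exposed as parameters). Positive r
defines M(LPS)+, negative r defines M(LPS)−; within each list genes are
ordered by |r| descending so that "top N" subsets are well defined.
Constant genes are skipped and counted.

The mapping *positive correlation ⇒ M(LPS)+* is the package's fixed
convention; the alternative sign assignment is not offered because it
would silently flip every downstream interpretation.

Mouse-to-human symbol matching is case-insensitive uppercase equality.
This is a deliberate proxy: real cross-species application needs an
ortholog map, which is out of scope, and the proxy's coverage (~70% in
typical mouse-to-human transfers) should be kept in mind.

## Enrichment analysis

The enrichment score walks the ranked list; hits add
`|score|^p / Σ_hits |score|^p` (p = 1 by default, "weighted"), misses
subtract `1/(N − N_hit)`, and ES is the signed maximum deviation. With
p = 0 every hit adds `1/N_hit` (classic unweighted KS form). Numerical
choices: the running sum ends at 0 by construction; when the maximal
positive and negative deviations tie within 1e-12 the positive branch
is taken, so the sign is stable under floating-point summation order;
a set whose matched scores are all exactly zero falls back to equal
hit increments.

Null distributions: **gene-set permutation** (random equal-size member
sets drawn from the list) for preranked input, **phenotype permutation**
(label shuffles with full re-ranking by signal-to-noise) for two-class
input. NES is sign-matched — positive ES divided by the mean positive
null ES, negative by the mean |negative null|. The nominal p is the
add-one-smoothed one-sided frequency among same-sign nulls, so its floor
is 1/(n_same + 1), not 1/(n_perm + 1). FDR q compares the observed NES
against the pooled normalized null NES of matching sign (tail-ratio,
capped at 1); with a single query set this degenerates to the set's own
null tail and should be read accordingly. `n_perm` defaults to 100,
matching common practice for the weighted statistic; calibration
checks in the test suite use 1000 for stability.

The two-class metric is signal-to-noise, `(μ_A − μ_B)/(σ_A + σ_B)`,
with each class σ floored at `max(0.2·|μ|, 0.2)` — the shrinkage that
keeps near-constant genes from dominating microarray rankings.
Single-dataset ("pre-weighted") ranking uses mean expression.

### Activation axis

A dataset's position on the M1/M2 responsiveness spectrum combines the
NES of the top-200 (by |r|) M(LPS)+ and M(LPS)− signature genes. The
score is the **difference** `NES+ − NES−`: when a dataset is M1-skewed,
NES+ > 0 and NES− < 0, and a quotient of the two would be negative —
contradicting the intended "positive = LPS-high" semantics. The
difference preserves those semantics; the raw quotient is still
reported for comparison. This was a genuinely open design point and is
the package's own resolution.

## Survival analysis

* **Per-gene survival z**: univariate Cox regression of the hazard on
  standardized expression, one gene at a time; score = Wald z = β/se.
  Positive z means higher expression ⇒ higher hazard, so gene lists that
  "correlate with cancer death" enrich at the top. This is a locally
  computed, single-cohort analogue of survival gene-rank databases; an
  unweighted Stouffer combination is provided for multi-cohort use.
* **Tumour-specific gene set**: the signature's enrichment on the
  survival ranking is computed internally, and the k (10 or 30)
  highest-ranked leading-edge members are kept — fewer, with a warning,
  when the leading edge is short.
* **Scoring and split**: per-sample unweighted mean RMA expression over
  the matched set; samples with score strictly above the cohort median
  are "high", the rest "low" (ties at the median deterministically go
  low).
* **Kaplan–Meier** is the product-limit estimator at distinct event
  times. **Log-rank** accumulates observed-minus-expected events with
  the hypergeometric variance. **Cox fits** use Newton–Raphson on the
  partial likelihood with Breslow tie handling, convergence at
  |Δβ| < 1e-8 within 50 iterations; |β| > 50 is reported as divergence
  (monotone likelihood). The 95% CI is the Wald interval exp(β ± 1.96·se).
  Breslow was chosen over Efron because ties are rare for continuous
  signature scores and the estimators then coincide.

## Synthetic data

The generators emulate the study design the analysis targets, on the
RMA log2 scale, clipped to [2, 14]:

* **Strain panel** (defaults: 83 strains, 2000 genes, 200 + 200
  responders, β = 1 log2-unit per unit responsiveness, noise σ = 0.3):
  latent responsiveness r_s ~ Uniform(0,1); per-gene baseline
  b ~ Normal(μ_g, 0.3) with μ_g ~ Uniform(4, 10); LPS value
  x = b + β_g·r_s + ε, ε ~ Normal(0, noise_sd). Anchors carry the
  canonical pattern — Il12b (+4β, low baseline), Nos2 (+3β, low
  baseline), Arg1 (−2β, high and doubly variable baseline). Uniform
  latent responsiveness keeps the correlation interpretation simple;
  the real spectrum is continuous but its distribution is unknown.
* **Case/control cohorts**: controls Normal(μ_g, σ), cases shifted by a
  constant on a known gene set; labels are CLS-compatible.
* **Survival cohorts**: event times Exponential with rate
  h0·exp(logHR·z), z the standardized mean signature expression;
  censoring is independent Uniform(0, τ) with τ solved (Brent) so the
  expected censored fraction matches the request. The per-SD log HR is
  recovered by a continuous Cox fit on z; the binary high/low HR is a
  different (larger) estimand because dichotomisation at the median
  separates the groups by ≈1.6 SD.

What the generators do **not** model: probe-level effects, batch and
array artifacts, correlated gene programs beyond the single latent
factor, non-proportional hazards, informative censoring, mixed cell
populations. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted structure — not
robustness to the full messiness of real cohorts.

At the default panel conditions the dual-threshold screen recovers the
planted responder programs with mean precision ≈ 1.0 and mean recall
≈ 0.9 over ten seeds; individual seeds range down to ≈ 0.7 recall when
the Arg1 baseline draw happens to distort the PFR, which is the
expected behaviour of a ratio-based marker under anchor noise.

## Problem sizes and determinism

Simulation-based checks use 10 panels for signature recovery, 200
random sets × 1000 permutations for null GSEA calibration, 500 cohorts
of n = 100 for log-rank type-I error, and 20 cohorts of n = 400 for Cox
recovery — sizes at which the binomial/Monte-Carlo error of each
asserted bound is small relative to the bound itself. Every stochastic
routine takes an explicit seed; the pipeline fans a single global seed
out as seed + stage index, and identical configurations produce
byte-identical artifacts and manifest checksums.

## Known limitations

* The PFR is a two-gene marker; a strain with an atypical Arg1 baseline
  can be mis-ranked (visible in synthetic panels as occasional
  low-recall seeds).
* The expression-universe filter ("genes expressed") is left to the
  caller; no floor is imposed before correlation beyond dropping
  constant genes.
* FDR q for small set collections is coarse, as in any pooled-null GSEA.
* Single-covariate survival models only: no clinical covariate
  adjustment, time-dependence or competing risks.
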