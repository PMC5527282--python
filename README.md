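# polarspec

Population-spectrum analysis of macrophage LPS activation.

Most transcriptomic comparisons of "LPS-treated vs control" macrophages
assume a single genetic background. Across a genetically diverse
population — a panel of inbred mouse strains, or human individuals — the
strength of the LPS response is itself a continuous trait, and averaging
across the population destroys the signal. `polarspec` implements the
population-spectrum alternative for immunologists and computational
biologists working with multi-strain or multi-donor expression panels:

1. **Polarization factor ratio (PFR).** Each strain's M1/M2 balance is
   summarised as the ratio of a pro-inflammatory marker to arginase-1 on
   RMA-scale (log2, quantile-normalized) expression, normalized to the
   population's baseline mean:

       PFR_s = (E[Il12b, s] / E[Arg1, s]) / mean_s(E[Il12b, s] / E[Arg1, s] at baseline)

   (iNOS/`Nos2` can replace `Il12b` as the numerator). Ranking strains by
   the LPS-condition PFR orders the population from LPS-low to LPS-high
   responders.

2. **Responsiveness gene signatures.** Every gene's LPS expression is
   Pearson-correlated with the PFR across strains; genes passing
   *P* < 1e-4 **and** Benjamini–Hochberg FDR < 5% form the M(LPS)+
   (positively correlated, pro-inflammatory) and M(LPS)− (negatively
   correlated, homeostatic) signatures, ranked by |r|.

3. **From-scratch GSEA.** A weighted running-sum enrichment statistic
   with gene-set or phenotype permutation, sign-matched NES, nominal
   permutation p, pooled-null FDR q and leading-edge extraction. The
   **activation axis** score, NES(M(LPS)+) − NES(M(LPS)−), places any
   dataset on the M1/M2 responsiveness spectrum.

4. **Survival stratification.** Per-gene univariate Cox z-scores rank a
   tumour cohort's genes by survival association; the top leading-edge
   signature genes on that ranking define a tumour-specific set whose
   mean expression, median-split, is compared by Kaplan–Meier curves,
   the log-rank test and a binary Cox hazard ratio — all implemented
   from first principles (Newton–Raphson partial likelihood, Breslow
   ties).

A synthetic-data module generates strain panels, case/control cohorts
and survival cohorts with planted ground truth (latent responsiveness,
responder gene sets, per-SD log hazard ratios), so every stage is
testable end to end.

## Worked example

```
$ polarspec run --seed 1 --out demo_run
{
  "case_control_axis_score": 2.0473909878541896,
  "case_control_nes_pos": 2.7221985034845595,
  "case_control_p_pos": 0.005025125628140704,
  "pfr_responsiveness_spearman": 0.9455312539356029,
  "signature_precision": 0.9945054945054945,
  "signature_recall": 0.905,
  "survival_hr_high_vs_low": 3.491213242611215,
  "survival_logrank_p": 3.650938402940697e-13,
  "survival_planted_log_hr": 0.7
}
```

This simulates an 83-strain panel (2000 genes, 200 planted positive and
200 negative responders), ranks the strains by the IL-12β/Arg1 PFR —
which tracks the planted latent responsiveness with Spearman ρ ≈ 0.95 —
and recovers the planted responder programs with 99% precision and 91%
recall under the dual significance threshold. A simulated case/control
cohort shifted on M(LPS)+ genes scores +2.05 on the activation axis
(positive = LPS-high/M1-skewed; the planted set reaches NES 2.7,
permutation p ≈ 0.005 at 200 permutations). A 200-patient survival
cohort with hazard increasing in the M(LPS)− score (log HR 0.7 per SD)
stratifies into high/low signature groups with hazard ratio 3.5 and
log-rank p ≈ 4e-13. All artifacts (`pfr.tsv`, `sigs.gmt`, `gsea.tsv`,
`axis.tsv`, `survival_report.tsv`, `manifest.json`) land in `demo_run/`.

Individual stages are exposed both as library functions and as
subcommands (`polarspec simulate | pfr | signatures | gsea | classify |
survival`) operating on standard GCT / GMT / RNK / CLS / survival-TSV
files.

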