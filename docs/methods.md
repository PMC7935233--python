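# Methods

## The problem

In pharmacogenetic studies with very small cohorts (around a hundred
subjects) and a few hundred candidate SNPs, conventional polygenic-risk-score
construction — selecting SNPs by per-marker p-value and weighting them by
regression coefficients — overfits badly: no individual marker reaches
significance, and coefficients estimated at n ≈ 100 are noise.  `ppskit`
implements an alternative: unweighted −1/0/+1 allele scores, selected not by
effect size but by the *stability* of each allele's association with a
dichotomised outcome under repeated random half-splitting of the derivation
sample.

## Data model

Genotypes are three-category calls coded 1/2/3 (e.g. AA/AC/CC), subjects ×
SNPs, with missing cells allowed.  The outcome is ΔSSE, the integer change in
the count of satisfactory sexual events between a placebo run-in period and
an active on-demand treatment period; its dichotomisation ΔSSE_D labels
ΔSSE ≤ 0 as non-responder (1) and ΔSSE ≥ 1 as responder (2).  Orientation
(which homozygote is the "risk" category) is estimated from the data, not
assumed from allele frequencies.

## Derivation procedure

1. **Pre-filters.** Optionally restrict to SNPs annotated to candidate genes
   (a whitelist; unannotated SNPs drop).  Exclude SNPs with any missing call
   (default policy; a pairwise-complete mode exists) and SNPs in which any
   observed genotype category has fewer than `min_obs = 3` observations or
   which are monomorphic — a category mean estimated from one or two subjects
   would dominate the orientation step.
2. **Matched assignment.** Subjects are sorted by ΔSSE (ties broken by
   subject id), consecutive pairs are formed, and a seeded coin sends one
   member of each pair to the *first derivation set* and one to the
   *intermediary set*; an odd leftover joins the first derivation set.  This
   yields ceil(n/2) / floor(n/2) groups (65/64 at n = 129) whose outcome
   distributions agree up to within-pair substitutions.  Matching uses ΔSSE,
   the quantity subjects are ordered by; matching on run-in counts is
   available via `match_on="sse_pri"`.
3. **Recoding.** On the first derivation set only, the mean *raw* ΔSSE per
   observed genotype category orients each SNP: lowest mean → −1, highest →
   +1, middle → 0 (ties: lower category code takes the lower rank).  These
   maps are estimated once and reused unchanged by every later stage.
4. **Initial correlation filter.** Pearson r between the recoded allele and
   ΔSSE_D, on the first derivation set; alleles with r < 0.1 (or undefined r)
   are excluded.  The threshold is signed, not absolute, because recoding has
   already oriented each allele.
5. **Signed split and sign choice.** The recoded variable splits into a
   negative-risk indicator (−1/0) and a positive-risk indicator (0/+1).  On a
   random half of the first derivation set, the indicator with the higher
   signed correlation with ΔSSE_D is kept per SNP (undefined loses; an exact
   tie goes to the positive-risk indicator).
6. **Stability rounds.** The first derivation set is randomly halved;
   alleles whose correlation with ΔSSE_D is negative or undefined in either
   half are excluded; the set is reshuffled and the round repeated (2 rounds).
   r = 0 survives: only values *lower than* the threshold are excluded.
7. **Finalisation.** Half of the intermediary set (seeded; the larger half
   on odd sizes) joins the derivation set — 97/32 at n = 129 — and two
   further stability rounds run on this final derivation set, for four
   rounds in total.
8. **Scoring.** Each survivor contributes its restricted map (negative-risk
   survivors: the −1 category scores −1, everything else 0; positive-risk:
   +1 or 0).  The per-subject sum is the Phenotype Prediction Score; missing
   or unseen genotypes contribute 0, so |PPS| ≤ number of survivors.

All randomness derives from one master seed through named sub-streams
(assignment, sign-split, each stability round, finalisation), so the whole
pipeline and any single stage are exactly reproducible; two runs with the
same data, configuration and seed serialise to byte-identical model JSON.

## Evaluation

**Patient level.** ROC curves and AUC (Mann–Whitney convention, ties count
½) on the derivation, validation and full sets, with 95% CIs from the
Hanley–McNeil standard error (z = 1.96, clipped to [0, 1]); the DeLong
estimator is available via `ci_method="delong"`.  AUC = Φ(d′/√2) converts to
the binormal sensitivity index; d′ = 0.8 ↔ AUC ≈ 0.714 is the usual
"large effect" reference and AUC > 0.80 the customary clinical-utility bound.
The responder cutpoint maximises Youden's J over midpoints of adjacent
distinct scores (exact integer comparison; ties take the lowest threshold)
**on the derivation set only** and is reused verbatim on the validation and
full sets, so held-out statistics never see held-out labels.  Confusion
statistics (sensitivity, specificity, PPV, NPV, accuracy) report NaN on a
zero denominator.

**Group level.** Within the predicted responders and predicted
non-responders separately, a Friedman rank test over the two paired
conditions (run-in vs active counts; when only ΔSSE is known the pair
(0, ΔSSE) is used — it has the identical within-pair rank structure).  With
k = 2 the statistic reduces to (n₊ − n₋)²/(n₊ + n₋) on tie-free data; tied
pairs enter through the standard correction 1 − Σ(t³ − t)/(nk(k² − 1)).
When every pair is tied the statistic is 0 (warning).  scipy's Friedman test
requires k ≥ 3, so the k = 2 statistic is computed directly and is
cross-checked against R's `friedman.test` in the test suite.  Kendall's
W = χ²/(n(k − 1)), clipped to [0, 1], is the effect size: W = 1 means every
subject moved in the same direction.  Published two-condition W values
computed under other software's tie conventions may differ from this
package's in the second decimal.

## Synthetic cohorts

The generator emulates the study conditions the method was designed for: 129
subjects × 285 candidate SNPs.  Genotypes are drawn per SNP from
Hardy–Weinberg proportions at a minor-allele frequency drawn uniformly from
(0.1, 0.5) unless fixed; ΔSSE = round(N(0.5, 2.5²) + Σ planted effects),
where each planted SNP shifts the outcome by `effect_size` per step of a
random ±(−1/0/+1) orientation.  The noise scale matches the variability of
two-week diary event counts (run-in mean ≈ 3.6, SD ≈ 2.6); the baseline mean
of 0.5 puts the responder dichotomisation near the centre of the null
outcome distribution.  Presets: `strong` (20 planted, effect 0.8),
`moderate` (effect 0.4), `null` (no effects).  The generator has no linkage
disequilibrium, population structure, genotyping error or covariates, so
passing tests say nothing about those aspects of real cohorts.

## What the simulations show — and an honest limitation

Under the `null` preset, the mean validation AUC over 50 seeded runs is
≈ 0.50 (the test asserts [0.45, 0.55]): the held-out half of the
intermediary set is never touched by selection, so the method does not
*inflate* held-out performance even when it selects dozens of noise alleles.

Under the `strong` preset the method does **not** recover the planted panel:
each planted allele's point-biserial correlation with ΔSSE_D is only ≈ 0.11,
of the same order as the r ≥ 0.1 filter threshold, while the orientation
step — fitted on the same 65 subjects the initial filter uses — biases null
correlations upward enough that roughly half the noise SNPs pass it.  Median
over 10 seeds: validation AUC ≈ 0.57 with ≈ 12% of survivors planted, and
the corresponding acceptance test is expected to fail under these
conditions.  Even an oracle score built from the true planted set and true
orientations reaches only ≈ 0.85 full-cohort AUC here, so the per-SNP signal
is simply too weak for any selection rule at n = 65.  The derivation-set AUC
meanwhile exceeds 0.95 — a vivid illustration of why the held-out validation
set is indispensable.  Strong per-allele signals (r ≈ 0.5) do survive the
four rounds with high probability, as the unit suite verifies on planted
single columns.

## Numerical conventions

* Undefined correlations (zero variance, or fewer than 3 complete pairs)
  fail every filter — a constant column carries no stable signal.
* Tie-breaks are fixed and documented: category-code order in recoding,
  positive-risk preference in sign choice, lowest threshold in the cutpoint
  scan (exact integer arithmetic, no floating-point ties).
* Odd-size splits always favour the first-named set (derivation1, set 1x,
  derivation), which reproduces the 65/33/97 sizes.
* Problem sizes in the test suite follow the presets (129 × 285; 50 null
  seeds, 10 strong seeds), keeping the full suite under ten seconds.

## Known limitations

* No linkage-disequilibrium pruning or imputation; SNPs with missing calls
  are excluded by default (an LD-aware imputation hook is a natural
  extension).
* Multi-allelic sites cannot be represented in the 1/2/3 coding and are
  rejected at VCF ingestion.
* Recode maps are never re-estimated after the first derivation set; a
  category unseen there scores 0 at scoring time.
* The method's selection is unweighted by design; it will not outperform
  regression-based scores when n is large enough to estimate weights.
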