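# Methods

## The call model

Each cartridge measures cycle thresholds (Ct) for four target transcripts
and the internal reference *CYFIP1*. The quantity of record is the
delta-Ct, `dCt = Ct(CYFIP1) − Ct(target)`; because Ct falls by one cycle
per doubling of template, higher dCt means more target mRNA relative to the
reference. Calls follow a fixed cascade:

1. reference gate — `Ct(CYFIP1)` absent or `> 35` invalidates the whole
   cartridge (all four analytes), since one multiplexed reference serves
   the run;
2. positivity — `dCt ≥ cutoff` is POSITIVE (cutoffs: *ESR1* and *ERBB2* −1,
   *PGR* −3.5, *MKI67* −4 dCt units);
3. input gate — a below-cutoff *PGR* or *MKI67* with `Ct(CYFIP1) > 31` is
   INDETERMINATE: a reliable negative for these two analytes needs more
   template, so the call carries a retest-with-full-lysate reason code;
4. otherwise NEGATIVE.

Boundary conventions, chosen once and applied everywhere: dCt exactly at
the cutoff is positive, reference Ct exactly 35 is valid, exactly 31
satisfies the input gate. Ct values are carried at full floating precision
with exact comparisons — the instrument-reported Ct is the unit of record.
A target with no amplification signal against a valid reference is treated
as dCt = −∞ (no detectable transcript, below any cutoff) and still passes
through the input gate; a failed reference leaves dCt undefined (NaN).
Both conventions are deliberate: absence of target and absence of
reference are different facts and are kept distinguishable.

## Reference scoring

ER/PR positivity is `percent ≥ cutoff` with cutoff 1 (guideline practice)
or 10; the two rules disagree exactly on the 1–9% low-positive stratum.
The H-score `3·(%3+) + 2·(%2+) + 1·(%1+)` summarises extent and intensity
on 0–300. HER2 IHC maps 0/1+ → negative, 2+ → equivocal, 3+ → positive;
equivocals reflex to FISH, positive at HER2/CEP17 ratio ≥ 2.0 (the
dual-probe guideline ratio criterion; the mean-copy-number arm of the full
guideline is out of scope, and FISH is applied only to 2+ — an
IHC-negative/FISH-positive override is not modelled). Ki67 uses either a
single cutoff (HIGH strictly above 10% or 20%, mirroring the "<10% low,
>20% high" convention, which leaves exact-boundary samples LOW) or a
three-zone rule with inclusive intermediate bands [10, 20] or [10, 30];
intermediate-zone samples are excluded from binary agreement analyses.

## Agreement statistics

Tables are built per analyte × comparator rule after an explicit exclusion
pass — INVALID and INDETERMINATE calls, equivocal or unresolved reference
statuses, intermediate-zone Ki67, and missing records all land in a ledger
that conserves `n_input = n_table + n_excluded`. On the remaining 2×2
counts (`a` ref+/test+, `b` ref−/test+, `c` ref+/test−, `d` ref−/test−):

* PPA = a/(a+c), NPA = d/(b+d), OPA = (a+d)/n, each with a 95% binomial
  interval — Clopper–Pearson exact by default (it reproduces the published
  validation intervals digit for digit), Wilson as an option;
* Cohen's kappa = (p_o − p_e)/(1 − p_e) with the Fleiss–Cohen–Everitt
  large-sample variance for its interval (cross-checked against
  statsmodels in the tests); degenerate margins leave kappa undefined;
* an empty margin leaves the affected statistic undefined (NaN) while the
  others are still computed. Percents are displayed rounded half-up to one
  decimal; raw proportions are always retained.

ROC curves sweep thresholds over the distinct observed dCt values, calling
a sample positive at `score ≥ threshold` — the same boundary rule as the
call engine. The trapezoidal AUC is numerically identical to the
Mann–Whitney pairwise probability with ties counted ½ (asserted against a
brute-force pairwise oracle and scikit-learn). Cutoff optimisation
maximises OPA over the midpoints between adjacent distinct scores plus ±∞
sentinels; ties break toward higher PPA (favouring sensitivity, the
costlier error in this setting) and then the smallest cutoff.

## The synthetic cohort

No per-sample data accompany the published validation study, so the
generator emulates the joint structure its figures display. Defaults are
fixed once, from the published aggregate counts where available and
otherwise at values a validation statistician would call realistic; every
parameter is exposed on `CohortSpec`.

* **ER/PR**: three latent classes — negative / low-positive / positive
  (ER 0.16/0.05/0.79, PR 0.24/0.12/0.64, matching the published marginal
  positive fractions of ~0.84 and ~0.74) — with Gaussian dCt components
  (ER: −5.5 ± 1.5, −1.0 ± 0.9, 4.5 ± 1.5; PR: −7.0 ± 2.0, −3.5 ± 1.2,
  1.0 ± 2.0). The low-positive component is centred on the assay cutoff:
  that is what makes near-cutoff samples the dominant source of
  discordance. Percent staining comes from a monotone logistic link of the
  true dCt with logit-scale Gaussian noise (ER σ = 0.7, PR σ = 1.7); the
  link midpoint is anchored so the 1%-staining boundary falls exactly at
  the dCt cutoff, which is precisely the statement that the assay cutoffs
  were chosen to maximise concordance with IHC. Intensity fractions
  (1+/2+/3+) split the percent by a Dirichlet draw skewed toward 3+ at
  high dCt.
* **HER2**: a latent amplified state (prevalence 0.14) with dCt 2.5 ± 1.3
  against 'normal' −4.0 ± 1.8. The IHC category is an ordered cut of the
  dCt plus noise (cutpoints −4.5/−2.2/1.6), so 2+ equivocals straddle the
  cutoff as observed; the FISH ratio is lognormal per state with a positive
  dCt slope, making ratio and dCt monotonically associated.
* **Ki67**: a single broad latent continuum (−4.1 ± 2.2 dCt) — no
  separated classes, reflecting the observed continuum — with the high/low
  truth label thresholding the latent value at the assay cutoff and the
  20%-staining link boundary anchored at the same point; link noise
  σ = 1.0 and assay noise σ = 1.3 give this analyte the weakest
  discrimination by construction.
* **Reference gene**: a two-group block-age mixture (15% old blocks,
  CYFIP1 Ct 33.8 ± 2.0 against 28.0 ± 1.5), yielding a marginal
  cartridge-invalid probability of ≈ 0.041 concentrated almost entirely in
  old blocks — about 21 invalid cartridges at the study size of 523 — and,
  as a side effect of old blocks sitting in the (31, 35] window, on the
  order of 15 indeterminate *PGR* and ~25 indeterminate *MKI67* calls,
  matching the scale of the reported exclusions. Observed target Ct is
  reconstructed as `Ct(CYFIP1) − dCt_observed`, where observed dCt adds
  instrument noise (σ = 0.3 for ER/HER2, 0.5 for PR, 1.3 for Ki67); Ct
  beyond 42 cycles is recorded as absent.

With these defaults the pipeline lands in the regimes the validation study
reports: AUC ≈ 0.999 (*ESR1*), 0.995 (*ERBB2*), 0.96 (*PGR*), 0.83
(*MKI67*) against the published 0.99/0.99/0.95/0.85, overall agreement
≈ 97–99% for *ESR1* and ≈ 71–80% for *MKI67* at the 20% rule. The
calibration is qualitative by necessity — the study gives distributions
only as scatterplots and reports no within-stratum dispersions — so bands
were set from the figure shapes and frozen.

What the generator does **not** emulate: inter-observer scoring
variability, multi-antibody/multi-laboratory comparators, continuous block
age, spatial tumor heterogeneity, or any correlation between analytes
beyond their shared reference gene and block age. Passing tests therefore
demonstrate that the machinery is correct and that the published operating
characteristics are reachable under a plausible data-generating process,
not that the assay performs identically on real tissue.

## Numerical and design choices

* Exact floating comparisons at all decision boundaries; no rounding of Ct
  or dCt on input. Display rounding (half-up, one decimal) is separate
  from computation.
* Clopper–Pearson via the beta-quantile form; kappa variance by the
  general Fleiss–Cohen–Everitt formula (valid for the 2×2 as a special
  case), truncated at zero before the square root.
* ROC threshold sweep uses a stable descending sort with an explicit +∞
  sentinel so curves start at (0, 0) and ties collapse to single vertices;
  `np.trapezoid` integrates the curve.
* Cutoff-search candidates are midpoints of adjacent distinct scores: any
  cutoff strictly between two adjacent scores classifies identically, so
  the search is exhaustive over equivalence classes.
* Determinism: one `numpy` Generator seeded from the `CohortSpec` drives all
  draws in fixed order; identical spec + seed reproduces the cohort files
  byte for byte.
* Problem sizes in the test suite (cohorts of 200–6,000; 50 cutoff-recovery
  replicates at n = 2,000; 200 AUC-ordering replicates at n = 523; 10,000
  draws per coverage cell) were chosen to keep the whole suite around a
  minute while leaving comfortable statistical margins.
* The default report enumerates the eleven analysis configurations of the
  published validation layout (two ER, two PR, three HER2 policies, two ER
  strata for HER2, two Ki67 rules).

## Known limitations

* The HER2 pathway models only the ratio criterion; in-situ copy-number
  categories and the IHC-negative/FISH-positive discordance pathway are
  not represented.
* The optimal-cutoff search targets OPA; prevalence-weighted or
  utility-weighted criteria (e.g. Youden's J) are not implemented.
* The published per-sample data are unavailable, so real-cohort ROC values
  are matched only qualitatively via the synthetic cohorts; published
  confidence intervals are reproduced for the binomial statistics but the
  original report's CI method is unstated and is treated as a soft check.
* Indeterminate and invalid calls are excluded from agreement analyses in
  all configurations; alternative policies (e.g. worst-case imputation)
  are not offered.
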