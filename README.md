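# strat4concord

Concordance analysis between RT-qPCR breast-cancer biomarker calls and the
IHC/FISH reference standard.

Breast-cancer treatment selection hinges on four biomarkers — ER, PR, HER2
and the proliferation antigen Ki67 — conventionally assessed on FFPE tissue
by immunohistochemistry (IHC), with fluorescence in-situ hybridisation
(FISH) resolving HER2 equivocals. A multiplexed RT-qPCR cartridge assay
(the STRAT4 panel on the GeneXpert platform) instead quantifies the
corresponding transcripts *ESR1*, *PGR*, *ERBB2* and *MKI67*, which matters
where IHC/FISH infrastructure is scarce. This package implements, for
biostatisticians and assay developers:

* the **call engine**: each target is scored by its delta-Ct against the
  *CYFIP1* reference transcript,

  `dCt = Ct(CYFIP1) − Ct(target)`,

  called POSITIVE when `dCt ≥ cutoff` (cutoffs −1 for *ESR1*/*ERBB2*, −3.5
  for *PGR*, −4 for *MKI67*), with two reference-gene gates: the cartridge
  is INVALID when `Ct(CYFIP1) > 35`, and a below-cutoff *PGR*/*MKI67*
  result with `Ct(CYFIP1) > 31` is INDETERMINATE (insufficient input —
  retest with the full section lysate) rather than NEGATIVE;
* the **reference scoring rules**: ER/PR positivity at 1% or 10% staining,
  the H-score `3·(%3+) + 2·(%2+) + 1·(%1+)`, HER2 IHC categories with FISH
  reflex of 2+ equivocals (HER2/CEP17 ratio ≥ 2.0), and Ki67
  proliferation-rate rules (single 10%/20% cutoffs or inclusive
  intermediate zones);
* the **agreement statistics**: 2×2 tables under explicit exclusion ledgers,
  PPA `a/(a+c)`, NPA `d/(b+d)`, OPA `(a+d)/n` with exact Clopper–Pearson
  (or Wilson) 95% intervals, Cohen's kappa `(p_o − p_e)/(1 − p_e)` with the
  Fleiss–Cohen–Everitt standard error, ROC/AUC over dCt scores, and
  concordance-maximising cutoff selection;
* a **synthetic cohort generator** emulating the joint structure of a
  paired validation series (bimodal dCt mixtures with a near-cutoff
  low-positive stratum, a Ki67 continuum, a block-age-driven ~4%
  cartridge-invalid rate, FISH ratios rising with *ERBB2* dCt), so every
  stage is testable end to end without patient data.

## Worked example

The published 523-specimen validation cohort released only aggregate 2×2
counts; they ship with the package, and pushing them through the agreement
machinery reproduces the printed statistics:

```python
>>> from strat4concord import agreement_stats, cohen_kappa, validation_tables
>>> t = validation_tables()["esr1_er_1pct"]   # a/b/c/d = 407/4/7/75
>>> rep = agreement_stats(t)
>>> rep.ppa.percent, rep.npa.percent, rep.opa.percent
(98.3, 94.9, 97.8)
>>> rep.ppa.ci_percent
(96.5, 99.3)
>>> cohen_kappa(t).percent
91.8
```

PPA 98.3% says 407 of the 414 IHC-positive tumors were also RT-qPCR
positive; OPA 97.8% is overall agreement, and kappa 91.8% is that agreement
corrected for chance. `examples/` holds one short script per capability
(calling panels, scoring IHC/FISH, reconstructing the published table,
ROC/cutoff recovery, the full eleven-analysis pipeline); each prints its
results with a line on what they mean. A thin CLI wraps the same library:

```sh
strat4-concord simulate --seed 7 --out cohort/
strat4-concord call --input cohort/panels.csv --output calls.csv
strat4-concord score --ihc cohort/ihc.csv --fish cohort/fish.csv --output status.csv
strat4-concord concord --calls calls.csv --reference status.csv --out report/
```

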