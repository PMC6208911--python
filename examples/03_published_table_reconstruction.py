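"""Recompute the published validation cohort's agreement statistics.

The validation study of 523 FFPE specimens published per-analysis 2x2
agreement counts (shipped with the package); pushing them through the
agreement machinery reproduces the printed PPA/NPA/kappa/OPA values with
exact Clopper-Pearson intervals.
"""

from strat4concord import agreement_stats, cohen_kappa, validation_tables

for analysis_id, table in validation_tables().items():
    rep = agreement_stats(table)
    kappa = cohen_kappa(table)
    lo, hi = rep.opa.ci_percent
    print(
        f"{analysis_id:27s} a/b/c/d={table.a}/{table.b}/{table.c}/{table.d}"
        f" n={table.total:3d}  PPA={rep.ppa.percent:5.1f}%"
        f"  NPA={rep.npa.percent:5.1f}%  kappa={100 * kappa.kappa:5.1f}%"
        f"  OPA={rep.opa.percent:5.1f}% ({lo:.1f}-{hi:.1f}%)"
    )
print(
    "\nPPA = a/(a+c) (sensitivity against the reference method), NPA ="
    "\nd/(b+d), OPA = (a+d)/n; kappa corrects OPA for chance agreement."
)
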