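"""Score reference-method observations: ER/PR cutoffs, H-score, HER2, Ki67.

Walks one sample through every scoring rule and shows where the 1% and 10%
hormone-receptor rules disagree (the 1-9% 'low positive' stratum), how an
IHC 2+ HER2 equivocal is resolved by FISH, and the Ki67 rules.
"""

from strat4concord import (
    h_score,
    her2_combined_status,
    her2_ihc_status,
    hormone_receptor_status,
    ki67_status,
)

pct_er = 5.0  # a low-positive ER tumor: 5% of cells stain
print(f"ER {pct_er}% staining -> 1% rule: {hormone_receptor_status(pct_er, 1)}, "
      f"10% rule: {hormone_receptor_status(pct_er, 10)}")
print(f"H-score for 10%/20%/30% at 1+/2+/3+: {h_score(10, 20, 30):.0f}  "
      "(= 1*10 + 2*20 + 3*30, range 0-300)")
print(f"HER2 IHC 2+ alone: {her2_ihc_status('2+')}; "
      f"with FISH ratio 3.1: {her2_combined_status('2+', 3.1)}; "
      f"with ratio 1.2: {her2_combined_status('2+', 1.2)}")
print(f"Ki67 15% -> 20% cutoff: {ki67_status(15, cutoff=20)}; "
      f"10-20% zone: {ki67_status(15, zone=(10, 20))}")
print(
    "\nThe 1%/10% disagreement defines the low-positive stratum; FISH"
    "\n(HER2/CEP17 >= 2.0) resolves only the 2+ equivocals; single-cutoff"
    "\nKi67 calls HIGH strictly above the cutoff, the zone rule reports an"
    "\ninclusive INTERMEDIATE band."
)
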