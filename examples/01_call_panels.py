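"""Call four-analyte Ct panels with the production delta-Ct cutoffs.

Builds three cartridge runs by hand — a typical ER-positive tumor, an
input-limited sample whose below-cutoff PGR becomes INDETERMINATE, and a
cartridge whose reference gene failed — and prints the engine's calls.
"""

import pandas as pd

from strat4concord import AssayConfig, call_table

panels = pd.DataFrame(
    {
        "sample_id": ["typical_er_pos", "input_limited", "ref_failed"],
        "ct_esr1": [27.0, 30.5, 26.0],
        "ct_pgr": [29.5, 36.5, 27.0],
        "ct_erbb2": [33.0, 33.0, 28.0],
        "ct_mki67": [35.0, 35.0, 29.0],
        "ct_cyfip1": [29.0, 32.0, 36.0],
    }
)

calls = call_table(panels, AssayConfig())
print(calls.to_string(index=False))
print(
    "\nEach row is one analyte of one cartridge: dct = Ct(CYFIP1) - Ct(target),"
    "\ncalled POSITIVE at or above the analyte cutoff (-1 for ESR1/ERBB2,"
    "\n-3.5 for PGR, -4 for MKI67).  'input_limited' has reference Ct 32:"
    "\nvalid (<= 35) but above the PGR/MKI67 input gate (31), so its"
    "\nbelow-cutoff PGR is INDETERMINATE (retest with more lysate), while"
    "\n'ref_failed' (reference Ct 36 > 35) is INVALID for all four analytes."
)
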