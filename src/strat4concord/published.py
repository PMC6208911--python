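"""2x2 agreement counts of the published 523-specimen validation cohort.

The original study reported only aggregate 2x2 tables (per analyte and
scoring rule), not per-sample data.  Those printed counts are shipped as
package data so the agreement statistics can be recomputed from them; each
row carries the analysis id, the analyte, the comparator rule and the counts
``a`` (reference+/index+), ``b`` (reference-/index+), ``c``
(reference+/index-), ``d`` (reference-/index-).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import ContingencyTable

__all__ = ["load_validation_counts", "validation_tables"]


def load_validation_counts() -> pd.DataFrame:
    """The published per-analysis 2x2 counts as a DataFrame."""
    with resources.files("strat4concord.data").joinpath(
        "validation_cohort_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"stratum": str}, keep_default_na=False)


def validation_tables() -> dict[str, ContingencyTable]:
    """The published counts as ContingencyTable objects keyed by analysis id."""
    df = load_validation_counts()
    return {
        row.analysis_id: ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))
        for row in df.itertuples()
    }
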