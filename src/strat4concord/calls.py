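"""Categorical calling of RT-qPCR cycle-threshold panels.

The assay measures four breast-cancer transcripts (*ESR1*, *PGR*, *ERBB2*,
*MKI67*) in a single multiplexed cartridge, normalised against the internal
reference transcript *CYFIP1*.  Each target is called POSITIVE or NEGATIVE by
comparing its delta-Ct,

    dCt = Ct(CYFIP1) - Ct(target),

against a fixed per-analyte cutoff (higher dCt means more target mRNA relative
to the reference).  Two gates on the reference Ct protect the call:

* cartridge validity — the reference must amplify with Ct <= 35; otherwise
  every analyte on the cartridge is INVALID;
* minimum assay input — *PGR* and *MKI67* need more template for a reliable
  negative, so a below-cutoff result with reference Ct > 31 is reported
  INDETERMINATE (repeat with the full section lysate) instead of NEGATIVE.

Boundary conventions: dCt exactly at the cutoff is POSITIVE; reference Ct
exactly 35 is valid; exactly 31 satisfies the input gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "POSITIVE",
    "NEGATIVE",
    "INDETERMINATE",
    "INVALID",
    "CtPanel",
    "AssayConfig",
    "AnalyteCall",
    "is_absent",
    "compute_dct",
    "call_analyte",
    "call_panel",
    "call_table",
    "read_panels",
    "write_calls",
]

ANALYTES = ("ESR1", "PGR", "ERBB2", "MKI67")

# call statuses
POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
INDETERMINATE = "INDETERMINATE"
INVALID = "INVALID"

# machine-readable reason codes
REASON_REF_NO_AMPLIFICATION = "REF_NO_AMPLIFICATION"
REASON_REF_CT_ABOVE_MAX = "REF_CT_ABOVE_MAX"
REASON_ABOVE_CUTOFF = "DCT_AT_OR_ABOVE_CUTOFF"
REASON_BELOW_CUTOFF = "DCT_BELOW_CUTOFF"
REASON_TARGET_NO_AMPLIFICATION = "TARGET_NO_AMPLIFICATION"
REASON_INPUT_INSUFFICIENT = "INPUT_INSUFFICIENT_RETEST_FULL_LYSATE"


def is_absent(ct) -> bool:
    """True when a Ct slot holds no amplification signal (None or NaN)."""
    return ct is None or (isinstance(ct, float) and math.isnan(ct))


def _check_ct(name: str, ct) -> None:
    if is_absent(ct):
        return
    if not isinstance(ct, (int, float)) or not math.isfinite(ct) or ct < 0:
        raise ValueError(f"{name} must be a finite Ct >= 0 or absent, got {ct!r}")


@dataclass(frozen=True)
class CtPanel:
    """Raw cycle-threshold measurements from one cartridge run.

    ``None`` (or NaN) marks a target that produced no amplification signal;
    this is distinct from any numeric Ct.
    """

    sample_id: str
    ct_esr1: float | None = None
    ct_pgr: float | None = None
    ct_erbb2: float | None = None
    ct_mki67: float | None = None
    ct_cyfip1: float | None = None

    def __post_init__(self):
        for analyte in ANALYTES:
            _check_ct(f"ct_{analyte.lower()}", self.ct_target(analyte))
        _check_ct("ct_cyfip1", self.ct_cyfip1)

    def ct_target(self, analyte: str) -> float | None:
        try:
            return getattr(self, f"ct_{analyte.lower()}")
        except AttributeError:
            raise KeyError(f"unknown analyte {analyte!r}") from None


@dataclass(frozen=True)
class AssayConfig:
    """Delta-Ct cutoffs and reference-gene gating for one assay version.

    Defaults are the production settings of the multiplexed assay: cutoffs of
    -1 dCt for ESR1 and ERBB2, -3.5 for PGR and -4 for MKI67; reference Ct
    valid up to 35 and input-sufficient up to 31, with the input gate applied
    to PGR and MKI67 only.
    """

    dct_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {"ESR1": -1.0, "ERBB2": -1.0, "PGR": -3.5, "MKI67": -4.0}
    )
    cyfip1_valid_max: float = 35.0
    cyfip1_input_max: float = 31.0
    input_gated_analytes: frozenset[str] = frozenset({"PGR", "MKI67"})

    def __post_init__(self):
        if not self.cyfip1_input_max < self.cyfip1_valid_max:
            raise ValueError("cyfip1_input_max must be below cyfip1_valid_max")
        missing = set(self.input_gated_analytes) - set(self.dct_cutoffs)
        if missing:
            raise ValueError(f"input-gated analytes lack cutoffs: {sorted(missing)}")

    def cutoff(self, analyte: str) -> float:
        try:
            return float(self.dct_cutoffs[analyte])
        except KeyError:
            raise KeyError(f"no dCt cutoff configured for analyte {analyte!r}") from None

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssayConfig":
        kwargs = {}
        if "dct_cutoffs" in d:
            kwargs["dct_cutoffs"] = {str(k).upper(): float(v) for k, v in d["dct_cutoffs"].items()}
        for key in ("cyfip1_valid_max", "cyfip1_input_max"):
            if key in d:
                kwargs[key] = float(d[key])
        if "input_gated_analytes" in d:
            kwargs["input_gated_analytes"] = frozenset(str(a).upper() for a in d["input_gated_analytes"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AssayConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "dct_cutoffs": dict(self.dct_cutoffs),
            "cyfip1_valid_max": self.cyfip1_valid_max,
            "cyfip1_input_max": self.cyfip1_input_max,
            "input_gated_analytes": sorted(self.input_gated_analytes),
        }


@dataclass(frozen=True)
class AnalyteCall:
    """One analyte's categorical assay outcome with its delta-Ct.

    ``dct`` is NaN when the reference failed to amplify (no dCt is defined),
    and ``-inf`` when the target alone failed to amplify against a valid
    reference (no detectable transcript: below any cutoff).
    """

    sample_id: str
    analyte: str
    dct: float
    status: str
    reason: str


def compute_dct(ct_reference: float, ct_target: float) -> float:
    """Delta-Ct of a target against the reference: Ct(reference) - Ct(target).

    Higher values mean more target mRNA relative to the reference transcript.
    Both inputs must be present; absence must be gated by the caller.
    """
    if is_absent(ct_reference) or is_absent(ct_target):
        raise ValueError("compute_dct requires both Ct values present; gate absence first")
    _check_ct("ct_reference", ct_reference)
    _check_ct("ct_target", ct_target)
    return float(ct_reference) - float(ct_target)


def call_analyte(panel: CtPanel, analyte: str, config: AssayConfig | None = None) -> AnalyteCall:
    """Apply the decision cascade to one analyte of one panel.

    Order of precedence:

    1. reference absent or above ``cyfip1_valid_max``  -> INVALID
    2. dCt at or above the analyte cutoff              -> POSITIVE
    3. below cutoff, input-gated analyte, reference Ct
       above ``cyfip1_input_max``                      -> INDETERMINATE
    4. otherwise                                       -> NEGATIVE

    A target with no amplification signal against a valid reference is treated
    as dCt = -inf (below every cutoff) and follows steps 3-4.
    """
    config = config or AssayConfig()
    cutoff = config.cutoff(analyte)
    ref = panel.ct_cyfip1
    target = panel.ct_target(analyte)

    if is_absent(ref):
        return AnalyteCall(panel.sample_id, analyte, math.nan, INVALID, REASON_REF_NO_AMPLIFICATION)
    if ref > config.cyfip1_valid_max:
        return AnalyteCall(panel.sample_id, analyte, math.nan, INVALID, REASON_REF_CT_ABOVE_MAX)

    if is_absent(target):
        dct = -math.inf
        below_reason = REASON_TARGET_NO_AMPLIFICATION
    else:
        dct = compute_dct(ref, target)
        below_reason = REASON_BELOW_CUTOFF

    if dct >= cutoff:
        return AnalyteCall(panel.sample_id, analyte, dct, POSITIVE, REASON_ABOVE_CUTOFF)
    if analyte in config.input_gated_analytes and ref > config.cyfip1_input_max:
        return AnalyteCall(panel.sample_id, analyte, dct, INDETERMINATE, REASON_INPUT_INSUFFICIENT)
    return AnalyteCall(panel.sample_id, analyte, dct, NEGATIVE, below_reason)


def call_panel(panel: CtPanel, config: AssayConfig | None = None) -> list[AnalyteCall]:
    """Call all four analytes of one cartridge.

    The single CYFIP1 measurement gates the whole cartridge: if the reference
    gate fails, all four calls are INVALID.
    """
    config = config or AssayConfig()
    return [call_analyte(panel, analyte, config) for analyte in ANALYTES]


# ---------------------------------------------------------------------------
# table-level interface (CSV schema: sample_id,ct_esr1,ct_pgr,ct_erbb2,ct_mki67,ct_cyfip1)

_PANEL_COLUMNS = ["sample_id", "ct_esr1", "ct_pgr", "ct_erbb2", "ct_mki67", "ct_cyfip1"]


def read_panels(path) -> pd.DataFrame:
    """Read a Ct panel CSV; empty fields mean no amplification (NaN)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {missing}")
    return df[_PANEL_COLUMNS]


def _panel_from_row(row) -> CtPanel:
    def val(x):
        return None if pd.isna(x) else float(x)

    return CtPanel(
        sample_id=str(row["sample_id"]),
        ct_esr1=val(row["ct_esr1"]),
        ct_pgr=val(row["ct_pgr"]),
        ct_erbb2=val(row["ct_erbb2"]),
        ct_mki67=val(row["ct_mki67"]),
        ct_cyfip1=val(row["ct_cyfip1"]),
    )


def call_table(panels: pd.DataFrame, config: AssayConfig | None = None) -> pd.DataFrame:
    """Call every panel row; returns one row per (sample, analyte).

    Output columns: ``sample_id, analyte, dct, status, reason``.
    Duplicate sample ids are rejected.
    """
    config = config or AssayConfig()
    if panels["sample_id"].duplicated().any():
        dupes = panels.loc[panels["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in panel table: {dupes[:5]}")
    records = []
    for _, row in panels.iterrows():
        for call in call_panel(_panel_from_row(row), config):
            records.append(
                (call.sample_id, call.analyte, call.dct, call.status, call.reason)
            )
    return pd.DataFrame(records, columns=["sample_id", "analyte", "dct", "status", "reason"])


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False)
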