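"""Agreement statistics between index-test calls and a reference standard.

Builds 2x2 tables under explicit exclusion rules (invalid cartridges,
indeterminate calls, unresolved/equivocal reference results, missing data),
then computes:

* positive / negative / overall percent agreement (PPA = a/(a+c),
  NPA = d/(b+d), OPA = (a+d)/n) with exact Clopper-Pearson or Wilson 95%
  binomial intervals;
* Cohen's kappa, (po - pe)/(1 - pe), with the Fleiss-Cohen-Everitt
  large-sample standard error for its interval;
* ROC curves over delta-Ct scores (a sample is called positive when its score
  is at or above the threshold, matching the call engine's boundary rule),
  with trapezoidal AUC — numerically identical to the Mann-Whitney pairwise
  probability estimate with ties counted 1/2;
* delta-Ct cutoff optimisation by maximal overall agreement, tie-broken
  toward higher PPA and then the smallest cutoff.

Point estimates are kept as raw proportions; percent displays are rounded
half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .calls import POSITIVE, NEGATIVE, INDETERMINATE, INVALID
from .ihc import EQUIVOCAL, UNRESOLVED, HIGH, LOW, INTERMEDIATE

__all__ = [
    "ContingencyTable",
    "ProportionCI",
    "KappaResult",
    "ConcordanceReport",
    "ROCResult",
    "round_half_up",
    "build_table",
    "agreement_stats",
    "cohen_kappa",
    "roc",
    "mann_whitney_auc",
    "optimize_cutoff",
    "stratified_concordance",
    "POSITIVE_STATES",
    "NEGATIVE_STATES",
]

# reference states mapped onto the positive/negative axis of the 2x2 table
POSITIVE_STATES = frozenset({POSITIVE, HIGH})
NEGATIVE_STATES = frozenset({NEGATIVE, LOW})

# exclusion reasons
EXCL_INVALID = "INVALID"
EXCL_INDETERMINATE = "INDETERMINATE"
EXCL_EQUIVOCAL = "IHC_EQUIVOCAL_EXCLUDED"
EXCL_UNRESOLVED = "UNRESOLVED"
EXCL_MISSING = "MISSING"
EXCL_REFERENCE_INTERMEDIATE = "REFERENCE_INTERMEDIATE_EXCLUDED"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for percents)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 agreement counts plus the ledger of excluded samples.

    Cells follow the reference-by-index layout: ``a`` reference+/index+,
    ``b`` reference-/index+, ``c`` reference+/index-, ``d`` reference-/index-.
    """

    a: int
    b: int
    c: int
    d: int
    excluded: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return int(self.a + self.b + self.c + self.d)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.excluded:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.estimate)

    @property
    def ci_percent(self) -> tuple[float, float]:
        return (round_half_up(100.0 * self.lower), round_half_up(100.0 * self.upper))

    @property
    def defined(self) -> bool:
        return math.isfinite(self.estimate)


UNDEFINED_PROPORTION = ProportionCI(math.nan, math.nan, math.nan)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    lower: float
    upper: float

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.kappa)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.kappa)


@dataclass(frozen=True)
class ConcordanceReport:
    """PPA/NPA/OPA and kappa for one analyte x comparator configuration."""

    ppa: ProportionCI
    npa: ProportionCI
    opa: ProportionCI
    kappa: KappaResult
    n_total: int
    table: ContingencyTable
    configuration: Mapping[str, object] = field(default_factory=dict)


def _binom_ci(count: int, nobs: int, alpha: float, method: str) -> tuple[float, float]:
    meth = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if meth is None:
        raise ValueError(f"ci_method must be 'clopper_pearson' or 'wilson', got {method!r}")
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method=meth)
    return float(lo), float(hi)


def build_table(
    calls: Mapping[str, str] | pd.Series,
    reference: Mapping[str, str] | pd.Series,
    *,
    exclude_equivocal: bool = True,
    exclude_intermediate: bool = True,
) -> ContingencyTable:
    """Cross-tabulate index-test calls against reference statuses.

    Both inputs map sample_id -> status.  Samples are dropped to the exclusion
    ledger when the call is INVALID or INDETERMINATE, the reference is
    EQUIVOCAL (if ``exclude_equivocal``), UNRESOLVED, INTERMEDIATE (if
    ``exclude_intermediate``), or either side is missing.  The ledger
    preserves ``n_input = total + n_excluded``.
    """
    calls = _as_mapping(calls, "calls")
    reference = _as_mapping(reference, "reference")

    a = b = c = d = 0
    excluded: list[tuple[str, str]] = []
    for sid in sorted(set(calls) | set(reference), key=str):
        call = calls.get(sid)
        ref = reference.get(sid)
        if call is None or ref is None or (isinstance(call, float) and math.isnan(call)):
            excluded.append((sid, EXCL_MISSING))
            continue
        if call == INVALID:
            excluded.append((sid, EXCL_INVALID))
            continue
        if call == INDETERMINATE:
            excluded.append((sid, EXCL_INDETERMINATE))
            continue
        if ref == EQUIVOCAL:
            if exclude_equivocal:
                excluded.append((sid, EXCL_EQUIVOCAL))
                continue
            raise ValueError("EQUIVOCAL reference requires exclude_equivocal=True")
        if ref == UNRESOLVED:
            excluded.append((sid, EXCL_UNRESOLVED))
            continue
        if ref == INTERMEDIATE:
            if exclude_intermediate:
                excluded.append((sid, EXCL_REFERENCE_INTERMEDIATE))
                continue
            raise ValueError("INTERMEDIATE reference requires exclude_intermediate=True")
        if ref not in POSITIVE_STATES and ref not in NEGATIVE_STATES:
            raise ValueError(f"unrecognised reference status {ref!r} for sample {sid!r}")
        if call not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unrecognised call status {call!r} for sample {sid!r}")
        ref_pos = ref in POSITIVE_STATES
        call_pos = call == POSITIVE
        if ref_pos and call_pos:
            a += 1
        elif not ref_pos and call_pos:
            b += 1
        elif ref_pos and not call_pos:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, tuple(excluded))


def _as_mapping(obj, name: str) -> dict[str, str]:
    if isinstance(obj, pd.Series):
        if obj.index.duplicated().any():
            raise ValueError(f"duplicate sample_id in {name}")
        return {str(k): v for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        raise TypeError(f"{name} must be a Series or mapping keyed by sample_id")
    return {str(k): v for k, v in dict(obj).items()}


def agreement_stats(
    t: ContingencyTable,
    ci_method: str = "clopper_pearson",
    alpha: float = 0.05,
    configuration: Mapping[str, object] | None = None,
) -> ConcordanceReport:
    """PPA, NPA, OPA with binomial CIs, plus kappa, for one 2x2 table.

    A statistic whose margin is empty (e.g. PPA with no reference positives)
    is reported as undefined (NaN) while the others are still computed.
    """
    n = t.total
    if n <= 0:
        raise ValueError("agreement_stats requires a nonempty table")

    def prop(count: int, nobs: int) -> ProportionCI:
        if nobs == 0:
            return UNDEFINED_PROPORTION
        lo, hi = _binom_ci(count, nobs, alpha, ci_method)
        return ProportionCI(count / nobs, lo, hi)

    ppa = prop(t.a, t.a + t.c)
    npa = prop(t.d, t.b + t.d)
    opa = prop(t.a + t.d, n)
    kappa = cohen_kappa(t, alpha=alpha)
    return ConcordanceReport(
        ppa=ppa, npa=npa, opa=opa, kappa=kappa, n_total=n, table=t,
        configuration=dict(configuration or {}),
    )


def cohen_kappa(t: ContingencyTable, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa with the Fleiss-Cohen-Everitt asymptotic interval.

    kappa = (po - pe)/(1 - pe) with po the observed and pe the chance
    agreement from the table margins.  Degenerate margins (pe = 1) leave
    kappa undefined.
    """
    n = t.total
    if n <= 0:
        raise ValueError("cohen_kappa requires a nonempty table")
    p = np.array([[t.a, t.b], [t.c, t.d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        return KappaResult(math.nan, math.nan, math.nan, math.nan)
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    a_term = sum(
        p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(2)
    )
    b_term = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c_term = (po * pe - 2 * pe + po) ** 2
    var = (a_term + b_term - c_term) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return KappaResult(kappa, se, kappa - z * se, kappa + z * se)


# ---------------------------------------------------------------------------
# ROC / AUC / cutoff optimisation on delta-Ct scores


@dataclass(frozen=True)
class ROCResult:
    """An ROC curve over score thresholds (positive iff score >= threshold)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(
        [1 if l in (1, True, POSITIVE, HIGH) else 0 for l in np.asarray(labels).ravel()]
    )
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have equal length")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain NaN")
    return scores, labels


def roc(scores, labels) -> ROCResult:
    """ROC curve of a continuous score against binary reference labels.

    Thresholds sweep the distinct observed scores from high to low (with a
    +inf sentinel at the origin); at each, samples with score >= threshold
    are called positive.  AUC is the trapezoidal area, identical to the
    Mann-Whitney estimate with ties counted 1/2.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return ROCResult(np.array([]), np.array([]), np.array([]), math.nan)

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[True, s[1:] != s[:-1]]
    idx = np.flatnonzero(distinct)
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    # at threshold s[i] (a distinct value), everything with score >= s[i] is positive:
    # that is the cumulative count through the *last* occurrence of that value
    last = np.r_[idx[1:] - 1, s.size - 1]
    tpr = np.r_[0.0, tp_cum[last] / n_pos]
    fpr = np.r_[0.0, fp_cum[last] / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, tpr, fpr, auc)


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the probability a positive outscores a negative (ties 1/2)."""
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def optimize_cutoff(scores, labels) -> tuple[float, float]:
    """Score cutoff maximising overall agreement with the reference.

    Candidates are the midpoints between adjacent distinct sorted scores plus
    -inf and +inf sentinels; a sample is called positive when its score is at
    or above the cutoff.  Ties on OPA break toward the cutoff with higher PPA
    (favouring sensitivity), then toward the smallest cutoff.

    Returns ``(cutoff, achieved OPA)`` with OPA as a proportion.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("optimize_cutoff requires both classes present")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    n = scores.size
    n_pos = labels.sum()
    best = None
    for cut in candidates:
        pred = scores >= cut
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        opa = (tp + tn) / n
        ppa = tp / n_pos
        key = (opa, ppa, -cut)  # max opa, then max ppa, then smallest cutoff
        if best is None or key > best[0]:
            best = (key, cut, opa)
    return float(best[1]), float(best[2])


def stratified_concordance(
    calls: Mapping[str, str] | pd.Series,
    reference: Mapping[str, str] | pd.Series,
    strata: Mapping[str, object] | pd.Series,
    **kwargs,
) -> dict[object, ConcordanceReport | None]:
    """One concordance report per stratum (e.g. split by ER status).

    Samples without a stratum label are omitted; an empty stratum maps to
    ``None`` (undefined report).
    """
    calls = _as_mapping(calls, "calls")
    reference = _as_mapping(reference, "reference")
    strata = _as_mapping(strata, "strata")
    out: dict[object, ConcordanceReport | None] = {}
    for stratum in sorted(set(strata.values()), key=str):
        ids = {sid for sid, s in strata.items() if s == stratum}
        sub_calls = {k: v for k, v in calls.items() if k in ids}
        sub_ref = {k: v for k, v in reference.items() if k in ids}
        table = build_table(sub_calls, sub_ref, **kwargs)
        out[stratum] = agreement_stats(table, configuration={"stratum": stratum}) if table.total else None
    return out
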