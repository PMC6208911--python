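"""Agreement tables, PPA/NPA/OPA/kappa, ROC/AUC, cutoff optimisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score
from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

from strat4concord.calls import INDETERMINATE, INVALID, NEGATIVE, POSITIVE
from strat4concord.ihc import EQUIVOCAL, HIGH, LOW
from strat4concord.concordance import (
    ContingencyTable,
    agreement_stats,
    build_table,
    cohen_kappa,
    mann_whitney_auc,
    optimize_cutoff,
    roc,
    round_half_up,
    stratified_concordance,
)


# ---------------------------------------------------------------------------
# table construction


def test_build_table_exclusions():
    calls = {"s1": POSITIVE, "s2": POSITIVE, "s3": POSITIVE, "s4": INDETERMINATE, "s5": POSITIVE}
    ref = {"s1": POSITIVE, "s2": POSITIVE, "s3": POSITIVE, "s4": POSITIVE, "s5": EQUIVOCAL}
    t = build_table(calls, ref)
    assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 0)
    assert t.n_excluded == 2
    assert t.exclusion_counts() == {"INDETERMINATE": 1, "IHC_EQUIVOCAL_EXCLUDED": 1}


def test_build_table_empty_and_missing():
    t = build_table({}, {})
    assert t.total == 0 and t.excluded == ()
    t = build_table({"s1": POSITIVE}, {"s2": POSITIVE})
    assert t.total == 0 and t.exclusion_counts() == {"MISSING": 2}


def test_build_table_rejects_duplicates():
    calls = pd.Series([POSITIVE, NEGATIVE], index=["s1", "s1"])
    with pytest.raises(ValueError, match="duplicate"):
        build_table(calls, {"s1": POSITIVE})


def test_build_table_maps_ki67_states():
    t = build_table({"s1": POSITIVE, "s2": NEGATIVE}, {"s1": HIGH, "s2": LOW})
    assert (t.a, t.d) == (1, 1)


@given(
    st.lists(
        st.tuples(
            st.sampled_from([POSITIVE, NEGATIVE, INDETERMINATE, INVALID]),
            st.sampled_from([POSITIVE, NEGATIVE, EQUIVOCAL, HIGH, LOW]),
        ),
        max_size=60,
    )
)
@settings(max_examples=150, derandomize=True)
def test_exclusion_conservation(pairs):
    """Every input sample lands in exactly one cell or the exclusion ledger."""
    calls = {f"s{i}": c for i, (c, _) in enumerate(pairs)}
    ref = {f"s{i}": r for i, (_, r) in enumerate(pairs)}
    t = build_table(calls, ref)
    assert t.total + t.n_excluded == len(pairs)


# ---------------------------------------------------------------------------
# agreement statistics


def test_agreement_stats_perfect():
    rep = agreement_stats(ContingencyTable(10, 0, 0, 20))
    assert rep.ppa.estimate == rep.npa.estimate == rep.opa.estimate == 1.0
    assert rep.kappa.kappa == pytest.approx(1.0)
    assert rep.ppa.lower <= 1.0 <= rep.ppa.upper


def test_agreement_stats_undefined_margin():
    rep = agreement_stats(ContingencyTable(0, 3, 0, 7))
    assert not rep.ppa.defined
    assert rep.npa.defined and rep.opa.defined


def test_agreement_stats_known_row():
    # a concordance row with familiar hand-checked values
    rep = agreement_stats(ContingencyTable(407, 4, 7, 75))
    assert rep.ppa.percent == 98.3
    assert rep.npa.percent == 94.9
    assert rep.opa.percent == 97.8
    assert rep.ppa.ci_percent == (96.5, 99.3)
    assert rep.npa.ci_percent == (87.5, 98.6)
    assert rep.opa.ci_percent == (96.0, 98.9)


def test_wilson_option_differs_from_exact():
    cp = agreement_stats(ContingencyTable(407, 4, 7, 75), ci_method="clopper_pearson")
    wi = agreement_stats(ContingencyTable(407, 4, 7, 75), ci_method="wilson")
    assert cp.ppa.estimate == wi.ppa.estimate
    assert cp.ppa.lower != wi.ppa.lower
    with pytest.raises(ValueError):
        agreement_stats(ContingencyTable(1, 1, 1, 1), ci_method="bogus")


def test_opa_decomposition():
    """opa = [ppa*(a+c) + npa*(b+d)] / n exactly."""
    for t in [ContingencyTable(5, 3, 2, 7), ContingencyTable(407, 4, 7, 75)]:
        rep = agreement_stats(t)
        recomposed = (rep.ppa.estimate * (t.a + t.c) + rep.npa.estimate * (t.b + t.d)) / t.total
        assert rep.opa.estimate == pytest.approx(recomposed, abs=1e-12)
        assert min(rep.ppa.estimate, rep.npa.estimate) <= rep.opa.estimate <= max(
            rep.ppa.estimate, rep.npa.estimate
        )


def test_kappa_balanced_chance_agreement_is_zero():
    assert cohen_kappa(ContingencyTable(5, 5, 5, 5)).kappa == pytest.approx(0.0)


def test_kappa_degenerate_marginals_undefined():
    assert math.isnan(cohen_kappa(ContingencyTable(10, 0, 0, 0)).kappa)


@given(st.tuples(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80), st.integers(0, 80)))
@settings(max_examples=200, derandomize=True)
def test_kappa_matches_statsmodels(cells):
    """Point estimate and Fleiss-Cohen-Everitt SE against the independent
    statsmodels implementation."""
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    t = ContingencyTable(a, b, c, d)
    res = cohen_kappa(t)
    table = np.array([[a, b], [c, d]], dtype=float)
    sm = sm_kappa(table, return_results=True)
    if math.isnan(res.kappa):
        return
    assert res.kappa == pytest.approx(float(sm.kappa), abs=1e-12)
    assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12
    if np.isfinite(sm.var_kappa):
        assert res.se == pytest.approx(math.sqrt(float(sm.var_kappa)), rel=1e-9, abs=1e-12)


def test_kappa_is_one_iff_no_discordance():
    assert cohen_kappa(ContingencyTable(12, 0, 0, 9)).kappa == pytest.approx(1.0)
    assert cohen_kappa(ContingencyTable(12, 1, 0, 9)).kappa < 1.0


def test_round_half_up():
    assert round_half_up(97.75) == 97.8
    assert round_half_up(97.85) == 97.9
    assert round_half_up(-0.05) == -0.1  # away from zero


# ---------------------------------------------------------------------------
# ROC / AUC


def test_roc_perfect_and_chance():
    r = roc([1.0, 2.0, -1.0, -2.0], [1, 1, 0, 0])
    assert r.auc == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    scores = rng.normal(size=4000)
    labels = rng.random(4000) < 0.5
    assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.03)


def test_roc_small_examples():
    scores = [-2.0, -1.0, 0.0, 1.0]
    assert roc(scores, [0, 0, 1, 1]).auc == pytest.approx(1.0)
    assert roc(scores, [0, 1, 0, 1]).auc == pytest.approx(0.75)


def test_roc_single_class_undefined():
    assert math.isnan(roc([1.0, 2.0], [1, 1]).auc)
    assert math.isnan(mann_whitney_auc([1.0, 2.0], [0, 0]))


def test_roc_curve_monotone_and_ties():
    rng = np.random.default_rng(1)
    scores = np.round(rng.normal(size=200), 1)  # plenty of ties
    labels = rng.random(200) < 0.4
    r = roc(scores, labels)
    assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)
    assert r.tpr[0] == r.fpr[0] == 0.0
    assert r.tpr[-1] == r.fpr[-1] == 1.0
    assert np.all(np.diff(r.thresholds) < 0)


@pytest.mark.parametrize("n,seed", [(10, 0), (37, 1), (50, 2), (25, 3)])
def test_auc_equals_mann_whitney_and_sklearn(n, seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=n), 1)
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    auc = roc(scores, labels).auc
    assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
    assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# cutoff optimisation


def test_optimize_cutoff_separated_gap_midpoint():
    cutoff, opa = optimize_cutoff([-3.0, -2.0, 0.0, 1.0], [0, 0, 1, 1])
    assert cutoff == -1.0
    assert opa == 1.0


def test_optimize_cutoff_requires_both_classes():
    with pytest.raises(ValueError):
        optimize_cutoff([1.0, 2.0], [1, 1])


def _brute_force_cutoff(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    distinct = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    best = None
    for cut in candidates:
        pred = scores >= cut
        opa = np.mean(pred == labels)
        ppa = pred[labels == 1].mean()
        key = (opa, ppa, -cut)
        if best is None or key > best[0]:
            best = (key, cut, opa)
    return best[1], best[2]


@pytest.mark.parametrize("seed", range(8))
def test_optimize_cutoff_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 40)
    scores = np.round(rng.normal(size=n), 1)
    labels = (scores + rng.normal(scale=1.0, size=n) > 0).astype(int)
    if labels.all() or not labels.any():
        return
    got = optimize_cutoff(scores, labels)
    expected = _brute_force_cutoff(scores, labels)
    assert got == pytest.approx(expected)


def test_optimize_cutoff_tie_breaks_toward_sensitivity():
    # any cutoff in (-1, 1) misclassifies one sample either way (OPA 3/4);
    # the PPA tie-break must prefer calling the ambiguous sample positive
    scores = [-2.0, -1.0, 1.0, 2.0]
    labels = [0, 1, 0, 1]
    cutoff, opa = optimize_cutoff(scores, labels)
    assert opa == pytest.approx(0.75)
    assert cutoff <= -1.0


# ---------------------------------------------------------------------------
# stratification


def test_single_stratum_equals_unstratified():
    calls = {f"s{i}": POSITIVE if i % 3 else NEGATIVE for i in range(30)}
    ref = {f"s{i}": POSITIVE if i % 2 else NEGATIVE for i in range(30)}
    whole = agreement_stats(build_table(calls, ref))
    strat = stratified_concordance(calls, ref, {k: "all" for k in calls})
    assert strat["all"].opa.estimate == whole.opa.estimate
    assert strat["all"].table == whole.table


def test_stratified_concordance_splits():
    calls = {"s1": POSITIVE, "s2": NEGATIVE, "s3": POSITIVE, "s4": NEGATIVE}
    ref = {"s1": POSITIVE, "s2": NEGATIVE, "s3": NEGATIVE, "s4": NEGATIVE}
    strata = {"s1": "ER+", "s2": "ER+", "s3": "ER-", "s4": "ER-"}
    out = stratified_concordance(calls, ref, strata)
    assert out["ER+"].opa.estimate == 1.0
    assert out["ER-"].opa.estimate == 0.5
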