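"""Reference scoring: H-score, ER/PR cutoffs, HER2 reflex, Ki67 rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strat4concord.ihc import (
    EQUIVOCAL,
    HIGH,
    INTERMEDIATE,
    LOW,
    UNRESOLVED,
    DEFAULT_RULES,
    FISHObservation,
    IHCObservation,
    h_score,
    her2_combined_status,
    her2_fish_status,
    her2_ihc_status,
    hormone_receptor_status,
    ki67_status,
    score_table,
)
from strat4concord.calls import NEGATIVE, POSITIVE


@pytest.mark.parametrize(
    "p1,p2,p3,expected",
    [(0, 0, 0, 0), (0, 0, 100, 300), (10, 20, 30, 140), (100, 0, 0, 100)],
)
def test_h_score_values(p1, p2, p3, expected):
    assert h_score(p1, p2, p3) == expected


def test_h_score_rejects_oversum():
    with pytest.raises(ValueError):
        h_score(50, 40, 20)
    with pytest.raises(ValueError):
        h_score(-1, 0, 0)


@given(
    st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)
)
@settings(max_examples=200, derandomize=True)
def test_h_score_range_and_linearity(p1, p2, p3):
    if p1 + p2 + p3 > 100:
        return
    hs = h_score(p1, p2, p3)
    assert 0 <= hs <= 300
    # linear in each fraction
    if p1 + p2 + p3 + 1 <= 100:
        assert h_score(p1 + 1, p2, p3) == pytest.approx(hs + 1)
        assert h_score(p1, p2 + 1, p3) == pytest.approx(hs + 2)
        assert h_score(p1, p2, p3 + 1) == pytest.approx(hs + 3)


@pytest.mark.parametrize(
    "pct,cutoff,expected",
    [
        (0, 1, NEGATIVE),
        (5, 10, NEGATIVE),
        (5, 1, POSITIVE),
        (1, 1, POSITIVE),
        (10, 10, POSITIVE),
        (100, 10, POSITIVE),
    ],
)
def test_hormone_receptor_status(pct, cutoff, expected):
    assert hormone_receptor_status(pct, cutoff) == expected


def test_hormone_receptor_nonstandard_cutoff_guard():
    with pytest.raises(ValueError):
        hormone_receptor_status(50, 5)
    assert hormone_receptor_status(50, 5, allow_nonstandard_cutoff=True) == POSITIVE


def test_low_positive_stratum_is_exactly_where_rules_disagree():
    """The 1% and 10% rules disagree exactly on the 1-9% stratum."""
    for pct in np.arange(0, 100.5, 0.5):
        disagree = hormone_receptor_status(pct, 1) != hormone_receptor_status(pct, 10)
        assert disagree == (1 <= pct < 10)


@pytest.mark.parametrize(
    "category,expected",
    [("0", NEGATIVE), ("1+", NEGATIVE), ("2+", EQUIVOCAL), ("3+", POSITIVE)],
)
def test_her2_ihc_status(category, expected):
    assert her2_ihc_status(category) == expected


@pytest.mark.parametrize(
    "ratio,expected", [(1.0, NEGATIVE), (1.99, NEGATIVE), (2.0, POSITIVE), (5.4, POSITIVE)]
)
def test_her2_fish_status(ratio, expected):
    assert her2_fish_status(ratio) == expected
    assert her2_fish_status(FISHObservation("s", ratio)) == expected


@pytest.mark.parametrize(
    "category,ratio,expected",
    [
        ("2+", 3.1, POSITIVE),
        ("2+", 1.2, NEGATIVE),
        ("2+", None, UNRESOLVED),
        ("0", 3.1, NEGATIVE),  # reflex applies to 2+ only; the IHC call stands
        ("3+", 1.0, POSITIVE),
        ("1+", None, NEGATIVE),
    ],
)
def test_her2_combined_status(category, ratio, expected):
    assert her2_combined_status(category, ratio) == expected


def test_her2_combined_agrees_with_ihc_when_not_equivocal():
    for cat in ("0", "1+", "3+"):
        for ratio in (None, 1.0, 5.0):
            assert her2_combined_status(cat, ratio) == her2_ihc_status(cat)


@pytest.mark.parametrize(
    "pct,kwargs,expected",
    [
        (25, dict(cutoff=20), HIGH),
        (20, dict(cutoff=20), LOW),  # strict: high only above the cutoff
        (11, dict(cutoff=10), HIGH),
        (5, dict(zone=(10, 20)), LOW),
        (10, dict(zone=(10, 20)), INTERMEDIATE),  # zone bounds inclusive
        (20, dict(zone=(10, 20)), INTERMEDIATE),
        (15, dict(zone=(10, 30)), INTERMEDIATE),
        (30.5, dict(zone=(10, 30)), HIGH),
    ],
)
def test_ki67_status(pct, kwargs, expected):
    assert ki67_status(pct, **kwargs) == expected


def test_ki67_rule_validation():
    with pytest.raises(ValueError):
        ki67_status(15)
    with pytest.raises(ValueError):
        ki67_status(15, cutoff=20, zone=(10, 20))
    with pytest.raises(ValueError):
        ki67_status(15, zone=(20, 10))


@given(st.floats(0, 100), st.floats(1, 50), st.floats(0, 49))
@settings(max_examples=200, derandomize=True)
def test_cutoff_monotonicity(pct, cutoff, raise_by):
    """Raising a positivity cutoff never turns NEGATIVE into POSITIVE."""
    lo = hormone_receptor_status(pct, cutoff, allow_nonstandard_cutoff=True)
    hi = hormone_receptor_status(pct, cutoff + raise_by, allow_nonstandard_cutoff=True)
    assert not (lo == NEGATIVE and hi == POSITIVE)


def test_ihc_observation_invariants():
    with pytest.raises(ValueError):
        IHCObservation("s", "ER", percent_positive=120)
    with pytest.raises(ValueError):
        IHCObservation("s", "ER", intensity_fractions=(60, 30, 20))
    with pytest.raises(ValueError):
        IHCObservation("s", "ER", her2_category="2+")  # category only for HER2
    with pytest.raises(ValueError):
        IHCObservation("s", "HER2")  # HER2 requires a category
    with pytest.raises(ValueError):
        FISHObservation("s", 0.0)


def test_score_table_rules_and_h_score():
    ihc = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1", "s1", "s2"],
            "marker": ["ER", "PR", "HER2", "Ki67", "HER2"],
            "percent_positive": [5.0, 0.0, np.nan, 25.0, np.nan],
            "pct_1plus": [2.0, 0.0, np.nan, np.nan, np.nan],
            "pct_2plus": [2.0, 0.0, np.nan, np.nan, np.nan],
            "pct_3plus": [1.0, 0.0, np.nan, np.nan, np.nan],
            "her2_category": [None, None, "2+", None, "2+"],
        }
    )
    fish = pd.DataFrame({"sample_id": ["s1"], "her2_cep17_ratio": [3.0]})
    scored = score_table(ihc, fish, DEFAULT_RULES)
    by = scored.set_index(["sample_id", "rule_id"])["status"]
    assert by[("s1", "er_1pct")] == POSITIVE
    assert by[("s1", "er_10pct")] == NEGATIVE
    assert by[("s1", "pr_1pct")] == NEGATIVE
    assert by[("s1", "her2_ihc_plus_fish")] == POSITIVE  # 2+ resolved by FISH
    assert by[("s1", "her2_ihc_excluding_2plus")] == EQUIVOCAL
    assert by[("s1", "ki67_20pct")] == HIGH
    assert by[("s2", "her2_ihc_plus_fish")] == UNRESOLVED  # no FISH for s2
    er_row = scored[(scored.sample_id == "s1") & (scored.rule_id == "er_1pct")]
    assert er_row["h_score"].iloc[0] == pytest.approx(2 + 4 + 3)
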