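"""Filtering/normalization rules: RT trim, blank dominance, IS ratios,
1/3-minimum imputation, QA RSD — including the strict-inequality boundaries."""

import numpy as np
import pandas as pd
import pytest

from oatchemo.preprocess import (
    PreprocessParams,
    blank_filter,
    impute_missing,
    normalize_is,
    preprocess,
    qa_rsd_filter,
    trim_rt,
)

from conftest import toy_design, toy_table

BIO = ["b1", "b2"]
QA = ["q1", "q2", "q3"]


def _design():
    return toy_design(
        bio=BIO, varieties=["V1", "V2"], doses=[0.0, 50.0], reps=[1, 1],
        qa=QA, blank=["k1"],
    )


def test_trim_rt_boundaries():
    """First 0.3 min and final 4 min of a 15 min run are removed; the
    boundaries themselves are retained."""
    rows = [
        ("void", 0.2, 100.0, [1, 1, 1, 1, 1, 1]),
        ("edge_lo", 0.3, 100.0, [1, 1, 1, 1, 1, 1]),
        ("mid", 5.0, 100.0, [1, 1, 1, 1, 1, 1]),
        ("edge_hi", 11.0, 100.0, [1, 1, 1, 1, 1, 1]),
        ("tail", 11.5, 100.0, [1, 1, 1, 1, 1, 1]),
    ]
    table = toy_table(rows, BIO + QA + ["k1"])
    log = []
    out = trim_rt(table, PreprocessParams(), log)
    assert list(out.feature_ids) == ["edge_lo", "mid", "edge_hi"]
    reasons = {e["feature_id"]: e["reason"] for e in log}
    assert reasons == {"void": "void", "tail": "tail"}


def test_blank_filter_strict_double_rule():
    """Removed iff max(blank) strictly exceeds 2 x max(biological)."""
    rows = [
        ("gone", 5.0, 100.0, [2000, 1500, 1, 1, 1, 5000]),  # 5000 > 4000
        ("edge", 5.0, 110.0, [2000, 1500, 1, 1, 1, 4000]),  # exactly 2x: kept
        ("absent", 5.0, 120.0, [2000, 1500, 1, 1, 1, np.nan]),  # no blank signal
    ]
    table = toy_table(rows, BIO + QA + ["k1"])
    out = blank_filter(table, _design(), PreprocessParams())
    assert list(out.feature_ids) == ["edge", "absent"]


def test_blank_filter_without_blanks_warns_and_passes():
    rows = [("f", 5.0, 100.0, [1, 2, 1, 1, 1])]
    table = toy_table(rows, BIO + QA)
    design = toy_design(bio=BIO, varieties=["V1", "V2"], doses=[0, 50], reps=[1, 1], qa=QA)
    with pytest.warns(UserWarning, match="blank"):
        out = blank_filter(table, design, PreprocessParams())
    assert list(out.feature_ids) == ["f"]


def test_normalize_is_ratio_and_errors():
    rows = [
        ("f", 5.0, 100.0, [1000, 600, 500, 500, 500, np.nan]),
        ("IS_reserpine_pos", 6.0, 609.28, [500, 300, 250, 250, 250, np.nan]),
    ]
    table = toy_table(rows, BIO + QA + ["k1"])
    ratios = normalize_is(table, _design(), PreprocessParams())
    assert "IS_reserpine_pos" not in ratios.index
    assert ratios.loc["f", "b1"] == pytest.approx(2.0)
    assert ratios.loc["f", "q1"] == pytest.approx(2.0)

    bad = toy_table(
        [
            ("f", 5.0, 100.0, [1000, 600, 500, 500, 500, np.nan]),
            ("IS_reserpine_pos", 6.0, 609.28, [500, 0, 250, 250, 250, np.nan]),
        ],
        BIO + QA + ["k1"],
    )
    with pytest.raises(ValueError, match="b2"):
        normalize_is(bad, _design(), PreprocessParams())


def test_impute_one_third_of_global_minimum():
    ratios = pd.DataFrame(
        [[0.09, np.nan], [1.0, 2.0]], index=["f1", "f2"], columns=["s1", "s2"]
    )
    out = impute_missing(ratios, PreprocessParams())
    assert out.loc["f1", "s2"] == pytest.approx(0.03)
    assert out.loc["f2", "s1"] == 1.0  # observed cells untouched
    # no missing cells: unchanged
    pd.testing.assert_frame_equal(impute_missing(out, PreprocessParams()), out)
    with pytest.raises(ValueError):
        impute_missing(ratios * np.nan, PreprocessParams())


def test_qa_rsd_filter_strict_boundary():
    """(1,2,3) -> RSD 50% removed; constant -> 0% kept; exactly 25% kept."""
    # construct a feature with RSD exactly 25%: mean 1, sd 0.25 over q1..q3
    # values (a, 1, 2-a) have mean 1 and sample sd (1-a); choose a = 0.75
    vals = [0.75, 1.0, 1.25]
    assert np.std(vals, ddof=1) == pytest.approx(0.25)
    ratios = pd.DataFrame(
        {
            "b1": [1, 1, 1],
            "b2": [1, 1, 1],
            "q1": [1.0, vals[0], 10.0],
            "q2": [2.0, vals[1], 10.0],
            "q3": [3.0, vals[2], 10.0],
        },
        index=["wild", "edge25", "flat"],
    )
    out, rsd = qa_rsd_filter(ratios, _design(), PreprocessParams())
    assert rsd["wild"] == pytest.approx(50.0)
    assert rsd["edge25"] == pytest.approx(25.0)
    assert rsd["flat"] == pytest.approx(0.0)
    assert list(out.index) == ["edge25", "flat"]


def test_conditioning_qa_excluded_from_rsd():
    design = toy_design(
        bio=BIO, varieties=["V1", "V2"], doses=[0, 50], reps=[1, 1], qa=QA
    )
    design.samples.loc["q1", "conditioning"] = True
    ratios = pd.DataFrame(
        {"b1": [1.0], "b2": [1.0], "q1": [100.0], "q2": [1.0], "q3": [1.0]},
        index=["f"],
    )
    out, rsd = qa_rsd_filter(ratios, design, PreprocessParams())
    assert rsd["f"] == pytest.approx(0.0)  # q1 ignored
    assert "f" in out.index


def test_chain_order_and_monotone_thresholds(default_sim):
    """Tightening any threshold never retains more features."""
    table, design, _ = default_sim
    base = preprocess(table, design, PreprocessParams())
    tighter_rsd = preprocess(table, design, PreprocessParams(qa_rsd_max=15.0))
    tighter_blank = preprocess(table, design, PreprocessParams(blank_factor=1.0))
    tighter_rt = preprocess(table, design, PreprocessParams(void_cutoff=1.0, tail_cutoff=5.0))
    n = len(base.ratios)
    assert len(tighter_rsd.ratios) <= n
    assert len(tighter_blank.ratios) <= n
    assert len(tighter_rt.ratios) <= n
    # order contract: every removal carries one of the known step reasons
    assert set(base.removal_log["reason"]) <= {
        "void", "tail", "blank_dominant", "qa_rsd", "is_feature"
    }


def test_injected_contaminants_exactly_removed(default_sim):
    """All labelled blank contaminants removed, nothing else removed as blank."""
    table, design, truth = default_sim
    norm = preprocess(table, design)
    removed_blank = set(
        norm.removal_log.loc[norm.removal_log["reason"] == "blank_dominant", "feature_id"]
    )
    assert removed_blank == set(truth.blank_contaminant_ids)


def test_imputed_minimum_equals_fraction_of_observed_minimum(default_sim):
    table, design, _ = default_sim
    norm = preprocess(table, design)
    pre_min = norm.ratios_unimputed.min().min()
    # rows kept after RSD may exclude the global pre-imputation minimum, so
    # check the invariant on the matrix actually imputed
    assert norm.ratios.min().min() <= pre_min
    assert norm.ratios.notna().all().all()
    assert (norm.ratios > 0).all().all()
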