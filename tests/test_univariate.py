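"""Friedman statistic and exact enumeration, BH-FDR, monotone-response
screening, and the consensus selection semantics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oatchemo import univariate as uv
from oatchemo.univariate import ConsensusParams, bh_fdr, consensus_select, friedman_test

from conftest import toy_design


def _layout(k, b, values):
    """Design with one variety block per b, k doses, one replicate."""
    bio, varieties, doses, reps = [], [], [], []
    for bi in range(b):
        for ki in range(k):
            bio.append(f"s{bi}_{ki}")
            varieties.append(f"V{bi + 1}")
            doses.append(float(ki * 50))
            reps.append(1)
    design = toy_design(bio=bio, varieties=varieties, doses=doses, reps=reps)
    mat = pd.DataFrame(
        np.asarray(values, dtype=float).reshape(1, -1), index=["f"], columns=bio
    )
    return mat, design


def test_friedman_perfectly_ordered_layout():
    """k=5 doses, b=4 blocks, every block ranking 1..5 -> chi2 = 16, df = 4."""
    vals = []
    for bi in range(4):
        vals.extend([10 + j + bi for j in range(5)])  # increasing in dose
    mat, design = _layout(5, 4, vals)
    res = friedman_test(mat, design, factor="nitrogen", exact=False)
    assert res.table.loc["f", "statistic"] == pytest.approx(16.0)
    assert res.table.loc["f", "df"] == 4
    assert res.table.loc["f", "p"] == pytest.approx(sps.chi2.sf(16.0, 4))


def test_friedman_constant_feature_null():
    mat, design = _layout(5, 4, [7.0] * 20)
    res = friedman_test(mat, design, factor="nitrogen", exact=False)
    assert res.table.loc["f", "statistic"] == pytest.approx(0.0)
    assert res.table.loc["f", "p"] == pytest.approx(1.0)


def test_friedman_agrees_with_scipy_without_ties():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=20)
    mat, design = _layout(5, 4, vals)
    res = friedman_test(mat, design, factor="nitrogen", exact=False)
    blocks = np.asarray(vals).reshape(4, 5)
    ref_stat, ref_p = sps.friedmanchisquare(*blocks.T)
    assert res.table.loc["f", "statistic"] == pytest.approx(ref_stat)
    assert res.table.loc["f", "p"] == pytest.approx(ref_p)


def test_friedman_exact_enumeration_k3_b3():
    """Package's DP-based exact p equals brute force over all (3!)^3 = 216
    per-block rankings, to 1e-12."""
    rng = np.random.default_rng(5)
    vals = rng.normal(size=9)
    mat, design = _layout(3, 3, vals)
    res = friedman_test(mat, design, factor="nitrogen")  # auto-exact for k=3
    assert res.exact

    obs = res.table.loc["f", "statistic"]
    count = total = 0
    for combo in itertools.product(itertools.permutations([1, 2, 3]), repeat=3):
        sums = np.sum(combo, axis=0)
        stat = 12.0 / (3 * 3 * 4) * np.sum(sums**2) - 3 * 3 * 4
        total += 1
        count += stat >= obs - 1e-9
    assert res.table.loc["f", "p"] == pytest.approx(count / total, abs=1e-12)


def test_friedman_monotone_invariance(prepared):
    """Rank statistic is unchanged by monotone transformation of the data."""
    X = prepared.matrix.T.iloc[:10]
    r1 = friedman_test(X, prepared.design, "nitrogen")
    r2 = friedman_test(np.exp(X), prepared.design, "nitrogen")
    np.testing.assert_allclose(
        r1.table["statistic"].to_numpy(), r2.table["statistic"].to_numpy(), atol=1e-12
    )


def test_bh_fdr_worked_example():
    q, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert reject.all()


def test_bh_fdr_degenerate_inputs():
    q, reject = bh_fdr([1.0, 1.0, 1.0])
    np.testing.assert_allclose(q, 1.0)
    assert not reject.any()
    q1, _ = bh_fdr([0.2])
    assert q1[0] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_rejections_superset_of_bonferroni(ps):
    alpha = 0.05
    _, bh = bh_fdr(ps, alpha)
    bonf = np.asarray(ps) <= alpha / len(ps)
    assert (bh | ~bonf).all()  # bonferroni-rejected => BH-rejected


def test_monotone_screen_signs(quiet_sim):
    table, design, truth = quiet_sim
    fids = truth.features.index[~truth.features["is_internal_standard"]]
    vals = table.areas.loc[fids, design.biological_ids]
    rep = uv.monotone_response_screen(vals, design, "Gerald")
    pos = truth.features.index[truth.features["nitrogen_slope"] > 0]
    neg = truth.features.index[truth.features["nitrogen_slope"] < 0]
    np.testing.assert_allclose(rep.loc[pos, "spearman_rho"], 1.0, atol=1e-9)
    np.testing.assert_allclose(rep.loc[neg, "spearman_rho"], -1.0, atol=1e-9)
    assert rep.loc[pos, "linear"].all() and rep.loc[neg, "linear"].all()
    # exactly constant feature: undefined rho, flagged non-responsive
    const = vals.iloc[[0]].copy()
    const[:] = 7.0
    const.index = ["const"]
    rep_const = uv.monotone_response_screen(const, design, "Gerald")
    assert not rep_const.loc["const", "responsive"]
    assert not rep_const.loc["const", "linear"]


def test_consensus_union_flags_and_dedup():
    idx = pd.Index([f"f{i}" for i in range(10)])
    pca = pd.Series(np.linspace(1, 0.1, 10), index=idx)
    asca = pd.Series(np.linspace(0.1, 1, 10), index=idx)
    ranks = pd.Series(range(1, 11), index=idx)
    fr_table = pd.DataFrame(
        {"statistic": 1.0, "df": 4, "p": np.linspace(0.001, 0.5, 10),
         "q": np.linspace(0.001, 0.5, 10), "reject": True},
        index=idx,
    )
    fr = uv.FriedmanResult(fr_table, "nitrogen", "variety|replicate", 5, 12, False)
    params = ConsensusParams(pca_top_frac=0.1, asca_top_frac=0.1,
                             pls_top_frac=0.1, friedman_top_n=1)
    sel = consensus_select(pca, asca, ranks, fr, params=params)
    # f0 tops pca, pls and friedman; f9 tops asca
    assert set(sel.selected) == {"f0", "f9"}
    assert sel.table.loc["f0", ["pca_loading", "pls_rank", "friedman_top"]].all()
    assert sel.table.loc["f9", "asca_loading"]

    # dedup: f9 is a satellite of f0 -> only f0 kept, flags merged
    sel2 = consensus_select(pca, asca, ranks, fr, group_parent={"f9": "f0"}, params=params)
    assert set(sel2.selected) == {"f0"}
    assert sel2.table.loc["f0", "asca_loading"]
    assert sel2.dedup_map == {"f9": "f0"}


def test_consensus_mismatched_inputs_rejected():
    idx = pd.Index(["a", "b"])
    s = pd.Series([1.0, 2.0], index=idx)
    fr_table = pd.DataFrame(
        {"statistic": 0.0, "df": 1, "p": [0.5], "q": [0.5], "reject": False},
        index=pd.Index(["a"]),
    )
    fr = uv.FriedmanResult(fr_table, "nitrogen", "b", 5, 12, False)
    with pytest.raises(ValueError, match="different feature sets"):
        consensus_select(s, s, s, fr)


def test_consensus_empty_inputs():
    idx = pd.Index([], dtype=object)
    s = pd.Series([], dtype=float, index=idx)
    fr = uv.FriedmanResult(
        pd.DataFrame(columns=["statistic", "df", "p", "q", "reject"], index=idx),
        "nitrogen", "b", 5, 12, False,
    )
    sel = consensus_select(s, s, s, fr)
    assert len(sel.selected) == 0


def test_null_fdr_control():
    """Pure-null trials: empirical FDR of the BH-corrected Friedman screen
    stays at or below ~alpha (200 replicates, 100 features)."""
    from oatchemo.simulate import SimulationConfig, simulate_experiment

    fdrs = []
    for i in range(200):
        cfg = SimulationConfig(
            rng_seed=20_000 + i,
            n_features=100,
            effect_size_nitrogen=0.0,
            effect_size_variety=0.0,
            missing_rate=0.0,
            adduct_satellite_rate=0.0,
            frac_blank_contaminants=0.0,
        )
        table, design, _ = simulate_experiment(cfg)
        fids = [f for f in table.feature_ids if not f.startswith("IS_")]
        X = np.log(table.areas.loc[fids, design.biological_ids])
        res = friedman_test(X, design, "nitrogen", alpha=0.05)
        n_rej = int(res.table["reject"].sum())
        fdrs.append(1.0 if n_rej > 0 else 0.0)  # every rejection is false
    assert np.mean(fdrs) <= 0.07


def test_power_and_consensus_recovery(prepared):
    """Generator defaults: >= 90% of injected nitrogen-responsive parents are
    BH-significant and enter the consensus set."""
    res = prepared
    fr = friedman_test(res.matrix.T, res.design, "nitrogen")
    inj = res.injected_parents
    assert fr.table.loc[inj, "reject"].mean() >= 0.9

    import oatchemo.chemometrics as cm

    rk = cm.rfe(res.matrix, res.design, step=0.1, n_components=5)
    pca = cm.pca(res.matrix, 2)
    asca = cm.asca_fit(res.matrix, res.design)
    sel = consensus_select(
        pca.loadings["PC1"],
        asca.effects["nitrogen"].loadings["SC1"],
        rk.ranks,
        fr,
        group_parent=res.group_parent,
    )
    in_consensus = np.mean([f in set(sel.selected) for f in inj])
    assert in_consensus >= 0.9
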