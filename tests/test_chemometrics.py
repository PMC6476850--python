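"""PCA behaviour, ASCA decomposition identities and permutation inference,
structured-response PLS (vs an independent PLS1 oracle), bootstrap
validation, and recursive feature elimination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oatchemo import chemometrics as cm
from oatchemo.preprocess import log10_transform
from oatchemo.simulate import SimulationConfig, simulate_experiment

from conftest import toy_design


def _bio_matrix(prepared):
    return prepared.matrix


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank1_explains_everything():
    rng = np.random.default_rng(0)
    u = rng.normal(size=8)[:, None]
    v = rng.normal(size=5)[None, :]
    m = pd.DataFrame(u @ v)
    res = cm.pca(m, 2)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_pc1_tracks_nitrogen_gradient(prepared):
    X = _bio_matrix(prepared)
    res = cm.pca(X, 2)
    dose = prepared.design.samples.loc[X.index, "nitrogen"].astype(float)
    rho = spearmanr(res.scores["PC1"], dose).statistic
    assert abs(rho) > 0.9


def test_pca_qa_samples_centrally_clustered(prepared):
    """Pooled-QA injections sit near the origin of the PC1/PC2 score plane."""
    res = prepared
    qa_ids = [s for s in res.design.qa_ids() if s in res.norm.ratios.columns]
    with_qa = log10_transform(
        res.norm.ratios.loc[res.matrix.columns, list(res.matrix.index) + qa_ids]
    ).T
    p = cm.pca(with_qa, 2)
    for pc in ("PC1", "PC2"):
        centroid = p.scores.loc[qa_ids, pc].mean()
        assert abs(centroid) < p.scores[pc].std()


def test_pca_rejects_excess_components():
    m = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
    with pytest.raises(ValueError):
        cm.pca(m, 10)


# ---------------------------------------------------------------------------
# ASCA


def test_asca_reconstruction_identity(prepared):
    X = _bio_matrix(prepared)
    res = cm.asca_fit(X, prepared.design)
    assert res.reconstruction_error(X) < 1e-10
    for eff in res.effects.values():
        col_means = eff.effect_matrix.mean(axis=0).abs().max()
        assert col_means < 1e-10


def test_asca_ssq_partitions_orthogonally(prepared):
    """Balanced 4 x 5 x 3 design: SSQ(total) = SSQ(variety) + SSQ(nitrogen)
    + SSQ(residual), by direct summation."""
    X = _bio_matrix(prepared)
    res = cm.asca_fit(X, prepared.design)
    parts = sum(e.ssq for e in res.effects.values())
    resid = float((res.residual**2).to_numpy().sum())
    assert parts + resid == pytest.approx(res.total_ssq, rel=1e-10)


def test_asca_noiseless_additive_residual_zero(quiet_sim):
    """With additive log signal and no interaction, the residual after the
    two main effects vanishes when replicate noise -> 0 ... up to replicate
    means; interaction separation leaves exactly zero."""
    table, design, truth = quiet_sim
    fids = truth.features.index[
        (truth.features["satellite_of"] == "")
        & ~truth.features["is_internal_standard"]
    ]
    X = np.log(table.areas.loc[fids, design.biological_ids]).T
    res = cm.asca_fit(X, design, separate_interaction=True)
    resid = float(np.abs(res.residual.to_numpy()).max())
    assert resid < 1e-6
    inter = float(np.abs(res.effects["interaction"].effect_matrix.to_numpy()).max())
    assert inter < 1e-6  # generative model has no interaction either


def test_asca_similar_pair_centroids_mutually_nearest(prepared):
    res = cm.asca_fit(_bio_matrix(prepared), prepared.design)
    em = res.effects["variety"].effect_matrix
    v = prepared.design.samples.loc[em.index, "variety"]
    cents = em.groupby(v.values).mean()
    d = {
        (a, b): float(np.linalg.norm(cents.loc[a] - cents.loc[b]))
        for a, b in itertools.combinations(cents.index, 2)
    }
    assert min(d, key=d.get) == ("Mascani", "Tardis")


def test_asca_single_level_factor_rejected():
    design = toy_design(
        bio=["b1", "b2", "b3", "b4"],
        varieties=["V1"] * 4,
        doses=[0, 50, 0, 50],
        reps=[1, 1, 2, 2],
    )
    X = pd.DataFrame(
        np.random.default_rng(0).normal(size=(4, 3)),
        index=["b1", "b2", "b3", "b4"],
    )
    with pytest.raises(ValueError, match="single level"):
        cm.asca_fit(X, design)


def test_permutation_p_minimum_with_strong_effect(prepared):
    """Injected nitrogen effect dwarfs every permutation: p = 1/(n_perm+1)."""
    X = _bio_matrix(prepared)
    p = cm.asca_permutation_test(X, prepared.design, "nitrogen", n_perm=1000, seed=3)
    assert p == pytest.approx(1.0 / 1001.0)


def test_permutation_requires_positive_n_perm(prepared):
    with pytest.raises(ValueError):
        cm.asca_permutation_test(_bio_matrix(prepared), prepared.design, "nitrogen", n_perm=0)


def test_permutation_null_type_one_error():
    """Empirical size of the nitrogen test within [0.03, 0.07] at alpha=0.05
    over 200 pure-null simulated trials."""
    rejections = 0
    n_datasets = 200
    for i in range(n_datasets):
        cfg = SimulationConfig(
            rng_seed=10_000 + i,
            n_features=40,
            effect_size_nitrogen=0.0,
            effect_size_variety=0.0,
            missing_rate=0.0,
            adduct_satellite_rate=0.0,
            frac_blank_contaminants=0.0,
        )
        table, design, _ = simulate_experiment(cfg)
        X = np.log(table.areas.loc[
            [f for f in table.feature_ids if not f.startswith("IS_")],
            design.biological_ids,
        ]).T
        p = cm.asca_permutation_test(X, design, "nitrogen", n_perm=199, seed=i)
        rejections += p <= 0.05
    rate = rejections / n_datasets
    assert 0.03 <= rate <= 0.07


# ---------------------------------------------------------------------------
# PLS-S


def test_pls_single_column_matches_independent_pls1():
    """With one response column the structured model degenerates to PLS1;
    coefficients agree with scikit-learn's implementation to 1e-8."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(1)
    X = rng.normal(size=(5, 4))
    y = rng.normal(size=(5, 1))
    mine = cm.PlsStructuredModel(n_components=2)
    mine.fit(X, y)
    ref = PLSRegression(n_components=2, scale=False).fit(X, y)
    np.testing.assert_allclose(mine.coef, ref.coef_.T, atol=1e-8)


def test_pls_scores_orthogonal(prepared):
    model = cm.pls_structured_fit(_bio_matrix(prepared), prepared.design, 5)
    T = model.x_scores
    gram = T.T @ T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


def test_pls_perfect_classification_on_noiseless_data(quiet_sim):
    table, design, truth = quiet_sim
    fids = truth.features.index[~truth.features["is_internal_standard"]]
    X = np.log(table.areas.loc[fids, design.biological_ids]).T
    model = cm.pls_structured_fit(X, design, 5)
    cls, dose = model.predict(X.to_numpy())
    v_true = design.samples.loc[X.index, "variety"].to_numpy()
    assert (cls == v_true).all()
    d_true = design.samples.loc[X.index, "nitrogen"].to_numpy(float)
    assert 1 - np.sum((dose - d_true) ** 2) / np.sum((d_true - d_true.mean()) ** 2) > 0.999


def test_pls_rejects_excess_components():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        cm.PlsStructuredModel(n_components=0).fit(
            rng.normal(size=(3, 2)), rng.normal(size=(3, 1))
        )


def test_structured_y_coding(prepared):
    X = _bio_matrix(prepared)
    Y, coding = cm.build_structured_y(prepared.design, X.index)
    onehot = Y[[c for c in Y.columns if c.startswith("variety:")]]
    assert (onehot.sum(axis=1) == 1).all()
    assert Y["dose"].mean() == pytest.approx(0.0, abs=1e-12)
    assert Y["dose"].std(ddof=0) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# bootstrap + RFE


def test_bootstrap_deterministic_and_bounded(prepared):
    X = _bio_matrix(prepared)
    b1 = cm.bootstrap_validate(X, prepared.design, n_boot=20, seed=5)
    b2 = cm.bootstrap_validate(X, prepared.design, n_boot=20, seed=5)
    np.testing.assert_array_equal(b1.accuracies, b2.accuracies)
    np.testing.assert_array_equal(b1.q2, b2.q2)
    assert ((b1.accuracies >= 0) & (b1.accuracies <= 1)).all()
    assert (b1.q2 <= 1).all()


def test_bootstrap_recovers_injected_structure(prepared):
    """Desk-scale analogue of the study's validation: near-perfect variety
    classification and high dose Q^2 on the default synthetic trial."""
    bv = cm.bootstrap_validate(_bio_matrix(prepared), prepared.design, n_boot=200, seed=4)
    assert bv.mean_accuracy >= 0.95
    assert bv.mean_q2 >= 0.9


def test_permuted_dose_destroys_q2(prepared):
    """Shuffling the dose labels of the design wipes out predictive power."""
    X = _bio_matrix(prepared)
    design = prepared.design
    rng = np.random.default_rng(0)
    shuffled = design.samples.copy()
    bio = list(design.biological_ids)
    shuffled.loc[bio, "nitrogen"] = rng.permutation(
        shuffled.loc[bio, "nitrogen"].to_numpy()
    )
    from oatchemo.io import SampleDesign

    bv = cm.bootstrap_validate(X, SampleDesign(shuffled), n_boot=50, seed=6)
    assert bv.mean_q2 <= 0.1


def test_rfe_two_features_signal_first():
    design = toy_design(
        bio=[f"b{i}" for i in range(12)],
        varieties=["V1", "V2"] * 6,
        doses=[0, 0, 50, 50, 100, 100, 150, 150, 200, 200, 0, 50],
        reps=[1] * 12,
    )
    rng = np.random.default_rng(2)
    dose = design.samples.loc[design.biological_ids, "nitrogen"].to_numpy(float)
    X = pd.DataFrame(
        {
            "signal": dose / 100.0 + 0.01 * rng.normal(size=12),
            "noise": rng.normal(size=12),
        },
        index=design.biological_ids,
    )
    rk = cm.rfe(X, design, step=0.5, n_components=1)
    assert rk.ranks["signal"] == 1
    assert rk.ranks["noise"] > 1


def test_rfe_ranks_are_valid_and_recover_injected(prepared):
    rk = prepared_rfe(prepared)
    ranks = rk.ranks
    assert ranks.min() == 1
    assert ranks.max() <= len(ranks)
    inj = prepared.injected_parents
    top = set(rk.top(len(inj)))
    recovery = np.mean([f in top for f in inj])
    assert recovery >= 0.9


def prepared_rfe(prepared, _cache={}):
    if "rk" not in _cache:
        _cache["rk"] = cm.rfe(prepared.matrix, prepared.design, step=0.1, n_components=5)
    return _cache["rk"]


def test_rfe_sparse_injection_top_five_percent():
    """10 nitrogen-responsive features among 500: at least 9 land in the
    top 5% of the elimination ranking."""
    cfg = SimulationConfig(
        rng_seed=11,
        n_features=500,
        frac_nitrogen_responsive=0.02,
        frac_variety_discriminant=0.10,
        adduct_satellite_rate=0.0,
        frac_blank_contaminants=0.0,
        missing_rate=0.0,  # isolate the ranking property from QC attrition
    )
    table, design, truth = simulate_experiment(cfg)
    from oatchemo.preprocess import preprocess

    norm = preprocess(table, design)
    X = log10_transform(norm.ratios[list(design.biological_ids)]).T
    rk = cm.rfe(X, design, step=0.1, n_components=5)
    inj = [f for f in truth.nitrogen_responsive_ids if f in X.columns]
    assert len(inj) == 10
    top = set(rk.top(int(np.ceil(0.05 * len(rk.ranks)))))
    assert np.mean([f in top for f in inj]) >= 0.9
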