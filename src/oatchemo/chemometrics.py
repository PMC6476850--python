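"""Designed-experiment chemometrics: PCA, ASCA with permutation inference,
and structured-response PLS with recursive feature elimination and bootstrap
validation.

ASCA partitions the column-centered data matrix X (samples x features) of a
balanced two-factor design into per-factor effect matrices built from
factor-level means::

    X_c = X_variety + X_nitrogen [+ X_interaction] + E

Each effect matrix is analysed by a simultaneous-component (PCA-like) SVD;
factor significance comes from permutation tests on the effect sum of
squares, with the tested factor's labels permuted within the strata of the
other factor.  By default the interaction is pooled into the residual.

The structured-response PLS (PLS-S) codes the whole design into one response
block — a variety indicator matrix plus a standardized numeric nitrogen-dose
column — and fits a NIPALS PLS2 model, so class membership and the dose
regression are modelled simultaneously.  Prediction returns the arg-max
variety and the de-standardized dose.  Validation is by bootstrap
resampling: fit on the in-bag samples, score out-of-bag classification
accuracy and dose Q^2 = 1 - PRESS/TSS.  Recursive feature elimination
refits the model while discarding the least important fraction of features
per round; importance is |dose coefficient| + max |variety coefficient|.

All models mean-center only (no unit-variance scaling): the data are
internal-standard ratios on a log scale, already on a common footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .io import SampleDesign

# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int) -> PcaResult:
    """PCA of a samples-x-features matrix (mean-centering only, full SVD)."""
    n, p = matrix.shape
    if n < 2:
        raise ValueError("need >= 2 samples")
    if n_components > min(n, p):
        raise ValueError("n_components exceeds matrix rank bound")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy(dtype=float))
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(model.components_.T, index=matrix.columns, columns=comps),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# ASCA


@dataclass
class AscaEffect:
    name: str
    effect_matrix: pd.DataFrame  # samples x features, zero column means
    ssq: float
    scores: pd.DataFrame  # SCA scores (effect + residual projected)
    scores_pure: pd.DataFrame  # scores of the effect matrix alone
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    p_value: float | None = None


@dataclass
class AscaResult:
    grand_mean: pd.Series
    effects: dict  # factor name -> AscaEffect
    residual: pd.DataFrame
    total_ssq: float
    n_permutations: int = 0

    def reconstruction_error(self, matrix: pd.DataFrame) -> float:
        """Max abs deviation of centered data from sum(effects) + residual."""
        centered = matrix - self.grand_mean
        recon = self.residual.copy()
        for eff in self.effects.values():
            recon = recon + eff.effect_matrix
        return float((centered - recon).abs().to_numpy().max())


def _effect_matrix(centered: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rows = level means of the centered data for each sample's level."""
    out = np.empty_like(centered)
    for lvl in np.unique(labels):
        m = labels == lvl
        out[m] = centered[m].mean(axis=0)
    return out


def _factor_labels(design: SampleDesign, samples, factor: str) -> np.ndarray:
    col = {"variety": "variety", "nitrogen": "nitrogen"}[factor]
    return design.samples.loc[samples, col].to_numpy()


def asca_fit(
    matrix: pd.DataFrame,
    design: SampleDesign,
    factors: tuple = ("variety", "nitrogen"),
    separate_interaction: bool = False,
    n_components: int = 2,
) -> AscaResult:
    """ASCA decomposition of a samples-x-features matrix over design factors.

    ``matrix`` rows must be biological samples.  Each factor needs >= 2
    levels.  SCA score plots conventionally add the residual projected onto
    the effect loadings (``scores``); ``scores_pure`` holds the projection
    of the effect matrix alone.
    """
    samples = matrix.index
    x = matrix.to_numpy(dtype=float)
    grand = x.mean(axis=0)
    centered = x - grand
    label_arrays = {}
    for f in factors:
        labs = _factor_labels(design, samples, f)
        if len(np.unique(labs)) < 2:
            raise ValueError(f"factor {f!r} has a single level")
        label_arrays[f] = labs

    effect_mats = {f: _effect_matrix(centered, label_arrays[f]) for f in factors}
    residual = centered - sum(effect_mats.values())
    if separate_interaction and len(factors) == 2:
        combo = np.array(
            [f"{a}|{b}" for a, b in zip(*[label_arrays[f] for f in factors])]
        )
        cell = _effect_matrix(centered, combo)
        inter = cell - sum(effect_mats.values())
        effect_mats["interaction"] = inter
        residual = centered - cell

    effects = {}
    for name, em in effect_mats.items():
        # SCA: SVD of the (already centered) effect matrix; component count
        # limited by the effect matrix's numerical rank
        u, s, vt = np.linalg.svd(em, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 1
        k = max(1, min(n_components, rank))
        load = vt[:k].T
        comps = [f"SC{i + 1}" for i in range(k)]
        sc_pure = em @ load
        sc_vis = (em + residual) @ load
        tot = float((em**2).sum())
        evr = (s[:k] ** 2) / max(tot, np.finfo(float).tiny)
        effects[name] = AscaEffect(
            name=name,
            effect_matrix=pd.DataFrame(em, index=samples, columns=matrix.columns),
            ssq=tot,
            scores=pd.DataFrame(sc_vis, index=samples, columns=comps),
            scores_pure=pd.DataFrame(sc_pure, index=samples, columns=comps),
            loadings=pd.DataFrame(load, index=matrix.columns, columns=comps),
            explained_variance_ratio=evr,
        )
    return AscaResult(
        grand_mean=pd.Series(grand, index=matrix.columns),
        effects=effects,
        residual=pd.DataFrame(residual, index=samples, columns=matrix.columns),
        total_ssq=float((centered**2).sum()),
    )


def _stratified_permutation(labels: np.ndarray, strata: np.ndarray | None, rng) -> np.ndarray:
    out = labels.copy()
    if strata is None:
        return rng.permutation(labels)
    for s in np.unique(strata):
        m = strata == s
        out[m] = rng.permutation(labels[m])
    return out


def asca_permutation_test(
    matrix: pd.DataFrame,
    design: SampleDesign,
    factor: str,
    n_perm: int = 1000,
    seed: int | None = None,
    stratify_by_other: bool = True,
) -> float:
    """Permutation p-value for one ASCA factor.

    Statistic: sum of squares of the factor's effect matrix.  The tested
    factor's labels are permuted within the strata of the other factor;
    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = matrix.index
    x = matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    labels = _factor_labels(design, samples, factor)
    other = {"variety": "nitrogen", "nitrogen": "variety"}[factor]
    strata = _factor_labels(design, samples, other) if stratify_by_other else None
    obs = float((_effect_matrix(centered, labels) ** 2).sum())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = _stratified_permutation(labels, strata, rng)
        stat = float((_effect_matrix(centered, perm) ** 2).sum())
        if stat >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# structured-response PLS


def build_structured_y(design: SampleDesign, samples) -> tuple[pd.DataFrame, dict]:
    """Design-coded response block: variety one-hot + standardized dose column.

    Returns ``(Y, coding)`` where ``coding`` records the variety column
    order and the dose mean/sd used for standardization (dose is treated as
    continuous; the model's dose output is reported as Q^2 of a regression).
    """
    varieties = design.varieties
    v = design.samples.loc[samples, "variety"]
    onehot = pd.DataFrame(
        {f"variety:{name}": (v == name).astype(float) for name in varieties},
        index=samples,
    )
    dose = design.samples.loc[samples, "nitrogen"].astype(float)
    mu, sd = float(dose.mean()), float(dose.std(ddof=0))
    if sd == 0:
        raise ValueError("nitrogen dose has zero variance")
    y = onehot.copy()
    y["dose"] = (dose - mu) / sd
    coding = {"varieties": varieties, "dose_mean": mu, "dose_sd": sd}
    return y, coding


@dataclass
class PlsStructuredModel:
    """NIPALS PLS2 fit against the structured response block."""

    n_components: int
    x_mean: np.ndarray = field(default=None, repr=False)
    y_mean: np.ndarray = field(default=None, repr=False)
    weights: np.ndarray = field(default=None, repr=False)  # W, p x a
    x_loadings: np.ndarray = field(default=None, repr=False)  # P
    y_loadings: np.ndarray = field(default=None, repr=False)  # Q
    x_scores: np.ndarray = field(default=None, repr=False)  # T
    coef: np.ndarray = field(default=None, repr=False)  # B, p x m
    coding: dict = None
    feature_names: list = None
    y_names: list = None

    def fit(self, X: np.ndarray, Y: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, p = X.shape
        m = Y.shape[1]
        a = min(self.n_components, n - 1, p)
        if a < 1:
            raise ValueError("n_components exceeds the rank bound of X")
        self.n_components = a
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        Xc = X - self.x_mean
        Yc = Y - self.y_mean
        W = np.zeros((p, a))
        P = np.zeros((p, a))
        Q = np.zeros((m, a))
        T = np.zeros((n, a))
        for k in range(a):
            if np.allclose(Xc, 0) or np.allclose(Yc, 0):
                a = k
                break
            u = Yc[:, [int(np.argmax(Yc.var(axis=0)))]]
            t_old = None
            for _ in range(max_iter):
                w = Xc.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w /= nw
                t = Xc @ w
                tt = float(np.sum(t * t))
                if tt == 0:
                    break
                q = Yc.T @ t / tt
                qq = float(np.sum(q * q))
                if qq == 0:
                    break
                u = Yc @ q / qq
                if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                    break
                t_old = t
            pvec = Xc.T @ t / tt
            W[:, k] = w[:, 0]
            P[:, k] = pvec[:, 0]
            Q[:, k] = q[:, 0]
            T[:, k] = t[:, 0]
            Xc = Xc - t @ pvec.T
            Yc = Yc - t @ q.T
        if a < 1:
            raise ValueError("X carries no variance; cannot fit PLS")
        self.n_components = a
        W, P, Q, T = W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
        self.weights, self.x_loadings, self.y_loadings, self.x_scores = W, P, Q, T
        # B = W (P'W)^-1 Q'
        self.coef = W @ np.linalg.solve(P.T @ W, Q.T)
        return self

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict(self, X: np.ndarray):
        """Return ``(variety labels, dose values)`` decoded from Y-hat."""
        yhat = self.predict_y(X)
        varieties = self.coding["varieties"]
        k = len(varieties)
        cls = [varieties[i] for i in np.argmax(yhat[:, :k], axis=1)]
        dose = yhat[:, k] * self.coding["dose_sd"] + self.coding["dose_mean"]
        return np.array(cls, dtype=object), dose


def pls_structured_fit(
    matrix: pd.DataFrame,
    design: SampleDesign,
    n_components: int = 5,
) -> PlsStructuredModel:
    """Fit PLS-S on biological samples of a samples-x-features matrix."""
    samples = matrix.index
    Y, coding = build_structured_y(design, samples)
    model = PlsStructuredModel(n_components=n_components)
    model.coding = coding
    model.feature_names = list(matrix.columns)
    model.y_names = list(Y.columns)
    model.fit(matrix.to_numpy(dtype=float), Y.to_numpy(dtype=float))
    return model


# ---------------------------------------------------------------------------
# bootstrap validation


@dataclass
class BootstrapValidation:
    n_bootstrap: int
    accuracies: np.ndarray  # per-resample out-of-bag variety accuracy
    q2: np.ndarray  # per-resample out-of-bag dose Q^2
    n_redrawn: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_q2(self) -> float:
        return float(np.mean(self.q2))


def bootstrap_validate(
    matrix: pd.DataFrame,
    design: SampleDesign,
    n_boot: int = 1000,
    n_components: int = 5,
    seed: int | None = None,
) -> BootstrapValidation:
    """Bootstrap-resampling validation of the structured-response PLS.

    Each resample draws n samples with replacement, fits on the in-bag set,
    and evaluates on the out-of-bag samples: variety classification accuracy
    and dose Q^2 = 1 - PRESS/TSS (TSS about the in-bag mean dose).  Resamples
    with an empty out-of-bag set are redrawn (counted in ``n_redrawn``).
    """
    rng = np.random.default_rng(seed)
    samples = matrix.index
    n = len(samples)
    X = matrix.to_numpy(dtype=float)
    v_true = design.samples.loc[samples, "variety"].to_numpy()
    dose_true = design.samples.loc[samples, "nitrogen"].to_numpy(dtype=float)
    accs, q2s, redrawn = [], [], 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > 0:
                break
            redrawn += 1
        sub = matrix.iloc[idx]
        sub.index = samples[idx]  # keep design lookup on original ids
        Y, coding = build_structured_y(design, samples[idx])
        model = PlsStructuredModel(n_components=n_components)
        model.coding = coding
        model.fit(X[idx], Y.to_numpy(dtype=float))
        cls, dose_hat = model.predict(X[oob])
        accs.append(float(np.mean(cls == v_true[oob])))
        press = float(np.sum((dose_true[oob] - dose_hat) ** 2))
        tss = float(np.sum((dose_true[oob] - dose_true[idx].mean()) ** 2))
        q2s.append(1.0 - press / tss if tss > 0 else np.nan)
    return BootstrapValidation(
        n_bootstrap=n_boot,
        accuracies=np.asarray(accs),
        q2=np.asarray(q2s),
        n_redrawn=redrawn,
    )


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass
class RfeRanking:
    ranks: pd.Series  # per-feature rank, 1 = most important (ties allowed)
    schedule: list  # (rank, [features eliminated at that rank])
    importances: pd.Series | None = None  # importance when (last) scored

    def top(self, k: int) -> pd.Index:
        """Best-ranked k features; ties broken by elimination-time importance."""
        if self.importances is not None:
            order = (
                pd.DataFrame({"rank": self.ranks, "imp": -self.importances})
                .sort_values(["rank", "imp"], kind="stable")
                .index
            )
        else:
            order = self.ranks.sort_values(kind="stable").index
        return order[:k]


def _pls_importance(
    model: PlsStructuredModel,
    n_varieties: int,
    importance: str = "dose",
    x_sd: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature importance from the PLS coefficient matrix.

    Coefficients are weighted by the feature's standard deviation (the model
    is fit without unit-variance scaling, so a raw coefficient's size is
    confounded with the feature's scale; sd * |coef| is the feature's actual
    contribution to the prediction).

    ``"dose"`` (default): dose-column contribution only — the elimination
    then targets features responding to nitrogen regardless of variety.
    ``"dose+variety"``: adds the max variety-indicator contribution.
    """
    b = model.coef
    sd = np.ones(b.shape[0]) if x_sd is None else x_sd
    dose = np.abs(b[:, n_varieties]) * sd
    if importance == "dose":
        return dose
    if importance == "dose+variety":
        return dose + np.abs(b[:, :n_varieties]).max(axis=1) * sd
    raise ValueError(f"unknown importance scheme {importance!r}")


def rfe(
    matrix: pd.DataFrame,
    design: SampleDesign,
    step: float = 0.1,
    n_components: int = 5,
    min_features: int = 1,
    importance: str = "dose",
    seed: int | None = None,
) -> RfeRanking:
    """Recursive feature elimination under the structured-response PLS.

    Per round: fit PLS-S on the surviving features, score each by the
    coefficient importance, eliminate the lowest-scoring ``step`` fraction
    (at least one feature).  Features eliminated together share a rank equal
    to one plus the number of features still surviving; final survivors
    share rank 1.  Deterministic given the data; ``seed`` is accepted for
    interface symmetry.
    """
    if not 0 < step < 1:
        raise ValueError("step must be a fraction in (0, 1)")
    surviving = list(matrix.columns)
    n_var = len(design.varieties)
    ranks = pd.Series(index=matrix.columns, dtype=float)
    imps = pd.Series(index=matrix.columns, dtype=float)
    schedule = []
    while len(surviving) > min_features:
        model = pls_structured_fit(matrix[surviving], design, n_components)
        x_sd = matrix[surviving].to_numpy(dtype=float).std(axis=0)
        imp = _pls_importance(model, n_var, importance, x_sd)
        imps[surviving] = imp
        n_drop = max(1, int(np.floor(step * len(surviving))))
        n_drop = min(n_drop, len(surviving) - min_features)
        order = np.argsort(imp, kind="stable")
        dropped = [surviving[i] for i in order[:n_drop]]
        surviving = [f for f in surviving if f not in set(dropped)]
        rank = len(surviving) + 1
        ranks[dropped] = rank
        schedule.append((rank, dropped))
    ranks[surviving] = 1
    schedule.append((1, list(surviving)))
    return RfeRanking(ranks=ranks.astype(int), schedule=schedule[::-1], importances=imps)


def select_n_components(
    matrix: pd.DataFrame,
    design: SampleDesign,
    k_max: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> int:
    """Choose the component count by k-fold CV on the dose column (PRESS)."""
    rng = np.random.default_rng(seed)
    samples = matrix.index
    n = len(samples)
    folds = np.array_split(rng.permutation(n), n_folds)
    X = matrix.to_numpy(dtype=float)
    dose = design.samples.loc[samples, "nitrogen"].to_numpy(dtype=float)
    best, best_press = 1, np.inf
    for a in range(1, min(k_max, n - max(len(f) for f in folds) - 1) + 1):
        press = 0.0
        for f in folds:
            tr = np.setdiff1d(np.arange(n), f)
            Y, coding = build_structured_y(design, samples[tr])
            model = PlsStructuredModel(n_components=a)
            model.coding = coding
            model.fit(X[tr], Y.to_numpy(dtype=float))
            _, dose_hat = model.predict(X[f])
            press += float(np.sum((dose[f] - dose_hat) ** 2))
        if press < best_press:
            best, best_press = a, press
    return best
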