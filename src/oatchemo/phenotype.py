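"""Grain-phenotype statistics for the split-plot trial: two-stratum ANOVA
with Fisher's protected LSD and compact-letter display, plus simple derived
statistics (trait correlations, percent change across nitrogen levels).

The field layout is a split plot: nitrogen dose on main plots within
replicate blocks, variety on sub-plots.  The nitrogen F-test therefore uses
the block x nitrogen interaction as its error stratum; variety and the
variety x nitrogen interaction are tested against the sub-plot residual.

The published factor means of the trial (4 varieties x 5 nitrogen doses,
n = 3 replicates) are shipped as an in-package fixture
(:func:`published_factor_means`) and drive the worked examples: e.g. the
grain-yield increase from the zero-N control (4.90 t ha^-1) to 200 kg N
ha^-1 (11.26 t ha^-1) is 130% to the nearest integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = (
    "plant_height_mm",
    "grain_yield_t_ha",
    "panicle_number_m2",
    "grain_number_panicle",
    "grain_number_m2",
    "kernel_content_pct",
    "tgw_grain_g",
    "tgw_groat_g",
    "protein_pct_dm",
    "oil_pct_dm",
    "beta_glucan_pct_dm",
)

_NITROGEN_MEANS = {
    # dose kg N ha^-1 -> trait means, published factor means of the trial
    0: (83.80, 4.90, 251.80, 40.40, 10097.00, 72.98, 41.49, 32.47, 9.11, 8.00, 3.72),
    50: (101.10, 8.05, 353.70, 44.73, 15603.00, 73.47, 44.11, 33.46, 9.64, 7.89, 3.83),
    100: (111.90, 9.26, 414.60, 45.98, 18427.00, 73.94, 42.96, 33.55, 10.67, 7.70, 3.86),
    150: (126.40, 9.74, 408.10, 49.17, 19772.00, 74.10, 42.03, 33.66, 11.65, 7.57, 3.93),
    200: (124.30, 11.26, 390.80, 58.03, 22280.00, 75.50, 43.32, 34.65, 12.97, 7.39, 4.07),
}

_VARIETY_MEANS = {
    "Gerald": (112.80, 8.70, 392.00, 48.21, 18942.62, 73.90, 38.94, 29.59, 10.70, 7.66, 3.31),
    "Mascani": (114.00, 8.29, 399.78, 37.98, 15307.64, 77.23, 45.85, 37.33, 10.71, 7.31, 3.96),
    "Tardis": (112.27, 8.72, 363.22, 47.82, 17563.82, 72.64, 42.57, 32.18, 11.01, 8.19, 3.75),
    "Balado": (99.00, 8.86, 300.22, 56.64, 17128.92, 72.22, 43.76, 35.14, 10.82, 7.68, 4.50),
}


def published_factor_means(factor: str = "nitrogen") -> pd.DataFrame:
    """Published trait means by nitrogen dose or by variety (trial fixture)."""
    src = _NITROGEN_MEANS if factor == "nitrogen" else _VARIETY_MEANS
    return pd.DataFrame.from_dict(src, orient="index", columns=list(TRAITS))


# ---------------------------------------------------------------------------
# split-plot ANOVA


@dataclass
class AnovaTerm:
    ss: float
    df: int
    ms: float
    f: float | None = None
    p: float | None = None


@dataclass
class SplitPlotAnova:
    terms: dict  # name -> AnovaTerm; names: block, nitrogen, error_main,
    #             variety, interaction, error_sub, total
    balanced: bool

    def p(self, term: str) -> float:
        return self.terms[term].p


def split_plot_anova(
    data: pd.DataFrame,
    trait: str,
    main: str = "nitrogen",
    sub: str = "variety",
    block: str = "replicate",
) -> SplitPlotAnova:
    """Two-stratum ANOVA for one trait of a split-plot layout.

    ``data`` holds one row per plot with columns for the main-plot factor
    (nitrogen), sub-plot factor (variety), block, and the trait.  The main
    factor is tested against the block x main stratum; sub factor and
    interaction against the sub-plot residual.  Unbalanced layouts fall back
    to Type-II least squares with a single residual stratum (warning).
    """
    d = data[[main, sub, block, trait]].dropna()
    y = d[trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        # constant trait: all effects zero
        n = len(y)
        zero = AnovaTerm(0.0, 0, 0.0, 0.0, 1.0)
        terms = {k: zero for k in ("block", main, "error_main", sub, "interaction", "error_sub")}
        terms["total"] = AnovaTerm(0.0, n - 1, 0.0)
        return SplitPlotAnova(terms=terms, balanced=True)

    counts = d.groupby([main, sub, block], observed=True)[trait].count()
    balanced = counts.nunique() == 1
    a = d[main].nunique()
    blev = d[sub].nunique()
    r = d[block].nunique()
    if not balanced:
        warnings.warn("unbalanced layout: Type-II least squares, single stratum")
        return _type2_anova(d, trait, main, sub, block)

    grand = y.mean()
    n = len(y)

    def ss_of(group_cols):
        m = d.groupby(group_cols, observed=True)[trait].mean()
        cnt = d.groupby(group_cols, observed=True)[trait].count()
        return float((cnt * (m - grand) ** 2).sum())

    ss_total = float(((y - grand) ** 2).sum())
    ss_block = ss_of([block])
    ss_main = ss_of([main])
    ss_mainplots = ss_of([block, main])  # whole-plot stratum total
    ss_err_main = ss_mainplots - ss_block - ss_main
    ss_sub = ss_of([sub])
    ss_cells = ss_of([main, sub])
    ss_int = ss_cells - ss_main - ss_sub
    ss_err_sub = ss_total - ss_mainplots - ss_sub - ss_int

    df_block = r - 1
    df_main = a - 1
    df_err_main = (a - 1) * (r - 1)
    df_sub = blev - 1
    df_int = (a - 1) * (blev - 1)
    df_err_sub = a * (blev - 1) * (r - 1)

    def term(ss, df):
        return AnovaTerm(ss, df, ss / df if df > 0 else np.nan)

    t_block = term(ss_block, df_block)
    t_main = term(ss_main, df_main)
    t_em = term(ss_err_main, df_err_main)
    t_sub = term(ss_sub, df_sub)
    t_int = term(ss_int, df_int)
    t_es = term(ss_err_sub, df_err_sub)

    for t, err in ((t_main, t_em), (t_sub, t_es), (t_int, t_es)):
        if err.ms > 0:
            t.f = t.ms / err.ms
            t.p = float(stats.f.sf(t.f, t.df, err.df))
        else:
            t.f, t.p = np.inf if t.ms > 0 else 0.0, 0.0 if t.ms > 0 else 1.0
    terms = {
        "block": t_block,
        main: t_main,
        "error_main": t_em,
        sub: t_sub,
        "interaction": t_int,
        "error_sub": t_es,
        "total": AnovaTerm(ss_total, n - 1, ss_total / (n - 1)),
    }
    return SplitPlotAnova(terms=terms, balanced=True)


def _type2_anova(d, trait, main, sub, block):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = d.rename(columns={trait: "y", main: "A", sub: "B", block: "blk"})
    for c in ("A", "B", "blk"):
        frame[c] = frame[c].astype("category")
    model = smf.ols("y ~ C(blk) + C(A) * C(B)", data=frame).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    resid = tab.loc["Residual"]
    terms = {}
    mapping = {"C(blk)": "block", "C(A)": main, "C(B)": sub, "C(A):C(B)": "interaction"}
    for key, name in mapping.items():
        row = tab.loc[key]
        terms[name] = AnovaTerm(
            float(row["sum_sq"]), int(row["df"]),
            float(row["sum_sq"] / row["df"]), float(row["F"]), float(row["PR(>F)"]),
        )
    es = AnovaTerm(float(resid["sum_sq"]), int(resid["df"]), float(resid["sum_sq"] / resid["df"]))
    terms["error_main"] = es
    terms["error_sub"] = es
    terms["total"] = AnovaTerm(float(tab["sum_sq"].sum()), int(tab["df"].sum()), np.nan)
    return SplitPlotAnova(terms=terms, balanced=False)


# ---------------------------------------------------------------------------
# Fisher's protected LSD with compact letters


@dataclass
class LsdLetters:
    means: pd.Series  # sorted ascending
    lsd: float
    letters: pd.Series  # same index as means
    protected: bool = True


def fisher_lsd_letters(
    means: pd.Series,
    error_ms: float,
    df: int,
    n_per_mean: int,
    alpha: float = 0.05,
    omnibus_p: float | None = None,
) -> LsdLetters:
    """Fisher's LSD at level alpha with insert-and-absorb letter display.

    ``LSD = t(1 - alpha/2, df) * sqrt(2 * MS_error / n)``.  Two means differ
    significantly iff their difference strictly exceeds the LSD.  Letters are
    assigned from the smallest mean ('a') upward; when ``omnibus_p`` is given
    and not significant, the test is "unprotected" and no letters are emitted.
    """
    if df <= 0:
        raise ValueError("error degrees of freedom must be > 0")
    lsd = float(stats.t.ppf(1 - alpha / 2, df) * np.sqrt(2.0 * error_ms / n_per_mean))
    srt = means.sort_values(kind="stable")
    if omnibus_p is not None and omnibus_p >= alpha:
        return LsdLetters(
            means=srt, lsd=lsd,
            letters=pd.Series("", index=srt.index), protected=False,
        )
    vals = srt.to_numpy(dtype=float)
    m = len(vals)
    # maximal runs of mutually non-significant means (insert step) ...
    intervals = []
    for i in range(m):
        j = i
        while j + 1 < m and vals[j + 1] - vals[i] <= lsd:
            j += 1
        intervals.append((i, j))
    # ... absorb intervals contained in an earlier one
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] for o in maximal):
            maximal.append(iv)
    letters = ["" for _ in range(m)]
    for li, (i, j) in enumerate(maximal):
        ch = chr(ord("a") + li)
        for t in range(i, j + 1):
            letters[t] += ch
    return LsdLetters(
        means=srt, lsd=lsd, letters=pd.Series(letters, index=srt.index), protected=True
    )


def lsd_for_factor(
    data: pd.DataFrame,
    trait: str,
    anova: SplitPlotAnova,
    factor: str,
    alpha: float = 0.05,
) -> LsdLetters:
    """Protected LSD letters for a factor's means using its ANOVA stratum."""
    err = anova.terms["error_main" if factor == "nitrogen" else "error_sub"]
    means = data.groupby(factor, observed=True)[trait].mean()
    n_per = data.groupby(factor, observed=True)[trait].count().min()
    return fisher_lsd_letters(
        means, err.ms, err.df, int(n_per), alpha, omnibus_p=anova.p(factor)
    )


# ---------------------------------------------------------------------------
# derived statistics


def trait_correlations(data: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Plot-level Pearson correlation matrix between traits."""
    traits = list(traits or [t for t in TRAITS if t in data.columns])
    sub = data[traits]
    zero_var = [t for t in traits if sub[t].std(ddof=0) == 0]
    if zero_var:
        raise ValueError(f"zero-variance traits: {zero_var}")
    return sub.corr()


def percent_change(means: pd.Series, from_level, to_level) -> float:
    """Percent change between two factor-level means, to the nearest integer."""
    a, b = float(means.loc[from_level]), float(means.loc[to_level])
    if a == 0:
        raise ValueError("reference mean is zero")
    return float(round((b - a) / a * 100.0))


def factor_mean_correlation(trait_x: str, trait_y: str, factor: str = "nitrogen") -> float:
    """Pearson r between two traits over the published factor means."""
    m = published_factor_means(factor)
    return float(np.corrcoef(m[trait_x], m[trait_y])[0, 1])
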