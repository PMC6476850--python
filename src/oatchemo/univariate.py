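"""Friedman screening with Benjamini-Hochberg FDR, per-variety monotone
nitrogen-response reports, and the cross-method consensus feature selection.

The Friedman test is the rank-based analogue of two-way ANOVA for a
randomized block layout: within each block the treatment values are ranked
(mid-ranks for ties) and the statistic

    chi2 = 12 / (b k (k+1)) * sum_j R_j^2  -  3 b (k+1)

is referred to the chi-squared distribution with k-1 degrees of freedom
(b blocks, k treatments, R_j the rank sum of treatment j).  For the nitrogen
factor the default blocking is variety x replicate (each field plot enters
directly); for the variety factor it is nitrogen x replicate.  With k = 3
treatments the chi-squared approximation is coarse, so the p-value is
computed by exact enumeration of the (3!)^b equally likely per-block
rankings (dynamic programming over rank-sum states) for b <= 10.

The consensus selection unions the most influential PCA loadings, the top
ASCA nitrogen-effect loadings, the best RFE-ranked PLS features, and the
top-N Friedman features, then deduplicates by ion-group membership (each
group is represented by its parent ion).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleDesign

BLOCKING = {
    "nitrogen": ("nitrogen", ["variety", "replicate"]),
    "variety": ("variety", ["nitrogen", "replicate"]),
}


@dataclass
class FriedmanResult:
    table: pd.DataFrame  # per feature: statistic, df, p, q, reject
    factor: str
    block: str
    k: int
    b: int
    exact: bool

    def top(self, n: int) -> pd.Index:
        return self.table["p"].sort_values(kind="stable").index[:n]


def _friedman_stat(ranks: np.ndarray, tie_correction: bool = False) -> np.ndarray:
    """Vectorised Friedman chi-squared over features.

    ``ranks``: (features, blocks, treatments) within-block ranks.
    """
    f, b, k = ranks.shape
    rank_sums = ranks.sum(axis=1)  # features x treatments
    stat = 12.0 / (b * k * (k + 1)) * (rank_sums**2).sum(axis=1) - 3.0 * b * (k + 1)
    if tie_correction:
        # classical correction: divide by 1 - sum(t^3 - t) / (b k (k^2-1))
        corr = np.ones(f)
        for fi in range(f):
            tie_term = 0.0
            for bi in range(b):
                _, counts = np.unique(ranks[fi, bi], return_counts=True)
                tie_term += float(np.sum(counts**3 - counts))
            denom = 1.0 - tie_term / (b * k * (k**2 - 1))
            corr[fi] = denom if denom > 0 else np.nan
        stat = stat / corr
    return stat


def _exact_friedman_sf(k: int, b: int):
    """Null survival function of the Friedman statistic by DP enumeration.

    Returns a callable mapping observed statistics to exact P(stat >= obs)
    under uniform independent per-block rankings.  Feasible for small k
    (state space = all reachable rank-sum vectors).
    """
    perms = list(itertools.permutations(range(1, k + 1)))
    states = {(0.0,) * k: 1.0}
    for _ in range(b):
        new: dict = {}
        for sums, cnt in states.items():
            for p in perms:
                key = tuple(s + r for s, r in zip(sums, p))
                new[key] = new.get(key, 0.0) + cnt
        states = new
    total = float(len(perms)) ** b
    stats_w = {}
    for sums, cnt in states.items():
        s = 12.0 / (b * k * (k + 1)) * sum(x**2 for x in sums) - 3.0 * b * (k + 1)
        s = round(s, 10)
        stats_w[s] = stats_w.get(s, 0.0) + cnt
    levels = np.array(sorted(stats_w))
    weights = np.array([stats_w[s] for s in levels])
    sf_at = np.cumsum(weights[::-1])[::-1] / total  # P(stat >= level)

    def sf(obs):
        obs = np.atleast_1d(np.asarray(obs, dtype=float))
        out = np.empty_like(obs)
        for i, o in enumerate(obs):
            mask = levels >= o - 1e-9
            out[i] = sf_at[np.argmax(mask)] if mask.any() else 0.0
        return out

    return sf


def friedman_test(
    values: pd.DataFrame,
    design: SampleDesign,
    factor: str = "nitrogen",
    alpha: float = 0.05,
    tie_correction: bool = False,
    exact: bool | None = None,
) -> FriedmanResult:
    """Friedman test per feature over the biological samples.

    ``values`` is features x samples.  Treatments are the levels of
    ``factor``; blocks are the crossed combinations of the remaining design
    columns (each block must contain exactly one value per treatment —
    replicate cells are averaged otherwise).  ``exact=None`` auto-selects
    exact enumeration for k = 3, b <= 10.
    """
    fac_col, block_cols = BLOCKING[factor]
    bio = [s for s in values.columns if s in set(design.biological_ids)]
    meta = design.samples.loc[bio]
    treat = meta[fac_col]
    block = meta[block_cols].astype(str).agg("|".join, axis=1)
    treatments = sorted(treat.unique())
    blocks = sorted(block.unique())
    k, b = len(treatments), len(blocks)
    if k < 2:
        raise ValueError("factor has fewer than 2 levels")
    if k < 3:
        warnings.warn("chi-squared approximation unreliable for k < 3 treatments")

    # cell means: features x blocks x treatments (averaging replicate cells)
    cells = np.full((len(values), b, k), np.nan)
    t_idx = {t: j for j, t in enumerate(treatments)}
    b_idx = {g: i for i, g in enumerate(blocks)}
    counts = np.zeros((b, k))
    vals = values[bio].to_numpy(dtype=float)
    for col, s in enumerate(bio):
        i, j = b_idx[block[s]], t_idx[treat[s]]
        if counts[i, j] == 0:
            cells[:, i, j] = vals[:, col]
        else:
            cells[:, i, j] += vals[:, col]
        counts[i, j] += 1
    if (counts == 0).any():
        raise ValueError("incomplete block layout: empty block x treatment cell")
    cells = cells / counts[None, :, :]

    ranks = stats.rankdata(cells, axis=2)  # mid-ranks within block
    stat = _friedman_stat(ranks, tie_correction)
    if exact is None:
        exact = k == 3 and b <= 10
    if exact:
        p = _exact_friedman_sf(k, b)(stat)
    else:
        p = stats.chi2.sf(stat, df=k - 1)
    q, reject = bh_fdr(p, alpha)
    table = pd.DataFrame(
        {"statistic": stat, "df": k - 1, "p": p, "q": q, "reject": reject},
        index=values.index,
    )
    return FriedmanResult(table=table, factor=factor, block="|".join(block_cols), k=k, b=b, exact=bool(exact))


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjusted q-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def monotone_response_screen(
    values: pd.DataFrame,
    design: SampleDesign,
    variety: str,
) -> pd.DataFrame:
    """Per-feature monotone nitrogen-response report within one variety.

    Spearman rho of the replicate-mean ratio against the dose index; the
    ``linear`` flag marks a strictly monotone (|rho| = 1) response over the
    level means.  Constant features have undefined rho and are flagged
    non-responsive.
    """
    bio = design.biological_ids
    meta = design.samples.loc[bio]
    cols = [s for s in values.columns if s in set(bio) and meta.loc[s, "variety"] == variety]
    if not cols:
        raise ValueError(f"no biological samples for variety {variety!r}")
    dose = meta.loc[cols, "nitrogen"].astype(float)
    levels = sorted(dose.unique())
    if len(levels) < 3:
        raise ValueError("need >= 3 dose levels within the variety")
    means = np.column_stack(
        [values[[c for c in cols if dose[c] == lvl]].mean(axis=1) for lvl in levels]
    )
    idx = np.arange(len(levels))
    rho = np.full(len(values), np.nan)
    for i in range(len(values)):
        row = means[i]
        if np.ptp(row) == 0:
            continue
        rho[i] = stats.spearmanr(idx, row).statistic
    out = pd.DataFrame(
        {
            "spearman_rho": rho,
            "sign": np.sign(np.nan_to_num(rho)),
            "linear": np.abs(rho) > 1.0 - 1e-12,
            "responsive": ~np.isnan(rho),
        },
        index=values.index,
    )
    out.loc[np.isnan(rho), "linear"] = False
    return out


# ---------------------------------------------------------------------------
# consensus selection


@dataclass
class ConsensusParams:
    pca_top_frac: float = 0.01  # top |loading| fraction on the nitrogen PC
    asca_top_frac: float = 0.01
    pls_top_frac: float = 0.05  # best RFE-ranked fraction
    friedman_top_n: int = 100


@dataclass
class ConsensusSelection:
    table: pd.DataFrame  # feature x evidence flags, one row per kept feature
    dedup_map: dict  # dropped feature -> ion-group parent kept in its place

    @property
    def selected(self) -> pd.Index:
        return self.table.index


def _top_by_abs(series: pd.Series, frac: float) -> set:
    n = max(1, int(np.ceil(frac * len(series))))
    return set(series.abs().sort_values(ascending=False, kind="stable").index[:n])


def consensus_select(
    pca_loadings: pd.Series,
    asca_loadings: pd.Series,
    pls_ranks: pd.Series,
    friedman: FriedmanResult,
    group_parent: dict | None = None,
    params: ConsensusParams | None = None,
) -> ConsensusSelection:
    """Union the four evidence lists, then deduplicate by ion group.

    All four inputs must cover the same feature set.  ``group_parent`` maps
    satellite feature ids to their ion-group parent; when both a parent and
    its satellite are selected only the parent is retained (evidence flags
    are merged onto it).
    """
    params = params or ConsensusParams()
    idx = pca_loadings.index
    for other in (asca_loadings.index, pls_ranks.index, friedman.table.index):
        if not idx.sort_values().equals(other.sort_values()):
            raise ValueError("evidence inputs cover different feature sets")
    flags = pd.DataFrame(
        False,
        index=idx,
        columns=["pca_loading", "asca_loading", "pls_rank", "friedman_top"],
    )
    flags.loc[list(_top_by_abs(pca_loadings, params.pca_top_frac)), "pca_loading"] = True
    flags.loc[list(_top_by_abs(asca_loadings, params.asca_top_frac)), "asca_loading"] = True
    n_pls = max(1, int(np.ceil(params.pls_top_frac * len(idx))))
    pls_sel = pls_ranks.sort_values(kind="stable").index[:n_pls]
    flags.loc[pls_sel, "pls_rank"] = True
    flags.loc[friedman.top(params.friedman_top_n), "friedman_top"] = True

    selected = flags.index[flags.any(axis=1)]
    group_parent = group_parent or {}
    dedup: dict = {}
    keep_flags = flags.loc[selected].copy()
    for fid in list(selected):
        rep = group_parent.get(fid, fid)
        if rep != fid:
            dedup[fid] = rep
            if rep in keep_flags.index:
                keep_flags.loc[rep] |= keep_flags.loc[fid]
            else:
                row = keep_flags.loc[fid]
                keep_flags.loc[rep] = row
            keep_flags = keep_flags.drop(index=fid)
    return ConsensusSelection(table=keep_flags, dedup_map=dedup)
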