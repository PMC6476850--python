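"""Ion grouping, adduct/isotope role assignment, neutral-mass computation,
accurate-mass library matching, and redundant-ion collapse.

Co-eluting features whose intensity profiles are strongly correlated across
biological samples are taken to originate from one compound.  Grouping is
single-linkage over the graph whose edges join feature pairs with
``|dRT| <= rt_window`` seconds and Pearson r strictly greater than
``corr_min`` — the "moving RT window" read as a symmetric pairwise
constraint, which makes the grouping order-independent.

Within a group, pairwise m/z differences are matched against a rule table of
isotope/adduct mass deltas; the elected parent is the member from which the
most other members are explainable by a rule delta (ties broken by higher
summed intensity).  Neutral mass follows from the protonated/deprotonated
parent; library matching is by relative mass error (ppm); MSI confidence is
level 2 when a candidate was previously reported in oats, level 3 for
generic candidates, level 4 for unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import (
    PROTON_MASS,
    SECONDS_PER_MINUTE,
    AdductRuleSet,
    MetaboliteLibrary,
    SampleDesign,
)


@dataclass
class AnnotateParams:
    rt_window: float = 5.0  # seconds, +- around a feature
    corr_min: float = 0.8  # Pearson threshold (strict >)
    mz_abs_tol: float = 0.015  # Da
    ppm_tol: float = 5.0  # ppm
    proton_mass: float = PROTON_MASS

    def validate(self) -> None:
        if self.rt_window <= 0:
            raise ValueError("rt_window must be > 0")
        if not 0 < self.corr_min < 1:
            raise ValueError("corr_min must be in (0, 1)")
        if min(self.mz_abs_tol, self.ppm_tol) <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class IonGroup:
    group_id: str
    members: list
    roles: dict  # feature_id -> parent | isotope | adduct | in-source fragment | unassigned
    rule_matches: dict  # feature_id -> rule name
    parent: str | None = None
    neutral_mass: float | None = None


@dataclass
class Identification:
    group_id: str
    feature_id: str
    neutral_mass: float | None
    candidates: pd.DataFrame  # name, formula, monoisotopic_mass, oat_reported, ppm_error
    msi_level: int = 4
    oat_reported: bool = False


def _mz_match(delta: float, rule_delta: float, larger_mz: float, params: AnnotateParams) -> bool:
    """Pass if within EITHER the absolute Da tolerance OR the ppm tolerance."""
    err = abs(delta - rule_delta)
    return err <= params.mz_abs_tol or err <= params.ppm_tol * 1e-6 * larger_mz


def group_features(
    values: pd.DataFrame,
    rt_min: pd.Series,
    params: AnnotateParams | None = None,
    design: SampleDesign | None = None,
) -> list[list[str]]:
    """Single-linkage ion groups; returns lists of feature ids (incl. singletons).

    ``values`` is the ratio matrix; correlations are computed over biological
    samples only (pass ``design`` to restrict the columns — QA injections are
    near-constant replicates of the mean and would inflate r).  NaN cells
    (undetected peaks) are excluded pairwise, so imputation artefacts cannot
    bias the grouping; pairs with fewer than 3 co-detected samples and
    features with zero variance are never linked.
    """
    params = params or AnnotateParams()
    params.validate()
    if design is not None:
        cols = [c for c in values.columns if c in set(design.biological_ids)]
        values = values[cols]
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples to define correlations")
    fids = list(values.index)
    x = values.to_numpy(dtype=float)
    obs = np.isfinite(x)
    rt = rt_min.loc[fids].to_numpy(dtype=float)
    window_min = params.rt_window / SECONDS_PER_MINUTE
    close = np.abs(rt[:, None] - rt[None, :]) <= window_min
    n = len(fids)
    linked = np.zeros((n, n), dtype=bool)
    # pairwise-complete Pearson r, only for co-eluting candidate pairs;
    # undetected (NaN) cells are excluded rather than imputed so that
    # fill-in values cannot manufacture or destroy correlation
    ii, jj = np.nonzero(np.triu(close, k=1))
    for i, j in zip(ii, jj):
        m = obs[i] & obs[j]
        if m.sum() < 3:
            continue
        a, bvec = x[i, m], x[j, m]
        if a.std() == 0 or bvec.std() == 0:
            continue  # constant feature: correlation undefined, never linked
        r = np.corrcoef(a, bvec)[0, 1]
        if r > params.corr_min:
            linked[i, j] = linked[j, i] = True
    np.fill_diagonal(linked, True)
    n_comp, labels = connected_components(csr_matrix(linked), directed=False)
    groups = [[] for _ in range(n_comp)]
    for fid, lab in zip(fids, labels):
        groups[lab].append(fid)
    # deterministic order: by first member's position in the input
    groups.sort(key=lambda g: fids.index(g[0]))
    return groups


def assign_roles(
    members: list[str],
    mz: pd.Series,
    intensity: pd.Series,
    rules: AdductRuleSet,
    polarity: str,
    params: AnnotateParams | None = None,
    group_id: str = "G1",
) -> IonGroup:
    """Elect a parent and label isotope/adduct members by rule mass deltas.

    The parent is the member from which the largest number of other members
    are explainable as ``parent m/z + rule delta`` (within the absolute-Da /
    ppm tolerance of the larger m/z); ties break toward higher summed
    intensity.  Members matching no rule from the parent stay unassigned
    (possible in-source fragments).
    """
    params = params or AnnotateParams()
    params.validate()
    rule_df = rules.for_polarity(polarity)
    if len(members) == 1:
        return IonGroup(group_id, list(members), {members[0]: "parent"}, {}, members[0])
    mzs = mz.loc[members].to_numpy(dtype=float)
    best = (-1, -np.inf, None)
    for pi, p in enumerate(members):
        explained = 0
        for oi, o in enumerate(members):
            if o == p:
                continue
            d = mzs[oi] - mzs[pi]
            larger = max(mzs[oi], mzs[pi])
            if any(
                _mz_match(d, float(r["mass_delta"]), larger, params)
                for _, r in rule_df.iterrows()
            ):
                explained += 1
        score = (explained, float(intensity.loc[p]))
        if score > best[:2]:
            best = (explained, score[1], p)
    parent = best[2]
    roles, matches = {parent: "parent"}, {}
    p_mz = float(mz.loc[parent])
    for o in members:
        if o == parent:
            continue
        d = float(mz.loc[o]) - p_mz
        larger = max(float(mz.loc[o]), p_mz)
        hit = None
        for _, r in rule_df.iterrows():
            if _mz_match(d, float(r["mass_delta"]), larger, params):
                hit = r
                break
        if hit is not None:
            roles[o] = str(hit["role"])
            matches[o] = str(hit["name"])
        else:
            roles[o] = "unassigned"
    return IonGroup(group_id, list(members), roles, matches, parent)


def neutral_mass(mz: float, polarity: str, params: AnnotateParams | None = None) -> float:
    """Neutral mass of a protonated ([M+H]+) or deprotonated ([M-H]-) parent."""
    params = params or AnnotateParams()
    if polarity == "positive":
        return mz - params.proton_mass
    if polarity == "negative":
        return mz + params.proton_mass
    raise ValueError(f"unknown polarity {polarity!r}")


def match_library(
    neutral: float,
    library: MetaboliteLibrary,
    params: AnnotateParams | None = None,
    group_id: str = "G1",
    feature_id: str = "",
) -> Identification:
    """All library entries within ``ppm_tol`` relative error, ranked by |ppm|.

    MSI level: 2 if any oat-reported candidate, 3 if only generic
    candidates, 4 if none.
    """
    params = params or AnnotateParams()
    e = library.entries
    ppm = (neutral - e["monoisotopic_mass"]) / e["monoisotopic_mass"] * 1e6
    hits = e.loc[np.abs(ppm) <= params.ppm_tol].copy()
    hits["ppm_error"] = ppm[np.abs(ppm) <= params.ppm_tol]
    hits = hits.reindex(hits["ppm_error"].abs().sort_values(kind="stable").index)
    oat = bool(hits["oat_reported"].any()) if len(hits) else False
    level = 4 if hits.empty else (2 if oat else 3)
    return Identification(
        group_id=group_id,
        feature_id=feature_id,
        neutral_mass=neutral,
        candidates=hits.reset_index(drop=True),
        msi_level=level,
        oat_reported=oat,
    )


def collapse_redundant(groups: list[IonGroup], ratios: pd.DataFrame):
    """Keep one row per ion group (the parent; else the most intense member).

    Isotope/adduct/fragment rows are dropped; retained rows are unchanged.
    Returns ``(collapsed ratios, mapping dropped feature_id -> kept id)``.
    """
    keep, mapping = [], {}
    for g in groups:
        rep = g.parent
        if rep is None:
            totals = ratios.loc[g.members].sum(axis=1)
            rep = totals.idxmax()
        keep.append(rep)
        for m in g.members:
            if m != rep:
                mapping[m] = rep
    kept = [fid for fid in ratios.index if fid in set(keep)]
    return ratios.loc[kept], mapping


def annotate_table(
    ratios: pd.DataFrame,
    rt_min: pd.Series,
    mz: pd.Series,
    design: SampleDesign,
    rules: AdductRuleSet,
    library: MetaboliteLibrary,
    polarity: str,
    params: AnnotateParams | None = None,
):
    """Full annotation pass: group, assign roles, neutral mass, library match.

    Returns ``(groups, identifications, collapsed ratios, mapping)``.
    """
    params = params or AnnotateParams()
    member_lists = group_features(ratios, rt_min, params, design)
    intensity = ratios.sum(axis=1)
    groups, idents = [], []
    for k, members in enumerate(member_lists, start=1):
        g = assign_roles(members, mz, intensity, rules, polarity, params, f"G{k:04d}")
        if g.parent is not None:
            g.neutral_mass = neutral_mass(float(mz.loc[g.parent]), polarity, params)
            idents.append(
                match_library(g.neutral_mass, library, params, g.group_id, g.parent)
            )
        groups.append(g)
    collapsed, mapping = collapse_redundant(groups, ratios)
    return groups, idents, collapsed, mapping
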