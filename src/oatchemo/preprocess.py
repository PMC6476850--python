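"""Feature-table preprocessing: RT trimming, blank filtering, internal-standard
normalization, missing-value imputation, and the QA-repeatability (RSD) filter.

The chain is applied in a fixed order — trim -> blank filter -> IS
normalization -> imputation -> QA-RSD filter — matching the order in which a
deconvolved table is cleaned before chemometrics: retention-time and blank
filters act on raw areas (blanks have no meaningful internal-standard
context), normalization converts areas to IS ratios, the global 1/3-minimum
imputation fills undetected cells, and the repeatability filter excludes
features whose pooled-QA ratios vary by more than ``qa_rsd_max`` percent.

Boundary conventions (read literally from the filtering rules): a feature is
blank-dominant only if its blank maximum *strictly exceeds* ``blank_factor``
times its biological maximum, and the RSD filter removes only features
*strictly above* the cut-off.  RSD uses the sample (n-1) standard deviation.
Column-conditioning QA injections are excluded from the RSD computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleDesign
from .simulate import IS_FEATURES


@dataclass
class PreprocessParams:
    void_cutoff: float = 0.3  # minutes
    tail_cutoff: float = 4.0  # minutes trimmed from the end of the run
    run_length: float = 15.0  # minutes
    blank_factor: float = 2.0
    is_feature_id: str | None = None  # default: polarity-specific IS feature
    impute_fraction: float = 1.0 / 3.0
    qa_rsd_max: float = 25.0  # percent
    rsd_on_ratios: bool = True  # compute QA RSD on IS ratios (textual order)

    def validate(self) -> None:
        if not 0 <= self.void_cutoff < self.run_length - self.tail_cutoff:
            raise ValueError("need 0 <= void_cutoff < run_length - tail_cutoff")
        if self.blank_factor <= 0:
            raise ValueError("blank_factor must be > 0")
        if not 0 < self.impute_fraction <= 1:
            raise ValueError("impute_fraction must be in (0, 1]")
        if self.qa_rsd_max <= 0:
            raise ValueError("qa_rsd_max must be > 0")

    def resolve_is_feature(self, polarity: str) -> str:
        return self.is_feature_id or IS_FEATURES[polarity][0]


@dataclass
class NormalizedMatrix:
    """Analysis-ready IS-ratio matrix plus a removal provenance log.

    ``ratios``: features x (biological + QA) samples, no missing values,
    all entries > 0.  ``removal_log``: one row per removed feature with the
    step and reason.  ``rsd``: per-feature QA RSD (percent) for every
    feature that reached the RSD step.
    """

    ratios: pd.DataFrame
    removal_log: pd.DataFrame
    rsd: pd.Series
    #: same rows as ``ratios`` but with missing cells left as NaN — used by
    #: the ion-grouping step, whose correlations exclude undetected cells
    ratios_unimputed: pd.DataFrame | None = None


def _log_removals(log: list, ids, step: str, detail=None) -> None:
    for fid in ids:
        log.append({"feature_id": fid, "reason": step, "detail": detail})


def trim_rt(table: FeatureTable, params: PreprocessParams, log: list | None = None) -> FeatureTable:
    """Drop features eluting in the void or re-equilibration windows.

    Retains ``void_cutoff <= rt <= run_length - tail_cutoff``.
    """
    params.validate()
    rt = table.features["rt_min"]
    keep = (rt >= params.void_cutoff) & (rt <= params.run_length - params.tail_cutoff)
    if log is not None:
        _log_removals(log, table.feature_ids[rt < params.void_cutoff], "void")
        _log_removals(
            log, table.feature_ids[rt > params.run_length - params.tail_cutoff], "tail"
        )
    return table.subset(table.feature_ids[keep])


def blank_filter(
    table: FeatureTable,
    design: SampleDesign,
    params: PreprocessParams,
    log: list | None = None,
) -> FeatureTable:
    """Remove features dominant in blanks.

    A feature is removed iff its maximum raw area over blank injections
    strictly exceeds ``blank_factor`` times its maximum over biological
    samples (missing cells count as zero).  Without blank injections the
    table passes through with a warning.
    """
    blanks = design.blank_ids
    if len(blanks) == 0:
        warnings.warn("no blank samples in design; blank filter skipped")
        return table
    bio = design.biological_ids
    blank_max = table.areas[blanks].fillna(0.0).max(axis=1)
    bio_max = table.areas[bio].fillna(0.0).max(axis=1)
    dominant = blank_max > params.blank_factor * bio_max
    if log is not None:
        _log_removals(log, table.feature_ids[dominant], "blank_dominant")
    return table.subset(table.feature_ids[~dominant])


def normalize_is(
    table: FeatureTable,
    design: SampleDesign,
    params: PreprocessParams,
    log: list | None = None,
) -> pd.DataFrame:
    """Divide every biological/QA cell by that sample's internal-standard area.

    Returns the ratio matrix over biological + QA columns with the IS row
    removed from the analyte set.  Raises if the IS is missing or zero in
    any biological/QA sample (naming the sample).
    """
    is_id = params.resolve_is_feature(table.polarity)
    if is_id not in table.feature_ids:
        raise ValueError(f"internal-standard feature {is_id!r} not in table")
    cols = list(design.biological_ids) + list(design.qa_ids(include_conditioning=True))
    is_row = table.areas.loc[is_id, cols]
    bad = [s for s in cols if not np.isfinite(is_row[s]) or is_row[s] <= 0]
    if bad:
        raise ValueError(f"internal standard missing or zero in samples: {bad}")
    ratios = table.areas[cols].drop(index=is_id).div(is_row, axis=1)
    if log is not None:
        _log_removals(log, [is_id], "is_feature")
    return ratios


def impute_missing(ratios: pd.DataFrame, params: PreprocessParams) -> pd.DataFrame:
    """Replace missing cells by ``impute_fraction`` x the global minimum ratio."""
    vals = ratios.to_numpy(dtype=float)
    if np.isnan(vals).all():
        raise ValueError("cannot impute an all-missing matrix")
    fill = params.impute_fraction * np.nanmin(vals)
    return ratios.fillna(fill)


def qa_rsd(ratios: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """Percent RSD (100 * sd / mean, ddof=1) across non-conditioning QA columns."""
    qa = [s for s in design.qa_ids() if s in ratios.columns]
    if len(qa) < 2:
        raise ValueError("need at least 2 (non-conditioning) QA samples for RSD")
    sub = ratios[qa]
    return 100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1)


def qa_rsd_filter(
    ratios: pd.DataFrame,
    design: SampleDesign,
    params: PreprocessParams,
    log: list | None = None,
):
    """Drop features whose QA RSD strictly exceeds ``qa_rsd_max`` percent.

    Returns ``(filtered ratios, per-feature RSD report)``.
    """
    rsd = qa_rsd(ratios, design)
    drop = rsd > params.qa_rsd_max
    if log is not None:
        for fid in ratios.index[drop]:
            log.append(
                {"feature_id": fid, "reason": "qa_rsd", "detail": float(rsd[fid])}
            )
    return ratios.loc[~drop], rsd


def preprocess(
    table: FeatureTable,
    design: SampleDesign,
    params: PreprocessParams | None = None,
) -> NormalizedMatrix:
    """Run the full chain: trim -> blank -> normalize -> impute -> QA RSD."""
    params = params or PreprocessParams()
    params.validate()
    design.check_against(table)
    log: list = []
    t = trim_rt(table, params, log)
    t = blank_filter(t, design, params, log)
    ratios = normalize_is(t, design, params, log)
    raw_ratios = ratios
    if params.rsd_on_ratios:
        ratios = impute_missing(ratios, params)
        ratios, rsd = qa_rsd_filter(ratios, design, params, log)
    else:
        # variant: RSD on raw areas before normalization
        raw = t.areas[ratios.columns].drop(index=params.resolve_is_feature(t.polarity))
        rsd_raw = qa_rsd(raw, design)
        drop = rsd_raw > params.qa_rsd_max
        for fid in raw.index[drop]:
            log.append({"feature_id": fid, "reason": "qa_rsd", "detail": float(rsd_raw[fid])})
        ratios = impute_missing(ratios.loc[~drop], params)
        rsd = rsd_raw
    return NormalizedMatrix(
        ratios=ratios,
        removal_log=pd.DataFrame(log, columns=["feature_id", "reason", "detail"]),
        rsd=rsd,
        ratios_unimputed=raw_ratios.loc[ratios.index],
    )


def log10_transform(ratios: pd.DataFrame) -> pd.DataFrame:
    """log10 of an all-positive ratio matrix (variance stabilisation for
    multiplicative noise); the chemometric models mean-center internally."""
    vals = ratios.to_numpy(dtype=float)
    if (vals <= 0).any() or np.isnan(vals).any():
        raise ValueError("log transform requires a fully observed, positive matrix")
    return np.log10(ratios)
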