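"""Readers, writers and validated containers for feature tables and metadata.

The central object is the :class:`FeatureTable`: an XCMS-style deconvolved
peak table whose rows are RT–m/z pairs and whose columns are injections
(biological plots, pooled-QA injections, and blanks).  Retention times are
stored in **minutes** throughout; the ±5 s ion-grouping window used elsewhere
is converted centrally (:data:`SECONDS_PER_MINUTE`) to avoid unit bugs.

Missing peak areas are encoded as NaN (empty CSV cells), never as zero —
zero is a legal measured area, and the downstream imputation rule
distinguishes the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

SECONDS_PER_MINUTE = 60.0

#: Mass of a proton in Da, used for [M+H]+/[M-H]- neutral-mass arithmetic.
PROTON_MASS = 1.007276

ROLES = ("biological", "QA", "blank")


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


# ---------------------------------------------------------------------------
# formula mass


def formula_mass(formula: str) -> float:
    """Monoisotopic neutral mass (Da) of an elemental formula.

    Standard atomic masses via pyteomics.  The empty formula has mass 0.
    Raises ``ValueError`` for an unparseable formula or unknown element.
    """
    if not formula:
        return 0.0
    try:
        return float(_ptmass.calculate_mass(formula=formula))
    except Exception as exc:  # pyteomics raises its own error type
        raise ValueError(f"cannot compute mass of formula {formula!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureTable:
    """Deconvolved peak-area matrix indexed by feature.

    Parameters
    ----------
    features
        DataFrame indexed by ``feature_id`` with columns ``rt_min`` (retention
        time, minutes) and ``mz``.
    areas
        DataFrame of non-negative peak areas, same index as ``features``,
        one column per sample; NaN marks a missing (undetected) peak.
    polarity
        ``"positive"`` or ``"negative"`` electrospray mode.
    """

    features: pd.DataFrame
    areas: pd.DataFrame
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.features.index.name = "feature_id"
        self.areas.index.name = "feature_id"
        self.areas.columns.name = None
        self.validate()

    def validate(self) -> None:
        f, a = self.features, self.areas
        for col in ("rt_min", "mz"):
            if col not in f.columns:
                raise SchemaError(f"feature metadata lacks column {col!r}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dups}")
        if a.columns.has_duplicates:
            dups = a.columns[a.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        if not f.index.equals(a.index):
            raise SchemaError("feature metadata and area matrix indices differ")
        if (f["rt_min"] < 0).any():
            bad = f.index[f["rt_min"] < 0].tolist()
            raise SchemaError(f"negative retention times for features: {bad}")
        if (f["mz"] <= 0).any():
            bad = f.index[f["mz"] <= 0].tolist()
            raise SchemaError(f"non-positive m/z for features: {bad}")
        vals = a.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise SchemaError("negative peak areas present")
        if self.polarity not in ("positive", "negative"):
            raise SchemaError(f"unknown polarity {self.polarity!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.areas.columns

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.features.loc[feature_ids], self.areas.loc[feature_ids], self.polarity
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.areas.copy(), self.polarity)


@dataclass
class SampleDesign:
    """Per-injection metadata for the split-plot field design.

    ``samples`` is indexed by sample id with columns:

    - ``role``: biological / QA / blank
    - ``variety``: oat variety (biological only)
    - ``nitrogen``: applied dose in kg N ha^-1 (biological only)
    - ``replicate``: field replicate / block index (biological only)
    - ``conditioning``: True for the initial column-conditioning QA
      injections, which are excluded from repeatability statistics.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.samples
        for col in ("role",):
            if col not in s.columns:
                raise SchemaError("design lacks a 'role' column")
        if "conditioning" not in s.columns:
            s["conditioning"] = False
        s["conditioning"] = s["conditioning"].fillna(False).astype(bool)
        if s.index.has_duplicates:
            raise SchemaError("duplicate sample ids in design")
        bad_roles = sorted(set(s["role"]) - set(ROLES))
        if bad_roles:
            raise SchemaError(f"unknown sample roles: {bad_roles}")
        bio = s["role"] == "biological"
        for col in ("variety", "nitrogen", "replicate"):
            if col not in s.columns:
                raise SchemaError(f"design lacks column {col!r}")
            if s.loc[bio, col].isna().any():
                missing = s.index[bio & s[col].isna()].tolist()
                raise SchemaError(f"biological samples missing {col!r}: {missing}")
        nonbio = ~bio
        if nonbio.any():
            # design factors are defined iff the sample is biological
            defined = s.loc[nonbio, ["variety"]].notna().any(axis=1)
            if defined.any():
                raise SchemaError(
                    "variety defined for non-biological samples: "
                    f"{s.index[nonbio][defined].tolist()}"
                )

    @property
    def biological_ids(self) -> pd.Index:
        return self.samples.index[self.samples["role"] == "biological"]

    def qa_ids(self, include_conditioning: bool = False) -> pd.Index:
        m = self.samples["role"] == "QA"
        if not include_conditioning:
            m &= ~self.samples["conditioning"]
        return self.samples.index[m]

    @property
    def blank_ids(self) -> pd.Index:
        return self.samples.index[self.samples["role"] == "blank"]

    @property
    def varieties(self) -> list:
        v = self.samples.loc[self.biological_ids, "variety"]
        return sorted(v.unique().tolist())

    @property
    def nitrogen_levels(self) -> list:
        n = self.samples.loc[self.biological_ids, "nitrogen"]
        return sorted(float(x) for x in n.unique())

    def dose_index(self) -> pd.Series:
        """0-based nitrogen level index per biological sample."""
        levels = {lvl: i for i, lvl in enumerate(self.nitrogen_levels)}
        n = self.samples.loc[self.biological_ids, "nitrogen"].astype(float)
        return n.map(levels).astype(int)

    def check_against(self, table: FeatureTable) -> None:
        """Every designed sample must exist in the table and vice versa."""
        missing = [s for s in self.samples.index if s not in table.sample_ids]
        extra = [s for s in table.sample_ids if s not in self.samples.index]
        if missing:
            raise SchemaError(f"design samples absent from feature table: {missing}")
        if extra:
            raise SchemaError(f"table samples absent from design: {extra}")


@dataclass
class AdductRuleSet:
    """Accurate-mass difference rules relative to the reference ion.

    ``rules`` has columns ``name``, ``mass_delta`` (Da relative to [M+H]+
    or [M-H]- of the same polarity), ``role`` (adduct / isotope /
    in-source fragment) and ``polarity``.
    """

    rules: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.rules
        for col in ("name", "mass_delta", "role", "polarity"):
            if col not in r.columns:
                raise SchemaError(f"rules lack column {col!r}")
        if not np.isfinite(r["mass_delta"].to_numpy(dtype=float)).all():
            raise SchemaError("non-finite mass delta in rules")
        dup = r.duplicated(subset=["name", "polarity"])
        if dup.any():
            raise SchemaError(f"duplicate rule names: {r.loc[dup, 'name'].tolist()}")

    def for_polarity(self, polarity: str) -> pd.DataFrame:
        return self.rules[self.rules["polarity"] == polarity].reset_index(drop=True)


def default_rules() -> AdductRuleSet:
    """Common isotope/adduct mass-difference rules for both ESI polarities.

    Deltas are relative to the protonated/deprotonated reference ion and
    derived from standard monoisotopic atomic masses.
    """
    c13 = 1.003355  # 13C - 12C
    rows = [
        ("13C isotope", c13, "isotope", "positive"),
        ("[M+Na]+", formula_mass("Na") - formula_mass("H"), "adduct", "positive"),
        ("[M+NH4]+", formula_mass("NH4") - formula_mass("H"), "adduct", "positive"),
        ("[M+K]+", formula_mass("K") - formula_mass("H"), "adduct", "positive"),
        ("13C isotope", c13, "isotope", "negative"),
        ("[M+Cl]-", formula_mass("Cl") + formula_mass("H"), "adduct", "negative"),
        ("[M+HCOO]-", formula_mass("CH2O2"), "adduct", "negative"),
    ]
    return AdductRuleSet(
        pd.DataFrame(rows, columns=["name", "mass_delta", "role", "polarity"])
    )


@dataclass
class MetaboliteLibrary:
    """Accurate-mass metabolite library used for putative identification.

    ``entries`` has columns ``name``, ``formula``, ``monoisotopic_mass``
    (Da) and ``oat_reported`` (bool: previously reported in oats, the
    confidence flag that promotes a match to MSI level 2).
    """

    entries: pd.DataFrame
    mass_check_tol: float = 1e-4

    def __post_init__(self) -> None:
        e = self.entries
        for col in ("name", "formula", "monoisotopic_mass"):
            if col not in e.columns:
                raise SchemaError(f"library lacks column {col!r}")
        if "oat_reported" not in e.columns:
            e["oat_reported"] = False
        e["oat_reported"] = e["oat_reported"].astype(bool)
        if (e["monoisotopic_mass"] <= 0).any():
            raise SchemaError("non-positive monoisotopic mass in library")
        for i, row in e.iterrows():
            recomputed = formula_mass(str(row["formula"]))
            if abs(recomputed - float(row["monoisotopic_mass"])) > self.mass_check_tol:
                raise SchemaError(
                    f"library row {i} ({row['name']}): stated mass "
                    f"{row['monoisotopic_mass']} disagrees with formula mass "
                    f"{recomputed:.6f}"
                )


def toy_library() -> MetaboliteLibrary:
    """Small built-in library: internal standards plus a few oat metabolites."""
    rows = [
        ("reserpine", "C33H40N2O9", 608.273381, False),
        ("morin", "C15H10O7", 302.042653, False),
        ("tryptophan", "C11H12N2O2", 204.089878, True),
        ("phenylalanine", "C9H11NO2", 165.078979, True),
        ("citric acid", "C6H8O7", 192.027003, True),
        ("malic acid", "C4H6O5", 134.021523, True),
        ("caffeic acid", "C9H8O4", 180.042259, True),
        ("glutathione", "C10H17N3O6S", 307.083806, True),
    ]
    return MetaboliteLibrary(
        pd.DataFrame(
            rows, columns=["name", "formula", "monoisotopic_mass", "oat_reported"]
        )
    )


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(df: pd.DataFrame, cols, what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} {path}: missing columns {missing}")


def read_feature_table(path, polarity: str = "positive") -> FeatureTable:
    """Read a feature table CSV: feature_id, rt_min, mz, then sample columns."""
    df = pd.read_csv(path)
    _require_columns(df, ["feature_id", "rt_min", "mz"], "feature table", path)
    dup = df["feature_id"].duplicated()
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"feature table {path}: duplicate feature_id at rows {rows}")
    df = df.set_index("feature_id")
    features = df[["rt_min", "mz"]].astype(float)
    areas = df.drop(columns=["rt_min", "mz"]).astype(float)
    neg = areas.lt(0)
    if neg.any().any():
        rows = sorted({areas.index.get_loc(i) + 2 for i in areas.index[neg.any(axis=1)]})
        raise SchemaError(f"feature table {path}: negative areas at rows {rows}")
    return FeatureTable(features, areas, polarity)


def write_feature_table(table: FeatureTable, path) -> None:
    out = pd.concat([table.features, table.areas], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "role"], "design table", path)
    if df["sample_id"].duplicated().any():
        rows = (df.index[df["sample_id"].duplicated()] + 2).tolist()
        raise SchemaError(f"design {path}: duplicate sample_id at rows {rows}")
    df = df.set_index("sample_id")
    for col in ("variety", "nitrogen", "replicate", "conditioning"):
        if col not in df.columns:
            df[col] = np.nan
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    out = design.samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_rules(path) -> AdductRuleSet:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "mass_delta", "role", "polarity"], "rules", path)
    return AdductRuleSet(df)


def write_rules(rules: AdductRuleSet, path) -> None:
    rules.rules.to_csv(path, index=False)


def read_library(path) -> MetaboliteLibrary:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "formula", "monoisotopic_mass"], "library", path)
    return MetaboliteLibrary(df)


def write_library(library: MetaboliteLibrary, path) -> None:
    library.entries.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
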