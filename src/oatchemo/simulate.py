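"""Synthetic UHPLC-MS feature tables emulating the oat nitrogen field trial.

The generator produces an XCMS-style deconvolved peak table for a split-plot
experiment: ``n_varieties`` oat varieties (sub-plot factor) crossed with
increasing nitrogen doses (main-plot factor) in ``n_reps`` field replicates,
plus pooled-QA injections, blank injections, an internal-standard feature,
and correlated adduct/isotope satellite features.

Signal model (natural-log scale, multiplicative on the area scale)::

    log area[f, s] = baseline_f
                   + variety_offset[f, variety(s)]
                   + nitrogen_slope_f * dose_index(s)
                   + eps,   eps ~ N(0, sigma^2),  sigma = sqrt(log(1 + cv^2))

so measurement noise has a constant coefficient of variation ``noise_cv`` —
the assumption underlying RSD-based QC.  With ``noise_cv -> 0`` the log
matrix is exactly additive in grand mean + variety effect + nitrogen effect,
which feeds the ASCA decomposition identity tests.

QA cells are the arithmetic mean of the feature's biological areas perturbed
by the same multiplicative noise (a pooled extract of every sample).
Satellites are a fixed multiple of their parent's per-sample area (plus a
small noise) at the rule-shifted m/z within +-2 s of the parent RT, so
parent-satellite Pearson correlations are high by construction and
satellites inherit the parent's biological effects.  Missingness is
censoring-like: low-intensity cells are more likely to be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    FeatureTable,
    SampleDesign,
    SchemaError,
    default_rules,
    read_design,
    read_feature_table,
    read_json,
    write_design,
    write_feature_table,
    write_json,
)

DEFAULT_VARIETIES = ("Gerald", "Mascani", "Tardis", "Balado")

#: Internal-standard identity per polarity: (feature id, m/z of the IS ion, RT min).
IS_FEATURES = {
    "positive": ("IS_reserpine_pos", 609.280657, 6.0),  # reserpine [M+H]+
    "negative": ("IS_morin_neg", 301.035377, 5.0),  # morin [M-H]-
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic trial.

    Defaults mirror the field design: 4 winter oat varieties x 5 nitrogen
    doses (0..200 kg N ha^-1) x 3 replicates = 60 biological samples.
    ``similar_variety_pair`` indexes two varieties whose discriminant
    offsets are strongly correlated (a near-identical metabolic phenotype,
    like Mascani/Tardis); ``similar_pair_scale`` is the residual relative
    difference between them.
    """

    n_varieties: int = 4
    nitrogen_levels: tuple = (0.0, 50.0, 100.0, 150.0, 200.0)
    n_reps: int = 3
    n_features: int = 500
    frac_nitrogen_responsive: float = 0.10
    frac_variety_discriminant: float = 0.10
    similar_variety_pair: tuple = (1, 2)
    similar_pair_scale: float = 0.4
    effect_size_nitrogen: float = 0.6  # log-scale slope per dose-index step
    effect_size_variety: float = 0.8  # log-scale sd of variety offsets
    noise_cv: float = 0.15
    missing_rate: float = 0.02
    n_qa: int = 8
    n_conditioning_qa: int = 0
    n_blanks: int = 2
    frac_blank_contaminants: float = 0.02
    adduct_satellite_rate: float = 0.20
    is_area_mean: float = 1.0e6
    polarity: str = "positive"
    rt_range: tuple = (0.5, 10.5)
    mz_range: tuple = (120.0, 1000.0)
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_varieties, self.n_reps, self.n_features) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_qa < 2:
            raise ValueError("need at least 2 QA injections for RSD filtering")
        levels = tuple(self.nitrogen_levels)
        if len(levels) < 2 or any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("nitrogen_levels must be strictly increasing")
        for name in (
            "frac_nitrogen_responsive",
            "frac_variety_discriminant",
            "missing_rate",
            "frac_blank_contaminants",
            "adduct_satellite_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        p = self.similar_variety_pair
        if p is not None and (
            len(p) != 2 or not all(0 <= i < self.n_varieties for i in p) or p[0] == p[1]
        ):
            raise ValueError("similar_variety_pair must be two distinct variety indices")
        if self.polarity not in IS_FEATURES:
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class GroundTruth:
    """Per-feature generative parameters and labels for recovery tests.

    ``features`` is indexed by feature_id with columns:

    - ``baseline_log``: natural-log baseline intensity
    - ``nitrogen_responsive`` (bool) and ``nitrogen_slope`` (ln units per
      dose-index step)
    - ``variety_discriminant`` (bool)
    - ``blank_contaminant`` (bool)
    - ``satellite_of``: parent feature id ('' for base features) and
      ``satellite_rule``: the mass-difference rule name
    - ``satellite_factor``: area multiple relative to the parent
    - ``is_internal_standard`` (bool)

    ``variety_offsets`` holds the ln-scale variety effects (features x
    varieties).  ``expected_log_matrix`` reconstructs the noise-free
    biological log matrix from these parameters.
    """

    features: pd.DataFrame
    variety_offsets: pd.DataFrame

    def __post_init__(self) -> None:
        self.features.index.name = "feature_id"
        self.variety_offsets.index.name = "feature_id"

    def validate(self) -> None:
        sat = self.features["satellite_of"]
        parents = sat[sat != ""]
        dangling = sorted(set(parents) - set(self.features.index))
        if dangling:
            raise SchemaError(f"satellite parents not in feature set: {dangling}")

    @property
    def nitrogen_responsive_ids(self) -> pd.Index:
        return self.features.index[self.features["nitrogen_responsive"]]

    @property
    def variety_discriminant_ids(self) -> pd.Index:
        return self.features.index[self.features["variety_discriminant"]]

    @property
    def blank_contaminant_ids(self) -> pd.Index:
        return self.features.index[self.features["blank_contaminant"]]

    @property
    def satellite_ids(self) -> pd.Index:
        return self.features.index[self.features["satellite_of"] != ""]

    @property
    def parent_of(self) -> dict:
        sat = self.features["satellite_of"]
        return {fid: p for fid, p in sat.items() if p != ""}

    def expected_log_matrix(self, design: SampleDesign) -> pd.DataFrame:
        """Noise-free ln-areas of biological samples (features x samples)."""
        bio = design.biological_ids
        dose_idx = design.dose_index()
        variety = design.samples.loc[bio, "variety"]
        base = self.features["baseline_log"].to_numpy()[:, None]
        slope = self.features["nitrogen_slope"].to_numpy()[:, None]
        voff = self.variety_offsets.loc[self.features.index, variety].to_numpy()
        out = base + voff + slope * dose_idx.loc[bio].to_numpy()[None, :]
        return pd.DataFrame(out, index=self.features.index, columns=bio)


def _lognoise_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def preprocess_demo_table():
    """Hand-constructed 20-feature table exercising every filtering rule.

    Returns ``(FeatureTable, SampleDesign, expected_retained_ids)``: RT-trim
    boundaries at 0.3 / 11.0 min, the strict 2x blank-dominance rule, QA-RSD
    boundaries at exactly 25%, a missing cell for the 1/3-minimum imputation
    (global minimum ratio 0.09 -> fill 0.03), and the internal standard.
    """
    bio, qa, blank = ["b1", "b2"], ["q1", "q2", "q3"], ["k1"]
    samples = bio + qa + blank
    n = np.nan
    rows = [
        # feature_id, rt, mz, [b1, b2, q1, q2, q3, k1]
        ("f01_void", 0.2, 150.0, [500, 500, 500, 500, 500, n]),  # rt < 0.3
        ("f02_edge_lo", 0.3, 151.0, [500, 500, 500, 500, 500, n]),  # kept
        ("f03_edge_hi", 11.0, 152.0, [500, 500, 500, 500, 500, n]),  # kept
        ("f04_tail", 11.5, 153.0, [500, 500, 500, 500, 500, n]),  # rt > 11.0
        ("f05_blank_dom", 5.0, 154.0, [2000, 1500, 1800, 1800, 1800, 5000]),  # > 2x
        ("f06_blank_edge", 5.0, 155.0, [2000, 1500, 1800, 1800, 1800, 4000]),  # = 2x kept
        ("f07_no_blank", 5.0, 156.0, [2000, 1500, 1800, 1800, 1800, n]),  # kept
        ("f08_rsd_high", 5.0, 157.0, [1500, 1500, 1000, 2000, 3000], ),  # RSD 50%
        ("f09_rsd_edge", 5.0, 158.0, [1000, 1000, 750, 1000, 1250]),  # RSD 25% kept
        ("f10_rsd_zero", 5.0, 159.0, [1000, 1000, 1000, 1000, 1000]),  # kept
        ("f11_missing", 5.0, 160.0, [90, n, 90, 90, 90]),  # min ratio 0.09
        ("f12", 4.0, 161.0, [800, 900, 850, 850, 850]),
        ("f13", 4.1, 162.0, [800, 900, 850, 850, 850]),
        ("f14", 4.2, 163.0, [800, 900, 850, 850, 850]),
        ("f15", 4.3, 164.0, [800, 900, 850, 850, 850]),
        ("f16", 4.4, 165.0, [800, 900, 850, 850, 850]),
        ("f17", 4.5, 166.0, [800, 900, 850, 850, 850]),
        ("f18", 4.6, 167.0, [800, 900, 850, 850, 850]),
        ("f19", 4.7, 168.0, [800, 900, 850, 850, 850]),
        (IS_FEATURES["positive"][0], 6.0, IS_FEATURES["positive"][1],
         [1000, 1000, 1000, 1000, 1000]),
    ]
    fids = [r[0] for r in rows]
    areas = []
    for r in rows:
        vals = list(r[3])
        if len(vals) == 5:  # no blank signal recorded
            vals = vals + [n]
        areas.append(vals)
    features = pd.DataFrame(
        {"rt_min": [r[1] for r in rows], "mz": [r[2] for r in rows]}, index=fids
    )
    table = FeatureTable(
        features, pd.DataFrame(areas, index=fids, columns=samples, dtype=float)
    )
    drows = [("b1", "biological", "Gerald", 0.0, 1, False),
             ("b2", "biological", "Mascani", 50.0, 1, False)]
    drows += [(q, "QA", np.nan, np.nan, np.nan, False) for q in qa]
    drows += [(k, "blank", np.nan, np.nan, np.nan, False) for k in blank]
    design = SampleDesign(
        pd.DataFrame(
            drows,
            columns=["sample_id", "role", "variety", "nitrogen", "replicate", "conditioning"],
        ).set_index("sample_id")
    )
    expected = [
        "f02_edge_lo", "f03_edge_hi", "f06_blank_edge", "f07_no_blank",
        "f09_rsd_edge", "f10_rsd_zero", "f11_missing",
        "f12", "f13", "f14", "f15", "f16", "f17", "f18", "f19",
    ]
    return table, design, expected


def simulate_experiment(config: SimulationConfig):
    """Generate ``(FeatureTable, SampleDesign, GroundTruth)`` for one polarity.

    Deterministic for a fixed ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    varieties = (
        list(DEFAULT_VARIETIES[: config.n_varieties])
        if config.n_varieties <= len(DEFAULT_VARIETIES)
        else [f"V{i + 1}" for i in range(config.n_varieties)]
    )
    levels = [float(x) for x in config.nitrogen_levels]
    n_lvl = len(levels)
    sigma = _lognoise_sigma(config.noise_cv)

    # ---- sample design -------------------------------------------------
    rows = []
    for r in range(1, config.n_reps + 1):
        for li, lvl in enumerate(levels):
            for v in varieties:
                sid = f"bio_{v}_N{li}_r{r}"
                rows.append((sid, "biological", v, lvl, r, False))
    for q in range(1, config.n_conditioning_qa + 1):
        rows.append((f"qa_cond_{q:02d}", "QA", np.nan, np.nan, np.nan, True))
    for q in range(1, config.n_qa + 1):
        rows.append((f"qa_{q:02d}", "QA", np.nan, np.nan, np.nan, False))
    for b in range(1, config.n_blanks + 1):
        rows.append((f"blank_{b}", "blank", np.nan, np.nan, np.nan, False))
    design = SampleDesign(
        pd.DataFrame(
            rows,
            columns=["sample_id", "role", "variety", "nitrogen", "replicate", "conditioning"],
        ).set_index("sample_id")
    )
    bio = design.biological_ids
    dose_idx = design.dose_index().loc[bio].to_numpy()
    sample_variety = design.samples.loc[bio, "variety"].to_numpy()

    # ---- base (parent) features ----------------------------------------
    n = config.n_features
    fids = [f"F{i + 1:04d}" for i in range(n)]
    rt = rng.uniform(*config.rt_range, size=n)
    mz = rng.uniform(*config.mz_range, size=n)
    baseline = rng.normal(np.log(1.0e5), 1.0, size=n)

    n_resp = int(round(config.frac_nitrogen_responsive * n))
    n_disc = int(round(config.frac_variety_discriminant * n))
    perm = rng.permutation(n)
    resp_ix = perm[:n_resp]
    disc_ix = perm[n_resp : n_resp + n_disc]
    slope = np.zeros(n)
    slope[resp_ix] = config.effect_size_nitrogen * rng.choice([-1.0, 1.0], size=n_resp)

    voff = np.zeros((n, config.n_varieties))
    z = rng.normal(size=(n_disc, config.n_varieties))
    if config.similar_variety_pair is not None and config.effect_size_variety > 0:
        i, j = config.similar_variety_pair
        z[:, j] = z[:, i] + config.similar_pair_scale * rng.normal(size=n_disc)
    voff[disc_ix] = config.effect_size_variety * z
    # zero-mean offsets over varieties: pure variety contrast, no baseline shift
    voff[disc_ix] -= voff[disc_ix].mean(axis=1, keepdims=True)

    n_cont = int(round(config.frac_blank_contaminants * n))
    cont_ix = perm[n_resp + n_disc : n_resp + n_disc + n_cont]
    contaminant = np.zeros(n, dtype=bool)
    contaminant[cont_ix] = True

    var_col_idx = {v: k for k, v in enumerate(varieties)}
    voff_per_sample = voff[:, [var_col_idx[v] for v in sample_variety]]
    log_bio = (
        baseline[:, None]
        + voff_per_sample
        + slope[:, None] * dose_idx[None, :]
        + sigma * rng.standard_normal((n, bio.size))
    )
    areas_bio = np.exp(log_bio)

    # ---- satellites -----------------------------------------------------
    rules = default_rules().for_polarity(config.polarity)
    n_sat_parents = int(round(config.adduct_satellite_rate * n))
    sat_parent_ix = rng.choice(n, size=n_sat_parents, replace=False)
    sat_rows = []
    sat_areas = []
    for k, pix in enumerate(sorted(sat_parent_ix)):
        rule = rules.iloc[rng.integers(len(rules))]
        factor = rng.uniform(0.1, 0.5)
        jitter = rng.uniform(-2.0, 2.0) / 60.0  # within +-2 s of the parent
        sat_noise = (sigma / 4.0) * rng.standard_normal(bio.size)
        sat_rows.append(
            dict(
                fid=f"S{k + 1:04d}",
                parent=fids[pix],
                rule=str(rule["name"]),
                factor=factor,
                rt=rt[pix] + jitter,
                mz=mz[pix] + float(rule["mass_delta"]),
            )
        )
        sat_areas.append(areas_bio[pix] * factor * np.exp(sat_noise))
    sat_areas = np.asarray(sat_areas) if sat_rows else np.empty((0, bio.size))

    # ---- assemble full matrix -------------------------------------------
    all_fids = fids + [s["fid"] for s in sat_rows]
    all_rt = np.concatenate([rt, [s["rt"] for s in sat_rows]])
    all_mz = np.concatenate([mz, [s["mz"] for s in sat_rows]])
    bio_mat = np.vstack([areas_bio, sat_areas]) if len(sat_rows) else areas_bio
    n_all = len(all_fids)

    # QA: arithmetic mean of biological areas, perturbed by noise_cv
    n_qa_tot = config.n_conditioning_qa + config.n_qa
    qa_mean = bio_mat.mean(axis=1, keepdims=True)
    qa_mat = qa_mean * np.exp(sigma * rng.standard_normal((n_all, n_qa_tot)))

    # blanks: contaminants dominant (3x the max biological area, strictly
    # beyond the 2x removal rule); other features absent or trace (< 2x)
    blank_mat = np.full((n_all, config.n_blanks), np.nan)
    bio_max = bio_mat.max(axis=1)
    sat_parent_row = {s["fid"]: fids.index(s["parent"]) for s in sat_rows}
    cont_rows = [i for i in range(n) if contaminant[i]]
    cont_rows += [
        n + k
        for k, s in enumerate(sat_rows)
        if contaminant[sat_parent_row[s["fid"]]]
    ]
    for i in range(n_all):
        if i in cont_rows:
            blank_mat[i] = 3.0 * bio_max[i] * np.exp(
                (sigma / 4.0) * rng.standard_normal(config.n_blanks)
            )
        else:
            present = rng.random(config.n_blanks) < 0.2
            blank_mat[i, present] = 0.02 * bio_max[i]

    # censoring-like missingness: only cells below an intensity threshold
    # (the detection limit) can drop out, each with probability 0.8; the
    # threshold quantile is chosen so the expected missing fraction of
    # biological cells equals missing_rate.  QA injections are censored at
    # the same detection limit — features near the limit therefore show
    # erratic QA values and are caught by the downstream RSD filter, as in
    # a real run.
    if config.missing_rate > 0:
        thresh = np.quantile(bio_mat.ravel(), min(1.0, config.missing_rate / 0.8))

        def _censor(mat):
            p_miss = np.where(mat < thresh, 0.8, 0.0)
            return np.where(rng.random(mat.shape) < p_miss, np.nan, mat)

        bio_mat = _censor(bio_mat)
        qa_mat = _censor(qa_mat)

    # internal standard: present in every sample, analytical noise only
    is_id, is_mz, is_rt = IS_FEATURES[config.polarity]
    n_cols = bio.size + n_qa_tot + config.n_blanks
    is_row = config.is_area_mean * np.exp(
        (sigma / 2.0) * rng.standard_normal(n_cols)
    )

    sample_ids = list(bio) + [
        s for s in design.samples.index if design.samples.loc[s, "role"] == "QA"
    ] + list(design.blank_ids)
    full = np.vstack([np.hstack([bio_mat, qa_mat, blank_mat]), is_row[None, :]])
    areas = pd.DataFrame(full, index=all_fids + [is_id], columns=sample_ids)
    features = pd.DataFrame(
        {
            "rt_min": np.concatenate([all_rt, [is_rt]]),
            "mz": np.concatenate([all_mz, [is_mz]]),
        },
        index=all_fids + [is_id],
    )
    table = FeatureTable(features, areas[list(design.samples.index)], config.polarity)

    # ---- ground truth ----------------------------------------------------
    gt = pd.DataFrame(
        {
            "baseline_log": np.concatenate(
                [baseline, [baseline[sat_parent_row[s["fid"]]] + np.log(s["factor"]) for s in sat_rows], [np.log(config.is_area_mean)]]
            ),
            "nitrogen_responsive": np.concatenate(
                [slope != 0, [slope[sat_parent_row[s["fid"]]] != 0 for s in sat_rows], [False]]
            ),
            "nitrogen_slope": np.concatenate(
                [slope, [slope[sat_parent_row[s["fid"]]] for s in sat_rows], [0.0]]
            ),
            "variety_discriminant": np.concatenate(
                [
                    voff.any(axis=1),
                    [voff[sat_parent_row[s["fid"]]].any() for s in sat_rows],
                    [False],
                ]
            ),
            "blank_contaminant": np.concatenate(
                [contaminant, [contaminant[sat_parent_row[s["fid"]]] for s in sat_rows], [False]]
            ),
            "satellite_of": [""] * n + [s["parent"] for s in sat_rows] + [""],
            "satellite_rule": [""] * n + [s["rule"] for s in sat_rows] + [""],
            "satellite_factor": np.concatenate(
                [np.ones(n), [s["factor"] for s in sat_rows], [1.0]]
            ),
            "is_internal_standard": [False] * n_all + [True],
        },
        index=all_fids + [is_id],
    )
    # empty concatenations promote bools to float; pin the dtypes
    for col in ("nitrogen_responsive", "variety_discriminant", "blank_contaminant",
                "is_internal_standard"):
        gt[col] = gt[col].astype(bool)
    for col in ("baseline_log", "nitrogen_slope", "satellite_factor"):
        gt[col] = gt[col].astype(float)
    voff_df = pd.DataFrame(
        np.vstack([voff, voff[[sat_parent_row[s["fid"]] for s in sat_rows]], np.zeros((1, config.n_varieties))])
        if len(sat_rows)
        else np.vstack([voff, np.zeros((1, config.n_varieties))]),
        index=all_fids + [is_id],
        columns=varieties,
    )
    truth = GroundTruth(gt, voff_df)
    truth.validate()
    return table, design, truth


# ---------------------------------------------------------------------------
# fixture round-trip


def write_fixture(table: FeatureTable, design: SampleDesign, truth: GroundTruth, outdir) -> dict:
    """Write table/design as CSV and ground truth as JSON under ``outdir``.

    Validates object consistency first; returns the paths written.
    """
    from pathlib import Path

    design.check_against(table)
    truth.validate()
    missing = sorted(set(truth.features.index) - set(table.feature_ids))
    if missing:
        raise SchemaError(f"ground truth features absent from table: {missing}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "feature_table.csv",
        "design": out / "design.csv",
        "truth": out / "ground_truth.json",
    }
    write_feature_table(table, paths["table"])
    write_design(design, paths["design"])
    write_json(
        {
            "polarity": table.polarity,
            "features": truth.features.reset_index(names="feature_id").to_dict(orient="list"),
            "variety_offsets": {
                "index": truth.variety_offsets.index.tolist(),
                "columns": truth.variety_offsets.columns.tolist(),
                "values": truth.variety_offsets.to_numpy().tolist(),
            },
        },
        paths["truth"],
    )
    return paths


def read_fixture(outdir):
    """Read back a fixture written by :func:`write_fixture`."""
    from pathlib import Path

    out = Path(outdir)
    blob = read_json(out / "ground_truth.json")
    table = read_feature_table(out / "feature_table.csv", polarity=blob["polarity"])
    design = read_design(out / "design.csv")
    feats = pd.DataFrame(blob["features"]).set_index("feature_id")
    voff = pd.DataFrame(
        blob["variety_offsets"]["values"],
        index=blob["variety_offsets"]["index"],
        columns=blob["variety_offsets"]["columns"],
    )
    truth = GroundTruth(feats, voff)
    truth.validate()
    return table, design, truth
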