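"""End-to-end driver: simulate (or load) a feature table, preprocess,
annotate/collapse, and run the chemometric and univariate analyses.

This is the orchestration layer used by the numbered analysis scripts and
the acceptance checks; each step delegates to the corresponding module.
The chemometric models run on log10 internal-standard ratios of the
biological samples after redundant-ion collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import chemometrics as cm
from . import univariate as uv
from .annotate import AnnotateParams, annotate_table
from .io import FeatureTable, SampleDesign, default_rules, toy_library
from .preprocess import NormalizedMatrix, PreprocessParams, log10_transform, preprocess
from .simulate import GroundTruth, SimulationConfig, simulate_experiment


@dataclass
class PipelineResult:
    table: FeatureTable
    design: SampleDesign
    truth: GroundTruth | None
    norm: NormalizedMatrix
    groups: list
    identifications: list
    group_parent: dict  # satellite/adduct feature id -> retained parent id
    matrix: pd.DataFrame  # samples x features, log10 ratios, collapsed
    pca: cm.PcaResult | None = None
    pca_with_qa: cm.PcaResult | None = None
    asca: cm.AscaResult | None = None
    asca_p: dict = field(default_factory=dict)
    bootstrap: cm.BootstrapValidation | None = None
    rfe: cm.RfeRanking | None = None
    friedman: uv.FriedmanResult | None = None
    consensus: uv.ConsensusSelection | None = None

    @property
    def injected_parents(self) -> list:
        """Ground-truth nitrogen-responsive base features surviving QC/collapse."""
        if self.truth is None:
            return []
        t = self.truth.features
        return [
            f
            for f in self.truth.nitrogen_responsive_ids
            if f in self.matrix.columns and t.loc[f, "satellite_of"] == ""
        ]


def prepare(
    table: FeatureTable,
    design: SampleDesign,
    truth: GroundTruth | None = None,
    pre_params: PreprocessParams | None = None,
    ann_params: AnnotateParams | None = None,
    rules=None,
    library=None,
) -> PipelineResult:
    """Preprocess + annotate + collapse; returns a result with the analysis
    matrix ready (no models fitted yet)."""
    norm = preprocess(table, design, pre_params)
    groups, idents, collapsed, mapping = annotate_table(
        norm.ratios_unimputed,
        table.features["rt_min"],
        table.features["mz"],
        design,
        rules or default_rules(),
        library or toy_library(),
        table.polarity,
        ann_params,
    )
    matrix = log10_transform(
        norm.ratios.loc[collapsed.index, list(design.biological_ids)]
    ).T
    return PipelineResult(
        table=table,
        design=design,
        truth=truth,
        norm=norm,
        groups=groups,
        identifications=idents,
        group_parent=mapping,
        matrix=matrix,
    )


def run_models(
    res: PipelineResult,
    n_perm: int = 1000,
    n_boot: int = 1000,
    n_components: int = 5,
    seed: int = 0,
    consensus_params: uv.ConsensusParams | None = None,
) -> PipelineResult:
    """Fit PCA, ASCA (+ permutation tests), bootstrap PLS-S, RFE, Friedman,
    and the consensus selection on a prepared result."""
    X = res.matrix
    design = res.design
    ncomp_pca = min(5, X.shape[0] - 1, X.shape[1])
    res.pca = cm.pca(X, ncomp_pca)
    qa_ids = [s for s in design.qa_ids() if s in res.norm.ratios.columns]
    if qa_ids:
        with_qa = log10_transform(
            res.norm.ratios.loc[X.columns, list(X.index) + qa_ids]
        ).T
        res.pca_with_qa = cm.pca(with_qa, ncomp_pca)
    res.asca = cm.asca_fit(X, design)
    for off, factor in enumerate(("variety", "nitrogen"), start=11):
        res.asca.effects[factor].p_value = cm.asca_permutation_test(
            X, design, factor, n_perm=n_perm, seed=seed + off
        )
        res.asca_p[factor] = res.asca.effects[factor].p_value
    res.asca.n_permutations = n_perm
    res.bootstrap = cm.bootstrap_validate(
        X, design, n_boot=n_boot, n_components=n_components, seed=seed + 1
    )
    res.rfe = cm.rfe(X, design, step=0.1, n_components=n_components, seed=seed + 2)
    res.friedman = uv.friedman_test(X.T, design, factor="nitrogen")
    res.consensus = uv.consensus_select(
        pca_loadings=res.pca.loadings["PC1"],
        asca_loadings=res.asca.effects["nitrogen"].loadings["SC1"],
        pls_ranks=res.rfe.ranks,
        friedman=res.friedman,
        group_parent=res.group_parent,
        params=consensus_params,
    )
    return res


def run_synthetic(
    config: SimulationConfig | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    fit: bool = True,
) -> PipelineResult:
    """Simulate the trial with ``config`` and run the full pipeline."""
    config = config or SimulationConfig()
    table, design, truth = simulate_experiment(config)
    res = prepare(table, design, truth)
    if fit:
        run_models(res, n_perm=n_perm, n_boot=n_boot, seed=seed)
    return res
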