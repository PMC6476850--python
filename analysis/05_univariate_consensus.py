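#!/usr/bin/env python
"""Friedman screening with BH-FDR, per-variety monotone nitrogen-response
reports, and the cross-method consensus feature selection.

Combines the PCA/ASCA loadings and RFE ranks written by 04_chemometrics.py
with the Friedman top-100 list, deduplicates by ion group, and writes the
final selection table (feature, RT, m/z, identification, evidence flags,
response direction).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from oatchemo import univariate as uv
from oatchemo.pipeline import prepare
from oatchemo.simulate import read_fixture

ap = argparse.ArgumentParser()
ap.add_argument("--trial", type=Path, default=Path("results/trial"))
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

table, design, truth = read_fixture(args.trial)
res = prepare(table, design, truth)
X = res.matrix

fr = uv.friedman_test(X.T, design, factor="nitrogen")
fr_var = uv.friedman_test(X.T, design, factor="variety")
print(f"Friedman/BH at 5% FDR on {X.shape[1]} features:")
print(f"  nitrogen: {int(fr.table['reject'].sum())} significant")
print(f"  variety:  {int(fr_var.table['reject'].sum())} significant")

screens = {}
for v in design.varieties:
    rep = uv.monotone_response_screen(res.norm.ratios.loc[X.columns], design, v)
    screens[v] = rep
    n_lin = int(rep["linear"].sum())
    print(f"  {v}: {n_lin} features with strictly monotone level-mean response")
direction = pd.concat({v: s["sign"] for v, s in screens.items()}, axis=1)

pca_loadings = pd.read_csv(args.results / "pca_loadings.csv", index_col=0)["PC1"]
asca_loadings = pd.read_csv(
    args.results / "asca_nitrogen_loadings.csv", index_col=0
)["SC1"]
rfe_ranks = pd.read_csv(args.results / "rfe_ranks.csv", index_col=0)["rfe_rank"]

sel = uv.consensus_select(
    pca_loadings, asca_loadings, rfe_ranks, fr, group_parent=res.group_parent
)
out = sel.table.copy()
out.insert(0, "rt_min", table.features.loc[out.index, "rt_min"].round(3))
out.insert(1, "mz", table.features.loc[out.index, "mz"].round(4))
out["friedman_q"] = fr.table.loc[out.index, "q"]
out["mean_direction"] = np.sign(direction.loc[out.index].mean(axis=1))
out["truth_nitrogen_responsive"] = truth.features.loc[out.index, "nitrogen_responsive"]
out.index.name = "feature_id"
out.to_csv(args.results / "consensus_selection.csv")

inj = res.injected_parents
hit = np.mean([f in set(sel.selected) for f in inj])
print(f"consensus: {len(sel.selected)} features selected "
      f"({len(sel.dedup_map)} redundant ions folded into parents)")
print(f"  recovers {hit:.0%} of the {len(inj)} injected nitrogen-responsive parents")
print(f"wrote consensus_selection.csv under {args.results}/")
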