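import numpy as np
import pandas as pd
import pytest

from oatchemo.io import FeatureTable, SampleDesign
from oatchemo.pipeline import prepare
from oatchemo.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """One simulated trial at generator defaults (60 bio + 8 QA + 2 blanks)."""
    return simulate_experiment(SimulationConfig(rng_seed=7))


@pytest.fixture(scope="session")
def prepared(default_sim):
    """Preprocessed + annotated + collapsed pipeline state for the default trial."""
    table, design, truth = default_sim
    return prepare(table, design, truth)


@pytest.fixture(scope="session")
def quiet_sim():
    """Near-noiseless, fully observed trial: additive log-signal is exact."""
    cfg = SimulationConfig(
        rng_seed=5,
        n_features=80,
        noise_cv=1e-8,
        missing_rate=0.0,
        adduct_satellite_rate=0.2,
        frac_blank_contaminants=0.0,
    )
    return simulate_experiment(cfg)


def toy_table(rows, samples, polarity="positive"):
    """Build a FeatureTable from (feature_id, rt, mz, areas...) tuples."""
    fids = [r[0] for r in rows]
    features = pd.DataFrame(
        {"rt_min": [r[1] for r in rows], "mz": [r[2] for r in rows]}, index=fids
    )
    areas = pd.DataFrame(
        [r[3] for r in rows], index=fids, columns=samples, dtype=float
    )
    return FeatureTable(features, areas, polarity)


def toy_design(bio=(), qa=(), blank=(), varieties=None, doses=None, reps=None):
    rows = []
    for i, s in enumerate(bio):
        rows.append(
            (
                s,
                "biological",
                (varieties or ["V1"] * len(bio))[i],
                (doses or [0.0] * len(bio))[i],
                (reps or [1] * len(bio))[i],
                False,
            )
        )
    for s in qa:
        rows.append((s, "QA", np.nan, np.nan, np.nan, False))
    for s in blank:
        rows.append((s, "blank", np.nan, np.nan, np.nan, False))
    return SampleDesign(
        pd.DataFrame(
            rows,
            columns=["sample_id", "role", "variety", "nitrogen", "replicate", "conditioning"],
        ).set_index("sample_id")
    )
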