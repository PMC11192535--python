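import numpy as np
import pandas as pd
import pytest

from effectorscan.profiles import ExpressionMatrix
from effectorscan.simulate import SimulationConfig, simulate_all


def make_matrix(values: dict, meta_rows: dict) -> ExpressionMatrix:
    """values: gene -> {sample: tpm}; meta_rows: sample -> (tissue, stage, sex, rep)."""
    df = pd.DataFrame(values).T
    meta = pd.DataFrame(
        [
            {"sample_id": s, "tissue": t, "stage": st, "sex": sx, "replicate": r}
            for s, (t, st, sx, r) in meta_rows.items()
        ]
    ).set_index("sample_id")
    return ExpressionMatrix(df, meta)


@pytest.fixture
def four_group_matrix() -> ExpressionMatrix:
    """2 venom-gland replicates plus three single-sample comparator groups."""
    meta = {
        "VG_r1": ("venom_gland", "adult", "female", 1),
        "VG_r2": ("venom_gland", "adult", "female", 2),
        "carcass": ("carcass", "adult", "female", 1),
        "larva": ("whole_body", "larva", "mixed", 1),
        "pupa": ("whole_body", "pupa", "mixed", 1),
    }
    values = {
        "flat": {s: 5.0 for s in meta},
        "vg_high": {"VG_r1": 10.0, "VG_r2": 10.0, "carcass": 2.0, "larva": 2.0, "pupa": 2.0},
        "vg_only": {"VG_r1": 7.0, "VG_r2": 9.0, "carcass": 0.0, "larva": 0.0, "pupa": 0.0},
        "silent": {s: 0.0 for s in meta},
    }
    return make_matrix(values, meta)


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """A complete simulated input directory (small gene panel, fixed seed)."""
    outdir = tmp_path_factory.mktemp("simdata")
    config = SimulationConfig(
        seed=11,
        n_genes=400,
        planted_specialized=tuple(
            [(f"g{i:05d}", "venom_gland", 8.0) for i in range(1, 11)]
            + [(f"g{i:05d}", "teratocyte", 8.0) for i in range(11, 16)]
        ),
        planted_secreted=tuple(f"g{i:05d}" for i in range(1, 9)),
    )
    simulate_all(config, outdir)
    return outdir, config


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
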