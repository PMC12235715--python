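import numpy as np
import pandas as pd
import pytest

from bwproteo import generate_cohort, preprocess_pipeline
from bwproteo.config import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: study-design group sizes, 60 proteins, 12 LGA-
    and 4 SGA-affected at +1 log2."""
    cfg = CohortConfig(n_proteins=60, n_diff_lga=12, n_diff_sga=4, effect_size=1.0, seed=7)
    samples, rfu, truth = generate_cohort(cfg)
    return cfg, samples, rfu, truth


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    _, samples, rfu, _ = small_cohort
    wins, logm, fits, mom = preprocess_pipeline(rfu, samples)
    return samples, wins, logm, fits, mom


@pytest.fixture()
def toy_gmt(tmp_path):
    """Ten disjoint 5-gene sets over a 60-gene universe."""
    lines = []
    for i in range(10):
        members = [f"G{j:04d}" for j in range(1 + 5 * i, 6 + 5 * i)]
        lines.append(f"S{i}\tset {i}\t" + "\t".join(members))
    path = tmp_path / "sets.gmt"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
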