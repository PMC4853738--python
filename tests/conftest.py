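"""Shared fixtures: small deterministic synthetic experiments."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from glycopipe.glycans import parse_glycan
from glycopipe.pipeline import RunConfig
from glycopipe.synthetic import SimConfig, random_glycan_db, simulate_run


@pytest.fixture(scope="session")
def trimannosyl_core():
    return parse_glycan("(N(N(H(H)(H))))")


@pytest.fixture(scope="session")
def small_db():
    rng = np.random.default_rng(123)
    return random_glycan_db(rng, 30, allow_neugc=False)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """40 planted glycopeptides, default study conditions."""
    out = tmp_path_factory.mktemp("sim_small")
    cfg = SimConfig(rng_seed=5, n_glycopeptides=40, glycan_db_size=30)
    truth = simulate_run(cfg, out)
    return cfg, truth


@pytest.fixture(scope="session")
def small_run_config(small_experiment):
    _, truth = small_experiment
    return RunConfig(
        run1_mgf=str(truth.run1_mgf),
        run2_mgf=str(truth.run2_mgf),
        glycan_db=str(truth.glycan_db_path),
        fasta=str(truth.fasta_path),
        out_dir=str(truth.run1_mgf.parent / "out"),
        seed=5,
    )
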