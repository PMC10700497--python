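import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from follimap.io_formats import CountMatrix, ObservationTable
from follimap.preprocess import ExpressionMatrix, lognormalize
from follimap.synthetic import default_config, generate_scrna, generate_st


@pytest.fixture(scope="session")
def sim_cfg():
    """The default study conditions at a pinned seed, shared across tests."""
    return default_config(seed=1)


@pytest.fixture(scope="session")
def scrna_sim(sim_cfg):
    return generate_scrna(sim_cfg)


@pytest.fixture(scope="session")
def st_sim(sim_cfg):
    return generate_st(sim_cfg)


@pytest.fixture(scope="session")
def scrna_expr(scrna_sim):
    m, obs, truth = scrna_sim
    return lognormalize(m, "cells")


def make_count_matrix(counts, gene_ids=None, obs_ids=None, obs_kind="cell"):
    counts = np.asarray(counts)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    obs_ids = obs_ids or [f"c{i:03d}" for i in range(counts.shape[1])]
    return CountMatrix(gene_ids, obs_ids, sp.csr_matrix(counts), obs_kind)


def make_expression(values, gene_ids=None, obs_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    obs_ids = obs_ids or [f"c{i:03d}" for i in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, obs_ids, sp.csr_matrix(values), scale_factor=1e4)


def make_obs(obs_ids, obs_kind="cell", **columns):
    return ObservationTable(pd.DataFrame({"obs_id": obs_ids, **columns}), obs_kind)
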