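"""Shared fixtures: simulated bundles at the standard and a reduced scale.

The standard bundle (150 positives / 600-gene pool) is generated once per
session and shared by the training-scale tests; the small bundle keeps
unit tests fast.
"""

import numpy as np
import pytest

import cancerlnc as cl


#: Classifier problem size used throughout the suite: 100 trees keeps the
#: many cross-validation runs fast while leaving AUC estimates unchanged
#: relative to the shipped 500-tree default.
RF_PARAMS = {"n_estimators": 100}
N_SETS = 20


def small_config(seed=0, **overrides):
    defaults = dict(
        seed=seed,
        n_positive=40,
        n_negative_pool=120,
        n_unknown=40,
        n_coding=60,
        n_mirna=20,
        gene_length_range=(1500, 3000),
    )
    defaults.update(overrides)
    return cl.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_bundle():
    return cl.simulate_bundle(cl.SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_table(default_bundle):
    table, net = cl.feature_table_from_bundle(default_bundle)
    return table


@pytest.fixture(scope="session")
def default_labels(default_bundle):
    b = default_bundle
    pool = cl.build_negative_pool(
        b.lncrnas,
        cl.filter_cancer_snps(b.snps),
        positives=set(b.positives),
        exclude=set(b.unknown),
    )
    sets = cl.sample_negative_sets(pool, n_sets=N_SETS, size=150, seed=101)
    return pool, sets


@pytest.fixture(scope="session")
def small_bundle():
    return cl.simulate_bundle(small_config(seed=7))


@pytest.fixture(scope="session")
def small_table(small_bundle):
    table, net = cl.feature_table_from_bundle(small_bundle)
    return table


@pytest.fixture(scope="session")
def small_net(small_bundle):
    table, net = cl.feature_table_from_bundle(small_bundle)
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
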