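"""Shared fixtures: desk-scale datasets and trained network groups.

Training-dependent checks share session-scoped groups of networks trained
under the study conditions (T = 380, change probability 1/75, minibatches
of 20 sequences; 160 minibatches for the unigram environment and 400 for
the bigram environment), at a desk scale of 5 replicate seeds and 250
test sequences.  Fixtures are lazy: they are only built when a test
requests them.
"""

from __future__ import annotations

import numpy as np
import pytest

from seqpred.environments import EnvironmentConfig, generate_batch
from seqpred.optimal import run_optimal_batch
from seqpred.workflows import make_training_data, train_group

N_REPLICATES = 5
N_TEST_SEQUENCES = 250
# readout analyses use the study's printed sample sizes (they are cheap);
# only replicate counts and performance test sets are scaled down
READOUT_TRAIN_SEQUENCES = 900
READOUT_TEST_SEQUENCES = 100
CORRELATION_SEQUENCES = 300

DATA_SEED = 101
TEST_SEED = 202
AGENT_SEED = 303
READOUT_TRAIN_SEED = 404
READOUT_TEST_SEED = 505
ANALYSIS_SEED = 606


@pytest.fixture(scope="session")
def unigram_train_data():
    return make_training_data("unigram", 160, seed=DATA_SEED)


@pytest.fixture(scope="session")
def unigram_test_data():
    return generate_batch(EnvironmentConfig("unigram", seed=TEST_SEED), N_TEST_SEQUENCES)


@pytest.fixture(scope="session")
def unigram_gated_group(unigram_train_data):
    return train_group("unigram", "gated", 11, N_REPLICATES, unigram_train_data, AGENT_SEED)


@pytest.fixture(scope="session")
def unigram_no_gating_group(unigram_train_data):
    return train_group("unigram", "no_gating", 11, N_REPLICATES, unigram_train_data, AGENT_SEED)


@pytest.fixture(scope="session")
def bigram_train_data():
    return make_training_data("bigram_independent", 400, seed=DATA_SEED)


@pytest.fixture(scope="session")
def bigram_test_data():
    return generate_batch(
        EnvironmentConfig("bigram_independent", seed=TEST_SEED), N_TEST_SEQUENCES
    )


@pytest.fixture(scope="session")
def bigram_groups(bigram_train_data):
    return {
        arch: train_group("bigram_independent", arch, 11, N_REPLICATES, bigram_train_data, AGENT_SEED)
        for arch in ("gated", "no_gating", "no_lateral", "frozen_recurrence")
    }


@pytest.fixture(scope="session")
def unigram_readout_data():
    """Readout fit/test sequences with the optimal observer's traces."""
    cfg = EnvironmentConfig("unigram", seed=READOUT_TRAIN_SEED)
    train = generate_batch(cfg, READOUT_TRAIN_SEQUENCES)
    test = generate_batch(
        EnvironmentConfig("unigram", seed=READOUT_TEST_SEED), READOUT_TEST_SEQUENCES
    )
    return {
        "train": train,
        "test": test,
        "optimal_train": run_optimal_batch(train, cfg),
        "optimal_test": run_optimal_batch(test, cfg),
        "config": cfg,
    }


@pytest.fixture(scope="session")
def bigram_readout_data():
    cfg = EnvironmentConfig("bigram_independent", seed=READOUT_TRAIN_SEED)
    train = generate_batch(cfg, READOUT_TRAIN_SEQUENCES)
    test = generate_batch(
        EnvironmentConfig("bigram_independent", seed=READOUT_TEST_SEED), READOUT_TEST_SEQUENCES
    )
    return {
        "train": train,
        "test": test,
        "optimal_train": run_optimal_batch(train, cfg),
        "optimal_test": run_optimal_batch(test, cfg),
        "config": cfg,
    }
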