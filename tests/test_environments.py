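"""Generative-process contracts: change points, latent dynamics, observation sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqpred.environments import (
    EnvironmentConfig,
    generate_dataset,
    generate_locked_batch,
    generate_sequence,
    generate_streak_probes,
    sequence_to_frame,
)


def test_invalid_structure_rejected():
    with pytest.raises(ValueError):
        EnvironmentConfig(structure="trigram")
    with pytest.raises(ValueError):
        EnvironmentConfig(change_prob=1.5)
    with pytest.raises(ValueError):
        EnvironmentConfig(length=0)


@pytest.mark.parametrize("structure", ["unigram", "bigram_independent", "bigram_coupled"])
def test_no_change_limit(structure):
    """change_prob = 0 yields constant latents and no change flags."""
    seq = generate_sequence(EnvironmentConfig(structure, change_prob=0.0, seed=7))
    assert not seq.change_flags.any()
    assert np.all(seq.latents == seq.latents[:, :1])


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_piecewise_constant_latents(seed):
    """Latents change between t and t+1 exactly where a change flag is set."""
    for structure in ("unigram", "bigram_independent"):
        seq = generate_sequence(
            EnvironmentConfig(structure, change_prob=0.05, length=200, seed=seed)
        )
        moved = seq.latents[:, 1:] != seq.latents[:, :-1]
        # a flag without visible movement is possible only if the redraw repeats
        # the old value, which has probability zero for continuous uniforms
        assert np.array_equal(moved, seq.change_flags[:, 1:])
        assert not seq.change_flags[:, 0].any()


def test_coupled_change_flags_identical():
    for seed in range(10):
        seq = generate_sequence(EnvironmentConfig("bigram_coupled", seed=seed))
        assert np.array_equal(seq.change_flags[0], seq.change_flags[1])


def test_change_rate_matches_hazard():
    """Empirical change-flag rate over 10,000 sequences ~ 1/75 (binomial oracle)."""
    pc = 1.0 / 75.0
    cfg = EnvironmentConfig("unigram", seed=11)
    n, T = 10_000, cfg.length
    count = sum(seq.change_flags.sum() for seq in generate_dataset(cfg, n))
    trials = n * (T - 1)
    se = np.sqrt(pc * (1 - pc) / trials)
    assert abs(count / trials - pc) < 3 * se


def test_unigram_marginals_match_latents():
    """With no changes the per-sequence observation mean tracks the latent rate."""
    cfg = EnvironmentConfig("unigram", change_prob=0.0, seed=3)
    seqs = generate_dataset(cfg, 500)
    diffs = [seq.observations.mean() - seq.latents[0, 0] for seq in seqs]
    # each diff has SD <= 0.5/sqrt(T); the mean of 500 of them is tightly bounded
    assert abs(np.mean(diffs)) < 3 * 0.5 / np.sqrt(cfg.length * len(seqs))


def test_bigram_transition_frequencies():
    """Fixed-latent bigram generation reproduces the transition probabilities."""
    cfg = EnvironmentConfig("bigram_independent", change_prob=0.0, seed=21, length=380)
    n11 = n1x = 0
    for seq in generate_dataset(cfg, 300):
        x = seq.observations
        prev = x[:-1]
        p11 = seq.latents[1, 0]
        n11 += np.sum((prev == 1) & (x[1:] == 1) - 0) - p11 * np.sum(prev == 1)
        n1x += np.sum(prev == 1)
    # accumulated deviation of 1->1 counts from their conditional expectation
    assert abs(n11) < 3 * np.sqrt(n1x * 0.25)


def test_determinism_per_seed_and_index():
    cfg = EnvironmentConfig("bigram_coupled", seed=9)
    a = generate_sequence(cfg, index=4)
    b = generate_sequence(cfg, index=4)
    c = generate_sequence(cfg, index=5)
    assert np.array_equal(a.observations, b.observations)
    assert np.array_equal(a.latents, b.latents)
    assert not np.array_equal(a.observations, c.observations)


class TestLockedBatch:
    def test_rejects_out_of_range_times(self):
        cfg = EnvironmentConfig("unigram", seed=0)
        with pytest.raises(ValueError):
            generate_locked_batch(cfg, [0], 1)
        with pytest.raises(ValueError):
            generate_locked_batch(cfg, [cfg.length], 1)

    def test_empty_locked_times_constant_latents(self):
        cfg = EnvironmentConfig("unigram", seed=0, length=50)
        for seq in generate_locked_batch(cfg, [], 5):
            assert not seq.change_flags.any()
            assert np.all(seq.latents == seq.latents[:, :1])

    def test_flags_only_at_locked_times(self):
        cfg = EnvironmentConfig("unigram", seed=0)
        for seq in generate_locked_batch(cfg, [100], 50):
            assert np.array_equal(np.flatnonzero(seq.change_flags[0]), [100])

    def test_window_means_track_latent_draws(self):
        """Observation means before/after the locked change follow the latents."""
        cfg = EnvironmentConfig("unigram", seed=13)
        seqs = generate_locked_batch(cfg, [100], 2000)
        pre = np.array([s.observations[50:100].mean() - s.latents[0, 50] for s in seqs])
        post = np.array([s.observations[150:200].mean() - s.latents[0, 150] for s in seqs])
        assert abs(pre.mean()) < 3 * 0.5 / np.sqrt(50 * len(seqs))
        assert abs(post.mean()) < 3 * 0.5 / np.sqrt(50 * len(seqs))


class TestStreakProbes:
    def test_counts_and_conditions(self):
        probes = generate_streak_probes(seed=5)
        assert probes.n_probes == 400
        assert probes.prefixes.shape == (400, 74)
        # 100 per crossed condition
        for ob in (0, 1):
            for p in (0.2, 0.8):
                mask = (probes.observed_bigram == ob) & (probes.unobserved_prob == p)
                assert mask.sum() == 100

    def test_observed_bigram_frequency(self):
        """Frequency of 1->1 transitions ~ 0.2 when the observed bigram is 1|1."""
        probes = generate_streak_probes(seed=5)
        sel = probes.observed_bigram == 1
        reps = trans = 0
        for x in probes.prefixes[sel]:
            prev = x[:-1]
            trans += np.sum(prev == 1)
            reps += np.sum((prev == 1) & (x[1:] == 1))
        rate = reps / trans
        assert abs(rate - 0.2) < 3 * np.sqrt(0.2 * 0.8 / trans)


def test_sequence_to_frame_roundtrip():
    seq = generate_sequence(EnvironmentConfig("bigram_independent", seed=2, length=40))
    frame = sequence_to_frame(seq)
    assert list(frame.columns) == ["t", "x", "p00", "change_p00", "p11", "change_p11"]
    assert np.array_equal(frame["x"].to_numpy(), seq.observations)
    assert np.allclose(frame["p11"].to_numpy(), seq.latents[1])
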