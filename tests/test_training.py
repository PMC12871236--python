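"""Play loop, reward transforms, TD targets, and the training step."""

import numpy as np
import pytest

from rnaqdesign.environment import DesignTarget, nussinov_fold
from rnaqdesign.fixtures import make_hairpin, random_sequence
from rnaqdesign.qnet import QNetwork, QNetworkConfig
from rnaqdesign.structures import parse_dotbracket
from rnaqdesign.training import (
    AdamOptimizer,
    EpisodeRecord,
    TrainingConfig,
    discount_schedule,
    play_episodes,
    read_episodes,
    reweight_rewards,
    shift_left,
    sync_target,
    td_targets,
    train_epoch,
    valid_actions,
    write_episodes,
)


class TestValidActions:
    target = parse_dotbracket("((....))")

    def test_unpaired_position_allows_all(self):
        assert valid_actions(self.target, 2, "GC").all()

    def test_left_partner_not_yet_decoded_allows_all(self):
        assert valid_actions(self.target, 0, "").all()

    @pytest.mark.parametrize(
        "base, allowed",
        [("G", {"C", "U"}), ("A", {"U"}), ("C", {"G"}), ("U", {"A", "G"})],
    )
    def test_complement_masks(self, base, allowed):
        partial = base + "G....."
        mask = valid_actions(self.target, 7, partial)
        from rnaqdesign.qnet import BASES

        assert {BASES[i] for i in np.flatnonzero(mask)} == allowed


class TestRewardTransforms:
    def test_reweight_all_ones(self):
        out = reweight_rewards(np.ones(3))
        assert np.allclose(out, np.e, atol=1e-9)

    def test_reweight_all_zeros(self):
        assert np.array_equal(reweight_rewards(np.zeros(4)), np.zeros(4))

    def test_reweight_half(self):
        out = reweight_rewards(np.array([1.0, 0.0, 1.0, 0.0]))
        assert np.allclose(out, [np.exp(0.5), 0, np.exp(0.5), 0], atol=1e-9)

    def test_reweight_preserves_zeros(self, rng):
        r = (rng.random(20) > 0.5).astype(float)
        out = reweight_rewards(r)
        assert np.array_equal(out == 0, r == 0)

    def test_reweight_empty_rejected(self):
        with pytest.raises(ValueError):
            reweight_rewards(np.array([]))

    def test_discount_endpoints(self):
        sched = discount_schedule(10, 0.9, 0.4)
        assert sched[0] == pytest.approx(0.9, abs=1e-9)
        assert sched[-1] == pytest.approx(0.4, abs=1e-9)

    def test_discount_tabulated_value(self):
        sched = discount_schedule(11, 0.95, 0.5)
        assert sched[5] == pytest.approx(0.725, abs=1e-9)

    def test_discount_degenerate_length(self):
        assert np.array_equal(discount_schedule(1, 0.95, 0.5), [0.95])

    def test_td_targets_hand_computed(self):
        out = td_targets(
            np.array([1.0, 0.0, 1.0]),
            np.array([0.5, 0.2, 0.0]),
            np.full(3, 0.9),
        )
        assert np.allclose(out, [1.45, 0.18, 1.0], atol=1e-9)

    def test_td_targets_zero(self):
        assert np.array_equal(td_targets(np.zeros(4), np.zeros(4), np.full(4, 0.9)), np.zeros(4))

    def test_td_final_position_equals_reward(self, rng):
        r = rng.random(6)
        nxt = rng.random(6)  # deliberately nonzero in the last slot
        out = td_targets(r, nxt, np.full(6, 0.9))
        assert out[-1] == pytest.approx(r[-1])

    def test_shift_left(self):
        assert np.array_equal(shift_left(np.array([3.0, 1.0, 2.0])), [1.0, 2.0, 0.0])


@pytest.fixture(scope="module")
def small_net():
    cfg = QNetworkConfig(
        embed_dim=16, encoder_layers=1, decoder_layers=1, attention_heads=2,
        conv_kernel=3, seed=11,
    )
    return QNetwork(cfg)


@pytest.fixture(scope="module")
def hairpin_targets():
    return [
        DesignTarget(make_hairpin(stem, 20 - 2 * stem), name=f"h{stem}")
        for stem in (3, 4, 5, 6)
    ]


class TestPlay:
    def test_greedy_play_deterministic(self, small_net, predictor, hairpin_targets):
        a, ra = play_episodes(small_net, predictor, hairpin_targets, epsilon=0.0, seed=1)
        b, rb = play_episodes(small_net, predictor, hairpin_targets, epsilon=0.0, seed=2)
        assert [e.sequence for e in a] == [e.sequence for e in b]
        assert ra == rb

    def test_exploratory_play_seeded(self, small_net, predictor, hairpin_targets):
        a, _ = play_episodes(small_net, predictor, hairpin_targets, epsilon=1.0, seed=7)
        b, _ = play_episodes(small_net, predictor, hairpin_targets, epsilon=1.0, seed=7)
        c, _ = play_episodes(small_net, predictor, hairpin_targets, epsilon=1.0, seed=8)
        assert [e.sequence for e in a] == [e.sequence for e in b]
        assert [e.sequence for e in a] != [e.sequence for e in c]

    def test_fold_derived_target_reaches_full_reward(self, predictor, rng):
        """A target defined by a sequence's own fold gives that sequence
        an all-ones structure reward (environment self-consistency)."""
        from rnaqdesign.environment import compute_rewards

        seq = random_sequence(24, rng)
        target = nussinov_fold(seq)
        rewards = compute_rewards(predictor.fold(seq), target)
        assert np.array_equal(rewards, np.ones(24))

    def test_masked_positions_are_complementary(self, small_net, predictor, hairpin_targets):
        from rnaqdesign.environment import CANONICAL_PAIRS

        records, _ = play_episodes(small_net, predictor, hairpin_targets, epsilon=1.0, seed=3)
        for e in records:
            for i, j in e.target.structure.pairs:
                assert (e.sequence[i], e.sequence[j]) in CANONICAL_PAIRS


class TestTrainEpoch:
    def test_loss_decreases_on_frozen_batch(self, predictor, hairpin_targets):
        cfg = QNetworkConfig(
            embed_dim=16, encoder_layers=1, decoder_layers=1, attention_heads=2,
            conv_kernel=3, seed=5,
        )
        net = QNetwork(cfg)
        frozen = net.copy()
        episodes, _ = play_episodes(net, predictor, hairpin_targets, epsilon=0.5, seed=0)
        tc = TrainingConfig(learning_rate=3e-3, batch_size=8, seed=0)
        opt = AdamOptimizer(tc.learning_rate, tc.grad_clip)
        losses = [train_epoch(net, frozen, episodes, tc, opt) for _ in range(50)]
        assert losses[-1] < losses[0]

    def test_hand_built_episode_matches_composed_oracles(self):
        """The TD loss on one episode equals the value composed from the
        reward-reweighting, discount and td_targets oracles directly."""
        cfg = QNetworkConfig(
            embed_dim=16, encoder_layers=1, decoder_layers=1, attention_heads=2,
            conv_kernel=3, seed=2,
        )
        net = QNetwork(cfg)
        frozen = net.copy()
        target = DesignTarget(parse_dotbracket("....."), name="loop")
        episode = EpisodeRecord(target=target, sequence="ACGUA", rewards=np.ones(5))
        tc = TrainingConfig(gamma_start=0.9, gamma_end=0.9, batch_size=1, seed=0)

        from rnaqdesign.qnet import START_TOKEN, tokenize_sequence

        ctx = frozen.encode_structure(target.structure)
        prefix = np.concatenate([[START_TOKEN], tokenize_sequence("ACGUA")[:-1]])
        flags = target.structure.paired_flags()
        grid = np.asarray(frozen.decode_full(prefix[None], flags[None], ctx[None]))[0]
        expected_targets = td_targets(
            reweight_rewards(np.ones(5)),
            shift_left(grid.max(axis=-1)),
            discount_schedule(5, 0.9, 0.9),
        )
        q_sel = grid[np.arange(5), tokenize_sequence("ACGUA")]
        expected_loss = float(np.mean((q_sel - expected_targets) ** 2))
        got = train_epoch(net, frozen, [episode], tc)
        assert got == pytest.approx(expected_loss, abs=1e-6)

    def test_empty_episode_list_rejected(self, small_net):
        with pytest.raises(ValueError):
            train_epoch(small_net, small_net.copy(), [], TrainingConfig())


class TestSyncTarget:
    def test_sync_then_identical_grids(self, predictor, hairpin_targets):
        cfg = QNetworkConfig(
            embed_dim=16, encoder_layers=1, decoder_layers=1, attention_heads=2,
            conv_kernel=3, seed=9,
        )
        net = QNetwork(cfg)
        frozen = net.copy()
        episodes, _ = play_episodes(net, predictor, hairpin_targets, epsilon=0.3, seed=1)
        train_epoch(net, frozen, episodes, TrainingConfig(seed=0))
        s = hairpin_targets[0].structure
        assert not np.allclose(net.encode_structure(s), frozen.encode_structure(s))
        sync_target(net, frozen)
        assert np.array_equal(net.encode_structure(s), frozen.encode_structure(s))
        sync_target(net, frozen)  # idempotent
        assert np.array_equal(net.encode_structure(s), frozen.encode_structure(s))

    def test_config_mismatch_rejected(self, small_net, tiny_network):
        with pytest.raises(ValueError):
            sync_target(small_net, tiny_network)


def test_episode_file_roundtrip(tmp_path, predictor, small_net, hairpin_targets):
    episodes, _ = play_episodes(small_net, predictor, hairpin_targets, epsilon=0.5, seed=4)
    path = str(tmp_path / "episodes.tsv")
    write_episodes(path, episodes)
    write_episodes(path, episodes[:1], append=True)
    back = read_episodes(path)
    assert len(back) == len(episodes) + 1
    for orig, rt in zip(episodes, back):
        assert rt.sequence == orig.sequence
        assert rt.target.structure == orig.target.structure
        assert np.allclose(rt.rewards, orig.rewards)
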