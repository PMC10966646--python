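"""Protocols, label noise, campaigns, repeats, benchmark and the cost model."""

import numpy as np
import pandas as pd
import pytest

from albench.driver import (
    DEFAULT_NOISE_GRID,
    NoiseSpec,
    Protocol,
    add_label_noise,
    benchmark_split,
    build_protocol,
    rbfe_cost,
    repeat_campaigns,
    run_campaign,
)
from albench.surrogate import GPHyperparams
from albench.synthetic import SyntheticScenario, generate_library

FIXED_GP = GPHyperparams(amplitude=1.0, noise_variance=0.1)


class TestProtocols:
    @pytest.mark.parametrize(
        "name,n_explore,n_exploit,exploit_batch",
        [
            ("random-exploit", 0, 10, 30),
            ("random-explore-exploit", 2, 8, 30),
            ("random-random-exploit", 0, 8, 30),
            ("batch-size-20", 3, 12, 20),
            ("batch-size-30", 2, 8, 30),
            ("batch-size-60", 1, 4, 60),
            ("batch-size-120", 1, 2, 120),
        ],
    )
    def test_catalogue_expansion(self, name, n_explore, n_exploit, exploit_batch):
        p = build_protocol(name)
        explore = [ph for ph in p.phases if ph[0] == "explore"]
        exploit = [ph for ph in p.phases if ph[0] == "exploit"]
        assert sum(c for _, _, c in explore) == n_explore
        assert sum(c for _, _, c in exploit) == n_exploit
        if exploit:
            assert exploit[0][1] == exploit_batch

    @pytest.mark.parametrize(
        "name",
        [
            "random-exploit",
            "random-explore-exploit",
            "random-random-exploit",
            "batch-size-20",
            "batch-size-30",
            "batch-size-60",
            "batch-size-120",
        ],
    )
    def test_phases_sum_to_budget(self, name):
        p = build_protocol(name)
        assert sum(b * c for _, b, c in p.phases) == 360
        assert p.phases[0][0] == "random"

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            build_protocol("zigzag")

    def test_budget_violation_states_deficit(self):
        with pytest.raises(ValueError, match="deficit 300"):
            Protocol(name="bad", phases=(("random", 60, 1),), total_budget=360)

    def test_first_phase_must_be_random(self):
        with pytest.raises(ValueError, match="random"):
            Protocol(name="bad", phases=(("exploit", 60, 1),), total_budget=60)

    def test_custom_phase_list(self):
        p = build_protocol(
            "custom", total_budget=90, phases=[("random", 30, 1), ("exploit", 20, 3)]
        )
        assert p.n_cycles == 4


class TestLabelNoise:
    def test_zero_multiplier_is_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        noisy = add_label_noise(y, pool_sd=1.5, spec=NoiseSpec(0.0, seed=1))
        assert np.array_equal(noisy, y)

    def test_noise_sd_scales_with_pool_sd(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=10000)
        pool_sd = 1.36
        noisy = add_label_noise(y, pool_sd, NoiseSpec(1.0, seed=2))
        assert np.std(noisy - y) == pytest.approx(pool_sd, rel=0.05)
        noisy2 = add_label_noise(y, pool_sd, NoiseSpec(2.0, seed=2))
        assert np.std(noisy2 - y) == pytest.approx(2 * pool_sd, rel=0.05)

    def test_same_seed_same_draw(self):
        y = np.zeros(100)
        a = add_label_noise(y, 1.0, NoiseSpec(2.0, seed=5))
        b = add_label_noise(y, 1.0, NoiseSpec(2.0, seed=5))
        assert np.array_equal(a, b)

    def test_default_grid(self):
        assert DEFAULT_NOISE_GRID == (0.0, 0.5, 1.0, 1.5, 2.0)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(-0.5)


class TestRunCampaign:
    def test_single_random_phase(self, small_pool):
        protocol = build_protocol("init", total_budget=60, phases=[("random", 60, 1)])
        log, traj = run_campaign(small_pool, protocol, FIXED_GP, seed=1)
        assert len(traj) == 1
        assert traj.n_acquired.iloc[0] == 60
        assert len(log.acquired_ids) == 60
        assert not log.truncated

    def test_budget_conservation_and_no_reacquisition(self, small_pool):
        protocol = build_protocol(
            "c", total_budget=100, phases=[("random", 20, 1), ("exploit", 20, 4)]
        )
        log, traj = run_campaign(small_pool, protocol, FIXED_GP, seed=2)
        acquired = log.acquired_ids
        assert len(acquired) == 100
        assert len(set(acquired)) == 100
        assert traj.n_acquired.iloc[-1] == 100

    def test_pool_exhaustion_truncates(self):
        pool = generate_library(
            SyntheticScenario(
                n_compounds=100, n_clusters=4, core_bits_per_cluster=20,
                substituent_bits=15, fingerprint_length=256, seed=3,
            )
        )
        log, traj = run_campaign(pool, build_protocol("random-exploit"), FIXED_GP, seed=1)
        assert log.truncated
        assert len(log.acquired_ids) == 100
        assert traj.n_acquired.iloc[-1] == 100

    def test_recall_trajectory_monotone(self, small_pool):
        protocol = build_protocol(
            "c", total_budget=100, phases=[("random", 20, 1), ("exploit", 10, 8)]
        )
        _, traj = run_campaign(small_pool, protocol, FIXED_GP, seed=3)
        for col in ("recall_top2", "recall_top5", "n_acquired"):
            assert (np.diff(traj[col]) >= -1e-12).all()

    def test_campaign_deterministic_in_seed(self, small_pool):
        protocol = build_protocol(
            "c", total_budget=60, phases=[("random", 20, 1), ("exploit", 20, 2)]
        )
        log1, traj1 = run_campaign(small_pool, protocol, FIXED_GP, seed=9)
        log2, traj2 = run_campaign(small_pool, protocol, FIXED_GP, seed=9)
        assert log1.acquired_ids == log2.acquired_ids
        pd.testing.assert_frame_equal(traj1, traj2)

    def test_perfect_oracle_exploitation_reaches_full_recall(
        self, small_pool, oracle_surrogate_factory
    ):
        """Sanity ceiling: a perfect surrogate plus pure exploitation recovers
        every top-2% compound once the budget covers the active set."""
        protocol = build_protocol(
            "c", total_budget=100, phases=[("random", 20, 1), ("exploit", 20, 4)]
        )
        _, traj = run_campaign(
            small_pool, protocol, oracle_surrogate_factory, seed=4
        )
        assert traj.recall_top2.iloc[-1] == 1.0
        assert traj.recall_top5.iloc[-1] == 1.0

    def test_noisy_labels_used_for_training_truth_for_scoring(self, small_pool):
        """Retrieval metrics are computed against the noiseless top-k sets
        even when training labels are heavily corrupted."""
        protocol = build_protocol("c", total_budget=40, phases=[("random", 40, 1)])
        noise = NoiseSpec(multiplier=2.0)
        log, traj = run_campaign(small_pool, protocol, FIXED_GP, noise=noise, seed=5)
        rec = log.cycles[0]
        idx = {c: i for i, c in enumerate(small_pool.ids)}
        truth = small_pool.potency[[idx[c] for c in rec.acquired_ids]]
        assert not np.allclose(rec.noisy_labels, truth)  # training saw noise
        # the same campaign with noise 0 has the same first random batch, and
        # identical first-cycle recall because scoring ignores label noise
        log0, traj0 = run_campaign(small_pool, protocol, FIXED_GP, seed=5)
        assert log0.cycles[0].acquired_ids == rec.acquired_ids
        assert traj0.recall_top2.iloc[0] == traj.recall_top2.iloc[0]


class TestRepeatCampaigns:
    def test_single_seed_band_is_zero(self, small_pool):
        protocol = build_protocol("c", total_budget=40, phases=[("random", 40, 1)])
        res = repeat_campaigns(small_pool, protocol, FIXED_GP, seeds=[1])
        agg = res.aggregate
        assert (agg["recall_top2_min"] == agg["recall_top2_max"]).all()

    def test_seeds_vary_initial_batch_not_structure(self, small_pool):
        protocol = build_protocol(
            "c", total_budget=60, phases=[("random", 30, 1), ("exploit", 30, 1)]
        )
        res = repeat_campaigns(small_pool, protocol, FIXED_GP, seeds=[1, 2, 3])
        batches = {
            tuple(log.cycles[0].acquired_ids) for log, _ in res.per_seed.values()
        }
        assert len(batches) == 3  # different initial draws
        assert all(len(t) == 2 for _, t in res.per_seed.values())

    def test_rerun_identical(self, small_pool):
        protocol = build_protocol("c", total_budget=40, phases=[("random", 20, 2)])
        a = repeat_campaigns(small_pool, protocol, FIXED_GP, seeds=[1, 2, 3])
        b = repeat_campaigns(small_pool, protocol, FIXED_GP, seeds=[1, 2, 3])
        pd.testing.assert_frame_equal(a.aggregate, b.aggregate)

    def test_requires_a_seed(self, small_pool):
        protocol = build_protocol("c", total_budget=40, phases=[("random", 40, 1)])
        with pytest.raises(ValueError):
            repeat_campaigns(small_pool, protocol, FIXED_GP, seeds=[])


class TestBenchmarkSplit:
    def test_folds_partition_pool(self, small_pool):
        # with train_fraction 0.2 and 5 folds the train sets tile the pool
        n = len(small_pool)
        seen = []
        folds, _ = benchmark_split(small_pool, surrogate_spec=FIXED_GP, seed=0)
        assert len(folds) == 5
        rng = np.random.default_rng(0)
        order = rng.permutation(n)
        train_sets = [set(order[f * 40 : (f + 1) * 40]) for f in range(5)]
        assert set().union(*train_sets) == set(range(n))
        for a in range(5):
            for b in range(a + 1, 5):
                assert not (train_sets[a] & train_sets[b])

    def test_perfect_stub_scores_perfectly(self, small_pool, oracle_surrogate_factory):
        folds, summary = benchmark_split(
            small_pool, surrogate_spec=oracle_surrogate_factory, seed=1
        )
        assert summary["r2"]["mean"] == pytest.approx(1.0)
        assert summary["recall_top2"]["mean"] == pytest.approx(1.0)
        assert summary["rmse"]["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_pool_too_small(self):
        pool = generate_library(
            SyntheticScenario(
                n_compounds=5, n_clusters=2, core_bits_per_cluster=8,
                substituent_bits=8, fingerprint_length=64, seed=1,
            )
        )
        with pytest.raises(ValueError, match=">= 2"):
            benchmark_split(pool, train_fraction=0.2, surrogate_spec=FIXED_GP)


class TestRbfeCost:
    @pytest.mark.parametrize(
        "n,expected", [(5000, 100_000.0), (300, 6_000.0), (0, 0.0)]
    )
    def test_cost_arithmetic(self, n, expected):
        assert rbfe_cost(n) == expected

    def test_custom_rates(self):
        assert rbfe_cost(10, gpu_hours_each=2, rate=1.5) == 30.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rbfe_cost(-1)
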