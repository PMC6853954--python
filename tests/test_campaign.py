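import numpy as np
import pytest

from pathwayopt import (
    CampaignConfig,
    CampaignState,
    DesignPoint,
    MissingResultsError,
    NoiseModel,
    ValidationError,
    batch_size_study,
    benchmark_error_robustness,
    ingest_round,
    make_design_space,
    propose_round,
    random_screen,
    resampled_max_stats,
    run_campaign,
    run_sequential_max_search,
    sample_gmm_landscape,
)
from pathwayopt.landscapes import Observation


@pytest.fixture(scope="module")
def lyco_campaign(unimodal_landscape):
    """The canonical 3-round, batch-46 campaign with the (12,12,12) control."""
    config = CampaignConfig(rounds=3, batch_size=46, replicates=4,
                            control_point=DesignPoint((12, 12, 12)),
                            noise=NoiseModel(0.10), seed=11)
    return run_campaign(unimodal_landscape, config)


class TestRunCampaign:
    def test_three_rounds_touch_136_distinct_designs(self, lyco_campaign):
        # 46 new + (45 new + control) + (45 new + control)
        assert len(lyco_campaign.evaluated) == 136
        assert len(set(lyco_campaign.evaluated)) == 136
        per_round = [sum(1 for o in lyco_campaign.observations
                         if o.round_index == r) for r in range(3)]
        assert per_round == [46, 46, 46]

    def test_control_reevaluated_every_round(self, lyco_campaign):
        control = DesignPoint((12, 12, 12))
        control_rounds = {o.round_index for o in lyco_campaign.observations
                          if o.point == control}
        assert control_rounds == {0, 1, 2}

    def test_best_trajectory_nondecreasing(self, lyco_campaign):
        best = [e["best_mean"] for e in lyco_campaign.best_trajectory]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_deterministic_given_seed(self, unimodal_landscape):
        config = CampaignConfig(rounds=2, batch_size=8, replicates=2,
                                control_point=DesignPoint((12, 12, 12)),
                                noise=NoiseModel(0.10), seed=3)
        s1 = run_campaign(unimodal_landscape, config)
        s2 = run_campaign(unimodal_landscape, config)
        assert s1.to_json() == s2.to_json()

    def test_noiseless_campaign_on_easy_landscape_reaches_max(
            self, unimodal_landscape):
        config = CampaignConfig(rounds=3, batch_size=46, replicates=1,
                                control_point=None, noise=NoiseModel(0.0),
                                seed=1)
        state = run_campaign(unimodal_landscape, config)
        assert state.best_trajectory[-1]["best_mean"] == pytest.approx(
            unimodal_landscape.f_max)

    def test_state_json_roundtrip(self, lyco_campaign):
        restored = CampaignState.from_json(lyco_campaign.to_json())
        assert restored.to_json() == lyco_campaign.to_json()
        assert restored.evaluated == lyco_campaign.evaluated

    def test_campaign_larger_than_space_rejected(self, small_space):
        landscape = sample_gmm_landscape(small_space, seed=0)
        config = CampaignConfig(rounds=3, batch_size=4, replicates=1,
                                control_point=None, seed=0)
        with pytest.raises(ValidationError):
            run_campaign(landscape, config)


class TestLabMode:
    def test_missing_assay_results_block_the_round(self, tiny_cube):
        state = CampaignState(space=tiny_cube)
        config = CampaignConfig(rounds=2, batch_size=5, replicates=1,
                                control_point=None, seed=0)
        proposal = propose_round(state, config)
        partial = [Observation.from_replicates(p, [1.0])
                   for p in proposal.points[:-2]]
        with pytest.raises(MissingResultsError) as err:
            ingest_round(state, partial)
        assert set(err.value.missing) == set(proposal.points[-2:])

    def test_complete_ingestion_advances_round(self, tiny_cube):
        state = CampaignState(space=tiny_cube)
        config = CampaignConfig(rounds=2, batch_size=5, replicates=1,
                                control_point=None, seed=0)
        proposal = propose_round(state, config)
        ingest_round(state, [Observation.from_replicates(p, [1.0, 1.2])
                             for p in proposal.points])
        assert state.round_index == 1
        assert len(state.evaluated) == 5


class TestSequentialSearch:
    def test_exhaustive_cap_always_terminates_with_max(self, tiny_cube):
        landscape = sample_gmm_landscape(tiny_cube, seed=2)
        res = run_sequential_max_search(landscape, NoiseModel(0.0),
                                        cap=tiny_cube.size(), seed=0)
        assert res.found_max
        assert res.n_to_max <= tiny_cube.size()

    def test_cap_one_finds_max_only_if_first_point_is_argmax(self, tiny_cube):
        landscape = sample_gmm_landscape(tiny_cube, seed=2)
        res = run_sequential_max_search(landscape, NoiseModel(0.0), cap=1, seed=0)
        assert res.n_evaluated == 1
        assert res.found_max == (res.evaluated[0] == landscape.argmax)

    def test_deterministic_given_seed(self, tiny_cube):
        landscape = sample_gmm_landscape(tiny_cube, seed=4)
        r1 = run_sequential_max_search(landscape, NoiseModel(0.1), cap=40, seed=9)
        r2 = run_sequential_max_search(landscape, NoiseModel(0.1), cap=40, seed=9)
        assert r1.evaluated == r2.evaluated


@pytest.fixture(scope="module")
def small_benchmark(tiny_cube):
    return benchmark_error_robustness([0.0, 0.2], n_landscapes=4,
                                      cap=tiny_cube.size(), seed=5,
                                      space=tiny_cube)


class TestBenchmark:
    def test_95_percent_criterion_dominates_max_criterion(self, small_benchmark):
        rows = small_benchmark.rows
        assert (rows["pct_95_found"] >= rows["pct_max_found"]).all()
        ok = rows.dropna()
        assert (ok["mean_points_before_95"]
                <= ok["mean_points_before_max"]).all()

    def test_same_seed_reproduces_table(self, tiny_cube, small_benchmark):
        again = benchmark_error_robustness([0.0, 0.2], n_landscapes=4,
                                           cap=tiny_cube.size(), seed=5,
                                           space=tiny_cube)
        assert again.rows.equals(small_benchmark.rows)
        assert again.runs.equals(small_benchmark.runs)

    def test_landscapes_paired_across_rates(self, small_benchmark):
        runs = small_benchmark.runs
        assert set(runs.groupby("error_rate")["landscape"].apply(tuple)) == {
            tuple(range(4))}


class TestBatchSizeStudy:
    def test_exhaustive_batch_takes_one_round(self, tiny_cube):
        table = batch_size_study([tiny_cube.size()], n_landscapes=2,
                                 noise=NoiseModel(0.0), cap=tiny_cube.size(),
                                 seed=0, space=tiny_cube)
        assert (table["mean_rounds_to_95"] <= 1.0).all()

    def test_larger_batches_never_need_more_rounds(self, tiny_cube):
        table = batch_size_study([2, 8, 36], n_landscapes=3,
                                 noise=NoiseModel(0.1), cap=tiny_cube.size(),
                                 seed=1, space=tiny_cube)
        rounds = table.sort_values("batch_size")["mean_rounds_to_95"].to_numpy()
        assert (np.diff(rounds) <= 0).all()


class TestRandomScreen:
    def test_exhaustive_noiseless_screen_finds_max(self, tiny_cube):
        landscape = sample_gmm_landscape(tiny_cube, seed=6)
        out = random_screen(landscape, tiny_cube.size(), NoiseModel(0.0),
                            replicates=1, seed=0)
        assert out["best_true"] == pytest.approx(landscape.f_max)

    def test_seeded_screen_reproducible(self, unimodal_landscape):
        a = random_screen(unimodal_landscape, 136, NoiseModel(0.1), seed=3)
        b = random_screen(unimodal_landscape, 136, NoiseModel(0.1), seed=3)
        assert a["points"] == b["points"]
        assert a["best_mean"] == b["best_mean"]

    def test_campaign_beats_equal_budget_random_screen(self, cube24):
        # paired comparison at the full-campaign budget of 136 designs:
        # the campaign's best true titer should beat the screen's in a
        # statistically decisive majority (sign test, p < 0.01)
        from scipy.stats import binomtest

        wins = losses = 0
        for i in range(30):
            landscape = sample_gmm_landscape(cube24, seed=100 + i)
            config = CampaignConfig(rounds=3, batch_size=46, replicates=4,
                                    control_point=DesignPoint((12, 12, 12)),
                                    noise=NoiseModel(0.10), seed=i)
            state = run_campaign(landscape, config)
            best_true_campaign = max(landscape.value_at(p)
                                     for p in state.evaluated)
            screen = random_screen(landscape, 136, NoiseModel(0.10),
                                   replicates=4, seed=i)
            if best_true_campaign > screen["best_true"]:
                wins += 1
            elif best_true_campaign < screen["best_true"]:
                losses += 1
        result = binomtest(wins, wins + losses, p=0.5, alternative="greater")
        assert result.pvalue < 0.01


class TestResampledMax:
    def test_degenerate_distribution(self):
        out = resampled_max_stats(4.0, 0.0, n_draw=136, reps=50, seed=0)
        assert out == {"mean_of_maxima": 4.0, "sd_of_maxima": 0.0}

    def test_monotone_in_draw_count(self):
        means = [resampled_max_stats(0.0, 1.0, n_draw=n, reps=4000,
                                     seed=1)["mean_of_maxima"]
                 for n in (10, 136, 1000)]
        assert means[0] < means[1] < means[2]

    def test_screen_summary_matches_reported_workflow(self):
        # mean/sd of a screened library in, expected best-of-136 out
        out = resampled_max_stats(2.9, 0.75, n_draw=136, reps=1000, seed=7)
        assert out["mean_of_maxima"] > 2.9
        assert 0 < out["sd_of_maxima"] < 0.75
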