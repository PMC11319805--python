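"""Generator behaviour: sampling rules, generative laws, matrices, dataset I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lookstack import models, spatial, synthetic, variables


class TestSimulateRoster:
    def test_minimal_group(self):
        roster = synthetic.simulate_roster(2, 1, seed=0)
        assert sorted(roster.table["latent_rank"]) == [1, 2]
        assert roster.table["clique_label"].nunique() == 1

    def test_full_group_size(self):
        roster = synthetic.simulate_roster(65, 5, seed=1)
        assert roster.table["individual_id"].nunique() == 65
        assert sorted(roster.table["latent_rank"]) == list(range(1, 66))
        sizes = roster.table["clique_label"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_tolerance_centred_at_zero(self):
        # Monte-Carlo check of the centring: mean over many rosters ~ 0
        means = [
            synthetic.simulate_roster(10, 3, seed=s).table["tolerance_score"].mean()
            for s in range(2000)
        ]
        mc_se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * mc_se + 1e-12

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_roster(1, 1, seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_roster(5, 6, seed=0)


class TestSimulateLandscape:
    def test_layer_kinds_and_ranges(self):
        land = synthetic.simulate_landscape(4, seed=0)
        assert set(land) == {"ud", "leopard_rsf", "encounter_ud", "habitat"}
        for name in ("ud", "leopard_rsf"):
            v = land[name].values
            assert v.shape == (4, 4)
            assert v.min() >= 0.0 and v.max() <= 1.0
        assert np.isfinite(land["encounter_ud"].values).all()
        codes = land["habitat"].values
        assert set(np.unique(codes)) <= set(range(len(spatial.HABITAT_TYPES)))

    def test_continuous_layers_are_smooth(self):
        land = synthetic.simulate_landscape(24, seed=3)
        for name in ("ud", "leopard_rsf"):
            v = land[name].values
            # positive nearest-neighbour correlation = spatial smoothness
            corr = np.corrcoef(v[:-1].ravel(), v[1:].ravel())[0, 1]
            assert corr > 0

    def test_encounter_mass_matches_configuration(self):
        land = synthetic.simulate_landscape(16, seed=5, total_encounters=240.0)
        assert land["encounter_ud"].values.sum() == pytest.approx(240.0, rel=1e-9)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_landscape(3, seed=0)


class TestSimulateFocals:
    def test_sampling_rules_respected(self, roster, landscape):
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1, coefficients={},
            n_individuals=roster.n, n_days=8, focals_per_day=30, seed=9,
        )
        obs = synthetic.simulate_focals(roster, landscape, config)
        frame = synthetic.focals_to_frame(obs)
        per_day = frame.groupby(["date", "individual_id"]).size()
        assert per_day.max() <= 2
        per_period = frame.groupby(["date", "individual_id", "time_period"]).size()
        assert per_period.max() <= 1

    def test_single_individual_day_capped_at_two_distinct_periods(self, landscape):
        pair = synthetic.simulate_roster(2, 1, seed=1)
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1, coefficients={},
            n_individuals=2, n_days=1, focals_per_day=50, seed=2,
        )
        obs = synthetic.simulate_focals(pair, landscape, config)
        frame = synthetic.focals_to_frame(obs)
        counts = frame.groupby("individual_id")["time_period"].agg(["count", "nunique"])
        assert (counts["count"] <= 2).all()
        assert (counts["count"] == counts["nunique"]).all()

    def test_zero_event_rates_give_no_event_everywhere(self, roster, landscape):
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1, coefficients={},
            event_rates={ev: 0.0 for ev in variables.EVENT_TYPES},
            n_individuals=roster.n, n_days=3, focals_per_day=10, seed=4,
        )
        obs = synthetic.simulate_focals(roster, landscape, config)
        for o in obs:
            assert all(v == "no_event" for v in o.event_clock.values())

    def test_ongoing_fraction_matches_renewal_theory(self, landscape):
        # stationary P(ongoing) for Poisson starts with exponential durations
        # is 1 - exp(-rate * mean_duration)  (M/G/infinity occupancy)
        rate_hr, dur_min = 6.0, 3.0
        roster = synthetic.simulate_roster(50, 5, seed=8)
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1, coefficients={},
            event_rates={"male_call": rate_hr},
            event_mean_duration_min=dur_min,
            n_individuals=50, n_days=60, focals_per_day=100, seed=10,
        )
        obs = synthetic.simulate_focals(roster, landscape, config)
        frac = np.mean([o.event_clock["male_call"] == "ongoing" for o in obs])
        expected = 1.0 - np.exp(-(rate_hr / 60.0) * dur_min)
        se = np.sqrt(expected * (1 - expected) / len(obs))
        assert abs(frac - expected) < 4 * se + 0.01

    def test_negative_rate_rejected(self, roster, landscape):
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1, coefficients={},
            n_individuals=roster.n, n_days=1, focals_per_day=5, seed=0,
        )
        config.event_rates["alarm"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            synthetic.simulate_focals(roster, landscape, config)

    def test_determinism(self, roster, landscape, frequency_config):
        a = synthetic.simulate_focals(roster, landscape, frequency_config)
        b = synthetic.simulate_focals(roster, landscape, frequency_config)
        assert synthetic.focals_to_frame(a).equals(synthetic.focals_to_frame(b))


class TestGenerateLooking:
    def _null_study(self, roster, landscape, n_days=40):
        """Intercept-only generative config with all effects silenced."""
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1, coefficients={"Intercept": 0.0},
            re_sd_date=0.0, re_sd_individual=0.0,
            n_individuals=roster.n, n_days=n_days, focals_per_day=30, seed=21,
        )
        obs = synthetic.simulate_focals(roster, landscape, config)
        spec = next(s for s in models.build_model_set("frequency") if s.model_id == 1)
        return obs, spec, config

    def test_poisson_mean_equals_exposure_at_null_coefficients(self, roster, landscape):
        obs, spec, config = self._null_study(roster, landscape)
        obs = [dataclasses.replace(o, in_view_seconds=30.0) for o in obs]
        filled = synthetic.generate_looking(obs, spec, config, roster, landscape)
        counts = np.array([o.n_looks for o in filled])
        # lambda = exp(0 + log 30) = 30
        mc_se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - 30.0) < 3 * mc_se

    def test_exposure_proportionality(self, roster, landscape):
        obs, spec, config = self._null_study(roster, landscape)
        half = [dataclasses.replace(o, in_view_seconds=15.0) for o in obs]
        full = [dataclasses.replace(o, in_view_seconds=30.0) for o in obs]
        m_half = np.mean(
            [o.n_looks for o in synthetic.generate_looking(half, spec, config, roster, landscape)]
        )
        m_full = np.mean(
            [o.n_looks for o in synthetic.generate_looking(full, spec, config, roster, landscape)]
        )
        assert m_full / m_half == pytest.approx(2.0, rel=0.05)

    def test_far_above_cap_means_everything_censored(self, roster, landscape):
        config = synthetic.TrueModelConfig(
            response="duration", model_id=1, coefficients={"Intercept": 100.0},
            sigma=1.0, re_sd_date=0.0, re_sd_individual=0.0,
            n_individuals=roster.n, n_days=2, focals_per_day=10, seed=31,
        )
        obs = synthetic.simulate_focals(roster, landscape, config)
        spec = next(s for s in models.build_model_set("duration") if s.model_id == 1)
        filled = synthetic.generate_looking(obs, spec, config, roster, landscape)
        for o in filled:
            assert o.censored
            assert o.total_look_seconds == pytest.approx(o.in_view_seconds)

    def test_censoring_flag_consistency(self, duration_study):
        for o in duration_study["observations"]:
            at_cap = np.isclose(o.total_look_seconds, o.in_view_seconds)
            assert o.censored == bool(at_cap)

    def test_unknown_coefficient_name_rejected(self, roster, landscape):
        config = synthetic.TrueModelConfig(
            response="frequency", model_id=1,
            coefficients={"not_a_column": 1.0},
            n_individuals=roster.n, n_days=1, focals_per_day=5, seed=0,
        )
        obs = synthetic.simulate_focals(roster, landscape, config)
        spec = next(s for s in models.build_model_set("frequency") if s.model_id == 1)
        with pytest.raises(ValueError, match="not in the design"):
            synthetic.generate_looking(obs, spec, config, roster, landscape)


class TestAgonisticMatrix:
    def test_total_interactions_preserved(self, roster):
        mat = synthetic.simulate_agonistic_matrix(roster, 638, 1.0, seed=0)
        assert mat.sum() == 638

    def test_steep_hierarchy_is_transitive(self, roster):
        mat = synthetic.simulate_agonistic_matrix(roster, 2000, 50.0, seed=1)
        ranking = variables.isi_rank(mat.astype(float), ids=roster.individual_ids)
        assert ranking.I == 0
        # the recovered order is the latent one
        true_order = (
            roster.table.sort_values("latent_rank")["individual_id"].tolist()
        )
        assert ranking.order == true_order

    def test_zero_steepness_gives_fair_coin(self):
        pair = synthetic.simulate_roster(2, 1, seed=5)
        mat = synthetic.simulate_agonistic_matrix(pair, 10000, 0.0, seed=6)
        wins = mat[0, 1]
        total = mat[0, 1] + mat[1, 0]
        se = 0.5 / np.sqrt(total)
        assert abs(wins / total - 0.5) < 4 * se

    def test_win_fraction_monotone_in_rank_gap(self):
        group = synthetic.simulate_roster(6, 1, seed=7)
        mat = synthetic.simulate_agonistic_matrix(group, 30000, 0.5, seed=8)
        ranks = group.table["latent_rank"].to_numpy()
        gaps, fracs = [], []
        for i in range(6):
            for j in range(6):
                if i == j or mat[i, j] + mat[j, i] < 30:
                    continue
                gaps.append(ranks[j] - ranks[i])
                fracs.append(mat[i, j] / (mat[i, j] + mat[j, i]))
        order = np.argsort(gaps)
        # smoothed monotone trend: positive rank correlation
        assert np.corrcoef(np.array(gaps)[order], np.array(fracs)[order])[0, 1] > 0.9


class TestGrooming:
    def test_zero_between_rate_separates_cliques(self):
        roster = synthetic.simulate_roster(12, 3, seed=11)
        W = synthetic.simulate_grooming(roster, 8.0, 0.0, seed=12)
        cliques = roster.table["clique_label"].to_numpy()
        between = W[cliques[:, None] != cliques[None, :]]
        assert between.sum() == 0

    def test_no_structure_when_rates_equal(self):
        import networkx as nx

        roster = synthetic.simulate_roster(12, 3, seed=13)
        W = synthetic.simulate_grooming(roster, 5.0, 5.0, seed=14)
        g = nx.from_numpy_array(W)
        cliques = roster.table["clique_label"].to_numpy()
        parts = [set(np.flatnonzero(cliques == c)) for c in np.unique(cliques)]
        q = nx.community.modularity(g, parts, weight="weight")
        assert abs(q) < 0.1


class TestDatasetIO:
    def test_round_trip_exact(self, tmp_path, roster, landscape, frequency_study,
                              frequency_config):
        obs = frequency_study["observations"][:10]
        agonistic = synthetic.simulate_agonistic_matrix(roster, 100, 1.0, seed=1)
        grooming = synthetic.simulate_grooming(roster, 5.0, 0.5, seed=2)
        synthetic.write_dataset(
            tmp_path / "ds", obs, roster, agonistic, grooming, landscape,
            frequency_config,
        )
        obs2, roster2, ag2, gr2, layers2, config2 = synthetic.read_dataset(
            tmp_path / "ds"
        )
        assert synthetic.focals_to_frame(obs).equals(synthetic.focals_to_frame(obs2))
        assert roster2.table.equals(roster.table)
        assert np.array_equal(ag2, agonistic)
        assert np.array_equal(gr2, grooming)
        for name in landscape:
            a, b = landscape[name].values, layers2[name].values
            assert np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)])
        assert config2 == frequency_config

    def test_empty_observation_list(self, tmp_path, roster, landscape):
        agonistic = synthetic.simulate_agonistic_matrix(roster, 10, 1.0, seed=3)
        grooming = synthetic.simulate_grooming(roster, 5.0, 0.5, seed=4)
        synthetic.write_dataset(
            tmp_path / "empty", [], roster, agonistic, grooming, landscape
        )
        obs2, *_ = synthetic.read_dataset(tmp_path / "empty")
        assert obs2 == []
        header = (tmp_path / "empty" / "focals.csv").read_text().splitlines()[0]
        assert "individual_id" in header
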