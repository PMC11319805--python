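"""Hypothesis-set audit, design expansion, likelihood and prior correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from lookstack import models


class TestBuildModelSet:
    @pytest.mark.parametrize("response", ["frequency", "duration"])
    def test_exactly_21_models(self, response):
        specs = models.build_model_set(response)
        assert [s.model_id for s in specs] == list(range(1, 22))

    def test_model_1_is_intercept_only(self):
        spec = models.build_model_set("frequency")[0]
        assert spec.fixed_terms == [] and spec.interactions == []
        table = pd.DataFrame(
            {"n_looks": [1, 2], "in_view_seconds": [30.0, 28.0],
             "date": ["a", "b"], "individual_id": ["x", "y"]}
        )
        design = models.build_design(spec, table)
        assert design.column_names == ["Intercept"]

    def test_minimal_model_terms(self):
        spec = models.build_model_set("frequency")[1]
        assert spec.fixed_terms == ["age_sex", "behaviour"]
        assert spec.resolved_terms() == ["age_sex", "engaged_time"]

    def test_behaviour_slot_binds_per_response(self):
        freq = models.build_model_set("frequency")[1]
        dur = models.build_model_set("duration")[1]
        assert "engaged_time" in freq.resolved_terms()
        assert "not_engaged_time" in dur.resolved_terms()

    def test_observer_model_interaction_structure(self):
        spec = models.build_model_set("frequency")[20]
        assert spec.model_id == 21
        assert set(spec.interactions) == {
            ("tolerance", "observer_distance"),
            ("tolerance", "observer_moved"),
            ("tolerance", "behaviour"),
        }

    def test_risk_models_interact_with_cohesion_position_behaviour(self):
        for spec in models.build_model_set("duration")[15:20]:
            risk = spec.fixed_terms[0]
            assert set(spec.interactions) == {
                (risk, "n_neighbours"),
                (risk, "spatial_position"),
                (risk, "behaviour"),
            }
            assert {"visibility", "rank", "age_sex"} <= set(spec.fixed_terms)

    def test_no_risk_model_mixes_risk_types(self):
        risk_terms = {
            "leopard_rsf", "habitat", "inverted_ud", "familiarity_class",
            "encounter_risk",
        }
        for spec in models.build_model_set("frequency"):
            present = risk_terms & set(spec.fixed_terms)
            assert len(present) <= 1

    def test_every_model_but_1_and_5_carries_age_sex_and_behaviour(self):
        for spec in models.build_model_set("frequency"):
            if spec.model_id == 1:
                continue
            assert "age_sex" in spec.fixed_terms
            if spec.model_id != 5:
                assert "behaviour" in spec.fixed_terms

    def test_resting_excluded_from_specific_behaviours(self):
        spec = models.build_model_set("duration")[4]
        assert "beh_rest" not in spec.fixed_terms
        resting = models.resting_only_spec("duration")
        assert resting.fixed_terms == ["beh_rest", "age_sex"]

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            models.build_model_set("count")

    def test_serialisation_round_trip(self, tmp_path):
        specs = models.build_model_set("duration")
        p = tmp_path / "models.yaml"
        models.save_model_set(specs, p)
        back = models.load_model_set(p)
        for a, b in zip(specs, back):
            assert a.model_id == b.model_id
            assert a.fixed_terms == b.fixed_terms
            assert a.interactions == b.interactions
            assert a.family == b.family


class TestBuildDesign:
    def _table(self, n=3):
        return pd.DataFrame(
            {
                "n_looks": np.arange(n),
                "total_look_seconds": np.linspace(1, 5, n),
                "censored": [False] * n,
                "in_view_seconds": np.full(n, 28.0),
                "date": [f"d{i % 2}" for i in range(n)],
                "individual_id": [f"i{i}" for i in range(n)],
                "age_sex": ["adult-male", "adult-female", "adult-female"][:n],
                "engaged_time": np.linspace(0, 10, n),
                "not_engaged_time": np.linspace(10, 0, n),
            }
        )

    def test_two_class_minimal_design_has_three_columns(self):
        spec = models.build_model_set("frequency")[1]
        design = models.build_design(spec, self._table())
        # intercept + 1 observed age-sex dummy... treatment coding keeps all
        # non-reference levels regardless of observation
        assert "Intercept" in design.column_names
        assert "age_sex[adult-female]" in design.column_names
        assert "engaged_time" in design.column_names

    def test_factor_by_continuous_interaction_adds_level_products(self):
        table = self._table()
        table["leopard_rsf"] = [0.2, 0.4, 0.9]
        table["spatial_position"] = ["central", "peripheral", "central"]
        table["n_neighbours"] = [1, 2, 3]
        table["visibility"] = [50.0, 60.0, 70.0]
        table["rank"] = [1, 2, 3]
        spec = models.build_model_set("frequency")[15]
        design = models.build_design(spec, table)
        assert "leopard_rsf:spatial_position[peripheral]" in design.column_names
        assert "leopard_rsf:n_neighbours" in design.column_names
        assert "leopard_rsf:engaged_time" in design.column_names

    def test_within_group_threat_design_matches_hand_built_matrix(self):
        # five focals, model 15, written out by hand
        table = pd.DataFrame(
            {
                "n_looks": [3, 1, 4, 0, 2],
                "in_view_seconds": [30.0, 28.0, 29.0, 30.0, 27.0],
                "date": ["d1", "d1", "d2", "d2", "d2"],
                "individual_id": ["a", "b", "a", "c", "b"],
                "n_social_threats": [0, 2, 1, 0, 3],
                "age_sex": [
                    "adult-male", "adult-female", "adult-male",
                    "juvenile", "adult-female",
                ],
                "engaged_time": [5.0, 0.0, 12.0, 3.0, 8.0],
                "visibility": [80.0, 55.0, 60.0, 90.0, 75.0],
                "rank": [2, 5, 2, 9, 5],
                "n_neighbours": [1, 4, 2, 0, 5],
            }
        )
        spec = models.build_model_set("frequency")[14]
        assert spec.model_id == 15
        design = models.build_design(spec, table)
        expected = np.array(
            [
                # Int, threats, AF, sub, juv, engaged, vis, rank, neigh
                [1, 0, 0, 0, 0, 5.0, 80.0, 2, 1],
                [1, 2, 1, 0, 0, 0.0, 55.0, 5, 4],
                [1, 1, 0, 0, 0, 12.0, 60.0, 2, 2],
                [1, 0, 0, 0, 1, 3.0, 90.0, 9, 0],
                [1, 3, 1, 0, 0, 8.0, 75.0, 5, 5],
            ],
            dtype=float,
        )
        assert design.column_names == [
            "Intercept", "n_social_threats", "age_sex[adult-female]",
            "age_sex[subadult]", "age_sex[juvenile]", "engaged_time",
            "visibility", "rank", "n_neighbours",
        ]
        assert np.array_equal(design.X.to_numpy(), expected)
        assert np.array_equal(design.group_index_date, [0, 0, 1, 1, 1])

    def test_missing_column_named_in_error(self):
        spec = models.build_model_set("frequency")[14]
        with pytest.raises(ValueError, match="n_social_threats"):
            models.build_design(spec, self._table())

    def test_variables_enter_raw(self):
        table = self._table()
        spec = models.build_model_set("frequency")[1]
        design = models.build_design(spec, table)
        assert np.array_equal(
            design.X["engaged_time"].to_numpy(), table["engaged_time"].to_numpy()
        )


class TestLoglikFrequency:
    def test_zero_count_closed_form(self):
        # y=0, eta=0, exposure 1 -> log P = -lambda = -1
        assert models.loglik_frequency(0, 0.0, 1.0) == pytest.approx(-1.0)

    def test_offset_law(self):
        # doubling the exposure adds log 2 to log lambda
        base = models.loglik_frequency(3, 0.5, 10.0)
        direct = stats.poisson.logpmf(3, np.exp(0.5 + np.log(20.0)))
        assert models.loglik_frequency(3, 0.5, 20.0) == pytest.approx(direct)
        assert base == pytest.approx(stats.poisson.logpmf(3, np.exp(0.5) * 10))

    def test_tail_sums_to_one(self):
        for eta, v in [(-1.0, 30.0), (0.3, 12.0), (1.0, 5.0)]:
            y = np.arange(0, 2000)
            total = np.exp(models.loglik_frequency(y, eta, v)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(ValueError):
            models.loglik_frequency(1, 0.0, 0.0)


class TestLoglikDuration:
    def test_half_normal_closed_form(self):
        # mu=0, sigma=1, huge cap, y=0: density 2 phi(0)
        out = models.loglik_duration(0.0, False, 0.0, 1.0, 1e9)
        assert out == pytest.approx(np.log(2.0 / np.sqrt(2 * np.pi)))

    def test_censor_probability_approaches_one_when_mu_far_above_cap(self):
        out = models.loglik_duration(30.0, True, 300.0, 5.0, 30.0)
        assert out == pytest.approx(0.0, abs=1e-8)

    def test_density_plus_censor_mass_normalises(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            mu = rng.uniform(-10, 40)
            sigma = rng.uniform(0.5, 10)
            cap = rng.uniform(5, 35)
            dens, _ = integrate.quad(
                lambda y: np.exp(models.loglik_duration(y, False, mu, sigma, cap)),
                0.0, cap, limit=200,
            )
            censor = np.exp(models.loglik_duration(cap, True, mu, sigma, cap))
            assert dens + censor == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_mu_for_censored_record(self):
        mus = np.linspace(-5, 40, 50)
        vals = models.loglik_duration(
            np.full_like(mus, 25.0), np.ones_like(mus, dtype=bool), mus, 4.0, 25.0
        )
        assert np.all(np.diff(vals) > 0)

    def test_inconsistent_censor_flag_rejected(self):
        with pytest.raises(ValueError, match="at the cap"):
            models.loglik_duration(10.0, True, 5.0, 2.0, 30.0)
        with pytest.raises(ValueError, match="exceeds"):
            models.loglik_duration(31.0, False, 5.0, 2.0, 30.0)


class TestPriors:
    def test_student_t_closed_form_at_zero(self):
        expected = float(
            gammaln(2.0) - gammaln(1.5) - 0.5 * np.log(3 * np.pi) - np.log(10.0)
        )
        assert models.student_t_logpdf(0.0, 3.0, 0.0, 10.0) == pytest.approx(expected)

    def test_half_t_negative_is_minus_inf(self):
        assert models.half_student_t_logpdf(-0.1, 3.0, 10.0) == -np.inf

    def test_priors_integrate_to_one(self):
        t_mass, _ = integrate.quad(
            lambda x: np.exp(models.student_t_logpdf(x, 3.0, 0.0, 10.0)),
            -np.inf, np.inf,
        )
        ht_mass, _ = integrate.quad(
            lambda x: np.exp(models.half_student_t_logpdf(x, 3.0, 10.0)), 0, np.inf
        )
        assert t_mass == pytest.approx(1.0, abs=1e-8)
        assert ht_mass == pytest.approx(1.0, abs=1e-8)

    def test_joint_prior_rejects_nonpositive_scales(self):
        spec = models.PriorSpec()
        assert models.log_prior([0.0], [0.5], spec, sigma=-1.0) == -np.inf
        assert np.isfinite(models.log_prior([0.0], [0.5], spec, sigma=2.0))
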