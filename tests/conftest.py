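"""Shared fixtures: one small simulated study reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from lookstack import inference, models, pipeline, synthetic, variables

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def roster():
    return synthetic.simulate_roster(10, 3, seed=101)


@pytest.fixture(scope="session")
def landscape():
    return synthetic.simulate_landscape(16, seed=202)


@pytest.fixture(scope="session")
def frequency_config():
    return synthetic.TrueModelConfig(
        response="frequency",
        model_id=4,
        coefficients={
            "Intercept": -1.8,
            "amount_eaten": 0.08,
            "food_item[seeds]": 0.5,
            "engaged_time": -0.02,
        },
        re_sd_date=0.15,
        re_sd_individual=0.15,
        n_individuals=10,
        n_days=10,
        focals_per_day=20,
        seed=303,
    )


@pytest.fixture(scope="session")
def frequency_study(roster, landscape, frequency_config):
    """Simulated focals with frequency responses plus the analysis table."""
    spec = next(
        s for s in models.build_model_set("frequency") if s.model_id == 4
    )
    observations = synthetic.simulate_focals(roster, landscape, frequency_config)
    observations = synthetic.generate_looking(
        observations, spec, frequency_config, roster, landscape
    )
    table = variables.build_analysis_table(
        observations,
        roster,
        rank_map=roster.rank_map(),
        clique_map=roster.clique_map(),
        layers=landscape,
    )
    return {"observations": observations, "table": table, "spec": spec}


@pytest.fixture(scope="session")
def duration_study(roster, landscape):
    config = synthetic.TrueModelConfig(
        response="duration",
        model_id=15,
        coefficients={
            "Intercept": -20.0,
            "n_social_threats": 2.5,
            "not_engaged_time": 0.15,
        },
        sigma=5.0,
        re_sd_date=0.15,
        re_sd_individual=0.15,
        n_individuals=10,
        n_days=10,
        focals_per_day=20,
        seed=404,
    )
    spec = next(s for s in models.build_model_set("duration") if s.model_id == 15)
    observations = synthetic.simulate_focals(roster, landscape, config)
    observations = synthetic.generate_looking(
        observations, spec, config, roster, landscape
    )
    table = variables.build_analysis_table(
        observations,
        roster,
        rank_map=roster.rank_map(),
        clique_map=roster.clique_map(),
        layers=landscape,
    )
    return {"observations": observations, "table": table, "spec": spec, "config": config}


@pytest.fixture(scope="session")
def poisson_slope_table():
    """Tiny single-group Poisson dataset with a known intercept and slope."""
    rng = np.random.default_rng(11)
    n = 30
    x = rng.uniform(0, 5, size=n)
    in_view = rng.uniform(25, 30, size=n)
    y = rng.poisson(np.exp(-1.5 + 0.3 * x) * in_view)
    import pandas as pd

    return pd.DataFrame(
        {
            "amount_eaten": x,
            "n_looks": y,
            "in_view_seconds": in_view,
            "date": "D001",
            "individual_id": "ID001",
        }
    )


@pytest.fixture(scope="session")
def poisson_slope_spec():
    return models.ModelSpec(
        model_id=0,
        response="frequency",
        fixed_terms=["amount_eaten"],
        include_random_effects=False,
    )


@pytest.fixture(scope="session")
def poisson_slope_fit(poisson_slope_table, poisson_slope_spec):
    settings = inference.FitSettings(chains=4, iterations=1000, warmup=500, seed=5)
    return inference.fit(poisson_slope_spec, poisson_slope_table, settings)


@pytest.fixture()
def tiny_pipeline_config(tmp_path):
    return pipeline.PipelineConfig(
        seed=3,
        responses=("frequency",),
        model_ids=(1, 2, 4),
        synthetic=pipeline.SyntheticConfig(
            n_individuals=6,
            n_days=5,
            focals_per_day=10,
            grid_n=12,
            true_response="frequency",
            true_model_id=4,
            coefficients={"Intercept": -1.8, "amount_eaten": 0.1},
        ),
        chains=4,
        iterations=600,
        warmup=300,
        output_dir=str(tmp_path / "out"),
    )
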