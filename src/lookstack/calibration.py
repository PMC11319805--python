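"""Simulation-based calibration experiments.

These experiments close the loop on the whole pipeline: data are simulated
from a known generative model, the hypothesis set is fitted and stacked, and
the outcome is checked against the truth — does the generating model win the
stack, and do the credible intervals cover the generating coefficients at
their nominal rate?
"""

from __future__ import annotations

import dataclasses

import numpy as np

from lookstack import inference, loo, models, stacking, synthetic, variables

#: strong-effect generative settings for the feeding-rate hypothesis
#: (frequency response): feeding rate and food items drive looking bouts
FREQUENCY_TRUTH = {
    "model_id": 4,
    "coefficients": {
        "Intercept": -1.8,
        "amount_eaten": 0.12,
        "food_item[seeds]": 0.6,
        "food_item[fruit]": -0.4,
        "engaged_time": -0.04,
    },
}

#: strong-effect generative settings for the within-group-threat hypothesis
#: (duration response): social threats lengthen looking
DURATION_TRUTH = {
    "model_id": 15,
    "coefficients": {
        "Intercept": -21.0,
        "n_social_threats": 3.0,
        "n_neighbours": -0.8,
        "not_engaged_time": 0.25,
    },
    "sigma": 5.0,
}


def _true_config(response: str, seed: int, n_individuals: int, n_days: int,
                 focals_per_day: int) -> synthetic.TrueModelConfig:
    truth = FREQUENCY_TRUTH if response == "frequency" else DURATION_TRUTH
    return synthetic.TrueModelConfig(
        response=response,
        model_id=truth["model_id"],
        coefficients=dict(truth["coefficients"]),
        sigma=truth.get("sigma", 4.0),
        re_sd_date=0.15,
        re_sd_individual=0.15,
        n_individuals=n_individuals,
        n_days=n_days,
        focals_per_day=focals_per_day,
        seed=seed,
    )


def simulate_study(response: str, seed: int, n_individuals: int = 15,
                   n_days: int = 10, focals_per_day: int = 30):
    """One simulated study: focal table with responses from the true model."""
    config = _true_config(response, seed, n_individuals, n_days, focals_per_day)
    roster = synthetic.simulate_roster(n_individuals, 3, seed=seed + 7919)
    landscape = synthetic.simulate_landscape(16, seed=seed + 104729)
    spec = next(
        s for s in models.build_model_set(response) if s.model_id == config.model_id
    )
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
    return table, spec, config


def recovery_replicate(
    response: str,
    seed: int,
    settings: inference.FitSettings | None = None,
    n_individuals: int = 15,
    n_days: int = 10,
    focals_per_day: int = 30,
) -> dict:
    """Fit {true model, intercept, minimal} and stack; did the truth win?

    Returns the stacked weights keyed by model id and a ``recovered`` flag.
    """
    settings = settings or inference.FitSettings(
        chains=2, iterations=1500, warmup=750, seed=seed
    )
    table, true_spec, config = simulate_study(
        response, seed, n_individuals, n_days, focals_per_day
    )
    candidate_ids = [config.model_id, 1, 2]
    specs = [
        s for s in models.build_model_set(response) if s.model_id in candidate_ids
    ]
    loos, ids = [], []
    for spec in specs:
        sub = dataclasses.replace(settings, seed=settings.seed + spec.model_id)
        fit = inference.fit(spec, table, sub)
        loos.append(loo.psis_loo(inference.pointwise_loglik(fit)))
        ids.append(spec.model_id)
    stack = stacking.stacking_weights(loos, model_ids=ids, seed=seed)
    weights = dict(zip(ids, stack.weights))
    top = max(weights, key=weights.get)
    return {
        "weights": weights,
        "top_model": top,
        "recovered": top == config.model_id,
        "n": len(table),
    }


def coverage_replicate(
    response: str,
    seed: int,
    settings: inference.FitSettings | None = None,
    n_individuals: int = 15,
    n_days: int = 10,
    focals_per_day: int = 30,
) -> dict:
    """Fit the generating model; which 95% intervals cover the truth?"""
    settings = settings or inference.FitSettings(
        chains=4, iterations=3000, warmup=1500, seed=seed
    )
    table, true_spec, config = simulate_study(
        response, seed, n_individuals, n_days, focals_per_day
    )
    fit = inference.fit(true_spec, table, dataclasses.replace(settings, seed=seed))
    covered = {}
    for name, truth in config.coefficients.items():
        lo, hi = inference.credible_interval(fit, name)
        covered[name] = bool(lo <= truth <= hi)
    return {"covered": covered, "n": len(table)}
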