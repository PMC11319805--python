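"""The 21-model hypothesis set: specifications, designs, likelihoods, priors.

Each hypothesis about what drives looking is one model.  Frequency models are
Poisson with a log link and a log in-view-time offset; duration models are
Gaussian with an identity link, truncated below at zero and right-censored at
the in-view time, with the untransformed in-view time entering the linear
predictor as a unit-coefficient offset.  All models except the intercept-only
one carry age-sex class and a behaviour covariate (engaged time for
frequency, not-engaged time for duration), and all carry crossed
date x individual random intercepts.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats

from lookstack import variables

FAMILIES = ("poisson_log", "censored_truncated_normal_identity")
RESPONSES = ("frequency", "duration")


# ---------------------------------------------------------------------------
# Term registry: how each named term expands into design columns

#: categorical terms with fixed level orderings; first level is the reference
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_sex": variables.AGE_SEX_CLASSES,
    "spatial_position": variables.SPATIAL_POSITIONS,
    "habitat": ("forest", "woodland", "bush", "grassland", "rock", "camps", "farms", "roads"),
    "familiarity_class": ("core", "frequent", "boundary"),
    "food_item": variables.FOOD_ITEMS,
    **{f"ts_{ev}": variables.TIME_SINCE_LEVELS for ev in variables.EVENT_TYPES},
}

#: numeric (continuous or 0/1) terms that map straight to one column
NUMERIC_TERMS = (
    "n_neighbours",
    "visibility",
    "rank",
    "amount_eaten",
    "observer_distance",
    "observer_moved",
    "tolerance",
    "leopard_rsf",
    "inverted_ud",
    "encounter_risk",
    "n_social_threats",
    "engaged_time",
    "not_engaged_time",
) + tuple(f"beh_{b}" for b in variables.BEHAVIOUR_VOCABULARY)


@dataclasses.dataclass
class PriorSpec:
    """Weakly informative default priors.

    Location parameters get Student-t(3, 0, 10); random-effect standard
    deviations and the residual sigma get half-Student-t(3, 0, 10).
    """

    coef_df: float = 3.0
    coef_loc: float = 0.0
    coef_scale: float = 10.0
    sd_df: float = 3.0
    sd_scale: float = 10.0


@dataclasses.dataclass
class ModelSpec:
    """One hypothesis model: response family, fixed terms, interactions."""

    model_id: int
    response: str
    fixed_terms: list[str]
    interactions: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    label: str = ""
    family: str = ""
    offset_name: str = "in_view_seconds"
    priors: PriorSpec = dataclasses.field(default_factory=PriorSpec)
    include_random_effects: bool = True

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if not self.family:
            self.family = (
                "poisson_log"
                if self.response == "frequency"
                else "censored_truncated_normal_identity"
            )

    @property
    def response_column(self) -> str:
        return "n_looks" if self.response == "frequency" else "total_look_seconds"

    def resolved_terms(self) -> list[str]:
        """Fixed terms with the generic 'behaviour' slot bound to this response."""
        behaviour = "engaged_time" if self.response == "frequency" else "not_engaged_time"
        return [behaviour if t == "behaviour" else t for t in self.fixed_terms]

    def resolved_interactions(self) -> list[tuple[str, str]]:
        behaviour = "engaged_time" if self.response == "frequency" else "not_engaged_time"
        return [
            tuple(behaviour if t == "behaviour" else t for t in pair)
            for pair in self.interactions
        ]


# ---------------------------------------------------------------------------
# The hypothesis set

_SPECIFIC_BEHAVIOURS = [
    "beh_biting",
    "beh_dig",
    "beh_handling",
    "beh_pick",
    "beh_search_substrate",
    "beh_groom_other",
    "beh_self_groom",
    "beh_receive_groom",
    "beh_chew",
    "beh_self_scratch",
    "beh_movement",
    "beh_posture",
]

_RISK_INTERACTION_PARTNERS = ["n_neighbours", "spatial_position", "behaviour"]


def _risk_model(model_id: int, risk_term: str, label: str) -> dict:
    return dict(
        model_id=model_id,
        fixed_terms=[risk_term, "n_neighbours", "spatial_position", "behaviour",
                     "visibility", "rank", "age_sex"],
        interactions=[(risk_term, p) for p in _RISK_INTERACTION_PARTNERS],
        label=label,
    )


_MODEL_TABLE: list[dict] = [
    dict(model_id=1, fixed_terms=[], label="intercept only"),
    dict(model_id=2, fixed_terms=["age_sex", "behaviour"], label="minimal"),
    dict(
        model_id=3,
        fixed_terms=["n_neighbours", "spatial_position", "age_sex", "behaviour"],
        interactions=[("n_neighbours", "spatial_position")],
        label="group geometry and cohesion",
    ),
    dict(
        model_id=4,
        fixed_terms=["amount_eaten", "food_item", "behaviour", "age_sex"],
        label="feeding rate and food items",
    ),
    dict(
        model_id=5,
        fixed_terms=_SPECIFIC_BEHAVIOURS + ["age_sex"],
        label="specific behaviours",
    ),
    dict(
        model_id=6,
        fixed_terms=["ts_aggression", "age_sex", "behaviour", "visibility", "rank"],
        label="time since within-group aggression",
    ),
    dict(
        model_id=7,
        fixed_terms=["ts_mating", "age_sex", "behaviour"],
        label="time since mating",
    ),
    dict(
        model_id=8,
        fixed_terms=["ts_female_call", "age_sex", "behaviour"],
        label="time since adult female calls",
    ),
    dict(
        model_id=9,
        fixed_terms=["ts_male_call", "age_sex", "behaviour", "visibility", "rank"],
        label="time since male calls (wahoos)",
    ),
    dict(
        model_id=10,
        fixed_terms=["ts_active_hetero", "age_sex", "behaviour", "visibility", "rank"],
        label="time since active heterospecific encounter",
    ),
    dict(
        model_id=11,
        fixed_terms=["ts_passive_hetero", "age_sex", "behaviour"],
        label="time since passive heterospecific encounter",
    ),
    dict(
        model_id=12,
        fixed_terms=["ts_dog", "age_sex", "behaviour", "visibility",
                     "spatial_position", "n_neighbours"],
        label="time since dog encounter",
    ),
    dict(
        model_id=13,
        fixed_terms=["ts_alarm", "age_sex", "behaviour", "visibility",
                     "spatial_position", "n_neighbours"],
        label="time since alarm",
    ),
    dict(
        model_id=14,
        fixed_terms=["ts_group_encounter", "age_sex", "behaviour", "visibility",
                     "spatial_position", "rank", "n_neighbours"],
        label="time since extra-group encounter",
    ),
    dict(
        model_id=15,
        fixed_terms=["n_social_threats", "age_sex", "behaviour", "visibility",
                     "rank", "n_neighbours"],
        label="within-group threats",
    ),
    _risk_model(16, "leopard_rsf", "leopard encounter risk"),
    _risk_model(17, "habitat", "habitat type"),
    _risk_model(18, "inverted_ud", "continuous landscape familiarity"),
    _risk_model(19, "familiarity_class", "categorical landscape familiarity"),
    _risk_model(20, "encounter_risk", "spatial risk of extra-group encounter"),
    dict(
        model_id=21,
        fixed_terms=["tolerance", "observer_distance", "observer_moved",
                     "behaviour", "age_sex"],
        interactions=[("tolerance", "observer_distance"),
                      ("tolerance", "observer_moved"),
                      ("tolerance", "behaviour")],
        label="observer tolerance",
    ),
]


def build_model_set(response: str, priors: PriorSpec | None = None) -> list[ModelSpec]:
    """The full 21-model hypothesis set for one response variable."""
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    priors = priors or PriorSpec()
    specs = [
        ModelSpec(response=response, priors=priors, **row) for row in _MODEL_TABLE
    ]
    assert len(specs) == 21
    return specs


def resting_only_spec(response: str) -> ModelSpec:
    """The separate resting-time model (resting is collinear inside model 5)."""
    return ModelSpec(model_id=5, response=response,
                     fixed_terms=["beh_rest", "age_sex"], label="resting only")


# ---------------------------------------------------------------------------
# Design matrices

@dataclasses.dataclass
class DesignMatrix:
    """Expanded fixed-effects design plus grouping indices for one model."""

    X: pd.DataFrame
    y: np.ndarray
    offset: np.ndarray
    group_index_date: np.ndarray
    group_index_individual: np.ndarray
    date_levels: list
    individual_levels: list
    censored: np.ndarray | None = None

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)


def _expand_term(term: str, table: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded columns for one term (raw values, never centred)."""
    if term in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[term]
        observedlevels = set(table[term].unique())
        unknown = observedlevels - set(levels)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for term {term!r}")
        cols = {}
        for level in levels[1:]:  # first level is the reference
            cols[f"{term}[{level}]"] = (table[term] == level).astype(float).to_numpy()
        return pd.DataFrame(cols, index=table.index)
    if term in NUMERIC_TERMS:
        vals = table[term]
        if vals.dtype == bool:
            vals = vals.astype(float)
        return pd.DataFrame({term: vals.astype(float).to_numpy()}, index=table.index)
    raise ValueError(f"unknown model term {term!r}")


def build_design(spec: ModelSpec, table: pd.DataFrame) -> DesignMatrix:
    """Expand a model specification against the analysis table.

    Variables enter raw (uncentred, unscaled); categorical terms are
    treatment-coded against fixed reference levels; interaction columns are
    cellwise products of the expanded main-effect columns.
    """
    terms = spec.resolved_terms()
    missing = [t for t in terms if t not in table.columns]
    if missing:
        raise ValueError(f"analysis table is missing term column(s): {missing}")

    blocks: dict[str, pd.DataFrame] = {}
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for term in terms:
        block = _expand_term(term, table)
        blocks[term] = block
        X = pd.concat([X, block], axis=1)
    for a, b in spec.resolved_interactions():
        for ca in blocks[a].columns:
            for cb in blocks[b].columns:
                X[f"{ca}:{cb}"] = blocks[a][ca] * blocks[b][cb]

    date_levels = sorted(table["date"].unique().tolist())
    ind_levels = sorted(table["individual_id"].unique().tolist())
    date_idx = table["date"].map({d: i for i, d in enumerate(date_levels)}).to_numpy()
    ind_idx = (
        table["individual_id"].map({d: i for i, d in enumerate(ind_levels)}).to_numpy()
    )

    censored = None
    if spec.response == "duration":
        censored = table["censored"].to_numpy(dtype=bool)
    return DesignMatrix(
        X=X,
        y=table[spec.response_column].to_numpy(dtype=float),
        offset=table[spec.offset_name].to_numpy(dtype=float),
        group_index_date=date_idx,
        group_index_individual=ind_idx,
        date_levels=date_levels,
        individual_levels=ind_levels,
        censored=censored,
    )


# ---------------------------------------------------------------------------
# Likelihoods

def loglik_frequency(y, linear_predictor, in_view) -> np.ndarray:
    """Poisson log-density with log link and log-exposure offset.

    lambda = exp(linear_predictor + ln in_view); broadcasting follows numpy.
    """
    y = np.asarray(y, dtype=float)
    in_view = np.asarray(in_view, dtype=float)
    if np.any(in_view <= 0):
        raise ValueError("in-view exposure must be positive")
    log_lam = np.asarray(linear_predictor, dtype=float) + np.log(in_view)
    return y * log_lam - np.exp(log_lam) - special.gammaln(y + 1.0)


def loglik_duration(y, censored, mu, sigma, cap) -> np.ndarray:
    """Censored, zero-truncated Gaussian log-density on the identity link.

    The latent looking duration is Normal(mu, sigma) truncated below at 0;
    recorded values are right-censored at the in-view time ``cap``.  Both the
    censored mass and the density share the lower-truncation normaliser
    P(latent > 0) = Phi(mu / sigma).
    """
    y = np.asarray(y, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    cap = np.asarray(cap, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(y > cap + 1e-9):
        raise ValueError("recorded duration exceeds the in-view cap")
    if np.any(censored & ~np.isclose(y, np.broadcast_to(cap, y.shape))):
        raise ValueError("censored records must sit exactly at the cap")

    log_norm = special.log_ndtr(mu / sigma)  # log P(latent > 0)
    z = (y - mu) / sigma
    log_density = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma) - log_norm
    log_censor = special.log_ndtr(-(cap - mu) / sigma) - log_norm
    return np.where(censored, log_censor, log_density)


# ---------------------------------------------------------------------------
# Priors

def student_t_logpdf(x, df: float, loc: float, scale: float) -> np.ndarray:
    return stats.t.logpdf(np.asarray(x, dtype=float), df, loc=loc, scale=scale)


def half_student_t_logpdf(x, df: float, scale: float) -> np.ndarray:
    """Half-Student-t density on the positive reals; -inf outside."""
    x = np.asarray(x, dtype=float)
    out = np.log(2.0) + stats.t.logpdf(x, df, loc=0.0, scale=scale)
    return np.where(x > 0, out, -np.inf)


def log_prior(
    coefficients,
    sds,
    spec: PriorSpec,
    sigma: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Joint log-prior: Student-t on coefficients, half-t on scale parameters."""
    p = spec
    total = np.sum(
        student_t_logpdf(coefficients, p.coef_df, p.coef_loc, p.coef_scale), axis=-1
    )
    total = total + np.sum(half_student_t_logpdf(sds, p.sd_df, p.sd_scale), axis=-1)
    if sigma is not None:
        total = total + half_student_t_logpdf(sigma, p.sd_df, p.sd_scale)
    return total


# ---------------------------------------------------------------------------
# Serialisation

def model_set_to_dict(specs: list[ModelSpec]) -> list[dict]:
    out = []
    for s in specs:
        out.append(
            dict(
                model_id=s.model_id,
                response=s.response,
                fixed_terms=list(s.fixed_terms),
                interactions=[list(p) for p in s.interactions],
                label=s.label,
                family=s.family,
                offset_name=s.offset_name,
                include_random_effects=s.include_random_effects,
            )
        )
    return out


def model_set_from_dict(rows: list[dict]) -> list[ModelSpec]:
    return [
        ModelSpec(
            model_id=r["model_id"],
            response=r["response"],
            fixed_terms=list(r["fixed_terms"]),
            interactions=[tuple(p) for p in r.get("interactions", [])],
            label=r.get("label", ""),
            family=r.get("family", ""),
            offset_name=r.get("offset_name", "in_view_seconds"),
            include_random_effects=r.get("include_random_effects", True),
        )
        for r in rows
    ]


def save_model_set(specs: list[ModelSpec], path) -> None:
    text = yaml.safe_dump(model_set_to_dict(specs), sort_keys=False)
    with open(path, "w") as fh:
        fh.write(text)


def load_model_set(path) -> list[ModelSpec]:
    with open(path) as fh:
        if str(path).endswith(".json"):
            rows = json.load(fh)
        else:
            rows = yaml.safe_load(fh)
    return model_set_from_dict(rows)
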