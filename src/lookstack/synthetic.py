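"""Seeded synthetic focal-sampling datasets with known generative structure.

The generator emulates the statistical structure the analysis assumes: 30-s
focal observations with variable in-view exposure, Poisson looking-bout
counts with a log-exposure offset, right-censored zero-truncated Gaussian
looking durations, crossed date x individual random intercepts, homogeneous
Poisson event processes with exponential durations behind the time-since
categories, rank-structured agonistic outcomes, clique-structured grooming,
and smooth [0, 1] spatial surfaces.  One master seed drives deterministic
per-component streams.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from lookstack import models, spatial, variables

DAY_MINUTES = 720.0  # nominal 12-h observation day
N_TIME_PERIODS = 4

#: default per-hour rates of the contextual event processes
DEFAULT_EVENT_RATES = {
    "aggression": 1.5,
    "mating": 0.4,
    "female_call": 1.0,
    "male_call": 0.8,
    "active_hetero": 0.3,
    "passive_hetero": 0.5,
    "dog": 0.1,
    "alarm": 0.4,
    "group_encounter": 0.15,
}

DEFAULT_EVENT_MEAN_DURATION_MIN = 2.0


# ---------------------------------------------------------------------------
# Domain types

@dataclasses.dataclass
class GroupRoster:
    """Study-group composition: ids, age-sex classes, latent ranks, cliques."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        n = len(t)
        if t["individual_id"].nunique() != n:
            raise ValueError("individual ids must be unique")
        if sorted(t["latent_rank"]) != list(range(1, n + 1)):
            raise ValueError("latent ranks must be a permutation of 1..N")

    @property
    def individual_ids(self) -> list:
        return self.table["individual_id"].tolist()

    @property
    def n(self) -> int:
        return len(self.table)

    def rank_map(self) -> dict:
        return dict(zip(self.table["individual_id"], self.table["latent_rank"]))

    def clique_map(self) -> dict:
        return dict(zip(self.table["individual_id"], self.table["clique_label"]))


@dataclasses.dataclass
class FocalObservation:
    """One 30-s focal sample: responses, exposure, behaviours, context."""

    individual_id: str
    date: str
    time_period: int
    in_view_seconds: float
    behaviour_seconds: dict[str, float]
    food_item: str
    amount_eaten: int
    neighbour_ids: frozenset
    visibility_pct: float
    spatial_position: str
    habitat: str
    observer_distance_m: float
    observer_moved: bool
    event_clock: dict[str, str]
    location: tuple[int, int]
    n_looks: int | None = None
    total_look_seconds: float | None = None
    censored: bool | None = None

    def validate(self) -> None:
        if not 0 < self.in_view_seconds <= 30:
            raise ValueError("in-view time must lie in (0, 30]")
        if sum(self.behaviour_seconds.values()) > 30 + 1e-9:
            raise ValueError("behaviour budget exceeds the 30-s focal")
        if self.time_period not in range(1, N_TIME_PERIODS + 1):
            raise ValueError("time period must be 1..4")
        if self.total_look_seconds is not None:
            if self.total_look_seconds > self.in_view_seconds + 1e-9:
                raise ValueError("looking duration exceeds in-view time")
            capped = np.isclose(self.total_look_seconds, self.in_view_seconds)
            if bool(self.censored) != bool(capped):
                raise ValueError("censored flag inconsistent with duration")


@dataclasses.dataclass
class TrueModelConfig:
    """Generative twin of one hypothesis model.

    ``coefficients`` are keyed by design-matrix column names of the named
    model (e.g. ``"Intercept"``, ``"age_sex[adult-female]"``,
    ``"amount_eaten"``); columns not named default to zero.
    """

    response: str
    model_id: int
    coefficients: dict[str, float]
    re_sd_date: float = 0.2
    re_sd_individual: float = 0.2
    sigma: float = 4.0  # residual sd, duration response only
    event_rates: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    event_mean_duration_min: float = DEFAULT_EVENT_MEAN_DURATION_MIN
    n_individuals: int = 10
    n_days: int = 10
    focals_per_day: int = 15
    n_cliques: int = 3
    grid_n: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response not in models.RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be non-negative")
        if self.re_sd_date < 0 or self.re_sd_individual < 0:
            raise ValueError("random-effect sds must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic child generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Roster

def simulate_roster(n_individuals: int, n_cliques: int, seed: int) -> GroupRoster:
    """Draw a study-group roster with balanced cliques and centred tolerance."""
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not 1 <= n_cliques <= n_individuals:
        raise ValueError("n_cliques must lie in 1..n_individuals")
    rng = np.random.default_rng(seed)
    ids = [f"ID{i + 1:03d}" for i in range(n_individuals)]
    age_sex = rng.choice(
        variables.AGE_SEX_CLASSES, size=n_individuals, p=[0.15, 0.35, 0.2, 0.3]
    )
    ranks = rng.permutation(n_individuals) + 1
    # round-robin assignment after a shuffle keeps clique sizes within 1
    shuffled = rng.permutation(n_individuals)
    cliques = np.empty(n_individuals, dtype=int)
    cliques[shuffled] = np.arange(n_individuals) % n_cliques
    tolerance = rng.normal(0.0, 1.0, size=n_individuals)
    return GroupRoster(
        pd.DataFrame(
            {
                "individual_id": ids,
                "age_sex_class": age_sex,
                "latent_rank": ranks,
                "clique_label": cliques,
                "tolerance_score": tolerance,
            }
        )
    )


# ---------------------------------------------------------------------------
# Landscape

def _smooth_field(rng: np.random.Generator, grid_n: int, smoothness: float) -> np.ndarray:
    field = rng.normal(size=(grid_n, grid_n))
    return ndimage.gaussian_filter(field, sigma=smoothness, mode="wrap")


def simulate_landscape(
    grid_n: int,
    seed: int,
    n_visits: int = 2000,
    total_encounters: float = 240.0,
) -> dict[str, spatial.SpatialLayer]:
    """Simulate the gridded spatial layers the pre-emptive risk models use.

    The utilisation distribution is built from smoothed visit counts around a
    handful of core areas (a grid stand-in for a home-range estimator); the
    encounter surface integrates to ``total_encounters``; the leopard surface
    is a smooth stretched field; habitat is a quantised smooth field over the
    eight habitat types.
    """
    if grid_n < 4:
        raise ValueError("grid_n must be at least 4")
    rng_ud, rng_rsf, rng_enc, rng_hab = _streams(seed, 4)

    # visit counts: mixture of Gaussian-ish core areas
    n_cores = 3
    centres = rng_ud.uniform(grid_n * 0.2, grid_n * 0.8, size=(n_cores, 2))
    weights = rng_ud.dirichlet(np.ones(n_cores) * 2)
    comp = rng_ud.choice(n_cores, size=n_visits, p=weights)
    pts = centres[comp] + rng_ud.normal(0, grid_n / 8, size=(n_visits, 2))
    ij = np.clip(np.round(pts).astype(int), 0, grid_n - 1)
    counts = np.zeros((grid_n, grid_n))
    np.add.at(counts, (ij[:, 0], ij[:, 1]), 1.0)
    ud_vals = ndimage.gaussian_filter(counts, sigma=max(1.0, grid_n / 12), mode="wrap")
    ud = spatial.linear_stretch(spatial.SpatialLayer(ud_vals, kind="ud"))

    rsf_vals = _smooth_field(rng_rsf, grid_n, max(1.0, grid_n / 10))
    leopard = spatial.linear_stretch(
        spatial.SpatialLayer(rsf_vals, kind="leopard_rsf")
    )

    # encounter intensity: mass concentrated toward the range edge
    enc_centre = rng_enc.uniform(0, grid_n, size=2)
    ii, jj = np.meshgrid(np.arange(grid_n), np.arange(grid_n), indexing="ij")
    d2 = (ii - enc_centre[0]) ** 2 + (jj - enc_centre[1]) ** 2
    enc_raw = np.exp(-d2 / (2 * (grid_n / 5) ** 2)) + 0.02
    enc_raw = enc_raw * rng_enc.uniform(0.5, 1.5, size=enc_raw.shape)
    enc_raw = ndimage.gaussian_filter(enc_raw, sigma=1.0, mode="wrap")
    enc_vals = enc_raw * (total_encounters / enc_raw.sum())
    encounter = spatial.SpatialLayer(enc_vals, kind="encounter_ud")

    hab_field = _smooth_field(rng_hab, grid_n, max(1.0, grid_n / 10))
    edges = np.quantile(hab_field, np.linspace(0, 1, len(spatial.HABITAT_TYPES) + 1))
    hab_codes = np.clip(
        np.searchsorted(edges[1:-1], hab_field, side="right"),
        0,
        len(spatial.HABITAT_TYPES) - 1,
    )
    habitat = spatial.SpatialLayer(hab_codes.astype(float), kind="habitat")

    return {
        "ud": ud,
        "leopard_rsf": leopard,
        "encounter_ud": encounter,
        "habitat": habitat,
    }


# ---------------------------------------------------------------------------
# Event processes

def _simulate_day_events(
    rng: np.random.Generator, rates: dict[str, float], mean_duration_min: float
) -> dict[str, list[tuple[float, float]]]:
    """Homogeneous Poisson events with exponential durations over one day."""
    out: dict[str, list[tuple[float, float]]] = {}
    for ev in variables.EVENT_TYPES:
        rate = rates.get(ev, 0.0)
        intervals: list[tuple[float, float]] = []
        if rate > 0:
            n = rng.poisson(rate * DAY_MINUTES / 60.0)
            starts = np.sort(rng.uniform(0, DAY_MINUTES, size=n))
            durations = rng.exponential(mean_duration_min, size=n)
            intervals = [(float(s), float(s + d)) for s, d in zip(starts, durations)]
        out[ev] = intervals
    return out


# ---------------------------------------------------------------------------
# Focal observations

def simulate_focals(
    roster: GroupRoster,
    landscape: dict[str, spatial.SpatialLayer],
    config: TrueModelConfig,
) -> list[FocalObservation]:
    """Draw focal observations (responses unfilled) under the sampling rules.

    Scheduling honours the field protocol: an individual is never sampled
    more than twice per day nor more than once per seasonally adjusted time
    period (fixed quarters of a nominal 12-h day).
    """
    config.__post_init__()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ids = roster.individual_ids
    ud = landscape["ud"]
    habitat = landscape["habitat"]
    grid_n = ud.shape[0]
    ud_weights = np.maximum(ud.values.ravel(), 1e-9)
    ud_weights = ud_weights / ud_weights.sum()
    period_len = DAY_MINUTES / N_TIME_PERIODS

    observations: list[FocalObservation] = []
    for day in range(config.n_days):
        date = f"D{day + 1:03d}"
        events = _simulate_day_events(
            rng, config.event_rates, config.event_mean_duration_min
        )
        counts = {i: 0 for i in ids}
        used_periods: dict[str, set[int]] = {i: set() for i in ids}
        for _ in range(config.focals_per_day):
            eligible = [i for i in ids if counts[i] < 2]
            if not eligible:
                break
            ind = eligible[rng.integers(len(eligible))]
            free = [p for p in range(1, N_TIME_PERIODS + 1) if p not in used_periods[ind]]
            period = free[rng.integers(len(free))]
            counts[ind] += 1
            used_periods[ind].add(period)

            focal_start = (period - 1) * period_len + rng.uniform(0, period_len)
            clock = {
                ev: variables.time_since_category(events[ev], focal_start)
                for ev in variables.EVENT_TYPES
            }

            cell_flat = rng.choice(grid_n * grid_n, p=ud_weights)
            cell = (int(cell_flat // grid_n), int(cell_flat % grid_n))
            hab = spatial.HABITAT_TYPES[int(habitat.values[cell])]

            n_neigh = min(int(rng.poisson(2.5)), roster.n - 1)
            others = [i for i in ids if i != ind]
            neighbours = frozenset(
                rng.choice(others, size=n_neigh, replace=False).tolist()
            )

            in_view = 30.0 - 5.0 * rng.beta(1.0, 4.0)
            budget = rng.dirichlet(np.full(len(variables.BEHAVIOUR_VOCABULARY), 0.3))
            behaviour_seconds = {
                b: float(30.0 * w)
                for b, w in zip(variables.BEHAVIOUR_VOCABULARY, budget)
                if w > 1e-6
            }

            food = variables.FOOD_ITEMS[
                rng.choice(len(variables.FOOD_ITEMS), p=[0.3, 0.15, 0.2, 0.2, 0.1, 0.05])
            ]
            amount = int(rng.poisson(4)) if food != "none" else 0

            obs = FocalObservation(
                individual_id=ind,
                date=date,
                time_period=period,
                in_view_seconds=float(in_view),
                behaviour_seconds=behaviour_seconds,
                food_item=food,
                amount_eaten=amount,
                neighbour_ids=neighbours,
                visibility_pct=float(
                    variables.average_context(
                        rng.uniform(20, 100), rng.uniform(20, 100)
                    )
                ),
                spatial_position="peripheral" if rng.random() < 0.35 else "central",
                habitat=hab,
                observer_distance_m=float(rng.lognormal(np.log(6.0), 0.4)),
                observer_moved=bool(rng.random() < 0.3),
                event_clock=clock,
                location=cell,
            )
            obs.validate()
            observations.append(obs)
    return observations


# ---------------------------------------------------------------------------
# Responses

def generate_looking(
    observations: list[FocalObservation],
    spec: models.ModelSpec,
    config: TrueModelConfig,
    roster: GroupRoster,
    landscape: dict[str, spatial.SpatialLayer],
) -> list[FocalObservation]:
    """Fill the looking responses from the named model's generative process.

    Frequency: n_looks ~ Poisson(exp(x'b + u_date + u_id + ln in_view)).
    Duration: latent ~ Normal(x'b + u_date + u_id + in_view, sigma) truncated
    below 0; the recorded value is min(latent, in_view) with the censored
    flag set when the cap binds.
    """
    if spec.response != config.response or spec.model_id != config.model_id:
        raise ValueError("model spec does not match the generative config")
    table = variables.build_analysis_table(
        observations,
        roster,
        rank_map=roster.rank_map(),
        clique_map=roster.clique_map(),
        layers=landscape,
    )
    design = models.build_design(spec, table)
    unknown = set(config.coefficients) - set(design.column_names)
    if unknown:
        raise ValueError(
            f"coefficient name(s) not in the design: {sorted(unknown)}"
        )
    beta = np.array(
        [config.coefficients.get(c, 0.0) for c in design.column_names]
    )

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    u_date = rng.normal(0.0, config.re_sd_date, size=len(design.date_levels))
    u_ind = rng.normal(0.0, config.re_sd_individual, size=len(design.individual_levels))
    eta = (
        design.X.to_numpy() @ beta
        + u_date[design.group_index_date]
        + u_ind[design.group_index_individual]
    )

    filled = []
    if config.response == "frequency":
        lam = np.exp(eta + np.log(design.offset))
        counts = rng.poisson(lam)
        for obs, k in zip(observations, counts):
            filled.append(dataclasses.replace(obs, n_looks=int(k)))
    else:
        mu = eta + design.offset  # unit-coefficient untransformed offset
        # inverse-cdf draw from the zero-truncated normal
        from scipy import stats as _stats

        lo = _stats.norm.cdf(0.0, loc=mu, scale=config.sigma)
        u = rng.uniform(lo, 1.0)
        latent = _stats.norm.ppf(u, loc=mu, scale=config.sigma)
        capped = latent >= design.offset
        value = np.where(capped, design.offset, latent)
        for obs, v, c in zip(observations, value, capped):
            new = dataclasses.replace(
                obs, total_look_seconds=float(v), censored=bool(c)
            )
            new.validate()
            filled.append(new)
    return filled


# ---------------------------------------------------------------------------
# Interaction matrices

def simulate_agonistic_matrix(
    roster: GroupRoster, n_interactions: int, steepness: float, seed: int
) -> np.ndarray:
    """Directed win-count matrix with rank-structured outcomes.

    P(i beats j) = logistic(steepness * (rank_j - rank_i)); rank 1 is top, so
    higher-ranked animals win more as steepness grows, and outcomes are fair
    coin flips at steepness 0.
    """
    if n_interactions < 1:
        raise ValueError("need at least one interaction")
    if steepness < 0:
        raise ValueError("steepness must be non-negative")
    rng = np.random.default_rng(seed)
    n = roster.n
    ranks = roster.table["latent_rank"].to_numpy()
    mat = np.zeros((n, n), dtype=int)
    for _ in range(n_interactions):
        i, j = rng.choice(n, size=2, replace=False)
        adv = steepness * (ranks[j] - ranks[i])
        p_i_wins = 1.0 / (1.0 + np.exp(-adv)) if np.isfinite(adv) else float(adv > 0)
        if rng.random() < p_i_wins:
            mat[i, j] += 1
        else:
            mat[j, i] += 1
    return mat


def simulate_grooming(
    roster: GroupRoster, within_rate: float, between_rate: float, seed: int
) -> np.ndarray:
    """Symmetric grooming-weight matrix with clique-structured rates."""
    if between_rate < 0 or within_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    n = roster.n
    cliques = roster.table["clique_label"].to_numpy()
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rate = within_rate if cliques[i] == cliques[j] else between_rate
            w = rng.poisson(rate)
            W[i, j] = W[j, i] = w
    return W


# ---------------------------------------------------------------------------
# Dataset I/O

def focals_to_frame(observations: list[FocalObservation]) -> pd.DataFrame:
    rows = []
    for obs in observations:
        row = {
            "individual_id": obs.individual_id,
            "date": obs.date,
            "time_period": obs.time_period,
            "in_view_seconds": obs.in_view_seconds,
            # responses may be unfilled; carried as NaN-able floats so the
            # frame round-trips CSV exactly
            "n_looks": np.nan if obs.n_looks is None else float(obs.n_looks),
            "total_look_seconds": (
                np.nan if obs.total_look_seconds is None else obs.total_look_seconds
            ),
            "censored": np.nan if obs.censored is None else float(obs.censored),
            "food_item": obs.food_item,
            "amount_eaten": obs.amount_eaten,
            "neighbour_ids": ";".join(sorted(obs.neighbour_ids)),
            "visibility_pct": obs.visibility_pct,
            "spatial_position": obs.spatial_position,
            "habitat": obs.habitat,
            "observer_distance_m": obs.observer_distance_m,
            "observer_moved": obs.observer_moved,
            "location_i": obs.location[0],
            "location_j": obs.location[1],
        }
        for beh in variables.BEHAVIOUR_VOCABULARY:
            row[f"beh_{beh}"] = obs.behaviour_seconds.get(beh, 0.0)
        for ev in variables.EVENT_TYPES:
            row[f"ts_{ev}"] = obs.event_clock[ev]
        rows.append(row)
    columns = (
        [
            "individual_id", "date", "time_period", "in_view_seconds", "n_looks",
            "total_look_seconds", "censored", "food_item", "amount_eaten",
            "neighbour_ids", "visibility_pct", "spatial_position", "habitat",
            "observer_distance_m", "observer_moved", "location_i", "location_j",
        ]
        + [f"beh_{b}" for b in variables.BEHAVIOUR_VOCABULARY]
        + [f"ts_{e}" for e in variables.EVENT_TYPES]
    )
    return pd.DataFrame(rows, columns=columns)


def frame_to_focals(frame: pd.DataFrame) -> list[FocalObservation]:
    observations = []
    for _, row in frame.iterrows():
        behaviour_seconds = {
            b: float(row[f"beh_{b}"])
            for b in variables.BEHAVIOUR_VOCABULARY
            if float(row[f"beh_{b}"]) > 0
        }
        clock = {e: row[f"ts_{e}"] for e in variables.EVENT_TYPES}
        neigh = row["neighbour_ids"]
        neighbour_ids = frozenset(
            neigh.split(";") if isinstance(neigh, str) and neigh else []
        )
        obs = FocalObservation(
            individual_id=row["individual_id"],
            date=row["date"],
            time_period=int(row["time_period"]),
            in_view_seconds=float(row["in_view_seconds"]),
            behaviour_seconds=behaviour_seconds,
            food_item=row["food_item"],
            amount_eaten=int(row["amount_eaten"]),
            neighbour_ids=neighbour_ids,
            visibility_pct=float(row["visibility_pct"]),
            spatial_position=row["spatial_position"],
            habitat=row["habitat"],
            observer_distance_m=float(row["observer_distance_m"]),
            observer_moved=bool(row["observer_moved"]),
            event_clock=clock,
            location=(int(row["location_i"]), int(row["location_j"])),
            n_looks=None if pd.isna(row["n_looks"]) else int(row["n_looks"]),
            total_look_seconds=(
                None
                if pd.isna(row["total_look_seconds"])
                else float(row["total_look_seconds"])
            ),
            censored=None if pd.isna(row["censored"]) else bool(float(row["censored"])),
        )
        observations.append(obs)
    return observations


def write_dataset(
    path: str | Path,
    observations: list[FocalObservation],
    roster: GroupRoster,
    agonistic: np.ndarray,
    grooming: np.ndarray,
    layers: dict[str, spatial.SpatialLayer],
    config: TrueModelConfig | None = None,
) -> None:
    """Write a dataset as plain-text files: CSV tables, .asc rasters, JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # shortest-repr floats round-trip the CSV exactly
    fmt = {"float_format": lambda v: repr(float(v)), "index": False}
    focals_to_frame(observations).to_csv(path / "focals.csv", **fmt)
    roster.table.to_csv(path / "roster.csv", **fmt)

    ids = roster.individual_ids
    long_rows = [
        {"winner": ids[i], "loser": ids[j], "count": int(agonistic[i, j])}
        for i in range(len(ids))
        for j in range(len(ids))
        if agonistic[i, j] > 0
    ]
    pd.DataFrame(long_rows, columns=["winner", "loser", "count"]).to_csv(
        path / "agonistic.csv", index=False
    )
    groom_rows = [
        {"id_a": ids[i], "id_b": ids[j], "weight": float(grooming[i, j])}
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if grooming[i, j] > 0
    ]
    pd.DataFrame(groom_rows, columns=["id_a", "id_b", "weight"]).to_csv(
        path / "grooming.csv", **fmt
    )
    (path / "layers").mkdir(exist_ok=True)
    for name, layer in layers.items():
        spatial.write_ascii_grid(layer, path / "layers" / f"{name}.asc")
    sidecar = {"n_individuals": roster.n, "layer_names": sorted(layers)}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    (path / "config.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_dataset(path: str | Path):
    """Read back a dataset written by :func:`write_dataset`."""
    path = Path(path)
    sidecar = json.loads((path / "config.json").read_text())
    roster = GroupRoster(
        pd.read_csv(path / "roster.csv", float_precision="round_trip")
    )
    ids = roster.individual_ids
    idx = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)

    focals_frame = pd.read_csv(path / "focals.csv", float_precision="round_trip")
    observations = frame_to_focals(focals_frame) if len(focals_frame) else []

    agonistic = np.zeros((n, n), dtype=int)
    ag = pd.read_csv(path / "agonistic.csv")
    for _, row in ag.iterrows():
        agonistic[idx[row["winner"]], idx[row["loser"]]] = int(row["count"])

    grooming = np.zeros((n, n))
    gr = pd.read_csv(path / "grooming.csv", float_precision="round_trip")
    for _, row in gr.iterrows():
        w = float(row["weight"])
        grooming[idx[row["id_a"]], idx[row["id_b"]]] = w
        grooming[idx[row["id_b"]], idx[row["id_a"]]] = w

    layers = {
        name: spatial.read_ascii_grid(path / "layers" / f"{name}.asc", kind=name if name in spatial.LAYER_KINDS else "ud")
        for name in sidecar["layer_names"]
    }
    config = None
    if "config" in sidecar:
        cfg = dict(sidecar["config"])
        cfg["coefficients"] = dict(cfg["coefficients"])
        config = TrueModelConfig(**cfg)
    return observations, roster, agonistic, grooming, layers, config
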