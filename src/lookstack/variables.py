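"""Derived predictors: everything the hypothesis models consume.

This module turns raw focal records, interaction matrices and spatial layers
into the analysis table: time-since-event categories, engaged / not-engaged
time budgets, start/end context averaging, I&SI dominance ranks, grooming
cliques, within-group social-threat counts, and per-focal spatial values.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from lookstack import spatial

# ---------------------------------------------------------------------------
# Controlled vocabularies

AGE_SEX_CLASSES = ("adult-male", "adult-female", "subadult", "juvenile")

#: Behaviours requiring visual attention and use of the hands.
ENGAGED_BEHAVIOURS = (
    "groom_other",
    "self_groom",
    "dig",
    "search_substrate",
    "pick",
    "aggression_play",
)

#: Behaviours that leave the animal's focus of attention free.
NOT_ENGAGED_BEHAVIOURS = (
    "rest",
    "chew",
    "mate",
    "self_scratch",
    "receive_groom",
    "drink",
    "movement",
    "communication",
    "biting",
    "handling",
    "posture",
)

BEHAVIOUR_VOCABULARY = ENGAGED_BEHAVIOURS + NOT_ENGAGED_BEHAVIOURS

#: Event types whose time-since states enter the reactionary models.
EVENT_TYPES = (
    "aggression",
    "mating",
    "female_call",
    "male_call",
    "active_hetero",
    "passive_hetero",
    "dog",
    "alarm",
    "group_encounter",
)

TIME_SINCE_LEVELS = (
    "no_event",
    "ongoing",
    "post_0_5",
    "post_5_10",
    "post_10_15",
    "post_gt15",
)

FOOD_ITEMS = ("none", "fruit", "seeds", "leaves_grass", "roots", "other")

SPATIAL_POSITIONS = ("central", "peripheral")


# ---------------------------------------------------------------------------
# Time since event

def categorize_elapsed(elapsed_min: float) -> str:
    """Bin minutes-since-event-end into the ordered post-event categories.

    Bins are half-open: [0, 5), [5, 10), [10, 15), [15, inf).
    """
    if elapsed_min < 0:
        raise ValueError("elapsed time cannot be negative")
    if elapsed_min < 5:
        return "post_0_5"
    if elapsed_min < 10:
        return "post_5_10"
    if elapsed_min < 15:
        return "post_10_15"
    return "post_gt15"


def time_since_category(
    event_intervals: list[tuple[float, float]], focal_start: float
) -> str:
    """Categorise a focal's state relative to one event type.

    Parameters
    ----------
    event_intervals
        (start, end) times in minutes for every event of this type that day,
        covering the day from its start up to ``focal_start``.
    focal_start
        Start time of the focal observation, minutes from start of day.

    An ongoing event dominates any earlier one; otherwise the most recent
    event that ended before the focal started governs the category.
    """
    last_end = None
    for start, end in event_intervals:
        if end < start:
            raise ValueError("event end precedes event start")
        if start <= focal_start:
            if end > focal_start:
                return "ongoing"
            if last_end is None or end > last_end:
                last_end = end
    if last_end is None:
        return "no_event"
    return categorize_elapsed(focal_start - last_end)


# ---------------------------------------------------------------------------
# Behaviour budgets

def _check_vocabulary(behaviour_seconds: dict[str, float]) -> None:
    unknown = set(behaviour_seconds) - set(BEHAVIOUR_VOCABULARY)
    if unknown:
        raise ValueError(f"unknown behaviour name(s): {sorted(unknown)}")


def engaged_time(behaviour_seconds: dict[str, float]) -> float:
    """Seconds spent in behaviours requiring visual attention and the hands."""
    _check_vocabulary(behaviour_seconds)
    return float(
        sum(v for k, v in behaviour_seconds.items() if k in ENGAGED_BEHAVIOURS)
    )


def not_engaged_time(behaviour_seconds: dict[str, float]) -> float:
    """Seconds spent in behaviours leaving the focus of attention free."""
    _check_vocabulary(behaviour_seconds)
    return float(
        sum(v for k, v in behaviour_seconds.items() if k in NOT_ENGAGED_BEHAVIOURS)
    )


def average_context(start_value: float, end_value: float | None) -> float:
    """Average a context variable over its start and end assessments."""
    if end_value is None or (isinstance(end_value, float) and np.isnan(end_value)):
        warnings.warn("missing end assessment; propagating missing value")
        return float("nan")
    return 0.5 * (start_value + end_value)


# ---------------------------------------------------------------------------
# I&SI dominance ranking

@dataclasses.dataclass
class DominanceRanking:
    """A linear dominance order with its inconsistency scores.

    ``order`` lists individual ids from top (rank 1) downwards.  ``I`` counts
    dyads whose observed wins contradict the order; ``SI`` sums the rank
    distance of those inconsistent dyads.
    """

    order: list
    I: int
    SI: int

    def rank_of(self, individual_id) -> int:
        return self.order.index(individual_id) + 1

    def rank_map(self) -> dict:
        return {ind: pos + 1 for pos, ind in enumerate(self.order)}


def _isi_scores(wins: np.ndarray, perm: np.ndarray) -> tuple[int, int]:
    """(I, SI) of a candidate order: perm[p] = matrix index at rank position p."""
    sub = wins[np.ix_(perm, perm)]
    upper = np.triu_indices(len(perm), k=1)
    incons = sub[upper] < sub.T[upper]  # the lower-ranked animal wins the dyad
    i_count = int(incons.sum())
    si = int((upper[1][incons] - upper[0][incons]).sum())
    return i_count, si


def isi_rank(
    matrix: np.ndarray,
    ids: list | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    force_heuristic: bool = False,
) -> DominanceRanking:
    """I&SI linear ordering of a directed win matrix.

    Finds an order minimising the number of inconsistencies ``I`` first and
    their total strength ``SI`` second.  Exhaustive over all permutations for
    groups of up to 8; otherwise a seeded pairwise-swap hill climb with random
    restarts (``force_heuristic`` runs the climb at any size, used to audit it
    against the exhaustive optimum).
    """
    wins = np.asarray(matrix, dtype=float)
    n = wins.shape[0]
    if wins.shape != (n, n):
        raise ValueError("win matrix must be square")
    if np.any(np.diag(wins) != 0):
        raise ValueError("win matrix must have a zero diagonal")
    if wins.sum() == 0:
        raise ValueError("ranking undefined: no interactions recorded")
    if ids is None:
        ids = list(range(n))

    if n <= 8 and not force_heuristic:
        best_perm, best_score = None, (np.inf, np.inf)
        for perm in itertools.permutations(range(n)):
            score = _isi_scores(wins, np.array(perm))
            if score < best_score:
                best_score, best_perm = score, np.array(perm)
        perm = best_perm
    else:
        rng = np.random.default_rng(seed)
        # David's-score-flavoured start: order by net wins
        net = wins.sum(axis=1) - wins.sum(axis=0)
        starts = [np.argsort(-net, kind="stable")]
        for _ in range(n_restarts - 1):
            starts.append(rng.permutation(n))
        best_perm, best_score = None, (np.inf, np.inf)
        for perm in starts:
            perm = np.array(perm)
            score = _isi_scores(wins, perm)
            improved = True
            while improved:
                improved = False
                # pairwise swaps plus single-element insertions: insertions
                # escape the local optima that swaps alone stall in
                for a in range(n):
                    for b in range(n):
                        if a == b:
                            continue
                        if a < b:
                            cand = perm.copy()
                            cand[a], cand[b] = cand[b], cand[a]
                            cand_score = _isi_scores(wins, cand)
                            if cand_score < score:
                                perm, score = cand, cand_score
                                improved = True
                        moved = np.insert(np.delete(perm, a), b, perm[a])
                        cand_score = _isi_scores(wins, moved)
                        if cand_score < score:
                            perm, score = moved, cand_score
                            improved = True
            if score < best_score:
                best_score, best_perm = score, perm
        perm = best_perm

    i_count, si = _isi_scores(wins, perm)
    return DominanceRanking(order=[ids[p] for p in perm], I=i_count, SI=si)


# ---------------------------------------------------------------------------
# Grooming cliques

def detect_cliques(
    grooming: np.ndarray,
    ids: list | None = None,
    method: str = "modularity",
    seed: int = 0,
) -> dict:
    """Partition individuals into grooming cliques.

    The default method greedily maximises weighted modularity; ``spinglass``
    delegates to igraph's spin-glass community detection when python-igraph is
    importable.  Returns a mapping id -> integer clique label.  If the
    partition found has modularity <= 0 (no community structure), everyone is
    placed in a single clique.
    """
    W = np.asarray(grooming, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("grooming matrix must be square")
    if not np.allclose(W, W.T):
        raise ValueError("grooming matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("grooming weights must be non-negative")
    if ids is None:
        ids = list(range(n))

    if W.sum() == 0:
        warnings.warn("empty grooming graph; every individual is its own clique")
        return {ind: i for i, ind in enumerate(ids)}

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                graph.add_edge(i, j, weight=W[i, j])

    if method == "modularity":
        communities = list(
            nx.community.greedy_modularity_communities(graph, weight="weight")
        )
    elif method == "spinglass":
        import igraph

        edges = [(i, j) for i, j in graph.edges]
        weights = [graph[i][j]["weight"] for i, j in edges]
        g = igraph.Graph(n=n, edges=edges)
        # spinglass requires a connected graph; fall back per component
        communities = []
        for comp in nx.connected_components(graph):
            comp = sorted(comp)
            if len(comp) == 1:
                communities.append(set(comp))
                continue
            sub = g.subgraph(comp)
            sub_w = [
                W[comp[e.source], comp[e.target]] for e in sub.es
            ]
            import random as _random

            igraph.set_random_number_generator(_random.Random(seed))
            cl = sub.community_spinglass(weights=sub_w)
            for members in cl:
                communities.append({comp[m] for m in members})
    else:
        raise ValueError(f"unknown community detection method {method!r}")

    labels = np.zeros(n, dtype=int)
    for label, members in enumerate(communities):
        for m in members:
            labels[m] = label

    q = nx.community.modularity(
        graph, [set(np.flatnonzero(labels == c)) for c in np.unique(labels)],
        weight="weight",
    )
    if q <= 0:
        labels = np.zeros(n, dtype=int)
    return {ind: int(labels[i]) for i, ind in enumerate(ids)}


# ---------------------------------------------------------------------------
# Within-group social threats

@dataclasses.dataclass
class SocialContext:
    """Neighbourhood threat summary for one focal observation."""

    n_neighbours: int
    n_higher_ranked: int
    n_social_threats: int

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_social_threats <= self.n_higher_ranked <= self.n_neighbours
        ):
            raise ValueError("social context violates threat <= higher <= neighbours")


def count_social_threats(
    neighbour_ids, rank_map: dict, clique_map: dict, focal_id
) -> SocialContext:
    """Count higher-ranked neighbours that are not focal-clique affiliates.

    A within-group threat is a neighbour within 5 m that outranks the focal
    animal and does not belong to its grooming clique (higher-ranked clique
    members are assumed affiliative, not threatening).
    """
    neighbours = set(neighbour_ids)
    if focal_id in neighbours:
        raise ValueError("focal individual cannot be its own neighbour")
    missing = [j for j in neighbours if j not in rank_map or j not in clique_map]
    if missing or focal_id not in rank_map or focal_id not in clique_map:
        raise ValueError(f"ids missing from ranking/cliques: {missing}")
    focal_rank = rank_map[focal_id]
    focal_clique = clique_map[focal_id]
    higher = {j for j in neighbours if rank_map[j] < focal_rank}
    higher_affiliates = {j for j in higher if clique_map[j] == focal_clique}
    return SocialContext(
        n_neighbours=len(neighbours),
        n_higher_ranked=len(higher),
        n_social_threats=max(0, len(higher) - len(higher_affiliates)),
    )


# ---------------------------------------------------------------------------
# Analysis table

def build_analysis_table(
    observations,
    roster,
    rank_map: dict,
    clique_map: dict,
    layers: dict[str, spatial.SpatialLayer],
    tolerance_map: dict | None = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-focal analysis table all models consume.

    ``layers`` must contain the raw ``ud``, ``leopard_rsf`` and
    ``encounter_ud`` surfaces; stretched / inverted / ratio layers and the
    familiarity classes are derived here so every spatial predictor is
    constructed by exactly one code path.
    """
    ud_s = spatial.linear_stretch(layers["ud"])
    inverted_ud = spatial.invert_layer(ud_s)
    rsf_s = spatial.linear_stretch(layers["leopard_rsf"])
    enc_risk = spatial.encounter_risk_layer(
        spatial.linear_stretch(layers["encounter_ud"]), ud_s
    )
    t_core, t_frequent = spatial.familiarity_thresholds(ud_s)

    if tolerance_map is None:
        tolerance_map = dict(
            zip(roster.table["individual_id"], roster.table["tolerance_score"])
        )
    age_sex_map = dict(zip(roster.table["individual_id"], roster.table["age_sex_class"]))

    rows = []
    for obs in observations:
        cell = obs.location
        ud_val = float(ud_s.values[cell])
        if ud_val >= t_core:
            fam = "core"
        elif ud_val >= t_frequent:
            fam = "frequent"
        else:
            fam = "boundary"
        ctx = count_social_threats(
            obs.neighbour_ids, rank_map, clique_map, obs.individual_id
        )
        row = {
            "individual_id": obs.individual_id,
            "date": obs.date,
            "time_period": obs.time_period,
            "in_view_seconds": obs.in_view_seconds,
            "n_looks": obs.n_looks,
            "total_look_seconds": obs.total_look_seconds,
            "censored": obs.censored,
            "age_sex": age_sex_map[obs.individual_id],
            "rank": rank_map[obs.individual_id],
            "tolerance": tolerance_map[obs.individual_id],
            "engaged_time": engaged_time(obs.behaviour_seconds),
            "not_engaged_time": not_engaged_time(obs.behaviour_seconds),
            "n_neighbours": ctx.n_neighbours,
            "n_higher_ranked": ctx.n_higher_ranked,
            "n_social_threats": ctx.n_social_threats,
            "spatial_position": obs.spatial_position,
            "visibility": obs.visibility_pct,
            "habitat": obs.habitat,
            "observer_distance": obs.observer_distance_m,
            "observer_moved": obs.observer_moved,
            "food_item": obs.food_item,
            "amount_eaten": obs.amount_eaten,
            "ud_value": ud_val,
            "inverted_ud": float(inverted_ud.values[cell]),
            "leopard_rsf": float(rsf_s.values[cell]),
            "encounter_risk": float(np.nan_to_num(enc_risk.values[cell])),
            "familiarity_class": fam,
        }
        for beh in BEHAVIOUR_VOCABULARY:
            row[f"beh_{beh}"] = float(obs.behaviour_seconds.get(beh, 0.0))
        for ev in EVENT_TYPES:
            row[f"ts_{ev}"] = obs.event_clock[ev]
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table):
        bad = table["total_look_seconds"] > table["in_view_seconds"] + 1e-12
        if bad.any():
            raise ValueError(
                f"looking duration exceeds in-view exposure on rows {list(table.index[bad])}"
            )
    return table
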