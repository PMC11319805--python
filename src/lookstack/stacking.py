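"""Bayesian stacking of LOO predictive densities.

Stacking finds the simplex weights that maximise the summed log score of the
mixture of the candidate models' leave-one-out predictive densities,

    max_w  sum_i log sum_k w_k exp(elpd_ik),   w on the K-simplex.

The objective is concave in w, so the optimum value is unique; similar models
share weight while a model that predicts every point best takes weight 1.  A
second stage re-stacks the models retained above a small weight threshold, as
a diagnostic for weight sharing among similar models.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, softmax

from lookstack.loo import LooResult

DEFAULT_RESTACK_THRESHOLD = 0.001

#: weights at or above this are reported as predictively accurate models
ACCURACY_FLAG_THRESHOLD = 0.1


@dataclasses.dataclass
class StackResult:
    """Simplex weights over a model set, before and after re-stacking."""

    weights: np.ndarray
    model_ids: list
    objective: float
    restacked_weights: np.ndarray | None = None
    retained_ids: list | None = None
    threshold: float | None = None

    def weight_of(self, model_id) -> float:
        return float(self.weights[self.model_ids.index(model_id)])

    def restacked_weight_of(self, model_id) -> float:
        """Second-stage weight; models dropped at the threshold report 0."""
        if self.retained_ids is None:
            raise ValueError("re-stacking has not been run")
        if model_id not in self.retained_ids:
            return 0.0
        return float(self.restacked_weights[self.retained_ids.index(model_id)])


def _as_lpd_matrix(loo_results) -> np.ndarray:
    """Stack pointwise elpd vectors into an n x K matrix."""
    cols = []
    for r in loo_results:
        cols.append(r.elpd_i if isinstance(r, LooResult) else np.asarray(r, dtype=float))
    lengths = {len(c) for c in cols}
    if len(lengths) != 1:
        raise ValueError("all models must share the same number of observations")
    return np.column_stack(cols)


def stacking_objective(weights: np.ndarray, lpd: np.ndarray) -> float:
    """Summed log score of the weighted mixture of LOO predictive densities."""
    w = np.asarray(weights, dtype=float)
    shift = lpd.max(axis=1, keepdims=True)
    mix = np.exp(lpd - shift) @ w
    return float(np.sum(np.log(mix) + shift[:, 0]))


def stacking_weights(
    loo_results,
    model_ids: list | None = None,
    seed: int = 0,
    tol: float = 1e-10,
) -> StackResult:
    """Optimal stacking weights for a set of models.

    The simplex constraint is handled by a softmax parameterisation (last
    logit pinned at zero) solved with L-BFGS from several seeded starts; the
    problem is concave so every start converges to the same optimum value.
    """
    loo_results = list(loo_results)
    K = len(loo_results)
    if K == 0:
        raise ValueError("no models to stack")
    if model_ids is None:
        model_ids = list(range(1, K + 1))
    lpd = _as_lpd_matrix(loo_results)
    if K == 1:
        return StackResult(np.array([1.0]), list(model_ids), stacking_objective([1.0], lpd))

    shift = lpd.max(axis=1, keepdims=True)
    expd = np.exp(lpd - shift)  # n x K

    def neg_objective(z: np.ndarray):
        w = softmax(np.append(z, 0.0))
        mix = expd @ w
        value = -np.sum(np.log(mix))
        grad_w = -(expd / mix[:, None]).sum(axis=0)
        # chain rule through softmax
        grad_z = w * (grad_w - np.dot(grad_w, w))
        return value, grad_z[:-1]

    rng = np.random.default_rng(seed)
    best = None
    starts = [np.zeros(K - 1)] + [rng.normal(0, 1, size=K - 1) for _ in range(2)]
    for z0 in starts:
        res = optimize.minimize(
            neg_objective,
            z0,
            jac=True,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    weights = softmax(np.append(best.x, 0.0))
    weights = np.where(weights < 1e-12, 0.0, weights)
    weights = weights / weights.sum()
    return StackResult(
        weights=weights,
        model_ids=list(model_ids),
        objective=stacking_objective(weights, lpd),
    )


def restack(
    stack: StackResult,
    loo_results,
    threshold: float = DEFAULT_RESTACK_THRESHOLD,
    seed: int = 0,
) -> StackResult:
    """Second-stage stacking over the models retained at ``threshold`` weight.

    Models whose first-stage weight falls below the threshold are dropped and
    the remainder re-stacked, separating weight genuinely earned from weight
    shared among similar models.
    """
    loo_results = list(loo_results)
    retained = [k for k, w in enumerate(stack.weights) if w >= threshold]
    if not retained:
        raise ValueError(f"no model reaches the retention threshold {threshold}")
    sub = stacking_weights(
        [loo_results[k] for k in retained],
        model_ids=[stack.model_ids[k] for k in retained],
        seed=seed,
    )
    return StackResult(
        weights=stack.weights,
        model_ids=stack.model_ids,
        objective=stack.objective,
        restacked_weights=sub.weights,
        retained_ids=sub.model_ids,
        threshold=threshold,
    )


def grid_search_weights_k2(lpd_a, lpd_b, step: float = 1e-4) -> tuple[float, float]:
    """Brute-force two-model stacking: scan w_a over a fine grid.

    An independent check of the solver used in tests; returns (w_a, objective).
    """
    lpd = _as_lpd_matrix([lpd_a, lpd_b])
    grid = np.arange(0.0, 1.0 + step, step)
    shift = lpd.max(axis=1, keepdims=True)
    expd = np.exp(lpd - shift)
    mix = np.outer(expd[:, 0], grid) + np.outer(expd[:, 1], 1.0 - grid)
    objs = np.sum(np.log(mix) + shift, axis=0)
    best = int(np.argmax(objs))
    return float(grid[best]), float(objs[best])
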