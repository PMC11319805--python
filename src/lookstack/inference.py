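"""Posterior inference for the hypothesis models.

Parameters are the fixed-effect coefficients, crossed random intercepts for
observation date and individual identity, their standard deviations, and (for
duration models) the residual sigma.  Scale parameters are sampled on the log
scale with the half-Student-t prior applied through the usual Jacobian
correction.  The sampler is a seeded adaptive random-walk Metropolis run
vectorised across chains: proposal scales adapt per parameter during warmup
from the pooled chain history, and a per-chain global scale tracks the
acceptance rate toward the 0.234 optimum for multivariate random walks.
"""

from __future__ import annotations

import dataclasses
import warnings

import arviz as az
import numpy as np
import pandas as pd

from lookstack import models


@dataclasses.dataclass
class FitSettings:
    """MCMC run configuration.

    Defaults are desk-scale (half the reference 4 x 2000/1000 schedule);
    ``full_scale()`` restores the full schedule.
    """

    chains: int = 4
    iterations: int = 1000
    warmup: int = 500
    seed: int = 0
    method: str = "adaptive_rwm"

    def __post_init__(self) -> None:
        if min(self.chains, self.iterations, self.warmup) <= 0:
            raise ValueError("chains, iterations and warmup must be positive")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must leave post-warmup iterations")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "FitSettings":
        return cls(chains=4, iterations=2000, warmup=1000, seed=seed)

    @property
    def n_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)


@dataclasses.dataclass
class PosteriorFit:
    """Posterior draws plus everything needed for pointwise prediction."""

    draws: pd.DataFrame  # S rows, one named column per parameter
    chains: int
    draws_per_chain: int
    param_names: list[str]
    diagnostics: pd.DataFrame  # parameter, rhat, ess
    design: models.DesignMatrix
    spec: models.ModelSpec
    settings: FitSettings
    accept_rate: float

    @property
    def S(self) -> int:
        return len(self.draws)

    def coefficient_names(self) -> list[str]:
        return list(self.design.column_names)

    def summary(self) -> pd.DataFrame:
        """Parameter means, 95% interval bounds and convergence diagnostics."""
        d = self.draws
        out = pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": [d[p].mean() for p in self.param_names],
                "q2.5": [d[p].quantile(0.025) for p in self.param_names],
                "q97.5": [d[p].quantile(0.975) for p in self.param_names],
            }
        )
        return out.merge(self.diagnostics, on="parameter")


class _Posterior:
    """Batched log-posterior over parameter matrices (chains x P_total)."""

    def __init__(self, spec: models.ModelSpec, design: models.DesignMatrix):
        self.spec = spec
        self.design = design
        self.P = len(design.column_names)
        self.D = len(design.date_levels) if spec.include_random_effects else 0
        self.I = len(design.individual_levels) if spec.include_random_effects else 0
        self.is_duration = spec.response == "duration"
        names = list(design.column_names)
        if spec.include_random_effects:
            names += [f"u_date[{d}]" for d in design.date_levels]
            names += [f"u_individual[{i}]" for i in design.individual_levels]
            names += ["sd_date", "sd_individual"]
        if self.is_duration:
            names += ["sigma"]
        self.param_names = names
        self.n_params = (
            self.P
            + self.D
            + self.I
            + (2 if spec.include_random_effects else 0)
            + (1 if self.is_duration else 0)
        )
        self._X = design.X.to_numpy()

    def split(self, theta: np.ndarray):
        """theta (C, n_params) -> beta, u_date, u_ind, log_sds, log_sigma."""
        c = 0
        beta = theta[:, c : c + self.P]
        c += self.P
        u_date = theta[:, c : c + self.D]
        c += self.D
        u_ind = theta[:, c : c + self.I]
        c += self.I
        if self.spec.include_random_effects:
            log_sds = theta[:, c : c + 2]
            c += 2
        else:
            log_sds = None
        log_sigma = theta[:, c] if self.is_duration else None
        return beta, u_date, u_ind, log_sds, log_sigma

    def linear_predictor(self, theta: np.ndarray, conditional: bool = True) -> np.ndarray:
        """eta as an (C, n) array; marginal predictions zero the intercepts."""
        beta, u_date, u_ind, _, _ = self.split(theta)
        eta = beta @ self._X.T
        if conditional and self.spec.include_random_effects:
            eta = (
                eta
                + u_date[:, self.design.group_index_date]
                + u_ind[:, self.design.group_index_individual]
            )
        return eta

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """(C, n) conditional log-likelihood of each observation."""
        eta = self.linear_predictor(theta)
        d = self.design
        if self.is_duration:
            _, _, _, _, log_sigma = self.split(theta)
            sigma = np.exp(log_sigma)[:, None]
            mu = eta + d.offset[None, :]
            return models.loglik_duration(
                d.y[None, :], d.censored[None, :], mu, sigma, d.offset[None, :]
            )
        return models.loglik_frequency(d.y[None, :], eta, d.offset[None, :])

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        beta, u_date, u_ind, log_sds, log_sigma = self.split(theta)
        prior = self.spec.priors
        lp = np.sum(
            models.student_t_logpdf(beta, prior.coef_df, prior.coef_loc, prior.coef_scale),
            axis=1,
        )
        if self.spec.include_random_effects:
            sds = np.exp(log_sds)
            # half-t prior on the sd scale plus log-Jacobian of the transform
            lp = lp + np.sum(
                models.half_student_t_logpdf(sds, prior.sd_df, prior.sd_scale)
                + log_sds,
                axis=1,
            )
            for u, sd in ((u_date, sds[:, 0:1]), (u_ind, sds[:, 1:2])):
                if u.shape[1]:
                    lp = lp + np.sum(
                        -0.5 * (u / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi),
                        axis=1,
                    )
        if self.is_duration:
            sigma = np.exp(log_sigma)
            lp = (
                lp
                + models.half_student_t_logpdf(sigma, prior.sd_df, prior.sd_scale)
                + log_sigma
            )
        with np.errstate(over="ignore"):
            ll = self.pointwise_loglik(theta)
        lp = lp + np.where(np.isfinite(ll), ll, -np.inf).sum(axis=1)
        return np.where(np.isfinite(lp), lp, -np.inf)


def fit(
    spec: models.ModelSpec,
    table: pd.DataFrame,
    settings: FitSettings | None = None,
) -> PosteriorFit:
    """Sample the posterior of one hypothesis model.

    Duration models initialise every parameter at zero (which gives a finite
    log posterior under the censored/truncated likelihood); frequency models
    add a small seeded jitter to break chain symmetry.
    """
    settings = settings or FitSettings()
    design = models.build_design(spec, table)
    post = _Posterior(spec, design)
    if spec.include_random_effects and (
        len(design.date_levels) < 2 or len(design.individual_levels) < 2
    ):
        warnings.warn(
            "single date or individual: random-effect sds will be prior-dominated"
        )
    sampler = _BlockSampler(post, settings, spec)
    out = sampler.run()

    # scale parameters were sampled on the log scale; report natural scale
    scale_cols = [
        i
        for i, name in enumerate(post.param_names)
        if name in ("sd_date", "sd_individual", "sigma")
    ]
    out[:, :, scale_cols] = np.exp(out[:, :, scale_cols])
    rhat, ess = _diagnostics(out)
    C, keep, Ptot = out.shape
    draws = pd.DataFrame(out.reshape(C * keep, Ptot), columns=post.param_names)
    diag = pd.DataFrame({"parameter": post.param_names, "rhat": rhat, "ess": ess})
    return PosteriorFit(
        draws=draws,
        chains=C,
        draws_per_chain=keep,
        param_names=post.param_names,
        diagnostics=diag,
        design=design,
        spec=spec,
        settings=settings,
        accept_rate=sampler.accept_rate,
    )


class _BlockSampler:
    """Metropolis-within-Gibbs with adaptive proposals, vectorised over chains.

    Blocks per sweep: (1) all fixed-effect coefficients jointly, with a
    Haario-style empirical-covariance proposal learned during warmup;
    (2) date intercepts coordinate-wise (their full conditional factorises
    because each observation belongs to exactly one date); (3) individual
    intercepts likewise; (4) the log scale parameters as one small block.
    Coordinate-wise updates target ~0.44 acceptance, joint blocks ~0.27.
    """

    def __init__(self, post: _Posterior, settings: FitSettings, spec: models.ModelSpec):
        self.post = post
        self.settings = settings
        self.spec = spec
        self.rng = np.random.default_rng(settings.seed)
        d = post.design
        self.X = d.X.to_numpy()
        self.y = d.y
        self.offset = d.offset
        self.censored = d.censored
        self.is_duration = post.is_duration
        self.C, self.P, self.D, self.I = settings.chains, post.P, post.D, post.I
        self.n = len(d.y)
        self.date_idx = d.group_index_date
        self.ind_idx = d.group_index_individual
        # segment boundaries for per-group log-likelihood sums
        self.order_d = np.argsort(self.date_idx, kind="stable")
        self.starts_d = np.searchsorted(
            self.date_idx[self.order_d], np.arange(self.D)
        )
        self.order_i = np.argsort(self.ind_idx, kind="stable")
        self.starts_i = np.searchsorted(
            self.ind_idx[self.order_i], np.arange(self.I)
        )
        self.accept_rate = float("nan")

    def _ll_obs(self, eta: np.ndarray, log_sigma: np.ndarray | None) -> np.ndarray:
        """(C, n) per-observation log-likelihood; -inf rows are rejected."""
        with np.errstate(over="ignore", invalid="ignore"):
            if self.is_duration:
                mu = eta + self.offset[None, :]
                ll = models.loglik_duration(
                    self.y[None, :],
                    self.censored[None, :],
                    mu,
                    np.exp(log_sigma)[:, None],
                    self.offset[None, :],
                )
            else:
                ll = models.loglik_frequency(self.y[None, :], eta, self.offset[None, :])
        return np.where(np.isfinite(ll), ll, -np.inf)

    def _prior_beta(self, beta: np.ndarray) -> np.ndarray:
        p = self.spec.priors
        return np.sum(
            models.student_t_logpdf(beta, p.coef_df, p.coef_loc, p.coef_scale), axis=1
        )

    def _prior_scales(self, log_sds, log_sigma) -> np.ndarray:
        """Half-t priors plus log-Jacobians of the log transforms."""
        p = self.spec.priors
        total = np.zeros(self.C)
        if log_sds is not None:
            sds = np.exp(log_sds)
            total = total + np.sum(
                models.half_student_t_logpdf(sds, p.sd_df, p.sd_scale) + log_sds,
                axis=1,
            )
        if log_sigma is not None:
            total = total + (
                models.half_student_t_logpdf(np.exp(log_sigma), p.sd_df, p.sd_scale)
                + log_sigma
            )
        return total

    @staticmethod
    def _u_prior_terms(u: np.ndarray, sd: np.ndarray) -> np.ndarray:
        """(C, D) Gaussian log-density of each random intercept."""
        return -0.5 * (u / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)

    def run(self) -> np.ndarray:
        rng = self.rng
        s = self.settings
        C, P, D, I = self.C, self.P, self.D, self.I
        has_re = self.spec.include_random_effects and (D or I)

        beta = np.zeros((C, P))
        if self.spec.response == "frequency":
            beta += 0.1 * rng.standard_normal((C, P))
        u_date = np.zeros((C, D))
        u_ind = np.zeros((C, I))
        log_sds = np.zeros((C, 2)) if has_re else None
        log_sigma = np.zeros(C) if self.is_duration else None

        eta = beta @ self.X.T
        if has_re:
            eta = eta + u_date[:, self.date_idx] + u_ind[:, self.ind_idx]
        ll = self._ll_obs(eta, log_sigma)
        if not np.all(np.isfinite(ll.sum(axis=1))):
            raise RuntimeError(
                "non-finite log posterior at initialisation "
                f"(model {self.spec.model_id}, {self.spec.response})"
            )

        # proposal state
        step_beta = np.full(P, 0.05)
        chol_beta: np.ndarray | None = None
        lsc_beta = np.zeros(C)
        step_ud = np.full(D, 0.3) if D else None
        step_ui = np.full(I, 0.3) if I else None
        n_scales = (2 if has_re else 0) + (1 if self.is_duration else 0)
        step_sc = np.full(n_scales, 0.3) if n_scales else None
        lsc_sc = np.zeros(C)
        cols_list = list(self.post.design.column_names)
        self.intercept_col = (
            cols_list.index("Intercept") if "Intercept" in cols_list else None
        )
        step_tr = np.full(2, 0.3)
        acc_tr = np.zeros(2)

        window = 50
        acc_beta = np.zeros(C)
        acc_ud = np.zeros(D) if D else None
        acc_ui = np.zeros(I) if I else None
        acc_sc = np.zeros(C)
        beta_history: list[np.ndarray] = []
        keep = s.iterations - s.warmup
        out = np.empty((C, keep, self.post.n_params))
        post_accepts = 0

        for it in range(s.iterations):
            warm = it < s.warmup

            # --- block 1: coefficients ---------------------------------
            z = rng.standard_normal((C, P))
            jump = step_beta[None, :] * z if chol_beta is None else z @ chol_beta.T
            beta_prop = beta + np.exp(lsc_beta)[:, None] * jump
            eta_prop = beta_prop @ self.X.T
            if has_re:
                eta_prop = eta_prop + u_date[:, self.date_idx] + u_ind[:, self.ind_idx]
            ll_prop = self._ll_obs(eta_prop, log_sigma)
            logr = (
                ll_prop.sum(axis=1)
                - ll.sum(axis=1)
                + self._prior_beta(beta_prop)
                - self._prior_beta(beta)
            )
            acc = np.log(rng.uniform(size=C)) < logr
            beta = np.where(acc[:, None], beta_prop, beta)
            eta = np.where(acc[:, None], eta_prop, eta)
            ll = np.where(acc[:, None], ll_prop, ll)
            acc_beta += acc
            if not warm:
                post_accepts += int(acc.sum())

            # --- block 2 & 3: random intercepts, coordinate-wise -------
            if has_re:
                for (u, step_u, acc_u, idx, order, starts, sd_col) in (
                    (u_date, step_ud, acc_ud, self.date_idx, self.order_d, self.starts_d, 0),
                    (u_ind, step_ui, acc_ui, self.ind_idx, self.order_i, self.starts_i, 1),
                ):
                    G = u.shape[1]
                    if not G:
                        continue
                    u_prop = u + step_u[None, :] * rng.standard_normal((C, G))
                    eta_prop = eta + (u_prop - u)[:, idx]
                    ll_prop = self._ll_obs(eta_prop, log_sigma)
                    delta_sorted = (ll_prop - ll)[:, order]
                    delta_g = np.add.reduceat(delta_sorted, starts, axis=1)
                    sd = np.exp(log_sds[:, sd_col : sd_col + 1])
                    delta_g = delta_g + self._u_prior_terms(u_prop, sd) - self._u_prior_terms(u, sd)
                    mask = np.log(rng.uniform(size=(C, G))) < delta_g
                    u[mask] = u_prop[mask]
                    obs_mask = mask[:, idx]
                    eta = np.where(obs_mask, eta_prop, eta)
                    ll = np.where(obs_mask, ll_prop, ll)
                    if warm:
                        acc_u += mask.mean(axis=0)

            # --- translation moves -------------------------------------
            # eta identifies only intercept + mean(u); shifting mass between
            # them leaves the likelihood unchanged, so these ridge moves are
            # accepted on the prior ratio alone and decorrelate the blocks.
            if has_re and self.intercept_col is not None:
                ic = self.intercept_col
                for k, (u, sd_col) in enumerate(((u_date, 0), (u_ind, 1))):
                    G = u.shape[1]
                    if not G:
                        continue
                    delta = step_tr[k] * rng.standard_normal(C)
                    b0_prop = beta[:, ic] + delta
                    p = self.spec.priors
                    sd = np.exp(log_sds[:, sd_col])
                    logr = (
                        models.student_t_logpdf(b0_prop, p.coef_df, p.coef_loc, p.coef_scale)
                        - models.student_t_logpdf(beta[:, ic], p.coef_df, p.coef_loc, p.coef_scale)
                        - 0.5 * (np.sum((u - delta[:, None]) ** 2, axis=1) - np.sum(u**2, axis=1)) / sd**2
                    )
                    acc = np.log(rng.uniform(size=C)) < logr
                    beta[:, ic] = np.where(acc, b0_prop, beta[:, ic])
                    u -= np.where(acc, delta, 0.0)[:, None]
                    acc_tr[k] += acc.mean()

            # --- block 4: scale parameters -----------------------------
            if n_scales:
                zsc = rng.standard_normal((C, n_scales))
                prop = np.exp(lsc_sc)[:, None] * step_sc[None, :] * zsc
                if has_re:
                    log_sds_prop = log_sds + prop[:, :2]
                else:
                    log_sds_prop = None
                logr = self._prior_scales(log_sds_prop, None) - self._prior_scales(
                    log_sds, None
                )
                if has_re:
                    for u, col in ((u_date, 0), (u_ind, 1)):
                        if u.shape[1]:
                            logr = logr + (
                                self._u_prior_terms(u, np.exp(log_sds_prop[:, col : col + 1]))
                                - self._u_prior_terms(u, np.exp(log_sds[:, col : col + 1]))
                            ).sum(axis=1)
                if self.is_duration:
                    log_sigma_prop = log_sigma + prop[:, -1]
                    ll_prop = self._ll_obs(eta, log_sigma_prop)
                    logr = (
                        logr
                        + ll_prop.sum(axis=1)
                        - ll.sum(axis=1)
                        + self._prior_scales(None, log_sigma_prop)
                        - self._prior_scales(None, log_sigma)
                    )
                acc = np.log(rng.uniform(size=C)) < logr
                if has_re:
                    log_sds = np.where(acc[:, None], log_sds_prop, log_sds)
                if self.is_duration:
                    log_sigma = np.where(acc, log_sigma_prop, log_sigma)
                    ll = np.where(acc[:, None], ll_prop, ll)
                acc_sc += acc

            # --- adaptation --------------------------------------------
            if warm:
                beta_history.append(beta.copy())
                if (it + 1) % window == 0:
                    lsc_beta += 0.6 * (acc_beta / window - 0.27)
                    acc_beta[:] = 0
                    if n_scales:
                        lsc_sc += 0.6 * (acc_sc / window - 0.35)
                        acc_sc[:] = 0
                    for step_u, acc_u in ((step_ud, acc_ud), (step_ui, acc_ui)):
                        if step_u is not None:
                            rate = acc_u / window
                            np.multiply(
                                step_u,
                                np.exp(np.clip(0.8 * (rate - 0.44), -0.5, 0.5)),
                                out=step_u,
                            )
                            np.clip(step_u, 1e-3, 10.0, out=step_u)
                            acc_u[:] = 0
                    step_tr *= np.exp(np.clip(0.8 * (acc_tr / window - 0.44), -0.5, 0.5))
                    np.clip(step_tr, 1e-3, 10.0, out=step_tr)
                    acc_tr[:] = 0
                if (it + 1) % 100 == 0:
                    recent = np.concatenate(beta_history[-500:], axis=0)
                    if it + 1 < 300 or P == 1:
                        step_beta = np.maximum(recent.std(axis=0), 1e-3)
                        chol_beta = None
                    else:
                        cov = np.cov(recent.T) + 1e-8 * np.eye(P)
                        try:
                            chol_beta = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            step_beta = np.maximum(recent.std(axis=0), 1e-3)
                            chol_beta = None
            else:
                j = it - s.warmup
                cols = [beta]
                if has_re:
                    cols += [u_date, u_ind, log_sds]
                elif self.spec.include_random_effects:
                    cols += [u_date, u_ind, np.zeros((C, 2))]
                if self.is_duration:
                    cols.append(log_sigma[:, None])
                out[:, j, :] = np.concatenate(cols, axis=1)

        self.accept_rate = post_accepts / (C * keep)
        return out


def _diagnostics(out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-R-hat and bulk ESS per parameter via arviz."""
    C, keep, Ptot = out.shape
    rhat = np.empty(Ptot)
    ess = np.empty(Ptot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(Ptot):
            chains = out[:, :, p]
            if np.allclose(chains.std(), 0):
                rhat[p] = 1.0
                ess[p] = float(C * keep)
                continue
            rhat[p] = float(az.rhat(chains))
            ess[p] = float(az.ess(chains))
    return rhat, ess


def pointwise_loglik(
    fit_result: PosteriorFit,
    spec: models.ModelSpec | None = None,
    table: pd.DataFrame | None = None,
    batch: int = 500,
) -> np.ndarray:
    """S x n matrix of conditional per-observation log-likelihoods.

    With ``table`` given, log-likelihoods are evaluated for those rows
    (grouping levels must come from the fitted design); otherwise the
    training rows are scored.
    """
    spec = spec or fit_result.spec
    if table is None:
        post = _Posterior(spec, fit_result.design)
    else:
        design = models.build_design(spec, table)
        # score new rows against the fitted grouping levels
        fitted = fit_result.design
        date_map = {d: i for i, d in enumerate(fitted.date_levels)}
        ind_map = {d: i for i, d in enumerate(fitted.individual_levels)}
        try:
            design.group_index_date = np.array(
                [date_map[d] for d in table["date"]]
            )
            design.group_index_individual = np.array(
                [ind_map[i] for i in table["individual_id"]]
            )
        except KeyError as exc:
            raise ValueError(f"grouping level {exc} absent from the fit") from exc
        design.date_levels = fitted.date_levels
        design.individual_levels = fitted.individual_levels
        post = _Posterior(spec, design)
        post.param_names = fit_result.param_names
    theta = fit_result.draws[fit_result.param_names].to_numpy().copy()
    # stored draws hold sds/sigma on the natural scale; the posterior object
    # works on the log scale internally
    for i, name in enumerate(fit_result.param_names):
        if name in ("sd_date", "sd_individual", "sigma"):
            theta[:, i] = np.log(theta[:, i])
    rows = []
    for start in range(0, theta.shape[0], batch):
        rows.append(post.pointwise_loglik(theta[start : start + batch]))
    return np.concatenate(rows, axis=0)


def predicted_mean(
    fit_result: PosteriorFit, conditional: bool = True, batch: int = 500
) -> np.ndarray:
    """S x n posterior draws of each observation's expected response.

    Conditional predictions include the sampled random intercepts; marginal
    predictions set them to zero.  Frequency models return the Poisson mean
    (exposure included); duration models return the latent mean mu.
    """
    post = _Posterior(fit_result.spec, fit_result.design)
    theta = fit_result.draws[fit_result.param_names].to_numpy()
    out = []
    for start in range(0, theta.shape[0], batch):
        eta = post.linear_predictor(theta[start : start + batch], conditional=conditional)
        if fit_result.spec.response == "frequency":
            out.append(np.exp(eta + np.log(fit_result.design.offset)[None, :]))
        else:
            out.append(eta + fit_result.design.offset[None, :])
    return np.concatenate(out, axis=0)


def credible_interval(
    fit_result: PosteriorFit, parameter: str, level: float = 0.95
) -> tuple[float, float]:
    """Central credible interval from the empirical draw quantiles."""
    if parameter not in fit_result.draws.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    alpha = (1.0 - level) / 2.0
    d = fit_result.draws[parameter]
    return float(d.quantile(alpha)), float(d.quantile(1.0 - alpha))
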