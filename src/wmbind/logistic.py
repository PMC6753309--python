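"""Descriptive analysis: hierarchical logistic regression with Bayes factors.

Accuracy in the n-AFC conditions is modelled as binomial counts per subject x
condition cell with a logistic link. The linear predictor contains fixed main
effects of memory set size, RSS_List and RSS_New, a random (per-subject)
intercept, and random slopes for all three main effects and their two-way
interactions. Predictors are centered and scaled by twice their standard
deviation, so the fixed-effect coefficients are standardized effect sizes;
those receive Cauchy priors with a default scale of 0.353, and the
random-effect SDs half-Cauchy priors with the same scale.

The evidence for each predictor is the Bayes factor comparing the full model
against the model without that predictor's fixed main effect (the random part
is unchanged), computed from bridge-sampled marginal likelihoods. Because the
Bayes factor depends on the effect-size prior, a sensitivity analysis
recomputes it over a grid of Cauchy scales (default spanning 0.25-3.0).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import log_expit

from .bridge import BridgeResult, bridge_sample

PREDICTORS = ("set_size", "rss_list", "rss_new")
INTERACTIONS = (("set_size", "rss_list"), ("set_size", "rss_new"), ("rss_list", "rss_new"))


@dataclass
class BFConfig:
    """Priors, sampler and bridge settings for the Bayes-factor analysis."""

    prior_scale: float = 0.353
    intercept_scale: float = 2.5
    sensitivity_scales: tuple[float, ...] = (0.25, 0.353, 0.5, 1.0, 2.0, 3.0)
    chains: int = 4
    warmup: int = 1000
    draws: int = 2500
    bridge_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_scale <= 0 or any(s <= 0 for s in self.sensitivity_scales):
            raise ValueError("prior scales must be positive")


@dataclass
class LogisticData:
    """Aggregated accuracy counts with standardized design matrices."""

    subjects: np.ndarray          # (S,)
    k_correct: np.ndarray         # (S, n_cells)
    n_total: np.ndarray           # (S, n_cells)
    z: dict[str, np.ndarray]      # predictor -> standardized values (n_cells,)
    standardization: pd.DataFrame # predictor, mean, sd (invertible record)


def aggregate_accuracy(data: pd.DataFrame) -> LogisticData:
    """Collapse an n-AFC trial table to correct/total counts per subject x cell.

    Predictors are standardized as (x - mean)/(2 sd) over the design cells so
    that a one-unit change spans roughly the predictor's range and
    coefficients are comparable standardized effect sizes.
    """
    df = data
    if "analyze" in df.columns:
        df = df[df["analyze"]]
    df = df[~df["is_recall"].astype(bool)]
    if df.empty:
        raise ValueError("no analyzable n-AFC trials")
    agg = (
        df.assign(correct=df["response_category"].eq("correct"))
        .groupby(["subject", "set_size", "rss_list", "rss_new"], as_index=False)
        .agg(k=("correct", "sum"), n=("correct", "size"))
    )
    cells = (
        agg[["set_size", "rss_list", "rss_new"]]
        .drop_duplicates()
        .sort_values(["set_size", "rss_list", "rss_new"])
        .reset_index(drop=True)
    )
    subjects = np.sort(agg["subject"].unique())
    s_idx = {s: i for i, s in enumerate(subjects)}
    c_idx = {tuple(r): i for i, r in enumerate(cells.to_numpy())}
    k = np.zeros((len(subjects), len(cells)))
    n = np.zeros((len(subjects), len(cells)))
    for row in agg.itertuples(index=False):
        i, j = s_idx[row.subject], c_idx[(row.set_size, row.rss_list, row.rss_new)]
        k[i, j] = row.k
        n[i, j] = row.n
    z, std_rows = {}, []
    for p in PREDICTORS:
        x = cells[p].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std(ddof=0)
        # a predictor constant over the design carries no information; its
        # standardized column is zero and the coefficient is prior-dominated
        z[p] = (x - mu) / (2 * sd) if sd > 0 else np.zeros_like(x)
        std_rows.append(dict(predictor=p, mean=mu, sd=sd, scale=2 * sd))
    return LogisticData(subjects=subjects, k_correct=k, n_total=n, z=z,
                        standardization=pd.DataFrame(std_rows))


@dataclass
class LogisticModel:
    """One concrete model: which fixed main effects it contains.

    The random part (intercept + main-effect and two-way-interaction slopes)
    is identical for every model in a comparison, so dropping a fixed effect
    changes only the population-level claim being tested.
    """

    data: LogisticData
    config: BFConfig
    fixed: tuple[str, ...] = PREDICTORS

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        z = self.data.z
        self.z_fixed = np.column_stack(
            [np.ones(len(next(iter(z.values()))))] + [z[p] for p in self.fixed]
        )  # (n_cells, 1 + F)
        self.z_random = np.column_stack(
            [np.ones_like(z["set_size"])]
            + [z[p] for p in PREDICTORS]
            + [z[a] * z[b] for a, b in INTERACTIONS]
        )  # (n_cells, 7)
        self.n_fixed = self.z_fixed.shape[1]
        self.n_random = self.z_random.shape[1]
        self.n_subjects = self.data.k_correct.shape[0]
        self.dim = self.n_fixed + self.n_subjects * self.n_random + self.n_random

    # --- parameter packing: [beta, u.flatten(S x R), log_sigma] ---

    def unpack(self, theta: np.ndarray):
        theta = np.atleast_2d(theta)
        F, S, R = self.n_fixed, self.n_subjects, self.n_random
        beta = theta[:, :F]
        u = theta[:, F:F + S * R].reshape(-1, S, R)
        log_sigma = theta[:, F + S * R:]
        return beta, u, log_sigma

    def log_joint(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior density, vectorized over rows of theta.

        Includes the Jacobian of the log transform on the random-effect SDs,
        so the density is with respect to the unconstrained parameterization
        (as the bridge sampler requires).
        """
        beta, u, log_sigma = self.unpack(theta)
        sigma = np.exp(log_sigma)
        eta = beta @ self.z_fixed.T              # (D, n_cells)
        eta = eta[:, None, :] + np.einsum("dsr,cr->dsc", u, self.z_random)
        k, n = self.data.k_correct, self.data.n_total
        ll = (k * log_expit(eta) + (n - k) * log_expit(-eta)).sum(axis=(1, 2))
        # priors
        scales = np.array([self.config.intercept_scale]
                          + [self.config.prior_scale] * (self.n_fixed - 1))
        lp = -np.log1p((beta / scales) ** 2).sum(axis=1) - np.log(np.pi * scales).sum()
        z = u / sigma[:, None, :]
        lp += (-0.5 * z**2 - np.log(sigma)[:, None, :]).sum(axis=(1, 2))
        lp += -0.5 * u.shape[1] * u.shape[2] * np.log(2 * np.pi)
        # half-Cauchy on sigma, with log-Jacobian of the log transform
        hc = self.config.prior_scale
        lp += (-np.log1p((sigma / hc) ** 2) + np.log(2.0 / (np.pi * hc)) + log_sigma).sum(axis=1)
        return ll + lp

    def log_joint_noncentered(self, theta_nc: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior in the non-centered parameterization.

        Substitutes u = u_tilde * sigma (with the S*log(sigma) Jacobian per
        random-effect column). The marginal likelihood is invariant under this
        change of variables, but the posterior is much closer to Gaussian —
        the scale-funnel between u and sigma is flattened — which is where the
        bridge sampler's moment-matched normal proposal works best.
        """
        theta_nc = np.atleast_2d(theta_nc)
        beta, u_t, log_sigma = self.unpack(theta_nc)
        sigma = np.exp(log_sigma)
        u = u_t * sigma[:, None, :]
        theta_c = np.concatenate(
            [beta, u.reshape(len(theta_nc), -1), log_sigma], axis=1
        )
        S = self.n_subjects
        return self.log_joint(theta_c) + S * log_sigma.sum(axis=1)

    def to_noncentered(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta, u, log_sigma = self.unpack(theta)
        u_t = u / np.exp(log_sigma)[:, None, :]
        return np.concatenate([beta, u_t.reshape(len(theta), -1), log_sigma], axis=1)


@dataclass
class LogisticFit:
    """Posterior draws and diagnostics for one fitted logistic model."""

    model: LogisticModel
    draws: np.ndarray             # (chains, draws, dim)
    fixed_names: tuple[str, ...]
    diagnostics: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return not self.warnings

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def fixed_effect_draws(self, predictor: str) -> np.ndarray:
        idx = self.fixed_names.index(predictor)
        return self.flat()[:, idx]

    def hdi(self, predictor: str, prob: float = 0.95) -> tuple[float, float]:
        lo, hi = az.hdi(self.fixed_effect_draws(predictor), hdi_prob=prob)
        return float(lo), float(hi)


def fit_accuracy_model(
    data: LogisticData | pd.DataFrame,
    config: BFConfig | None = None,
    fixed: tuple[str, ...] = PREDICTORS,
) -> LogisticFit:
    """Sample the hierarchical logistic model by adaptive Metropolis-within-Gibbs.

    Component-wise random-walk updates for the fixed effects and (vectorized
    across subjects) for each random-effect column, plus log-scale random
    walks for the random-effect SDs; proposal scales adapt during warmup.
    """
    config = config or BFConfig()
    ldata = aggregate_accuracy(data) if isinstance(data, pd.DataFrame) else data
    model = LogisticModel(data=ldata, config=config, fixed=tuple(fixed))
    F, S, R = model.n_fixed, model.n_subjects, model.n_random
    k, n = ldata.k_correct, ldata.n_total
    Zf, Zr = model.z_fixed, model.z_random
    hc = config.prior_scale

    def loglik_subj(beta, u):
        eta = (Zf @ beta)[None, :] + u @ Zr.T
        return (k * log_expit(eta) + (n - k) * log_expit(-eta)).sum(axis=1)

    ss = np.random.SeedSequence(config.seed)
    all_draws = np.empty((config.chains, config.draws, model.dim))
    for c, child in enumerate(ss.spawn(config.chains)):
        rng = np.random.default_rng(child)
        beta = 0.1 * rng.standard_normal(F)
        sigma = 0.3 * np.exp(0.2 * rng.standard_normal(R))
        u = 0.05 * rng.standard_normal((S, R))
        ll = loglik_subj(beta, u)

        step_b = np.full(F, 0.05)
        step_u = np.full((S, R), 0.1)
        step_s = np.full(R, 0.3)
        step_t = np.full(F, 0.1)
        step_f = np.full(R, 0.2)
        total = config.warmup + config.draws
        for t in range(total):
            adapting = t < config.warmup
            gamma = 1.0 / (1 + t) ** 0.6 if adapting else 0.0

            # fixed effects, component-wise (beta couples all subjects)
            scales = np.array([config.intercept_scale] + [config.prior_scale] * (F - 1))
            for j in range(F):
                prop = beta.copy()
                prop[j] += step_b[j] * rng.standard_normal()
                ll_prop = loglik_subj(prop, u)
                la = (ll_prop.sum() - ll.sum()
                      - np.log1p((prop[j] / scales[j]) ** 2)
                      + np.log1p((beta[j] / scales[j]) ** 2))
                if np.log(rng.random()) < la:
                    beta, ll = prop, ll_prop
                    acc = 1.0
                else:
                    acc = 0.0
                if adapting:
                    step_b[j] *= np.exp(gamma * (acc - 0.44))

            # random effects, column-wise, vectorized across subjects
            for r in range(R):
                prop_u = u.copy()
                prop_u[:, r] = u[:, r] + step_u[:, r] * rng.standard_normal(S)
                ll_prop = loglik_subj(beta, prop_u)
                la = (ll_prop - ll
                      - 0.5 * (prop_u[:, r] / sigma[r]) ** 2
                      + 0.5 * (u[:, r] / sigma[r]) ** 2)
                accept = np.log(rng.random(S)) < la
                u[accept, r] = prop_u[accept, r]
                ll = np.where(accept, ll_prop, ll)
                if adapting:
                    step_u[:, r] *= np.exp(gamma * (accept - 0.44))

            # joint (beta_j, u_col) translation: the likelihood depends on
            # beta_j + mean(u) along shared design columns, so move along that
            # ridge; eta is unchanged and only the priors enter the ratio
            for j in range(F):
                r = 0 if j == 0 else 1 + PREDICTORS.index(model.fixed[j - 1])
                delta = step_t[j] * rng.standard_normal()
                b_new = beta[j] + delta
                u_new_col = u[:, r] - delta
                la = (
                    -np.log1p((b_new / scales[j]) ** 2)
                    + np.log1p((beta[j] / scales[j]) ** 2)
                    - 0.5 * ((u_new_col**2).sum() - (u[:, r] ** 2).sum()) / sigma[r] ** 2
                )
                if np.log(rng.random()) < la:
                    beta[j] = b_new
                    u[:, r] = u_new_col
                    acc = 1.0
                else:
                    acc = 0.0
                if adapting:
                    step_t[j] *= np.exp(gamma * (acc - 0.44))

            # joint (sigma_r, u_col) rescaling: traverses the funnel
            for r in range(R):
                lam = np.exp(step_f[r] * rng.standard_normal())
                s_new = sigma[r] * lam
                prop_u = u.copy()
                prop_u[:, r] = u[:, r] * lam
                ll_prop = loglik_subj(beta, prop_u)
                la = (
                    ll_prop.sum() - ll.sum()
                    - np.log1p((s_new / hc) ** 2) + np.log1p((sigma[r] / hc) ** 2)
                    + np.log(s_new) - np.log(sigma[r])
                )
                if np.log(rng.random()) < la:
                    u, ll = prop_u, ll_prop
                    sigma[r] = s_new
                    acc = 1.0
                else:
                    acc = 0.0
                if adapting:
                    step_f[r] *= np.exp(gamma * (acc - 0.234))

            # random-effect SDs: log-scale random walk, half-Cauchy prior
            sum_u2 = (u**2).sum(axis=0)
            log_s_prop = np.log(sigma) + step_s * rng.standard_normal(R)
            s_prop = np.exp(log_s_prop)

            def _sd_logpost(s):
                return (-S * np.log(s) - sum_u2 / (2 * s**2)
                        - np.log1p((s / hc) ** 2) + np.log(s))

            la = _sd_logpost(s_prop) - _sd_logpost(sigma)
            accept = np.log(rng.random(R)) < la
            sigma = np.where(accept, s_prop, sigma)
            if adapting:
                step_s *= np.exp(gamma * (accept - 0.44))

            if t >= config.warmup:
                all_draws[c, t - config.warmup] = np.concatenate(
                    [beta, u.reshape(-1), np.log(sigma)]
                )

    fixed_names = ("intercept",) + tuple(model.fixed)
    post = {nm: all_draws[:, :, i] for i, nm in enumerate(fixed_names)}
    post.update({f"sd_{i}": all_draws[:, :, F + S * R + i] for i in range(R)})
    idata = az.from_dict(posterior=post)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    warn = []
    max_rhat, min_ess = 0.0, np.inf
    for nm in post:
        r, e = float(rhat[nm].values), float(ess[nm].values)
        max_rhat, min_ess = max(max_rhat, r), min(min_ess, e)
        if r > 1.05:
            warn.append(f"{nm}: split-R-hat {r:.3f}")
    diagnostics = {"max_rhat": max_rhat, "min_ess_bulk": float(min_ess)}
    return LogisticFit(model=model, draws=all_draws, fixed_names=fixed_names,
                       diagnostics=diagnostics, warnings=warn)


@dataclass
class BFResult:
    """Bayes factor for keeping one predictor's fixed effect in the model."""

    predictor: str
    bf: float
    log_ml_full: BridgeResult
    log_ml_reduced: BridgeResult
    warnings: list[str] = field(default_factory=list)

    @property
    def log_bf(self) -> float:
        return self.log_ml_full.log_ml - self.log_ml_reduced.log_ml

    @property
    def spread(self) -> float:
        return float(np.hypot(self.log_ml_full.spread, self.log_ml_reduced.spread))


def marginal_likelihood(fit: LogisticFit, rng: np.random.Generator,
                        reps: int = 3) -> BridgeResult:
    """Bridge-sampled log marginal likelihood of a fitted model.

    Bridging runs in the non-centered parameterization, where the posterior
    geometry is closest to the normal proposal; the estimand is unchanged.
    """
    draws_nc = fit.model.to_noncentered(fit.flat())
    return bridge_sample(fit.model.log_joint_noncentered, draws_nc, rng, reps=reps)


def bayes_factor(
    data: LogisticData | pd.DataFrame,
    predictor: str,
    config: BFConfig | None = None,
    full_fit: LogisticFit | None = None,
) -> BFResult:
    """BF for the fixed main effect of ``predictor`` (full vs. reduced model).

    Both models are fitted on the same counts with identical priors except for
    the dropped fixed term; marginal likelihoods come from bridge sampling
    with repeated estimates to quantify estimator noise.
    """
    config = config or BFConfig()
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}; expected one of {PREDICTORS}")
    ldata = aggregate_accuracy(data) if isinstance(data, pd.DataFrame) else data
    if full_fit is None:
        full_fit = fit_accuracy_model(ldata, config)
    if predictor not in full_fit.model.fixed:
        raise ValueError(f"predictor {predictor!r} is not in the fitted model")
    reduced_fixed = tuple(p for p in full_fit.model.fixed if p != predictor)
    red_cfg = replace(config, seed=config.seed + 1)
    reduced_fit = fit_accuracy_model(ldata, red_cfg, fixed=reduced_fixed)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(97,)))
    ml_full = marginal_likelihood(full_fit, rng, reps=config.bridge_reps)
    ml_red = marginal_likelihood(reduced_fit, rng, reps=config.bridge_reps)
    warn = list(full_fit.warnings) + list(reduced_fit.warnings)
    spread = float(np.hypot(ml_full.spread, ml_red.spread))
    if spread > 0.1:
        warn.append(f"bridge estimator spread {spread:.3f} on the log scale exceeds 0.1")
    return BFResult(predictor=predictor, bf=float(np.exp(ml_full.log_ml - ml_red.log_ml)),
                    log_ml_full=ml_full, log_ml_reduced=ml_red, warnings=warn)


def sensitivity_analysis(
    data: LogisticData | pd.DataFrame,
    predictor: str,
    scales: tuple[float, ...] | None = None,
    config: BFConfig | None = None,
) -> pd.DataFrame:
    """Recompute the predictor's BF across a grid of Cauchy prior scales.

    Returns one row per scale plus the min/max range; the default grid spans
    0.25-3.0 and includes the default scale.
    """
    config = config or BFConfig()
    scales = tuple(scales) if scales is not None else config.sensitivity_scales
    if any(s <= 0 for s in scales):
        raise ValueError("prior scales must be positive")
    rows = []
    for s in scales:
        cfg = replace(config, prior_scale=s)
        res = bayes_factor(data, predictor, cfg)
        rows.append(dict(predictor=predictor, prior_scale=s, bf=res.bf,
                         log_bf=res.log_bf, spread=res.spread))
    out = pd.DataFrame(rows)
    out.attrs["bf_range"] = (out["bf"].min(), out["bf"].max())
    return out
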