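"""Bayesian two-species occupancy model with asymmetric interaction.

A dominant species (A, the jungle cat) and a subordinate species (B, the
leopard cat) are modelled jointly at n sites over T sampling occasions, with
imperfect detection:

    z_A(i) ~ Bernoulli(psi_A(i)),   logit psi_A = alpha0 + alpha1*evergreen
                                                 + alpha2*water
    z_B(i) ~ Bernoulli(psi_B(i)),   logit psi_B = beta0 + beta1*evergreen
                                                 + beta2*water
                                                 + eta_psi * z_A(i)
    y_A(i,t) | z_A ~ Bernoulli(z_A * p_A(i,t)),  logit p_A = a0 + a1*effort
    y_B(i,t) | z_B ~ Bernoulli(z_B * p_B(i,t)),  logit p_B = b0 + b1*effort
                                                 + b2 * d_A(i)

where d_A(i) indicates that the dominant species was detected at least once
at site i (the detection-level interaction) and eta_psi carries the
occupancy-level effect of dominant presence on the subordinate. Effort (days
a camera was functional per occasion) is standardized over surveyed
site-occasions. All coefficients get weakly informative Normal(0, 1.5^2)
priors on the logit scale.

Inference is Metropolis-within-Gibbs: the latent presence states z are drawn
from their exact Bernoulli full conditionals, coefficients move by random
walk Metropolis with per-coefficient step sizes adapted during burn-in only
(frozen afterwards, preserving detailed balance). Convergence is monitored
with the Gelman-Rubin statistic and fit with Freeman-Tukey posterior
predictive checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "PARAM_NAMES",
    "CoOccupancyData",
    "ModelSpec",
    "DESK_SPEC",
    "PAPER_SPEC",
    "PosteriorDraws",
    "FitSummary",
    "standardize_covariates",
    "complete_data_loglik",
    "fit_mcmc",
    "gelman_rubin",
    "freeman_tukey_gof",
    "summarize_posterior",
]

PARAM_NAMES = [
    "alpha0",            # dominant occupancy intercept
    "alpha_evergreen",   # dominant occupancy: evergreen effect
    "alpha_water",       # dominant occupancy: distance-to-water effect
    "beta0",             # subordinate occupancy intercept
    "beta_evergreen",
    "beta_water",
    "eta_psi",           # effect of dominant presence on subordinate occupancy
    "a0",                # dominant detection intercept
    "a_effort",
    "b0",                # subordinate detection intercept
    "b_effort",
    "b_dom_detected",    # effect of dominant detection on subordinate detection
]
_P = len(PARAM_NAMES)
_SL_A = slice(0, 3)      # alpha
_SL_B = slice(3, 6)      # beta (without eta)
_I_ETA = 6
_SL_DA = slice(7, 9)     # a
_SL_DB = slice(9, 12)    # b


def standardize_covariates(values) -> np.ndarray:
    """Center and scale to zero mean, unit SD (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant covariate cannot be standardized")
    return (x - x.mean()) / sd


@dataclass
class CoOccupancyData:
    """Detection matrices, effort, and site covariates for the joint model.

    ``y_a``/``y_b`` are site x occasion matrices in {0, 1, nan}; nan marks
    unsurveyed cells and must coincide with zero effort. ``dist_water_std``
    must arrive standardized; effort is standardized internally over the
    surveyed cells.
    """

    y_a: np.ndarray
    y_b: np.ndarray
    effort: np.ndarray
    evergreen: np.ndarray
    dist_water_std: np.ndarray
    surveyed: np.ndarray = field(init=False)
    effort_std: np.ndarray = field(init=False)
    detected_a: np.ndarray = field(init=False)
    detected_b: np.ndarray = field(init=False)
    x_occ: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y_a = np.asarray(self.y_a, dtype=float)
        self.y_b = np.asarray(self.y_b, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        self.evergreen = np.asarray(self.evergreen, dtype=float)
        self.dist_water_std = np.asarray(self.dist_water_std, dtype=float)
        n, t = self.effort.shape
        if self.y_a.shape != (n, t) or self.y_b.shape != (n, t):
            raise ValueError("y and effort shapes disagree")
        if self.evergreen.shape != (n,) or self.dist_water_std.shape != (n,):
            raise ValueError("covariate shapes disagree")
        if abs(self.dist_water_std.mean()) > 1e-6 or (
            n > 2 and abs(self.dist_water_std.std(ddof=1) - 1) > 1e-6
        ):
            raise ValueError("dist_water_std must be standardized")
        self.surveyed = self.effort > 0
        for y in (self.y_a, self.y_b):
            if np.any(np.isnan(y) != ~self.surveyed):
                raise ValueError("missing y must coincide with zero effort")
        mu = self.effort[self.surveyed].mean()
        sd = self.effort[self.surveyed].std(ddof=1)
        self.effort_std = np.where(
            self.surveyed, (self.effort - mu) / (sd if sd > 0 else 1.0), 0.0
        )
        ya0 = np.nan_to_num(self.y_a)
        yb0 = np.nan_to_num(self.y_b)
        self.detected_a = (ya0 > 0).any(axis=1).astype(float)
        self.detected_b = (yb0 > 0).any(axis=1).astype(float)
        self.x_occ = np.column_stack(
            [np.ones(n), self.evergreen, self.dist_water_std]
        )

    @property
    def n_sites(self) -> int:
        return self.effort.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.effort.shape[1]


@dataclass(frozen=True)
class ModelSpec:
    """MCMC protocol: chain count, length, burn-in, thinning, prior scale."""

    chains: int = 3
    iterations: int = 250_000
    burn_in: int = 50_000
    thin: int = 20
    prior_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")


#: The full sampling protocol: 3 x 250k iterations, 50k burn-in, thin 20.
PAPER_SPEC = ModelSpec()
#: Desk-scale protocol for exploratory fits and tests.
DESK_SPEC = ModelSpec(chains=3, iterations=20_000, burn_in=5_000, thin=5)


def _lin_preds(params: np.ndarray, data: CoOccupancyData, z_a: np.ndarray):
    lp_occ_a = data.x_occ @ params[_SL_A]
    lp_occ_b = data.x_occ @ params[_SL_B] + params[_I_ETA] * z_a
    lp_det_a = params[7] + params[8] * data.effort_std
    lp_det_b = (
        params[9]
        + params[10] * data.effort_std
        + params[11] * data.detected_a[:, None]
    )
    return lp_occ_a, lp_occ_b, lp_det_a, lp_det_b


def _bern_ll(z: np.ndarray, lp: np.ndarray) -> float:
    return float(np.sum(z * log_expit(lp) + (1 - z) * log_expit(-lp)))


def _det_ll(y: np.ndarray, lp: np.ndarray, z: np.ndarray,
            surveyed: np.ndarray) -> float:
    w = surveyed & (z[:, None] > 0)
    if not w.any():
        return 0.0
    y0 = np.nan_to_num(y)
    ll = y0 * log_expit(lp) + (1 - y0) * log_expit(-lp)
    return float(ll[w].sum())


def complete_data_loglik(
    params, z_a, z_b, data: CoOccupancyData
) -> float:
    """Complete-data log-likelihood (latent z included, priors excluded).

    Sums the occupancy Bernoulli terms for both latent states and the
    detection Bernoulli terms over surveyed occasions at occupied sites.
    Returns -inf for latent states inconsistent with an observed detection.
    """
    params = np.asarray(params, dtype=float)
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if params.shape != (_P,):
        raise ValueError(f"expected {_P} parameters")
    if np.any((z_a == 0) & (data.detected_a > 0)) or np.any(
        (z_b == 0) & (data.detected_b > 0)
    ):
        return -np.inf
    lp_oa, lp_ob, lp_da, lp_db = _lin_preds(params, data, z_a)
    return (
        _bern_ll(z_a, lp_oa)
        + _bern_ll(z_b, lp_ob)
        + _det_ll(data.y_a, lp_da, z_a, data.surveyed)
        + _det_ll(data.y_b, lp_db, z_b, data.surveyed)
    )


def _run_chain(
    data: CoOccupancyData, spec: ModelSpec, rng: np.random.Generator
):
    n = data.n_sites
    surveyed = data.surveyed
    no_det_a = data.detected_a == 0
    no_det_b = data.detected_b == 0

    params = rng.normal(0.0, 0.2, _P)
    z_a = np.where(no_det_a, rng.integers(0, 2, n).astype(float), 1.0)
    z_b = np.where(no_det_b, rng.integers(0, 2, n).astype(float), 1.0)

    scales = np.full(_P, 0.3)
    accepts = np.zeros(_P)
    tries = np.zeros(_P)
    prior_var = spec.prior_sd**2

    def block_ll(j: int, p: np.ndarray) -> float:
        if j < 3:
            return _bern_ll(z_a, data.x_occ @ p[_SL_A])
        if j < 7:
            return _bern_ll(
                z_b, data.x_occ @ p[_SL_B] + p[_I_ETA] * z_a
            )
        if j < 9:
            lp = p[7] + p[8] * data.effort_std
            return _det_ll(data.y_a, lp, z_a, surveyed)
        lp = p[9] + p[10] * data.effort_std + p[11] * data.detected_a[:, None]
        return _det_ll(data.y_b, lp, z_b, surveyed)

    n_keep = (spec.iterations - spec.burn_in) // spec.thin
    out_params = np.empty((n_keep, _P))
    out_za = np.empty((n_keep, n), dtype=np.int8)
    out_zb = np.empty((n_keep, n), dtype=np.int8)
    kept = 0

    cur_ll = np.array([block_ll(j, params) for j in (0, 3, 7, 9)])
    block_of = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 3, 3, 3])

    for it in range(spec.iterations):
        # --- coefficient updates (random-walk Metropolis) ---
        for j in range(_P):
            b = block_of[j]
            prop = params.copy()
            prop[j] = params[j] + rng.normal(0.0, scales[j])
            new_ll = block_ll(j, prop)
            log_ratio = (
                new_ll
                - cur_ll[b]
                + (params[j] ** 2 - prop[j] ** 2) / (2 * prior_var)
            )
            tries[j] += 1
            if np.log(rng.random()) < log_ratio:
                params = prop
                cur_ll[b] = new_ll
                accepts[j] += 1

        # --- adapt step sizes during burn-in only ---
        if it < spec.burn_in and (it + 1) % 50 == 0:
            rate = accepts / np.maximum(tries, 1)
            scales *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            scales = np.clip(scales, 1e-3, 5.0)
            accepts[:] = 0.0
            tries[:] = 0.0

        # --- latent state updates (exact full conditionals) ---
        lp_oa, _, lp_da, lp_db = _lin_preds(params, data, z_a)
        # z_A: occupancy prior + all-zero detection history + its effect on z_B
        miss_a = np.where(surveyed, log_expit(-lp_da), 0.0).sum(axis=1)
        lp_ob0 = data.x_occ @ params[_SL_B]  # logit psi_B at z_A = 0
        lp_ob1 = lp_ob0 + params[_I_ETA]
        zb_term = z_b * (log_expit(lp_ob1) - log_expit(lp_ob0)) + (1 - z_b) * (
            log_expit(-lp_ob1) - log_expit(-lp_ob0)
        )
        logit_pa = lp_oa + miss_a + zb_term  # log w1 - log w0
        p1 = expit(logit_pa)
        z_a = np.where(no_det_a, (rng.random(n) < p1).astype(float), 1.0)

        lp_ob = data.x_occ @ params[_SL_B] + params[_I_ETA] * z_a
        miss_b = np.where(surveyed, log_expit(-lp_db), 0.0).sum(axis=1)
        p1b = expit(lp_ob + miss_b)
        z_b = np.where(no_det_b, (rng.random(n) < p1b).astype(float), 1.0)

        # z moved: refresh cached block log-likelihoods that depend on z
        cur_ll = np.array([block_ll(j, params) for j in (0, 3, 7, 9)])

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            if kept < n_keep:
                out_params[kept] = params
                out_za[kept] = z_a
                out_zb[kept] = z_b
                kept += 1

    return out_params[:kept], out_za[:kept], out_zb[:kept]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: coefficients and latent presence states.

    ``params`` has shape (chains, draws, n_params); ``z_a``/``z_b`` have
    shape (chains, draws, n_sites).
    """

    params: np.ndarray
    z_a: np.ndarray
    z_b: np.ndarray
    param_names: list[str]
    spec: ModelSpec

    def flat(self) -> np.ndarray:
        return self.params.reshape(-1, self.params.shape[-1])


def fit_mcmc(data: CoOccupancyData, spec: ModelSpec = DESK_SPEC) -> PosteriorDraws:
    """Fit the two-species occupancy model by Metropolis-within-Gibbs.

    Runs ``spec.chains`` independent chains (seeded deterministically from
    ``spec.seed``), each of ``spec.iterations`` iterations with the first
    ``spec.burn_in`` discarded and the rest thinned. Non-convergence is not
    an error; check Gelman-Rubin in :func:`summarize_posterior`.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains_p, chains_za, chains_zb = [], [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        p, za, zb = _run_chain(data, spec, rng)
        chains_p.append(p)
        chains_za.append(za)
        chains_zb.append(zb)
    return PosteriorDraws(
        params=np.stack(chains_p),
        z_a=np.stack(chains_za),
        z_b=np.stack(chains_zb),
        param_names=list(PARAM_NAMES),
        spec=spec,
    )


def gelman_rubin(traces) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor, per parameter.

    ``traces`` has shape (chains, draws) or (chains, draws, n_params).
    Classic between/within form: Rhat = sqrt(((n-1)/n * W + B/n) / W).
    """
    t = np.asarray(traces, dtype=float)
    if t.ndim == 2:
        t = t[:, :, None]
    m, n = t.shape[0], t.shape[1]
    if m < 2:
        raise ValueError("need at least two chains")
    if n < 2:
        raise ValueError("need at least two draws per chain")
    chain_means = t.mean(axis=1)
    w = t.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    vhat = (n - 1) / n * w + b_over_n
    rhat = np.sqrt(vhat / np.where(w > 0, w, np.inf))
    rhat = np.where(w > 0, rhat, 1.0)
    return rhat if rhat.size > 1 else float(rhat[0])


def _freeman_tukey(y: np.ndarray, e: np.ndarray, mask: np.ndarray) -> float:
    d = (np.sqrt(y) - np.sqrt(e)) ** 2
    return float(d[mask].sum())


def freeman_tukey_gof(
    draws: PosteriorDraws,
    data: CoOccupancyData,
    max_draws: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> dict[str, float]:
    """Posterior-predictive Bayesian p-values from Freeman-Tukey residuals.

    Per retained draw, the discrepancy R = sum over surveyed site-occasions
    of (sqrt(y) - sqrt(E[y]))^2 with E[y] the product of the draw's site-use
    and detection probabilities, is computed for the observed detections and
    for a replicate dataset simulated from the same draw. The p-value is the
    fraction of draws whose replicate discrepancy exceeds the observed one;
    values near 0.5 indicate adequate fit, values near 0 or 1 misfit.
    """
    rng = np.random.default_rng(seed)
    flat_p = draws.flat()
    flat_za = draws.z_a.reshape(-1, draws.z_a.shape[-1])
    n_draws = flat_p.shape[0]
    use = np.linspace(0, n_draws - 1, min(max_draws, n_draws)).astype(int)

    surveyed = data.surveyed
    ya0 = np.nan_to_num(data.y_a)
    yb0 = np.nan_to_num(data.y_b)
    n, t = surveyed.shape
    exceed = {"A": 0, "B": 0}

    for k in use:
        params = flat_p[k]
        z_a = flat_za[k].astype(float)
        psi_a = expit(data.x_occ @ params[_SL_A])
        psi_b = expit(data.x_occ @ params[_SL_B] + params[_I_ETA] * z_a)
        p_a = expit(params[7] + params[8] * data.effort_std)
        p_b = expit(
            params[9]
            + params[10] * data.effort_std
            + params[11] * data.detected_a[:, None]
        )
        e_a = psi_a[:, None] * p_a
        e_b = psi_b[:, None] * p_b
        r_obs_a = _freeman_tukey(ya0, e_a, surveyed)
        r_obs_b = _freeman_tukey(yb0, e_b, surveyed)

        # replicate data from this draw
        z_rep_a = (rng.random(n) < psi_a).astype(float)
        y_rep_a = np.where(
            surveyed, (rng.random((n, t)) < z_rep_a[:, None] * p_a), 0.0
        ).astype(float)
        psi_b_rep = expit(
            data.x_occ @ params[_SL_B] + params[_I_ETA] * z_rep_a
        )
        d_a_rep = (y_rep_a > 0).any(axis=1).astype(float)
        p_b_rep = expit(
            params[9]
            + params[10] * data.effort_std
            + params[11] * d_a_rep[:, None]
        )
        z_rep_b = (rng.random(n) < psi_b_rep).astype(float)
        y_rep_b = np.where(
            surveyed, (rng.random((n, t)) < z_rep_b[:, None] * p_b_rep), 0.0
        ).astype(float)
        r_rep_a = _freeman_tukey(
            y_rep_a, psi_a[:, None] * p_a, surveyed
        )
        r_rep_b = _freeman_tukey(
            y_rep_b, psi_b_rep[:, None] * p_b_rep, surveyed
        )
        exceed["A"] += r_rep_a > r_obs_a
        exceed["B"] += r_rep_b > r_obs_b

    m = len(use)
    return {"A": exceed["A"] / m, "B": exceed["B"] / m}


@dataclass
class FitSummary:
    """Posterior summaries: moments, credible intervals, Rhat, site use."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rhat: np.ndarray
    strong_support: np.ndarray
    site_use: dict[str, float]

    def as_dict(self) -> dict:
        return {
            name: {
                "mean": float(self.mean[i]),
                "sd": float(self.sd[i]),
                "ci_low": float(self.ci_low[i]),
                "ci_high": float(self.ci_high[i]),
                "rhat": float(self.rhat[i]),
                "strong_support": bool(self.strong_support[i]),
            }
            for i, name in enumerate(self.names)
        }


def summarize_posterior(draws: PosteriorDraws) -> FitSummary:
    """Posterior mean/SD, central 95% credible intervals, Rhat, site use.

    The site-use proportion per species is the posterior mean of the
    finite-sample fraction of sites with z = 1. A coefficient has "strong
    support" when its 95% credible interval excludes zero.
    """
    flat = draws.flat()
    if flat.shape[0] < 100:
        raise ValueError("need at least 100 retained draws")
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    rhat = (
        gelman_rubin(draws.params)
        if draws.params.shape[0] > 1
        else np.ones(flat.shape[1])
    )
    rhat = np.atleast_1d(rhat)
    return FitSummary(
        names=list(draws.param_names),
        mean=mean,
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        rhat=rhat,
        strong_support=(lo > 0) | (hi < 0),
        site_use={
            "A": float(draws.z_a.mean()),
            "B": float(draws.z_b.mean()),
        },
    )
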