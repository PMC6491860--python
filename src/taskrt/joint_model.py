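"""Hierarchical joint model of item responses and response times.

Level 1 models the two observables per person-item cell independently
given the latent parameters: a Rasch model for the dichotomous score,

    P(Y_ji = 1 | theta_j, b_i) = 1 / (1 + exp(-(theta_j - b_i))),

and a two-parameter lognormal model for the RT,

    log T_ji = beta_i - tau_j + eps_ji,   eps_ji ~ N(0, alpha_i^-2),

where theta_j is ability, tau_j speed (larger = faster), b_i difficulty,
beta_i time-intensity (log seconds) and alpha_i time-discrimination
(inverse residual sd).  Level 2 ties the person parameters
(theta_j, tau_j) to a bivariate normal with mean zero and covariance
Sigma_p, and the item parameters (b_i, beta_i) to a bivariate normal
with mean (mu_b, mu_beta) and covariance Sigma_I; alpha_i is treated as
independent of (b_i, beta_i).

Priors: mu_b ~ N(0, 2), mu_beta ~ N(4.5, 2) (variances), Sigma_p and
Sigma_I ~ inverse-Wishart(identity, nu=1), alpha_i ~ inverse-gamma(1, 1)
on alpha itself.

Estimation is by a bespoke MCMC sampler: conjugate Gibbs steps for
tau_j, beta_i, (mu_b, mu_beta), Sigma_p and Sigma_I, and adaptive
random-walk Metropolis steps (target acceptance 0.44, adaptation frozen
at the end of burn-in) for theta_j, b_i and log alpha_i.  The latent
means of theta and tau are recentred to zero every iteration, with
compensating shifts of b and beta, which identifies the scales while
leaving mu_b and mu_beta estimable.

Convergence is assessed by the Gelman-Rubin potential scale reduction
factor (PSR) across chains; values below 1.1 for every reported
parameter are taken as satisfactory.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import TaskDataset, register_result

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "rasch_probability",
    "rt_log_density",
    "sample_posterior",
    "eap_summary",
    "psr",
    "psr_table",
    "correlation_from_covariance",
    "correlation_estimates",
    "icc_check",
    "summarize_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def rasch_probability(theta, b):
    """P(correct) = logistic(theta - b); stable for extreme arguments."""
    return expit(np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))


def rt_log_density(t, tau, beta, alpha):
    """Log density of the lognormal RT model at time ``t`` seconds."""
    t = np.asarray(t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(t <= 0):
        raise ValueError("RT must be positive")
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    z = np.log(t) - (np.asarray(beta, float) - np.asarray(tau, float))
    return np.log(alpha) - np.log(t) - 0.5 * _LOG_2PI - 0.5 * (alpha * z) ** 2


@dataclass
class McmcConfig:
    """Sampler configuration.

    ``iterations`` counts total iterations per chain including
    ``burn_in``; every ``thin``-th post-burn-in draw is retained, so each
    chain keeps ``(iterations - burn_in) / thin`` draws.  ``nu`` is the
    inverse-Wishart prior degrees of freedom for both 2x2 covariance
    matrices; the default 1 sits at the edge of propriety for a 2x2
    matrix and can be raised to 3 for a safely proper prior.
    ``fix_alpha`` pins the time-discriminations (no sampling);
    ``use_responses=False`` drops the Rasch likelihood entirely (RT-only
    model), which is useful for conjugate closed-form checks.
    """

    chains: int = 2
    iterations: int = 15_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    nu: float = 1.0
    target_accept: float = 0.44
    mu_b_prior: tuple[float, float] = (0.0, 2.0)  # mean, variance
    mu_beta_prior: tuple[float, float] = (4.5, 2.0)
    fix_alpha: np.ndarray | None = None
    use_responses: bool = True

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if (self.iterations - self.burn_in) % self.thin != 0:
            raise ValueError("(iterations - burn_in) must be divisible by thin")
        if self.nu == 1.0:
            warnings.warn(
                "inverse-Wishart prior with nu=1 on a 2x2 covariance is at the "
                "edge of propriety; set nu=3 for a safely proper prior",
                UserWarning,
                stacklevel=2,
            )

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["fix_alpha"] is not None:
            d["fix_alpha"] = np.asarray(d["fix_alpha"]).tolist()
        d["mu_b_prior"] = list(d["mu_b_prior"])
        d["mu_beta_prior"] = list(d["mu_beta_prior"])
        return d


@dataclass
class PosteriorDraws:
    """Retained, thinned draws for all chains.

    Person/item arrays have shape ``(chains, n_retained, J or I)``;
    hyperparameter arrays ``(chains, n_retained)`` or
    ``(chains, n_retained, 3)`` for the covariance entries ordered as
    (var1, cov, var2).
    """

    theta: np.ndarray
    tau: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    mu_b: np.ndarray
    mu_beta: np.ndarray
    sigma_p: np.ndarray  # (sigma_theta2, sigma_thetatau, sigma_tau2)
    sigma_i: np.ndarray  # (sigma_b2, sigma_bbeta, sigma_beta2)
    config: McmcConfig
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def J(self) -> int:
        return self.theta.shape[2]

    @property
    def I(self) -> int:
        return self.b.shape[2]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one block pooled over chains: (chains*n, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def parameter_chains(self) -> dict[str, np.ndarray]:
        """Every reported scalar parameter as a (chains, n) array."""
        out: dict[str, np.ndarray] = {}
        for j in range(self.J):
            out[f"theta[{j + 1}]"] = self.theta[:, :, j]
            out[f"tau[{j + 1}]"] = self.tau[:, :, j]
        for i in range(self.I):
            out[f"b[{i + 1}]"] = self.b[:, :, i]
            out[f"beta[{i + 1}]"] = self.beta[:, :, i]
            if self.config.fix_alpha is None:
                out[f"alpha[{i + 1}]"] = self.alpha[:, :, i]
        out["mu_b"] = self.mu_b
        out["mu_beta"] = self.mu_beta
        for k, nm in enumerate(("sigma_theta2", "sigma_thetatau", "sigma_tau2")):
            out[nm] = self.sigma_p[:, :, k]
        for k, nm in enumerate(("sigma_b2", "sigma_bbeta", "sigma_beta2")):
            out[nm] = self.sigma_i[:, :, k]
        return out


# ---------------------------------------------------------------------------
# Sampler internals


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _chi2(rng: np.random.Generator, df: float) -> float:
    return 2.0 * rng.standard_gamma(df / 2.0)


def _invwishart_2x2(rng: np.random.Generator, df: float, psi: np.ndarray) -> np.ndarray:
    """Draw from IW(psi, df) for a 2x2 scale via Bartlett decomposition."""
    det = psi[0, 0] * psi[1, 1] - psi[0, 1] * psi[1, 0]
    if det <= 0 or psi[0, 0] <= 0:
        raise ValueError("inverse-Wishart scale matrix not positive definite")
    inv_psi = np.array([[psi[1, 1], -psi[0, 1]], [-psi[1, 0], psi[0, 0]]]) / det
    L = np.linalg.cholesky(inv_psi)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(_chi2(rng, df))
    A[1, 1] = np.sqrt(_chi2(rng, df - 1.0))
    A[1, 0] = rng.standard_normal()
    LA = L @ A
    W = LA @ LA.T  # Wishart(inv_psi, df)
    det_w = W[0, 0] * W[1, 1] - W[0, 1] * W[1, 0]
    return np.array([[W[1, 1], -W[0, 1]], [-W[1, 0], W[0, 0]]]) / det_w


def _cond_moments(
    x: np.ndarray, var_x: float, cov: float, var_y: float, mu_x: float = 0.0, mu_y: float = 0.0
) -> tuple[np.ndarray, float]:
    """Conditional N(mean, var) of y given x under a bivariate normal."""
    mean = mu_y + (cov / var_x) * (x - mu_x)
    var = max(var_y - cov * cov / var_x, 1e-12)
    return mean, var


def _run_chain(
    Y: np.ndarray, logT: np.ndarray, cfg: McmcConfig, seed: np.random.SeedSequence
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    J, I = logT.shape
    n_keep = cfg.retained_per_chain

    # --- data-driven initial state, jittered per chain
    pbar = np.clip(Y.mean(axis=0), 1.0 / (2 * J), 1 - 1.0 / (2 * J))
    b = -np.log(pbar / (1 - pbar)) + 0.1 * rng.standard_normal(I)
    score = Y.mean(axis=1)
    theta = (score - score.mean()) / max(score.std(), 1e-3)
    theta = theta + 0.1 * rng.standard_normal(J)
    beta = logT.mean(axis=0) + 0.05 * rng.standard_normal(I)
    tau = (beta[None, :] - logT).mean(axis=1)
    tau = tau - tau.mean() + 0.05 * rng.standard_normal(J)
    resid = logT - beta[None, :] + tau[:, None]
    if cfg.fix_alpha is not None:
        alpha = np.asarray(cfg.fix_alpha, dtype=float).copy()
        if alpha.shape != (I,) or np.any(alpha <= 0):
            raise ValueError("fix_alpha must be a positive vector of length I")
    else:
        alpha = 1.0 / np.maximum(resid.std(axis=0), 1e-3)
    mu_b = float(b.mean())
    mu_beta = float(beta.mean())
    Sp = np.cov(np.vstack([theta, tau])) + 1e-3 * np.eye(2)
    Si = np.cov(np.vstack([b, beta])) + 1e-3 * np.eye(2)

    # adaptive RW step sizes (log scale)
    ls_theta = np.full(J, np.log(1.0))
    ls_b = np.full(I, np.log(0.3))
    ls_alpha = np.full(I, np.log(0.15))
    adapt_target = cfg.target_accept

    m0 = np.array([cfg.mu_b_prior[0], cfg.mu_beta_prior[0]])
    v0_inv = np.diag([1.0 / cfg.mu_b_prior[1], 1.0 / cfg.mu_beta_prior[1]])

    keep = {
        "theta": np.empty((n_keep, J)),
        "tau": np.empty((n_keep, J)),
        "b": np.empty((n_keep, I)),
        "beta": np.empty((n_keep, I)),
        "alpha": np.empty((n_keep, I)),
        "mu_b": np.empty(n_keep),
        "mu_beta": np.empty(n_keep),
        "sigma_p": np.empty((n_keep, 3)),
        "sigma_i": np.empty((n_keep, 3)),
    }
    acc_count = {"theta": 0.0, "b": 0.0, "alpha": 0.0}
    acc_iters = 0
    kept = 0

    def rasch_ll_person(th: np.ndarray) -> np.ndarray:
        x = th[:, None] - b[None, :]
        return (Y * x - _softplus(x)).sum(axis=1)

    def rasch_ll_item(bi: np.ndarray) -> np.ndarray:
        x = theta[:, None] - bi[None, :]
        return (Y * x - _softplus(x)).sum(axis=0)

    for it in range(cfg.iterations):
        adapting = it < cfg.burn_in
        gamma = (it + 1) ** -0.55 if adapting else 0.0

        s_th2, s_thtau, s_tau2 = Sp[0, 0], Sp[0, 1], Sp[1, 1]
        s_b2, s_bbeta, s_beta2 = Si[0, 0], Si[0, 1], Si[1, 1]

        # --- theta_j: random-walk Metropolis under Rasch + conditional prior
        if cfg.use_responses:
            m_th, v_th = _cond_moments(tau, s_tau2, s_thtau, s_th2)
            step = np.exp(ls_theta)
            prop = theta + step * rng.standard_normal(J)
            logr = (
                rasch_ll_person(prop)
                - rasch_ll_person(theta)
                - 0.5 * ((prop - m_th) ** 2 - (theta - m_th) ** 2) / v_th
            )
            acc = np.log(rng.random(J)) < logr
            theta = np.where(acc, prop, theta)
            if adapting:
                ls_theta += gamma * (acc.astype(float) - adapt_target)
            elif it >= cfg.burn_in:
                acc_count["theta"] += acc.mean()

        # --- tau_j: conjugate normal
        m_ta, v_ta = _cond_moments(theta, s_th2, s_thtau, s_tau2)
        a2 = alpha * alpha
        prec = 1.0 / v_ta + a2.sum()
        lik_sum = (beta * a2).sum() - logT @ a2
        mean = (m_ta / v_ta + lik_sum) / prec
        tau = mean + rng.standard_normal(J) / np.sqrt(prec)

        # --- b_i: random-walk Metropolis under Rasch + conditional prior
        if cfg.use_responses:
            m_b, v_b = _cond_moments(beta, s_beta2, s_bbeta, s_b2, mu_beta, mu_b)
            step = np.exp(ls_b)
            prop = b + step * rng.standard_normal(I)
            logr = (
                rasch_ll_item(prop)
                - rasch_ll_item(b)
                - 0.5 * ((prop - m_b) ** 2 - (b - m_b) ** 2) / v_b
            )
            acc = np.log(rng.random(I)) < logr
            b = np.where(acc, prop, b)
            if adapting:
                ls_b += gamma * (acc.astype(float) - adapt_target)
            elif it >= cfg.burn_in:
                acc_count["b"] += acc.mean()

        # --- beta_i: conjugate normal
        m_be, v_be = _cond_moments(b, s_b2, s_bbeta, s_beta2, mu_b, mu_beta)
        x_sum = (logT + tau[:, None]).sum(axis=0)
        prec = 1.0 / v_be + J * a2
        mean = (m_be / v_be + a2 * x_sum) / prec
        beta = mean + rng.standard_normal(I) / np.sqrt(prec)

        # --- alpha_i: Metropolis on log alpha, InvGamma(1,1) prior on alpha
        if cfg.fix_alpha is None:
            S = ((logT - beta[None, :] + tau[:, None]) ** 2).sum(axis=0)
            step = np.exp(ls_alpha)
            la = np.log(alpha)
            la_prop = la + step * rng.standard_normal(I)
            a_prop = np.exp(la_prop)

            def target(a: np.ndarray, la_: np.ndarray) -> np.ndarray:
                # J*log a - a^2 S/2 (likelihood) - 2 log a - 1/a (prior) + log a (Jacobian)
                return (J - 1.0) * la_ - 0.5 * a * a * S - 1.0 / a

            logr = target(a_prop, la_prop) - target(alpha, la)
            acc = np.log(rng.random(I)) < logr
            alpha = np.where(acc, a_prop, alpha)
            if adapting:
                ls_alpha += gamma * (acc.astype(float) - adapt_target)
            elif it >= cfg.burn_in:
                acc_count["alpha"] += acc.mean()
            a2 = alpha * alpha

        # --- (mu_b, mu_beta): conjugate bivariate normal
        det = s_b2 * s_beta2 - s_bbeta * s_bbeta
        si_inv = np.array([[s_beta2, -s_bbeta], [-s_bbeta, s_b2]]) / det
        vn_inv = v0_inv + I * si_inv
        vn = np.linalg.inv(vn_inv)
        xbar = np.array([b.mean(), beta.mean()])
        mn = vn @ (v0_inv @ m0 + I * si_inv @ xbar)
        mu = mn + np.linalg.cholesky(vn) @ rng.standard_normal(2)
        mu_b, mu_beta = float(mu[0]), float(mu[1])

        # --- Sigma_p, Sigma_I: conjugate inverse-Wishart
        U = np.vstack([theta, tau])
        Sp = _invwishart_2x2(rng, cfg.nu + J, np.eye(2) + U @ U.T)
        D = np.vstack([b - mu_b, beta - mu_beta])
        Si = _invwishart_2x2(rng, cfg.nu + I, np.eye(2) + D @ D.T)

        # --- identifiability: recentre latents, compensate item parameters
        m_theta = theta.mean()
        theta = theta - m_theta
        b = b - m_theta
        m_tau = tau.mean()
        tau = tau - m_tau
        beta = beta - m_tau

        if it >= cfg.burn_in:
            acc_iters += 1
            if (it - cfg.burn_in + 1) % cfg.thin == 0:
                keep["theta"][kept] = theta
                keep["tau"][kept] = tau
                keep["b"][kept] = b
                keep["beta"][kept] = beta
                keep["alpha"][kept] = alpha
                keep["mu_b"][kept] = mu_b
                keep["mu_beta"][kept] = mu_beta
                keep["sigma_p"][kept] = (Sp[0, 0], Sp[0, 1], Sp[1, 1])
                keep["sigma_i"][kept] = (Si[0, 0], Si[0, 1], Si[1, 1])
                kept += 1

    keep["accept"] = {  # type: ignore[assignment]
        k: v / max(acc_iters, 1) for k, v in acc_count.items()
    }
    return keep


def sample_posterior(dataset: TaskDataset, config: McmcConfig) -> PosteriorDraws:
    """Run the MCMC sampler and return retained draws for all chains.

    Per-chain seeds are derived deterministically from ``config.seed``.
    A warning is emitted when a Metropolis block's post-burn-in
    acceptance rate falls outside (0.1, 0.6).
    """
    Y = dataset.Y.astype(float)
    logT = np.log(dataset.T)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [_run_chain(Y, logT, config, s) for s in seeds]

    def stack(name: str) -> np.ndarray:
        return np.stack([c[name] for c in chains])

    accept: dict[str, float] = {}
    for key in chains[0]["accept"]:  # type: ignore[union-attr]
        rates = [c["accept"][key] for c in chains]  # type: ignore[index]
        accept[key] = float(np.mean(rates))
        if config.use_responses or key not in ("theta", "b"):
            if not 0.1 < accept[key] < 0.6 and not (
                key == "alpha" and config.fix_alpha is not None
            ):
                warnings.warn(
                    f"Metropolis acceptance rate for {key} is {accept[key]:.2f}, "
                    "outside (0.1, 0.6)",
                    UserWarning,
                    stacklevel=2,
                )
    return PosteriorDraws(
        theta=stack("theta"),
        tau=stack("tau"),
        b=stack("b"),
        beta=stack("beta"),
        alpha=stack("alpha"),
        mu_b=stack("mu_b"),
        mu_beta=stack("mu_beta"),
        sigma_p=stack("sigma_p"),
        sigma_i=stack("sigma_i"),
        config=config,
        accept_rates=accept,
    )


# ---------------------------------------------------------------------------
# Posterior summaries and diagnostics


def eap_summary(draws: np.ndarray) -> dict[str, float]:
    """EAP (posterior mean), posterior SE and equal-tailed 95% interval.

    ``draws`` is a 1-D pooled sample or a (chains, n) array, flattened.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw set")
    lo, hi = np.quantile(x, [0.025, 0.975])
    return {
        "eap": float(x.mean()),
        "se": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "ci_lower": float(lo),
        "ci_upper": float(hi),
    }


def psr(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n) with m >= 2 chains of equal length n.
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means (no splitting).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains as a 2-D (m, n) array")
    m, n = x.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    W = x.var(axis=1, ddof=1).mean()
    B = n * x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def psr_table(draws: PosteriorDraws) -> pd.Series:
    """PSR for every reported parameter, indexed by parameter name."""
    chains = draws.parameter_chains()
    return pd.Series({name: psr(arr) for name, arr in chains.items()})


def correlation_from_covariance(cov: float, var1: float, var2: float) -> float:
    """rho = cov / sqrt(var1 * var2) (worked-example helper)."""
    return float(cov / np.sqrt(var1 * var2))


def correlation_estimates(draws: PosteriorDraws) -> dict[str, dict[str, float]]:
    """Per-draw Level-2 correlations with EAP and 95% credible interval.

    The ability-speed correlation rho_theta_tau and the
    difficulty-time-intensity correlation rho_b_beta are computed from
    each retained draw's covariance entries and then summarized.
    """
    out = {}
    for key, name in (("sigma_p", "rho_theta_tau"), ("sigma_i", "rho_b_beta")):
        s = draws.pooled(key)
        rho = s[:, 1] / np.sqrt(s[:, 0] * s[:, 2])
        out[name] = eap_summary(rho)
    return out


@dataclass
class IccCheck:
    """Model-vs-observed accuracy by ability group for each item.

    ``group_theta`` holds per-group mean ability EAPs; ``observed`` and
    ``model`` are (n_groups, I) proportions correct.
    """

    group_theta: np.ndarray
    observed: np.ndarray
    model: np.ndarray
    group_sizes: np.ndarray


def icc_check(
    dataset: TaskDataset, eap_theta: np.ndarray, eap_b: np.ndarray, n_groups: int = 6
) -> IccCheck:
    """Split persons into ability groups and compare accuracy to the Rasch curve.

    Persons are ranked by ability EAP and split into ``n_groups``
    equal-size groups (any remainder spread over the lowest groups);
    per item, the observed proportion correct per group is set against
    the Rasch probability at the group's mean ability and the item's
    difficulty EAP.
    """
    if dataset.J < n_groups:
        raise ValueError(f"J={dataset.J} smaller than n_groups={n_groups}")
    order = np.argsort(np.asarray(eap_theta, dtype=float), kind="stable")
    groups = np.array_split(order, n_groups)
    group_theta = np.array([eap_theta[g].mean() for g in groups])
    observed = np.vstack([dataset.Y[g].mean(axis=0) for g in groups])
    model = rasch_probability(group_theta[:, None], np.asarray(eap_b)[None, :])
    return IccCheck(
        group_theta=group_theta,
        observed=observed,
        model=model,
        group_sizes=np.array([len(g) for g in groups]),
    )


@register_result
@dataclass
class PosteriorSummary:
    """JSON-ready posterior summary: per-item EAP/SE, hyperparameters,
    Level-2 correlations with credible intervals, and the PSR maximum."""

    items: dict[str, list[dict[str, float]]]
    hyper: dict[str, dict[str, float]]
    correlations: dict[str, dict[str, float]]
    max_psr: float
    n_retained_per_chain: int
    chains: int
    accept_rates: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PosteriorSummary":
        return cls(**d)


def summarize_posterior(draws: PosteriorDraws) -> PosteriorSummary:
    """EAP/SE/CI summaries for all item and hyper parameters plus max PSR."""
    items: dict[str, list[dict[str, float]]] = {}
    for name in ("b", "beta", "alpha"):
        pooled = draws.pooled(name)
        items[name] = [eap_summary(pooled[:, i]) for i in range(draws.I)]
    hyper: dict[str, dict[str, float]] = {
        "mu_b": eap_summary(draws.pooled("mu_b")),
        "mu_beta": eap_summary(draws.pooled("mu_beta")),
    }
    sp = draws.pooled("sigma_p")
    si = draws.pooled("sigma_i")
    for k, nm in enumerate(("sigma_theta2", "sigma_thetatau", "sigma_tau2")):
        hyper[nm] = eap_summary(sp[:, k])
    for k, nm in enumerate(("sigma_b2", "sigma_bbeta", "sigma_beta2")):
        hyper[nm] = eap_summary(si[:, k])
    table = psr_table(draws)
    return PosteriorSummary(
        items=items,
        hyper=hyper,
        correlations=correlation_estimates(draws),
        max_psr=float(table.max()),
        n_retained_per_chain=draws.config.retained_per_chain,
        chains=draws.config.chains,
        accept_rates=dict(draws.accept_rates),
    )
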