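"""Timing-distribution characterization.

Fits candidate right-skewed families (lognormal, gamma, Weibull) to a
vector of positive times by maximum likelihood, compares them with the
Kolmogorov-Smirnov statistic and QQ data, and ranks the families.  The
lognormal MLE is closed form (mean and variance, divisor n, of the log
times); gamma and Weibull are fit numerically with the origin fixed at
zero.

The KS p-value is computed from the asymptotic Kolmogorov distribution
treating the fitted parameters as known ("plain" KS); a parametric
bootstrap correction for estimated parameters is available via
``ks_method="bootstrap"`` but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import special, stats

from .data_model import register_result

__all__ = [
    "DegenerateDataError",
    "FitResult",
    "FamilyComparison",
    "fit_time_model",
    "ks_statistic",
    "compare_families",
    "FAMILIES",
]

FAMILIES = ("lognormal", "gamma", "weibull")


class DegenerateDataError(ValueError):
    """The sample carries no usable dispersion (e.g. all values equal)."""


@register_result
@dataclass
class FitResult:
    """One family's maximum-likelihood fit to a time sample.

    ``params`` is family specific: lognormal ``{mu, sigma}`` on the log
    scale; gamma ``{shape, scale}``; Weibull ``{shape, scale}``.  ``qq``
    holds (theoretical, empirical) quantile pairs at plotting positions
    (i - 0.5)/n.
    """

    family: str
    params: dict[str, float]
    loglik: float
    ks_d: float
    ks_p: float
    n: int
    qq: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ks_d <= 1.0:
            raise ValueError(f"KS statistic {self.ks_d} outside [0, 1]")
        if not 0.0 <= self.ks_p <= 1.0:
            raise ValueError(f"KS p-value {self.ks_p} outside [0, 1]")

    def frozen(self) -> stats.rv_continuous:
        return _frozen(self.family, self.params)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "params": self.params,
            "loglik": self.loglik,
            "ks_d": self.ks_d,
            "ks_p": self.ks_p,
            "n": self.n,
            "qq": None if self.qq is None else np.asarray(self.qq).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FitResult":
        qq = None if d.get("qq") is None else np.asarray(d["qq"], dtype=float)
        return cls(
            family=d["family"],
            params={k: float(v) for k, v in d["params"].items()},
            loglik=float(d["loglik"]),
            ks_d=float(d["ks_d"]),
            ks_p=float(d["ks_p"]),
            n=int(d["n"]),
            qq=qq,
        )


def _frozen(family: str, params: dict[str, float]) -> stats.rv_continuous:
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=np.exp(params["mu"]))
    if family == "gamma":
        return stats.gamma(params["shape"], loc=0.0, scale=params["scale"])
    if family == "weibull":
        return stats.weibull_min(params["shape"], loc=0.0, scale=params["scale"])
    raise ValueError(f"unknown family {family!r}")


def _validate_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need a 1-D sample of at least 3 times")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("all times must be finite and strictly positive")
    if np.ptp(t) == 0:
        raise DegenerateDataError("all observations are identical; no family is fittable")
    return t


def ks_statistic(
    times: Sequence[float], cdf: Callable[[np.ndarray], np.ndarray]
) -> tuple[float, float]:
    """Two-sided KS distance between the ECDF and a reference CDF.

    Uses both one-sided ECDF limits at every sample point:
    ``D = max_i max(F(t_(i)) - (i-1)/n, i/n - F(t_(i)))``.  The p-value
    comes from the asymptotic Kolmogorov distribution evaluated at
    ``sqrt(n) * D``.
    """
    t = np.sort(np.asarray(times, dtype=float))
    n = t.size
    if n == 0:
        raise ValueError("empty sample")
    F = np.asarray(cdf(t), dtype=float)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    D = float(max(d_plus, d_minus))
    p = float(np.clip(special.kolmogorov(np.sqrt(n) * D), 0.0, 1.0))
    return D, p


def _bootstrap_pvalue(
    t: np.ndarray, family: str, D_obs: float, n_boot: int, seed: int
) -> float:
    """Parametric-bootstrap KS p-value (parameters re-fit per replicate)."""
    rng = np.random.default_rng(seed)
    n = t.size
    frozen = _frozen(family, _mle(t, family)[0])
    exceed = 0
    for _ in range(n_boot):
        sample = frozen.rvs(size=n, random_state=rng)
        params_b, _ = _mle(sample, family)
        D_b, _ = ks_statistic(sample, _frozen(family, params_b).cdf)
        exceed += D_b >= D_obs
    return (exceed + 1) / (n_boot + 1)


def _mle(t: np.ndarray, family: str) -> tuple[dict[str, float], float]:
    if family == "lognormal":
        logs = np.log(t)
        mu = float(np.mean(logs))
        sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))  # divisor n
        if sigma == 0:
            raise DegenerateDataError("zero log-scale dispersion")
        params = {"mu": mu, "sigma": sigma}
    elif family == "gamma":
        shape, _, scale = stats.gamma.fit(t, floc=0.0)
        params = {"shape": float(shape), "scale": float(scale)}
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(t, floc=0.0)
        params = {"shape": float(shape), "scale": float(scale)}
    else:
        raise ValueError(f"unknown family {family!r}")
    frozen = _frozen(family, params)
    loglik = float(np.sum(frozen.logpdf(t)))
    if not np.isfinite(loglik):
        raise RuntimeError(f"{family} fit produced a non-finite likelihood")
    return params, loglik


def fit_time_model(
    times: Sequence[float],
    family: str,
    ks_method: str = "plain",
    n_boot: int = 500,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of one family with KS and QQ diagnostics."""
    t = _validate_times(times)
    params, loglik = _mle(t, family)
    frozen = _frozen(family, params)
    D, p = ks_statistic(t, frozen.cdf)
    if ks_method == "bootstrap":
        p = _bootstrap_pvalue(t, family, D, n_boot, seed)
    elif ks_method != "plain":
        raise ValueError("ks_method must be 'plain' or 'bootstrap'")
    probs = (np.arange(1, t.size + 1) - 0.5) / t.size
    qq = np.column_stack([frozen.ppf(probs), np.sort(t)])
    return FitResult(
        family=family, params=params, loglik=loglik, ks_d=D, ks_p=p, n=t.size, qq=qq
    )


@register_result
@dataclass
class FamilyComparison:
    """Ranked family fits for one time sample.

    ``fits`` are ordered by KS distance (primary) then log-likelihood;
    ``winner`` names the first.  Families whose fit failed appear in
    ``errors`` without aborting the rest.
    """

    fits: list[FitResult]
    winner: str | None
    errors: dict[str, str]

    def to_dict(self) -> dict[str, Any]:
        return {
            "fits": [f.to_dict() for f in self.fits],
            "winner": self.winner,
            "errors": self.errors,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FamilyComparison":
        return cls(
            fits=[FitResult.from_dict(f) for f in d["fits"]],
            winner=d["winner"],
            errors=dict(d["errors"]),
        )


def compare_families(
    times: Sequence[float],
    families: Sequence[str] = FAMILIES,
    ks_method: str = "plain",
) -> FamilyComparison:
    """Fit each family and rank by KS distance, then log-likelihood."""
    fits: list[FitResult] = []
    errors: dict[str, str] = {}
    for family in families:
        try:
            fits.append(fit_time_model(times, family, ks_method=ks_method))
        except (ValueError, RuntimeError) as exc:
            errors[family] = f"{type(exc).__name__}: {exc}"
    fits.sort(key=lambda f: (f.ks_d, -f.loglik))
    return FamilyComparison(
        fits=fits, winner=fits[0].family if fits else None, errors=errors
    )
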