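"""Normal linear regression of log task time on person covariates.

Supports the three models of interest: the intercept-only base model, a
prespecified 8-predictor model (task score, age, gender, ethnicity,
career plan, and the three motivation questions), and forward-stepwise
selection with partial-F tests at the 0.05 level for both entry and
removal.

Nominal covariates enter and leave as whole blocks of indicator columns
(reference level = first declared category), and the partial F test for
a block uses its full numerator degrees of freedom, so an 8-predictor
model can carry more than 8 model degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import TaskDataset, register_result

__all__ = [
    "SingularityError",
    "RegressionSpec",
    "RegressionFit",
    "StepwiseResult",
    "MODEL1_PREDICTORS",
    "adjusted_r2",
    "covariate_frame",
    "fit_ols",
    "stepwise_select",
]

#: The prespecified "Model 1" predictor list.
MODEL1_PREDICTORS = [
    "task_score",
    "age",
    "gender",
    "ethnicity",
    "career_plan",
    "motivation_engaging",
    "motivation_interesting",
    "motivation_learned",
]


class SingularityError(ValueError):
    """The encoded design matrix is rank deficient."""


@dataclass
class RegressionSpec:
    """Predictor set for a log-task-time regression.

    ``predictors`` name columns of the covariate frame (the derived
    ``task_score`` column is always available).  An empty list is the
    intercept-only base model.
    """

    predictors: list[str] = field(default_factory=list)
    response: str = "log_task_time"


@register_result
@dataclass
class RegressionFit:
    """OLS fit summary.

    ``df_model`` counts encoded non-intercept columns (a nominal block
    of q indicators contributes q); ``rmse`` is
    ``sqrt(SSE / (n - df_model - 1))``.
    """

    predictors: list[str]
    coefficients: dict[str, float]
    rmse: float
    r2: float
    adj_r2: float
    df_model: int
    n: int
    sse: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "rmse": self.rmse,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "df_model": self.df_model,
            "n": self.n,
            "sse": self.sse,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RegressionFit":
        return cls(
            predictors=list(d["predictors"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            rmse=float(d["rmse"]),
            r2=float(d["r2"]),
            adj_r2=float(d["adj_r2"]),
            df_model=int(d["df_model"]),
            n=int(d["n"]),
            sse=float(d["sse"]),
        )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def covariate_frame(dataset: TaskDataset) -> pd.DataFrame:
    """Covariate table augmented with the derived ``task_score`` column."""
    if dataset.covariates is not None:
        frame = dataset.covariates.copy()
    else:
        frame = pd.DataFrame(index=range(dataset.J))
    if "task_score" not in frame.columns:
        frame["task_score"] = dataset.task_score
    return frame


def _encode_block(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    """Indicator columns for one predictor (reference level dropped)."""
    if name not in frame.columns:
        raise KeyError(f"unknown predictor {name!r}")
    col = frame[name]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        cats = (
            list(col.cat.categories)
            if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(col.dropna().unique())
        )
        block = pd.DataFrame(
            {f"{name}[{c}]": (col.astype(str) == str(c)).astype(float) for c in cats[1:]}
        )
        return block
    return pd.DataFrame({name: pd.to_numeric(col).astype(float)})


def build_design(
    frame: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; returns (X, column names)."""
    blocks = [pd.DataFrame({"(intercept)": np.ones(len(frame))})]
    for name in predictors:
        blocks.append(_encode_block(frame, name))
    X = pd.concat(blocks, axis=1)
    return X.to_numpy(), list(X.columns)


def _lstsq(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[np.ndarray, float]:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns greedily by rank growth
        aliased = []
        basis: list[int] = []
        for k in range(X.shape[1]):
            trial = X[:, basis + [k]]
            if np.linalg.matrix_rank(trial) == len(basis) + 1:
                basis.append(k)
            else:
                aliased.append(names[k])
        raise SingularityError(f"design matrix is rank deficient; aliased: {aliased}")
    res = sm.OLS(y, X).fit()
    return np.asarray(res.params), float(res.ssr)


def fit_ols(
    spec: RegressionSpec,
    dataset: TaskDataset,
    frame: pd.DataFrame | None = None,
) -> RegressionFit:
    """Least-squares fit of log task time on the requested predictors."""
    frame = covariate_frame(dataset) if frame is None else frame
    y = np.log(dataset.task_time)
    X, names = build_design(frame, spec.predictors)
    n, p_plus_1 = X.shape
    p = p_plus_1 - 1
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} encoded predictors")
    beta, sse = _lstsq(X, y, names)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    r2 = float(np.clip(r2, 0.0, 1.0))
    return RegressionFit(
        predictors=list(spec.predictors),
        coefficients=dict(zip(names, map(float, beta))),
        rmse=float(np.sqrt(sse / (n - p - 1))),
        r2=r2,
        adj_r2=float(adjusted_r2(r2, n, p)),
        df_model=p,
        n=n,
        sse=sse,
    )


def partial_f_pvalue(
    sse_reduced: float, sse_full: float, q: int, df_resid_full: int
) -> float:
    """P-value of the partial F test for a block of q columns."""
    if df_resid_full <= 0:
        return 1.0
    num = max(sse_reduced - sse_full, 0.0) / q
    den = sse_full / df_resid_full
    if den == 0:
        return 0.0 if num > 0 else 1.0
    return float(stats.f.sf(num / den, q, df_resid_full))


@register_result
@dataclass
class StepwiseResult:
    """Final stepwise fit plus the full selection trace."""

    fit: RegressionFit
    trace: list[dict[str, Any]]

    def to_dict(self) -> dict[str, Any]:
        return {"fit": self.fit.to_dict(), "trace": self.trace}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StepwiseResult":
        return cls(fit=RegressionFit.from_dict(d["fit"]), trace=list(d["trace"]))


def _sse_for(frame: pd.DataFrame, y: np.ndarray, predictors: list[str]) -> tuple[float, int]:
    X, names = build_design(frame, predictors)
    _, sse = _lstsq(X, y, names)
    return sse, X.shape[1] - 1


def stepwise_select(
    candidates: Sequence[str],
    dataset: TaskDataset,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    frame: pd.DataFrame | None = None,
) -> StepwiseResult:
    """Forward-stepwise selection with partial-F entry and removal tests.

    At each forward step the candidate with the smallest partial-F
    p-value enters if it is below ``alpha_enter`` (ties broken by
    declared candidate order); after each entry, any included term whose
    removal p-value exceeds ``alpha_remove`` is dropped (worst first).
    Terminates when no entry occurs; SSE decreases monotonically within
    each forward step, so the loop cannot cycle through a repeated
    state with the standard choice ``alpha_enter <= alpha_remove``.
    """
    if not candidates:
        raise ValueError("at least one candidate predictor required")
    frame = covariate_frame(dataset) if frame is None else frame
    y = np.log(dataset.task_time)
    n = len(y)
    included: list[str] = []
    trace: list[dict[str, Any]] = []
    sse_cur, df_cur = _sse_for(frame, y, included)
    while True:
        best: tuple[float, str, float, int] | None = None
        for cand in candidates:
            if cand in included:
                continue
            try:
                sse_new, df_new = _sse_for(frame, y, included + [cand])
            except SingularityError:
                continue
            q = df_new - df_cur
            pval = partial_f_pvalue(sse_cur, sse_new, q, n - df_new - 1)
            if best is None or pval < best[0]:
                best = (pval, cand, sse_new, df_new)
        if best is None or best[0] >= alpha_enter:
            trace.append({"action": "stop", "reason": "no candidate below alpha_enter"})
            break
        pval, cand, sse_cur, df_cur = best
        included.append(cand)
        trace.append({"action": "add", "term": cand, "p": pval, "sse": sse_cur})
        # backward pass
        removed = True
        while removed and len(included) > 1:
            removed = False
            worst: tuple[float, str] | None = None
            for term in included:
                others = [t for t in included if t != term]
                sse_red, df_red = _sse_for(frame, y, others)
                q = df_cur - df_red
                p_rm = partial_f_pvalue(sse_red, sse_cur, q, n - df_cur - 1)
                if worst is None or p_rm > worst[0]:
                    worst = (p_rm, term)
            if worst is not None and worst[0] > alpha_remove:
                term = worst[1]
                included.remove(term)
                sse_cur, df_cur = _sse_for(frame, y, included)
                trace.append(
                    {"action": "remove", "term": term, "p": worst[0], "sse": sse_cur}
                )
                removed = True
    fit = fit_ols(RegressionSpec(predictors=included), dataset, frame=frame)
    return StepwiseResult(fit=fit, trace=trace)
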