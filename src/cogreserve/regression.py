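"""Three-step hierarchical moderated regression with a robust re-fit.

The complete-reserve model for one (brain, cognition, proxy) cell is the
nested sequence

    step 1:  cognition ~ age + sex + brain
    step 2:  cognition ~ age + sex + brain + proxy
    step 3:  cognition ~ age + sex + brain + proxy + brain x proxy

The step-2 increment in R-squared measures the proxy's *independent* effect
(association with cognition over and above age, sex and brain structure);
the step-3 increment measures its *moderation* effect on the brain-cognition
relationship. Each step is fitted by ordinary least squares; steps that add
a term are re-fitted by iteratively reweighted least squares with Tukey's
redescending biweight and MAD residual scaling, so that every effect can be
required to be significant under both estimators.

:class:`CompleteReserveModel` is the statsmodels-style entry point: build it
from a cohort DataFrame and call :meth:`~CompleteReserveModel.fit` to obtain
a :class:`CompleteReserveResults` carrying the three step fits, the
R-squared increments, added-term p-values, robust re-fits and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "StepFit",
    "RobustFit",
    "build_model_grid",
    "fit_ols",
    "partial_f_test",
    "fit_irls_tukey",
    "CompleteReserveModel",
    "CompleteReserveResults",
    "fit_hierarchical",
]


@dataclass(frozen=True)
class ModelSpec:
    """One brain-structure / cognitive-outcome pairing within a dataset."""

    dataset: str
    brain: str
    cognition: str


def build_model_grid(brain_names: Sequence[str], cognition_names: Sequence[str],
                     dataset: str = "") -> list[ModelSpec]:
    """Cross product of brain and cognition variables, brain-major order."""
    brains, cogs = list(brain_names), list(cognition_names)
    if len(set(brains)) != len(brains) or len(set(cogs)) != len(cogs):
        raise ValueError("brain and cognition names must be unique")
    if not brains or not cogs:
        raise ValueError("need at least one brain and one cognition variable")
    return [ModelSpec(dataset=dataset, brain=b, cognition=c)
            for b, c in product(brains, cogs)]


@dataclass(frozen=True)
class StepFit:
    """One OLS fit within the hierarchical sequence."""

    step: int
    predictors: tuple[str, ...]
    params: pd.Series          # includes the intercept ("const")
    bse: pd.Series
    pvalues: pd.Series
    beta: pd.Series            # standardized coefficients, no intercept
    r_squared: float
    f_stat: float
    f_pvalue: float
    n: int
    df_resid: int


@dataclass(frozen=True)
class RobustFit:
    """An IRLS Tukey-biweight fit with large-sample normal inference."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    scale: float
    weights: np.ndarray
    converged: bool
    n_iter: int
    n: int
    df_resid: int


def _check_design(X: pd.DataFrame, n: int) -> None:
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    if n < X.shape[1] + 2:
        raise ValueError(
            f"too few complete cases (n={n}) for {X.shape[1]} predictors"
        )
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the columns involved in the dependency via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [i for i, d in enumerate(diag) if d < diag[0] * 1e-10]
        names = ["const"] + list(X.columns)
        offenders = sorted({names[piv[i]] for i in bad})
        raise ValueError(
            f"design matrix is rank deficient; collinear predictors: {offenders}"
        )


def fit_ols(y: pd.Series | np.ndarray, X: pd.DataFrame, step: int = 0) -> StepFit:
    """Least-squares fit with intercept, R-squared, model F and standardized betas.

    Standardized coefficients are reported as ``coef * sd(x) / sd(y)`` for
    continuous predictors and ``coef / sd(y)`` for binary indicators (the
    expected difference between groups in outcome SD units).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    _check_design(X, n)
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    sd_y = y.std(ddof=1)
    beta = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if np.unique(x).size <= 2:
            beta[name] = res.params[name] / sd_y
        else:
            beta[name] = res.params[name] * x.std(ddof=1) / sd_y
    return StepFit(
        step=step,
        predictors=tuple(X.columns),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        beta=pd.Series(beta),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        n=n,
        df_resid=int(res.df_resid),
    )


def partial_f_test(small: StepFit, big: StepFit) -> tuple[float, float]:
    """F test of the predictors `big` adds over `small` (same cases).

    F = (dR2 / m) / ((1 - R2_big) / df_big) for m added terms. For a single
    added term this p-value equals the added coefficient's two-sided t-test
    p-value (t^2 = F).
    """
    s_set, b_set = set(small.predictors), set(big.predictors)
    if not (s_set < b_set):
        raise ValueError("fits are not strictly nested")
    if small.n != big.n:
        raise ValueError("nested fits must use the same cases")
    m = len(b_set - s_set)
    d_r2 = max(0.0, big.r_squared - small.r_squared)
    if d_r2 == 0.0:
        return 0.0, 1.0
    f = (d_r2 / m) / ((1.0 - big.r_squared) / big.df_resid)
    p = float(stats.f.sf(f, m, big.df_resid))
    return float(f), p


def _tukey_weight(u: np.ndarray, c: float) -> np.ndarray:
    t = u / c
    w = (1.0 - t * t) ** 2
    w[np.abs(u) > c] = 0.0
    return w


def fit_irls_tukey(y: pd.Series | np.ndarray, X: pd.DataFrame,
                   c: float = 4.685, scale_b: float = 1.4826,
                   tol: float = 1e-8, max_iter: int = 50,
                   scale_center: str = "median") -> RobustFit:
    """Iteratively reweighted least squares with Tukey's biweight.

    At each iteration residuals are scaled by ``scale_b * MAD`` (MAD about
    the residual median, or about zero with ``scale_center='zero'``),
    standardized residuals beyond `c` receive zero weight, and a weighted
    least-squares step updates the coefficients; iteration stops when the
    largest coefficient change falls below `tol`. Standard errors use the
    large-sample M-estimator covariance with Huber's small-sample
    correction, and p-values are two-sided normal.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    _check_design(X, n)
    if scale_center not in ("median", "zero"):
        raise ValueError("scale_center must be 'median' or 'zero'")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    p = design.shape[1]

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    converged = False
    n_iter = 0
    weights = np.ones(n)
    scale = np.nan
    for n_iter in range(1, max_iter + 1):
        resid = y - design @ beta
        center = np.median(resid) if scale_center == "median" else 0.0
        scale = scale_b * np.median(np.abs(resid - center))
        if scale <= 0:
            raise ValueError("robust scale is zero; residuals are degenerate")
        u = resid / scale
        weights = _tukey_weight(u, c)
        if weights.sum() <= p:
            raise ValueError("too many observations received zero weight")
        sw = np.sqrt(weights)
        beta_new, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    resid = y - design @ beta
    center = np.median(resid) if scale_center == "median" else 0.0
    scale = scale_b * np.median(np.abs(resid - center))
    u = resid / scale
    weights = _tukey_weight(u, c)
    t = u / c
    inside = np.abs(u) <= c
    psi = np.where(inside, u * (1.0 - t * t) ** 2, 0.0)
    psi_deriv = np.where(inside, (1.0 - t * t) * (1.0 - 5.0 * t * t), 0.0)
    m1 = psi_deriv.mean()
    if m1 <= 0:
        raise ValueError("robust fit degenerate: mean psi-derivative <= 0")
    k_corr = 1.0 + (p / n) * psi_deriv.var() / (m1 * m1)
    sigma2 = (scale ** 2 * np.sum(psi ** 2) / (n - p)) / (m1 * m1) * k_corr ** 2
    xtx_inv = np.linalg.pinv(design.T @ design)
    bse = np.sqrt(np.diag(sigma2 * xtx_inv))
    names = ["const"] + list(X.columns)
    params = pd.Series(beta, index=names)
    bse = pd.Series(bse, index=names)
    z = params / bse
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
    return RobustFit(
        predictors=tuple(X.columns),
        params=params,
        bse=bse,
        pvalues=pvals,
        scale=float(scale),
        weights=weights,
        converged=converged,
        n_iter=n_iter,
        n=n,
        df_resid=n - p,
    )


@dataclass(frozen=True)
class CompleteReserveResults:
    """Fitted three-step complete-reserve model for one cell.

    Carries the three nested OLS step fits, the step-2 (independent) and
    step-3 (moderation) R-squared increments with their added-term p-values,
    the robust re-fits used by the dual-significance gate, and the signs of
    the added coefficients.
    """

    spec: ModelSpec
    proxy: str
    step_fits: tuple[StepFit, StepFit, StepFit]
    delta_r2_step2: float
    delta_r2_step3: float
    p_added_step2: float
    p_added_step3: float
    robust_fits: Mapping[int, RobustFit]
    interaction_term: str
    n: int

    @property
    def proxy_sign(self) -> int:
        return int(np.sign(self.step_fits[1].params[self.proxy]))

    @property
    def interaction_sign(self) -> int:
        return int(np.sign(self.step_fits[2].params[self.interaction_term]))

    @property
    def robust_p_step2(self) -> float:
        return float(self.robust_fits[2].pvalues[self.proxy])

    @property
    def robust_p_step3(self) -> float:
        return float(self.robust_fits[3].pvalues[self.interaction_term])

    def summary(self) -> str:
        lines = [
            f"Complete reserve model  [{self.spec.dataset}]",
            f"  cognition: {self.spec.cognition}   brain: {self.spec.brain}   "
            f"proxy: {self.proxy}   n = {self.n}",
            "",
            f"{'step':>4} {'R2':>8} {'dR2':>8} {'F':>9} {'p(F)':>10}  predictors",
        ]
        prev_r2 = 0.0
        for fit in self.step_fits:
            d = fit.r_squared - prev_r2 if fit.step > 1 else np.nan
            lines.append(
                f"{fit.step:>4} {fit.r_squared:>8.4f} "
                f"{('' if np.isnan(d) else format(d, '.4f')):>8} "
                f"{fit.f_stat:>9.3f} {fit.f_pvalue:>10.3g}  "
                f"{' + '.join(fit.predictors)}"
            )
            prev_r2 = fit.r_squared
        lines.append("")
        lines.append(
            f"independent effect: dR2 = {self.delta_r2_step2:.4f}, "
            f"p = {self.p_added_step2:.4g}"
            + (f", robust p = {self.robust_p_step2:.4g}" if 2 in self.robust_fits else "")
        )
        lines.append(
            f"moderation effect:  dR2 = {self.delta_r2_step3:.4f}, "
            f"p = {self.p_added_step3:.4g}"
            + (f", robust p = {self.robust_p_step3:.4g}" if 3 in self.robust_fits else "")
        )
        step3 = self.step_fits[2]
        lines.append("")
        lines.append(f"{'term':>28} {'coef':>9} {'beta':>9} {'p':>10}")
        for name in ("const",) + step3.predictors:
            b = step3.beta.get(name, np.nan)
            lines.append(
                f"{name:>28} {step3.params[name]:>9.4f} "
                f"{('' if np.isnan(b) else format(b, '.4f')):>9} "
                f"{step3.pvalues[name]:>10.3g}"
            )
        return "\n".join(lines)


class CompleteReserveModel:
    """Hierarchical moderated regression model for one cohort cell.

    Parameters
    ----------
    data : DataFrame
        Cohort table with one row per subject.
    brain, cognition, proxy : str
        Column names of the brain-structure predictor, cognitive outcome and
        reserve proxy. The proxy column may be an individual proxy or a
        composite already built into the table.
    age, sex : str
        Covariate columns; age is expected standardized, sex coded 0/1
        (female = 1).
    dataset : str
        Cohort label carried into the results.

    Only complete cases across the five columns enter the fit. The step-3
    interaction is the product of the complete-case z-scores of the brain
    and proxy columns, which centres it by construction.
    """

    def __init__(self, data: pd.DataFrame, *, brain: str, cognition: str,
                 proxy: str, age: str = "age_z", sex: str = "sex",
                 dataset: str = "") -> None:
        for col in (brain, cognition, proxy, age, sex):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not found in cohort table")
        self.spec = ModelSpec(dataset=dataset, brain=brain, cognition=cognition)
        self.proxy = proxy
        self.age_col, self.sex_col = age, sex
        cols = [age, sex, brain, proxy, cognition]
        self.frame = data[cols].dropna().reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CompleteReserveModel":
        return cls(data, **kwargs)

    def fit(self, robust: bool = True, c: float = 4.685, scale_b: float = 1.4826,
            tol: float = 1e-8, max_iter: int = 50,
            robust_steps: Sequence[int] = (2, 3)) -> CompleteReserveResults:
        spec, proxy = self.spec, self.proxy
        frame = self.frame
        n = len(frame)
        y = frame[spec.cognition].to_numpy(dtype=float)

        zb = frame[spec.brain]
        zp = frame[proxy]
        zb = (zb - zb.mean()) / zb.std(ddof=1)
        zp = (zp - zp.mean()) / zp.std(ddof=1)
        inter_name = f"{spec.brain}_x_{proxy}"

        X1 = frame[[self.age_col, self.sex_col, spec.brain]]
        X2 = X1.assign(**{proxy: frame[proxy]})
        X3 = X2.assign(**{inter_name: zb * zp})

        fit1 = fit_ols(y, X1, step=1)
        fit2 = fit_ols(y, X2, step=2)
        fit3 = fit_ols(y, X3, step=3)

        robust_fits: dict[int, RobustFit] = {}
        if robust:
            designs = {2: X2, 3: X3}
            for step in robust_steps:
                robust_fits[step] = fit_irls_tukey(
                    y, designs[step], c=c, scale_b=scale_b,
                    tol=tol, max_iter=max_iter,
                )

        return CompleteReserveResults(
            spec=spec,
            proxy=proxy,
            step_fits=(fit1, fit2, fit3),
            delta_r2_step2=max(0.0, fit2.r_squared - fit1.r_squared),
            delta_r2_step3=max(0.0, fit3.r_squared - fit2.r_squared),
            p_added_step2=float(fit2.pvalues[proxy]),
            p_added_step3=float(fit3.pvalues[inter_name]),
            robust_fits=robust_fits,
            interaction_term=inter_name,
            n=n,
        )


def fit_hierarchical(data: pd.DataFrame, spec: ModelSpec, proxy: str,
                     **fit_kwargs) -> CompleteReserveResults:
    """Convenience wrapper: build and fit the model for one grid cell."""
    model = CompleteReserveModel(
        data, brain=spec.brain, cognition=spec.cognition, proxy=proxy,
        dataset=spec.dataset,
    )
    return model.fit(**fit_kwargs)
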