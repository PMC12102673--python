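"""Poisson log-linear count regression for district case counts.

The model is the standard Poisson GLM with log link,

    ln mu_i = b0 + sum_j b_j x_ij,     y_i ~ Poisson(mu_i),

fitted by iteratively reweighted least squares (Fisher scoring with
step-halving). Standard errors come from the inverse Fisher information.
The module also provides the multicollinearity screen used before fitting
(variance inflation factors with backward elimination at VIF > 10), the
partial Wald z tests, the simultaneous deviance (goodness-of-fit) test
against a chi-square quantile, and the Wald-Wolfowitz runs test on the
response residuals used as an autocorrelation diagnostic.

Usage mirrors statsmodels::

    model = PoissonRiskModel.from_dataframe(table)
    res = model.fit()
    print(res.summary())
    res.wald_tests(alpha=0.1)
    res.deviance_test(alpha=0.1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import (
    AllCollinearError,
    ConvergenceError,
    DegenerateInputError,
    InvalidArgumentError,
    RankDeficiencyError,
)

__all__ = [
    "PoissonRiskModel",
    "PoissonRiskResults",
    "VifReport",
    "compute_vif",
    "backward_eliminate_vif",
    "runs_test",
    "predict_mean",
    "rate_ratio",
    "wald_critical",
    "chi2_critical",
    "RunsTestResult",
    "DevianceTestResult",
]

_VIF_INF_R2 = 1.0 - 1e-12  # R^2 at or above this reports VIF = +inf


# ---------------------------------------------------------------------------
# multicollinearity screen
# ---------------------------------------------------------------------------

@dataclass
class VifReport:
    """Variance inflation factors with their tolerances (1/VIF).

    ``removed`` lists predictors dropped by backward elimination, in removal
    order; it is empty for a plain :func:`compute_vif` call.
    """

    vif: pd.Series
    tolerance: pd.Series
    removed: list[str]

    def __repr__(self):
        body = self.vif.round(3).to_string()
        tail = f"\nremoved: {self.removed}" if self.removed else ""
        return f"VifReport\n{body}{tail}"


def _as_design(design, names=None):
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def compute_vif(design, names: Sequence[str] | None = None) -> VifReport:
    """VIF_j = 1 / (1 - R^2_j), R^2_j from regressing predictor j on the rest.

    Each auxiliary regression includes an intercept. Exact linear dependence
    reports +inf. Tolerance is 1/VIF.
    """
    X, names = _as_design(design, names)
    n, p = X.shape
    if p < 2:
        raise InvalidArgumentError("need at least 2 predictor columns")
    if n < p:
        raise RankDeficiencyError(f"fewer rows ({n}) than predictors ({p})")
    if np.any(X.std(axis=0) == 0):
        j = int(np.argmin(X.std(axis=0)))
        raise InvalidArgumentError(f"constant predictor column: {names[j]}")

    vifs = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst
        vifs[j] = np.inf if r2 >= _VIF_INF_R2 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, index=names, name="vif")
    return VifReport(vif=vif, tolerance=1.0 / vif, removed=[])


def backward_eliminate_vif(
    design: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop the worst-VIF predictor until all VIF <= threshold.

    Ties on the maximum VIF are broken toward the later column. Returns the
    reduced design and a report whose ``vif``/``tolerance`` describe the
    surviving predictors.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
    current = design.copy()
    removed: list[str] = []
    while True:
        if current.shape[1] < 2:
            report = VifReport(
                vif=pd.Series([1.0], index=list(current.columns), name="vif"),
                tolerance=pd.Series([1.0], index=list(current.columns)),
                removed=removed,
            )
            return current, report
        report = compute_vif(current)
        vmax = report.vif.max()
        if not (vmax > threshold):
            report.removed = removed
            return current, report
        # later column wins ties
        worst_idx = int(np.flatnonzero(report.vif.to_numpy() == vmax)[-1])
        worst = report.vif.index[worst_idx]
        if current.shape[1] - 1 < 1:
            raise AllCollinearError("elimination would leave no predictors")
        removed.append(worst)
        current = current.drop(columns=[worst])


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------

class PoissonRiskModel:
    """Poisson log-linear regression model of district case counts.

    Parameters
    ----------
    counts : array-like of non-negative integers, the response.
    exog : 2-D array or DataFrame of predictors (no intercept column; one is
        added internally).
    exog_names : names for array input; ignored for DataFrames.
    """

    def __init__(self, counts, exog, exog_names: Sequence[str] | None = None):
        y = np.asarray(counts, dtype=float)
        if y.ndim != 1:
            raise InvalidArgumentError("counts must be 1-D")
        if np.any(y < 0) or np.any(y != np.floor(y)) or not np.all(np.isfinite(y)):
            raise InvalidArgumentError("counts must be non-negative integers")
        X, names = _as_design(exog, exog_names)
        if X.shape[0] != y.shape[0]:
            raise InvalidArgumentError("rows of exog must match counts")
        if np.any(X.std(axis=0) == 0):
            raise InvalidArgumentError(
                "constant predictor column; the intercept is added internally"
            )
        self.endog = y
        self.exog = np.column_stack([np.ones(len(y)), X])
        self.exog_names = ["intercept"] + names
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise RankDeficiencyError("design matrix is rank deficient with intercept")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "case_count",
        predictors: Sequence[str] | None = None,
    ) -> "PoissonRiskModel":
        """Build the model from a district table.

        ``predictors`` defaults to every numeric column except the response
        and any identifier column.
        """
        if response not in df.columns:
            raise InvalidArgumentError(f"missing response column {response!r}")
        if predictors is None:
            predictors = [
                c
                for c in df.columns
                if c not in (response, "district_id")
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        missing = [c for c in predictors if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"missing predictor columns: {missing}")
        return cls(df[response].to_numpy(), df[list(predictors)])

    # -- likelihood pieces ---------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        eta = self.exog @ params
        return float(np.sum(self.endog * eta - np.exp(eta) - gammaln(self.endog + 1)))

    def deviance(self, mu: np.ndarray) -> float:
        y = self.endog
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "PoissonRiskResults":
        """Maximize the Poisson log-likelihood by IRLS.

        Fisher scoring on the working response z = eta + (y - mu)/mu with
        weights mu; steps are halved whenever the deviance would increase,
        which makes the deviance sequence non-increasing. Convergence is a
        relative deviance change below ``tol``.
        """
        y, X = self.endog, self.exog
        n, p = X.shape
        beta = np.zeros(p)
        beta[0] = math.log(y.mean() + 0.5)
        mu = np.exp(X @ beta)
        dev = self.deviance(mu)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = X @ beta
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            WX = X * mu[:, None]
            try:
                beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            except np.linalg.LinAlgError as exc:
                raise RankDeficiencyError(f"weighted normal equations singular: {exc}")
            step = beta_new - beta
            # step-halving keeps the deviance monotone
            for _ in range(50):
                cand = beta + step
                dev_new = self.deviance(np.exp(X @ cand))
                if np.isfinite(dev_new) and dev_new <= dev + 1e-12:
                    break
                step *= 0.5
            beta = beta + step
            rel = abs(dev - dev_new) / (abs(dev) + 0.1)
            dev = dev_new
            if rel < tol:
                converged = True
                break
        mu = np.exp(X @ beta)
        info = X.T @ (X * mu[:, None])
        cov = np.linalg.inv(info)
        results = PoissonRiskResults(self, beta, cov, dev, n_iter, converged)
        if not converged:
            raise ConvergenceError(
                f"IRLS did not converge in {max_iter} iterations", last_result=results
            )
        return results


class DevianceTestResult(NamedTuple):
    statistic: float
    df: int
    critical: float
    reject: bool


class RunsTestResult(NamedTuple):
    runs: int
    expected: float
    z: float
    p_value: float


class PoissonRiskResults:
    """Fit results: estimates, uncertainties, diagnostics and tests."""

    def __init__(self, model, params, cov_params, deviance, n_iter, converged):
        self.model = model
        self._params = np.asarray(params)
        self._cov = np.asarray(cov_params)
        self.deviance = float(deviance)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)

    # -- core attributes ------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.exog_names, name="estimate")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self._cov)), index=self.model.exog_names, name="std_error"
        )

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._cov, index=self.model.exog_names, columns=self.model.exog_names
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.exp(self.model.exog @ self._params)

    @property
    def resid(self) -> np.ndarray:
        """Response residuals y - mu, in input row order."""
        return self.model.endog - self.fittedvalues

    @property
    def llf(self) -> float:
        return self.model.loglike(self._params)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * len(self._params)

    @property
    def df_resid(self) -> int:
        return len(self.model.endog) - len(self._params)

    @property
    def rate_ratios(self) -> pd.Series:
        """exp(beta): multiplicative change in expected count per unit covariate."""
        return pd.Series(
            np.exp(self._params), index=self.model.exog_names, name="rate_ratio"
        )

    # -- tests ----------------------------------------------------------------

    def wald_tests(self, alpha: float = 0.1) -> pd.DataFrame:
        """Partial z tests: z = estimate / SE vs the two-sided critical value."""
        if not 0 < alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        crit = wald_critical(alpha)
        z = self._params / np.sqrt(np.diag(self._cov))
        return pd.DataFrame(
            {
                "estimate": self._params,
                "std_error": np.sqrt(np.diag(self._cov)),
                "z_score": z,
                "critical": crit,
                "significant": np.abs(z) > crit,
            },
            index=self.model.exog_names,
        )

    def deviance_test(
        self, df: int | None = None, alpha: float = 0.1
    ) -> DevianceTestResult:
        """Simultaneous test: deviance vs upper-alpha chi-square quantile.

        ``df`` defaults to the number of non-intercept predictors.
        """
        if df is None:
            df = len(self._params) - 1
        crit = chi2_critical(alpha, df)
        return DevianceTestResult(self.deviance, df, crit, self.deviance > crit)

    def runs_test(self) -> RunsTestResult:
        """Wald-Wolfowitz runs test on the signs of the response residuals."""
        return runs_test(self.resid)

    # -- prediction -----------------------------------------------------------

    def predict(self, covariates: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        """Expected count(s) for new covariate values."""
        coef = {n: (e, s) for n, e, s in zip(self.params.index, self._params, self.bse)}
        if isinstance(covariates, pd.DataFrame):
            return np.array(
                [predict_mean(coef, row._asdict() if hasattr(row, "_asdict") else dict(row))
                 for _, row in covariates.iterrows()]
            )
        return np.array([predict_mean(coef, dict(covariates))])

    # -- presentation ---------------------------------------------------------

    def summary(self, alpha: float = 0.1) -> str:
        wt = self.wald_tests(alpha=alpha)
        dt = self.deviance_test(alpha=alpha)
        lines = [
            "Poisson log-linear regression of district case counts",
            "=" * 68,
            f"{'variable':<26}{'estimate':>12}{'std_error':>12}{'z_score':>10}  sig",
            "-" * 68,
        ]
        for name, row in wt.iterrows():
            label = "β0" if name == "intercept" else name
            star = "*" if row["significant"] else ""
            lines.append(
                f"{label:<26}{row['estimate']:>12.4f}{row['std_error']:>12.4f}"
                f"{row['z_score']:>10.3f}  {star}"
            )
        lines += [
            "-" * 68,
            f"Deviance: {self.deviance:.2f}    AIC: {self.aic:.2f}",
            f"Z_table({alpha / 2:g}): {_round_half_up(round(wald_critical(alpha), 3), 2):.2f}"
            f"    chi2({alpha:g}:{dt.df}): {dt.critical:.3f}",
            f"Significance alpha = {alpha:g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (variable, estimate, std_error, z_score) for CSV export."""
        wt = self.wald_tests()
        return wt[["estimate", "std_error", "z_score"]].reset_index(names="variable")


# ---------------------------------------------------------------------------
# stand-alone statistics
# ---------------------------------------------------------------------------

def wald_critical(alpha: float = 0.1) -> float:
    """Two-sided standard-normal critical value: Phi^-1(1 - alpha/2)."""
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def chi2_critical(alpha: float, df: int) -> float:
    """Upper-alpha chi-square quantile with ``df`` degrees of freedom."""
    if df < 1:
        raise InvalidArgumentError("df must be >= 1")
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def _round_half_up(x: float, ndigits: int) -> float:
    shift = 10.0**ndigits
    return math.floor(x * shift + 0.5) / shift


def runs_test(residuals) -> RunsTestResult:
    """Wald-Wolfowitz runs test on the sign sequence of the residuals.

    Exact zeros are dropped. R runs of +/- signs are compared with
    E[R] = 2 n+ n- / n + 1 under the standard normal approximation with a
    0.5 continuity correction; the p-value is two-sided.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise InvalidArgumentError("need at least 2 residuals")
    signs = np.sign(r)
    signs = signs[signs != 0]
    if signs.size < 2 or np.all(signs > 0) or np.all(signs < 0):
        raise DegenerateInputError("residuals are all of one sign")
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    expected = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        raise DegenerateInputError("degenerate runs variance")
    diff = abs(runs - expected)
    z = max(diff - 0.5, 0.0) / math.sqrt(var) * (1 if runs >= expected else -1)
    p = 2.0 * stats.norm.sf(abs(z))
    return RunsTestResult(runs, expected, z, min(p, 1.0))


def predict_mean(
    coefficients: Mapping[str, tuple[float, float]] | Mapping[str, float],
    covariates: Mapping[str, float],
) -> float:
    """exp(b0 + sum b_j x_j) for a single covariate vector.

    ``coefficients`` maps names to either estimates or (estimate, SE) pairs
    and must include ``"intercept"``.
    """
    def est(v):
        return v[0] if isinstance(v, (tuple, list)) else float(v)

    if "intercept" not in coefficients:
        raise InvalidArgumentError("coefficients must include an intercept")
    eta = est(coefficients["intercept"])
    for name, value in coefficients.items():
        if name == "intercept":
            continue
        if name not in covariates:
            raise InvalidArgumentError(f"missing covariate {name!r}")
        eta += est(value) * float(covariates[name])
    return math.exp(eta)


def rate_ratio(estimate: float) -> float:
    """exp(beta): multiplicative effect of a one-unit covariate increase."""
    return math.exp(estimate)
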