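"""Fractional logit (quasi-binomial GLM) estimated by IRLS.

The model for an outcome y in [0, 1] — here country-level coverage — is

    E[y | x] = mu = logit^{-1}(x' beta)

estimated by maximising the Bernoulli quasi-likelihood

    sum_i w_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ]

which is well-defined for fractional y, including values exactly at 0 or 1.
Because the Bernoulli variance function is generally misspecified for
fractional outcomes, inference uses robust (HC1 sandwich) standard errors
with two-sided p-values from the normal reference distribution.

The IRLS update is the familiar logistic-regression one: for the logit link
the quasi-score is X'(y - mu), the expected Hessian X' W X with
W = diag(w_i mu_i (1 - mu_i)).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["FractionalLogit", "FractionalLogitResults"]

_MU_FLOOR = 1e-10


class FractionalLogit:
    """Fractional-logit model for a proportion outcome.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Outcome on [0, 1]; values exactly 0 or 1 are admitted.
    exog : array-like, shape (n, k)
        Design matrix including the constant column (use
        :meth:`from_dataframe` to build it from named covariates).
    exog_names : sequence of str, optional
        Column names; defaults to ``const, x1, ...``.
    weights : array-like, optional
        Positive case weights (default: all ones).

    Examples
    --------
    >>> model = FractionalLogit.from_dataframe(panel, "coverage_pre_eclampsia",
    ...                                        ["blood_sample_rate", "anc4_rate"])
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        endog,
        exog,
        exog_names: Optional[Sequence[str]] = None,
        weights=None,
    ) -> None:
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("endog and exog have incompatible shapes")
        if np.any((y < 0) | (y > 1)) or np.any(~np.isfinite(y)):
            raise ValueError("endog must lie in [0, 1] with no missing values")
        if not np.all(np.isfinite(X)):
            raise ValueError("exog contains non-finite values")
        n, k = X.shape
        if n <= k:
            raise ValueError(f"need more observations ({n}) than parameters ({k})")
        if weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(weights, dtype=float).ravel()
            if w.shape != y.shape or np.any(w <= 0):
                raise ValueError("weights must be positive and match endog")
        if exog_names is None:
            exog_names = ["const"] + [f"x{j}" for j in range(1, k)]
        if len(exog_names) != k:
            raise ValueError("exog_names length does not match exog columns")
        self.endog = y
        self.exog = X
        self.exog_names = list(exog_names)
        self.weights = w
        self.nobs = n

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: Sequence[str],
        add_intercept: bool = True,
        weights: Optional[str] = None,
    ) -> "FractionalLogit":
        """Build the model from named columns of a DataFrame."""
        missing = [c for c in [response, *covariates] if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        X = data[list(covariates)].to_numpy(dtype=float)
        names = list(covariates)
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["const"] + names
        w = data[weights].to_numpy(dtype=float) if weights else None
        return cls(data[response], X, exog_names=names, weights=w)

    # -- estimation -----------------------------------------------------------

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-10,
        start_params=None,
    ) -> "FractionalLogitResults":
        """Estimate beta by IRLS; never raises on non-convergence.

        A fit that fails to converge within ``max_iter`` (or diverges, as
        under perfect separation) is returned with ``converged=False`` and
        the iteration diagnostics — it is the caller's job to decide whether
        to trust it.
        """
        y, X, w = self.endog, self.exog, self.weights
        n, k = X.shape
        beta = np.zeros(k) if start_params is None else np.asarray(start_params, float).copy()
        converged = False
        diverged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            eta = X @ beta
            mu = special.expit(eta)
            mu = np.clip(mu, _MU_FLOOR, 1.0 - _MU_FLOOR)
            W = w * mu * (1.0 - mu)
            score = X.T @ (w * (y - mu))
            XtWX = X.T @ (X * W[:, None])
            try:
                delta = np.linalg.solve(XtWX, score)
            except np.linalg.LinAlgError:
                diverged = True
                break
            beta = beta + delta
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
                diverged = True
                break
            rel_change = np.max(np.abs(delta) / (1.0 + np.abs(beta)))
            if rel_change < tol:
                converged = True
                break

        eta = X @ beta
        mu = np.clip(special.expit(eta), _MU_FLOOR, 1.0 - _MU_FLOOR)
        W = w * mu * (1.0 - mu)
        XtWX = X.T @ (X * W[:, None])
        resid = w * (y - mu)
        try:
            bread = np.linalg.inv(XtWX)
            meat = (X * (resid**2)[:, None]).T @ X
            cov = bread @ meat @ bread * (n / (n - k))  # HC1 small-sample factor
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            diverged = True
        return FractionalLogitResults(
            model=self,
            params=beta,
            cov_params=cov,
            converged=converged and not diverged,
            iterations=iterations,
            fittedvalues=special.expit(X @ beta),
        )


class FractionalLogitResults:
    """Estimates, robust uncertainties and diagnostics of a fractional logit.

    Attributes
    ----------
    params : ndarray
        Coefficients on the logit scale (covariates on the 0-1 scale).
    bse : ndarray
        HC1 sandwich standard errors.
    pvalues : ndarray
        Two-sided p-values from the normal reference distribution.
    converged : bool
    """

    def __init__(self, model, params, cov_params, converged, iterations, fittedvalues):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.fittedvalues = fittedvalues
        self.nobs = model.nobs
        self.df_resid = model.nobs - len(params)
        self.exog_names = model.exog_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    @property
    def terms(self) -> list:
        """Covariate names excluding the intercept."""
        return [n for n in self.exog_names if n != "const"]

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def predict(self, exog=None) -> np.ndarray:
        """Predicted proportions logit^{-1}(X beta), strictly inside (0, 1)."""
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return special.expit(X @ self.params)

    def predict_from_covariates(self, covariates: Union[Mapping[str, float], object]) -> float:
        """Predict one proportion from named covariate values.

        ``covariates`` may be a mapping or any object exposing the model's
        covariate names as attributes. A missing term raises, naming it.
        """
        getter = covariates.get if isinstance(covariates, Mapping) else None
        x = [1.0]
        for name in self.exog_names:
            if name == "const":
                continue
            if getter is not None:
                if name not in covariates:
                    raise KeyError(f"missing covariate {name!r}")
                x.append(float(getter(name)))
            else:
                if not hasattr(covariates, name):
                    raise KeyError(f"missing covariate {name!r}")
                x.append(float(getattr(covariates, name)))
        return float(special.expit(np.dot(self.params, np.array(x))))

    def summary(self) -> str:
        """Plain-text coefficient table in the style of statsmodels."""
        lines = [
            "Fractional logit (quasi-binomial, logit link; HC1 robust SEs)",
            f"No. observations: {self.nobs}    converged: {self.converged} "
            f"({self.iterations} iterations)",
            "-" * 72,
            f"{'term':<22}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>9}"
            f"{'[0.025':>10}{'0.975]':>10}",
            "-" * 72,
        ]
        ci = self.conf_int()
        for j, name in enumerate(self.exog_names):
            lines.append(
                f"{name:<22}{self.params[j]:>10.4f}{self.bse[j]:>10.4f}"
                f"{self.tvalues[j]:>8.2f}{self.pvalues[j]:>9.3f}"
                f"{ci[j, 0]:>10.4f}{ci[j, 1]:>10.4f}"
            )
        lines.append("-" * 72)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "terms": self.exog_names,
            "params": [float(v) for v in self.params],
            "bse": [float(v) for v in self.bse],
            "pvalues": [float(v) for v in self.pvalues],
            "converged": self.converged,
            "n_obs": int(self.nobs),
        }
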