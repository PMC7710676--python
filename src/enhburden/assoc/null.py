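"""Covariate-adjusted logistic null model for the score tests.

Status is regressed on intercept + covariates (sex and ten eigenvectors in
the standard configuration) by maximum likelihood. The fit stores the
quantities needed for the residual covariance kernel of the score tests:
mu, residuals y - mu, variance weights mu(1-mu) and the design.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ..errors import DataError, SeparationError
from ..io_formats import SampleTable

__all__ = ["NullModel", "fit_null"]


@dataclass
class NullModel:
    X: np.ndarray          # n x k design, first column = intercept
    y: np.ndarray          # observed status
    alpha_hat: np.ndarray  # k coefficients
    mu_hat: np.ndarray     # fitted case probabilities
    dropped_columns: tuple[int, ...] = ()

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu_hat

    @property
    def variance_weights(self) -> np.ndarray:
        return self.mu_hat * (1.0 - self.mu_hat)


def fit_null(
    samples: SampleTable,
    covariates: np.ndarray | None = None,
    *,
    use_table_covariates: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NullModel:
    """Fit the logistic null by Newton/IRLS to score-norm tolerance ``tol``.

    ``covariates`` overrides the sample table's own sex/PC covariates.
    Constant (rank-deficient) columns are dropped with a warning. Perfect
    separation raises :class:`SeparationError` advising Firth.
    """
    y = samples.status.astype(float)
    if y.min() == y.max():
        raise DataError("both cases and controls are required for the null fit")
    if covariates is None and use_table_covariates:
        covariates = samples.covariates()
    n = y.size
    cols = [np.ones(n)]
    dropped: list[int] = []
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        for j in range(C.shape[1]):
            col = C[:, j]
            if np.ptp(col) == 0:
                dropped.append(j)
                warnings.warn(
                    f"covariate column {j} is constant; coefficient indeterminate, dropped"
                )
            else:
                cols.append(col)
    X = np.column_stack(cols)

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            break
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.abs(X @ beta).max() > 30:
            raise SeparationError(
                "perfect separation on covariates: use Firth regression or "
                "remove the offending covariate"
            )
    else:
        eta = X @ beta
        mu = expit(eta)
        if np.linalg.norm(X.T @ (y - mu)) >= tol:
            raise DataError("null model failed to converge")
    eta = X @ beta
    if np.abs(eta).max() > 15 and X.shape[1] > 1:
        raise SeparationError(
            "perfect separation on covariates: use Firth regression or "
            "remove the offending covariate"
        )
    mu = expit(eta)
    return NullModel(
        X=X, y=y, alpha_hat=beta, mu_hat=mu, dropped_columns=tuple(dropped)
    )
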