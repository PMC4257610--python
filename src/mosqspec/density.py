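"""Ricker and Gompertz-logistic density-dependent model calibration.

Both models relate the per-capita log growth rate to abundance:

    Ricker:    log(N_{t+1}/N_t) = r_m (1 - N_{t-lag}/K)
    Gompertz:  log(N_{t+1}/N_t) = r_m (1 - log N_{t-lag} / log K)

which are linear in the density term D (= N or log N), so calibration is
ordinary least squares of the observed log growth rate on D and any
additive environmental covariates:

    log(N_{t+1}/N_t) = a + b * D_{t-lag} + sum_j c_j * E_{j,t} + eps

with r_m = a, K = -a/b (Ricker) or log K = -a/b (Gompertz).  Transitions
touching a zero count are dropped (the linearisation needs the log of a
ratio) and their number reported.  Least squares on ecological series can
bias parameter values; the fits here serve comparison of correlation
structures, not parameter inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = ["DensityFit", "fit_density_model", "multi_lag_fit",
           "simulate_density_model"]

MAX_LAG = 5


@dataclass
class DensityFit:
    """One calibrated density-dependent model."""

    model: str                   # "ricker" | "gompertz"
    lags: tuple[int, ...]        # density-dependence lags, each in 0..5
    r_m: float                   # maximum per-capita growth rate, 1/day
    K: float                     # carrying capacity, individuals
    density_coeffs: dict[int, float]      # slope on D_{t-lag} per lag
    covariate_coeffs: dict[str, float]    # additive environmental terms
    residual_sd: float           # log-scale
    n_used: int                  # transitions entering the regression
    n_dropped_zero: int          # transitions excluded for zero counts
    diagnostics: dict = field(default_factory=dict)

    @property
    def lag(self) -> int:
        return self.lags[0]


def _prepare(ts: TimeSeries, model: str, lags: tuple[int, ...],
             covariates: list[TimeSeries]):
    model = model.lower()
    if model not in ("ricker", "gompertz"):
        raise ValueError(f"model must be 'ricker' or 'gompertz', got {model!r}")
    if len(set(lags)) != len(lags):
        raise ValueError(f"duplicate lags {lags} give a collinear design")
    if any(l < 0 or l > MAX_LAG for l in lags):
        raise ValueError(f"lags must lie in 0..{MAX_LAG}, got {lags}")
    if ts.delta_t != 1.0:
        raise ValueError("density models are fitted on daily series")
    for cov in covariates:
        if len(cov) != len(ts) or not (cov.dates == ts.dates).all():
            raise ValueError(f"covariate {cov.label!r} is not aligned with the series")
    return model


def _design(ts: TimeSeries, model: str, lags: tuple[int, ...],
            covariates: list[TimeSeries]):
    N = np.asarray(ts.values, dtype=float)
    max_lag = max(lags)
    t_idx = np.arange(max_lag, len(N) - 1)
    ok = (N[t_idx] > 0) & (N[t_idx + 1] > 0)
    for l in lags:
        ok &= N[t_idx - l] > 0
    n_dropped = int((~ok).sum())
    t_idx = t_idx[ok]
    y = np.log(N[t_idx + 1] / N[t_idx])
    cols = [np.ones(len(t_idx))]
    for l in lags:
        D = N[t_idx - l] if model == "ricker" else np.log(N[t_idx - l])
        cols.append(D)
    for cov in covariates:
        cols.append(np.asarray(cov.values, dtype=float)[t_idx])
    X = np.column_stack(cols)
    return X, y, n_dropped


def fit_density_model(
    ts: TimeSeries,
    model: str = "ricker",
    lag: int = 0,
    covariates: list[TimeSeries] | None = None,
) -> DensityFit:
    """Least-squares calibration of a single-lag density-dependent model."""
    return multi_lag_fit(ts, model=model, lags=(lag,), covariates=covariates)


def multi_lag_fit(
    ts: TimeSeries,
    model: str = "ricker",
    lags: tuple[int, ...] = (0,),
    covariates: list[TimeSeries] | None = None,
) -> DensityFit:
    """Least-squares fit with one density term per requested lag.

    ``r_m`` and ``K`` are back-transformed from the intercept and the sum of
    density slopes (for a single lag this is the textbook inversion
    K = -a/b, respectively log K = -a/b).
    """
    covariates = covariates or []
    lags = tuple(lags)
    model = _prepare(ts, model, lags, covariates)
    X, y, n_dropped = _design(ts, model, lags, covariates)
    n_params = X.shape[1]
    if len(y) < 10 * n_params:
        raise ValueError(
            f"only {len(y)} usable transitions for {n_params} parameters "
            f"(need >= {10 * n_params}); {n_dropped} dropped for zero counts"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_params:
        raise ValueError("design matrix is rank-deficient (collinear terms)")
    resid = y - X @ beta
    dof = max(1, len(y) - n_params)
    a = float(beta[0])
    density_coeffs = {l: float(beta[1 + i]) for i, l in enumerate(lags)}
    b = sum(density_coeffs.values())
    if b == 0:
        raise ValueError("zero density slope: no density dependence recoverable")
    K = -a / b if model == "ricker" else float(np.exp(-a / b))
    cov_coeffs = {
        cov.label or f"cov{j}": float(beta[1 + len(lags) + j])
        for j, cov in enumerate(covariates)
    }
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    diagnostics = {
        "r_squared": 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan,
        "rmse": float(np.sqrt(resid @ resid / dof)),
    }
    return DensityFit(
        model=model,
        lags=lags,
        r_m=a,
        K=K,
        density_coeffs=density_coeffs,
        covariate_coeffs=cov_coeffs,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        n_used=len(y),
        n_dropped_zero=n_dropped,
        diagnostics=diagnostics,
    )


def simulate_density_model(
    fit: DensityFit,
    n: int,
    N0: float,
    covariates: list[TimeSeries] | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    start: str = "2004-01-01",
) -> TimeSeries:
    """Iterate the fitted recursion forward with Gaussian log-rate noise.

    Noise sd defaults to the fit's residual sd; pass 0 for the
    deterministic recursion.  Covariate series, when supplied, contribute
    their fitted additive terms.
    """
    if N0 <= 0:
        raise ValueError("N0 must be > 0")
    rng = rng or np.random.default_rng(0)
    sd = fit.residual_sd if noise_sd is None else noise_sd
    covariates = covariates or []
    for cov in covariates:
        if cov.label not in fit.covariate_coeffs:
            raise ValueError(f"covariate {cov.label!r} was not in the fit")
        if len(cov) < n:
            raise ValueError(f"covariate {cov.label!r} shorter than n={n}")
    max_lag = max(fit.lags)
    N = np.empty(n)
    N[: max_lag + 1] = N0
    eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
    for t in range(max_lag, n - 1):
        rate = fit.r_m
        for l, b in fit.density_coeffs.items():
            D = N[t - l] if fit.model == "ricker" else np.log(N[t - l])
            rate += b * D
        for cov in covariates:
            rate += fit.covariate_coeffs[cov.label] * cov.values[t]
        N[t + 1] = N[t] * np.exp(rate + eps[t])
        N[t + 1] = min(max(N[t + 1], 1e-12), 1e12)  # numeric guard
    dates = pd.date_range(start, periods=n, freq="D")
    return TimeSeries(dates, N, delta_t=1.0, label=f"{fit.model}.sim")
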