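"""Mean-dependent trial-to-trial variability model.

Cortical spike responses have a trial-to-trial standard deviation that
grows with the mean response, approximately linearly on a log-log plot.
The noise law used throughout this package adds a constant floor so the
noise is not identically zero at zero mean response:

    sigma_noise(m) = Cn + K * m**S

A single (Cn, K, S) triple is fitted from (mean, SD) pairs pooled over
all responses and all cells of a recording — never per cell, where the
limited data would make the fit unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["NoiseModel", "NoisePool", "noise_sd", "fit_noise_model", "pool_from_responses"]


@dataclass(frozen=True)
class NoiseModel:
    """Constants of the noise law sigma_noise(m) = Cn + K * m**S.

    ``Cn`` is the additive noise floor (response units), ``K`` the scale
    coefficient and ``S`` the exponent.  ``K`` may be negative (observed
    for some interneuron classes whose noise is nearly mean-independent),
    in which case the model is only valid over the response range where
    the predicted SD stays positive.
    """

    Cn: float
    K: float
    S: float

    def sd(self, m):
        return noise_sd(m, self)

    def asdict(self):
        return {"Cn": self.Cn, "K": self.K, "S": self.S}


def noise_sd(m, model: NoiseModel):
    """Trial-to-trial SD predicted for mean response ``m``.

    For ``m <= 0`` the power term is dropped and the floor ``Cn`` is
    returned (negative means can occur for dF/F data, where a fractional
    power of a negative number would be undefined).  Raises if the
    predicted SD is not positive anywhere in ``m``.
    """
    marr = np.asarray(m, dtype=float)
    mp = np.clip(marr, 0.0, None)
    with np.errstate(invalid="ignore"):
        sd = model.Cn + model.K * np.power(mp, model.S)
    sd = np.where(marr <= 0, model.Cn, sd)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError(
            f"noise model {model} predicts nonpositive SD within the requested "
            "response range; it is invalid for these data"
        )
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(sd)
    return sd


@dataclass(frozen=True)
class NoisePool:
    """Pooled (mean response, trial SD) pairs across cells and stimuli."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = np.atleast_1d(np.asarray(self.means, dtype=float))
        sds = np.atleast_1d(np.asarray(self.sds, dtype=float))
        if means.shape != sds.shape or means.ndim != 1:
            raise ValueError("means and sds must be 1-D arrays of equal length")
        if np.any(sds < 0):
            raise ValueError("trial SDs must be nonnegative")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def __len__(self):
        return self.means.size


def pool_from_responses(datasets) -> NoisePool:
    """Build a noise pool from trial-level response datasets.

    ``datasets`` is an iterable of :class:`~tuningbayes.grid.ResponseData`
    with trial-level responses.  One (mean, SD) pair is produced per cell
    per stimulus angle; the sample SD uses the n-1 denominator.
    """
    means, sds = [], []
    for data in datasets:
        if data.trials is None:
            raise ValueError("noise pooling requires trial-level data, got means only")
        if data.trials.shape[1] < 2:
            raise ValueError("noise pooling requires at least 2 trials per stimulus")
        means.append(data.trials.mean(axis=1))
        sds.append(data.trials.std(axis=1, ddof=1))
    if not means:
        raise ValueError("empty input: no datasets to pool")
    return NoisePool(np.concatenate(means), np.concatenate(sds))


def _loglog_init(pool: NoisePool):
    """Initial (Cn, K, S) from a log-log linear regression.

    Pairs with nonpositive mean or SD are excluded here (log undefined)
    but still enter the nonlinear fit.
    """
    ok = (pool.means > 0) & (pool.sds > 0)
    if ok.sum() >= 2:
        b, a = np.polyfit(np.log10(pool.means[ok]), np.log10(pool.sds[ok]), 1)
        k0, s0 = 10.0 ** a, b
    else:
        k0, s0 = 1.0, 1.0
    cn0 = max(1e-3, 0.01 * float(np.median(pool.sds)))
    return cn0, k0, s0


def fit_noise_model(pool: NoisePool, loss: str = "linear") -> NoiseModel:
    """Fit (Cn, K, S) to pooled (mean, SD) pairs by least squares.

    The fit minimizes residuals of sigma_noise(m) in linear space by
    default (the law is stated in linear space and the floor Cn breaks
    log-linearity); ``loss="log"`` selects log-space residuals instead.
    The log-log regression supplies the starting point.  ``Cn`` is
    constrained to be nonnegative; ``K`` and ``S`` are free.
    """
    if len(pool) < 3:
        raise ValueError(f"need at least 3 (mean, SD) pairs, got {len(pool)}")
    if np.unique(pool.means).size < 3:
        raise ValueError("degenerate pool: need at least 3 distinct mean responses")
    if loss not in ("linear", "log"):
        raise ValueError(f"loss must be 'linear' or 'log', got {loss!r}")

    m, s = pool.means, pool.sds
    mp = np.clip(m, 0.0, None)

    def predict(theta):
        cn, k, sexp = theta
        return cn + k * np.power(mp, sexp, where=mp > 0, out=np.zeros_like(mp))

    if loss == "linear":
        def resid(theta):
            return predict(theta) - s
    else:
        eps = 1e-12
        def resid(theta):
            return np.log(np.clip(predict(theta), eps, None)) - np.log(np.clip(s, eps, None))

    x0 = np.array(_loglog_init(pool))
    result = least_squares(
        resid, x0, bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not result.success:
        raise RuntimeError(
            f"noise-model fit did not converge: {result.message} (status {result.status})"
        )
    cn, k, sexp = result.x
    return NoiseModel(Cn=float(cn), K=float(k), S=float(sexp))
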