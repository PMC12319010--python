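"""Exhaustive grid evaluation of the tuning-curve posterior.

The posterior over the five tuning parameters (C, Rp, alpha, theta_pref,
sigma) is computed by brute force: the likelihood of the observed mean
responses is evaluated at every combination of a discrete value set per
parameter, multiplied by a uniform prior, and normalized to sum to 1
(the marginal likelihood of the data is never computed explicitly).

The likelihood of the mean response at each stimulus angle is a normal
density centred on the model response, with standard deviation given by
the mean-dependent noise law evaluated at the *model* response and
shrunk by sqrt(T) for the averaging over T trials.

All accumulation happens in log space; the maximum log likelihood is
subtracted before exponentiation, so grids whose best likelihood is
astronomically small still normalize cleanly.

The full joint is kept in memory only long enough to extract compact
summaries (per-parameter marginals, the grid MLE, histograms of the
orientation/direction indices and of the derived preferred response);
persisting the raw joint for production-size grids would take gigabytes
per cell and is deliberately unsupported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .noise import NoiseModel, noise_sd
from .tuning import TuningParams, angdiff, double_gaussian

__all__ = [
    "ResponseData",
    "GridSpec",
    "PosteriorSummary",
    "GridEvaluator",
    "predict_responses",
    "log_likelihood",
    "compute_posterior",
    "marginal",
    "mle",
    "index_histograms",
    "rpref_likelihood",
    "joint_2d",
]

PARAM_NAMES = ("C", "Rp", "alpha", "theta_pref", "sigma")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ResponseData:
    """Stimulus angles and (trial-averaged) responses for one cell.

    ``trials`` has shape (n_angles, T) when trial-level responses are
    available; otherwise ``means`` and the trial count ``T`` suffice for
    posterior estimation (the likelihood needs only per-angle means and
    T).  ``T`` may be a scalar or a per-angle array.
    """

    angles: np.ndarray
    means: np.ndarray
    T: np.ndarray | int
    trials: Optional[np.ndarray] = None

    def __post_init__(self):
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        if self.angles.ndim != 1 or self.angles.shape != self.means.shape:
            raise ValueError("angles and means must be 1-D arrays of equal length")
        if self.angles.size == 0:
            raise ValueError("ResponseData must contain at least one angle")
        if not (np.all(np.isfinite(self.angles)) and np.all(np.isfinite(self.means))):
            raise ValueError("angles and responses must be finite")
        wrapped = np.round(self.angles % 360.0, 9)
        if np.unique(wrapped).size != wrapped.size:
            raise ValueError("stimulus angles must be distinct modulo 360 degrees")
        if self.trials is not None:
            self.trials = np.asarray(self.trials, dtype=float)
            if self.trials.shape[0] != self.angles.size:
                raise ValueError("trials must have one row per stimulus angle")
        t = np.asarray(self.T)
        if np.any(t < 1):
            raise ValueError("trial count T must be >= 1")

    @classmethod
    def from_trials(cls, angles, trials) -> "ResponseData":
        trials = np.asarray(trials, dtype=float)
        if trials.ndim != 2:
            raise ValueError("trials must be a 2-D (n_angles, T) array")
        return cls(
            angles=np.asarray(angles, dtype=float),
            means=trials.mean(axis=1),
            T=trials.shape[1],
            trials=trials,
        )

    @classmethod
    def from_means(cls, angles, means, T) -> "ResponseData":
        return cls(angles=np.asarray(angles, float), means=np.asarray(means, float), T=T)

    @property
    def n_angles(self) -> int:
        return self.angles.size

    def trial_counts(self) -> np.ndarray:
        """Per-angle trial counts as an array."""
        return np.broadcast_to(np.asarray(self.T, dtype=float), self.angles.shape)


def _readonly(a) -> np.ndarray:
    out = np.ascontiguousarray(np.asarray(a, dtype=float))
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class GridSpec:
    """Discrete value sets for the five tuning parameters.

    Axis order is (C, Rp, alpha, theta_pref, sigma) throughout; the
    joint likelihood array uses the same order.
    """

    c: np.ndarray
    rp: np.ndarray
    alpha: np.ndarray
    theta_pref: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        for name in ("c", "rp", "alpha", "theta_pref", "sigma"):
            vals = _readonly(getattr(self, name))
            if vals.ndim != 1 or vals.size == 0:
                raise ValueError(f"grid axis {name} must be a non-empty 1-D array")
            if np.any(np.diff(vals) <= 0):
                raise ValueError(f"grid axis {name} must be strictly ascending")
            object.__setattr__(self, name, vals)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma grid values must be positive")
        if np.any((self.alpha < 0) | (self.alpha > 1)):
            raise ValueError("alpha grid values must lie in [0, 1]")

    @property
    def axes(self) -> tuple[np.ndarray, ...]:
        return (self.c, self.rp, self.alpha, self.theta_pref, self.sigma)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(a.size for a in self.axes)

    @property
    def n_combinations(self) -> int:
        return int(np.prod([a.size for a in self.axes], dtype=np.int64))

    def axis(self, name: str) -> np.ndarray:
        try:
            return self.axes[PARAM_NAMES.index(name)]
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")

    def step(self, name: str) -> float:
        """Median spacing of one axis (grid 'resolution')."""
        vals = self.axis(name)
        return float(np.median(np.diff(vals))) if vals.size > 1 else 0.0

    def params_at(self, index) -> TuningParams:
        """TuningParams at a multi-index (ic, ir, ia, it, is_)."""
        ic, ir, ia, it, is_ = index
        return TuningParams(
            C=float(self.c[ic]),
            Rp=float(self.rp[ir]),
            alpha=float(self.alpha[ia]),
            theta_pref=float(self.theta_pref[it]),
            sigma=float(self.sigma[is_]),
        )

    @classmethod
    def spiking_default(cls) -> "GridSpec":
        """Production grid for spike-rate data: 60*60*15*72*60 combinations."""
        return cls(
            c=np.linspace(0.1, 10.0, 60),
            rp=np.linspace(0.1, 20.0, 60),
            alpha=np.linspace(0.0, 1.0, 15),
            theta_pref=np.arange(0.0, 360.0, 5.0),
            sigma=np.linspace(1.0, 60.0, 60),
        )

    @classmethod
    def calcium_default(cls, mx: float) -> "GridSpec":
        """Production grid for dF/F data; 60*60*21*72*60 combinations.

        ``mx`` is the cell's maximum per-angle mean response: offsets
        span [-mx, mx] and amplitudes up to 3*mx.
        """
        if mx <= 0:
            raise ValueError(f"mx must be positive, got {mx}")
        return cls(
            c=np.linspace(-mx, mx, 60),
            rp=np.linspace(0.001, 3.0 * mx, 60),
            alpha=np.linspace(0.0, 1.0, 21),
            theta_pref=np.arange(0.0, 360.0, 5.0),
            sigma=np.linspace(1.0, 60.0, 60),
        )

    @classmethod
    def reduced_spiking(cls) -> "GridSpec":
        """Desk-scale spiking grid (~7e5 combinations) for simulation studies.

        Step sizes are chosen to be comparable to the posterior widths
        attainable in the simulated-recovery conditions (tens of angles,
        a handful of trials, ~50% multiplicative noise), so the grid
        resolves the posterior without wasting combinations.
        """
        return cls(
            c=np.arange(0.5, 10.0 + 0.25, 0.5),
            rp=np.arange(2.5, 22.5, 2.5),
            alpha=np.linspace(0.0, 1.0, 5),
            theta_pref=np.arange(0.0, 360.0, 10.0),
            sigma=np.arange(5.0, 65.0, 5.0),
        )

    def to_dict(self) -> dict:
        return {
            "C": self.c.tolist(),
            "Rp": self.rp.tolist(),
            "alpha": self.alpha.tolist(),
            "theta_pref": self.theta_pref.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            c=np.asarray(d["C"], float),
            rp=np.asarray(d["Rp"], float),
            alpha=np.asarray(d["alpha"], float),
            theta_pref=np.asarray(d["theta_pref"], float),
            sigma=np.asarray(d["sigma"], float),
        )


def predict_responses(params: TuningParams, angles) -> np.ndarray:
    """Model mean responses at each stimulus angle."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return np.array([], dtype=float)
    return np.asarray(double_gaussian(angles, params), dtype=float)


def log_likelihood(data: ResponseData, params: TuningParams, noise: NoiseModel) -> float:
    """Log probability density of the observed per-angle means.

    Independent normal densities per angle, centred on the model
    response with SD ``noise_sd(model response) / sqrt(T)``.
    """
    rhat = predict_responses(params, data.angles)
    sd = noise_sd(rhat, noise) / np.sqrt(data.trial_counts())
    z = (data.means - rhat) / sd
    return float(np.sum(-np.log(sd) - 0.5 * _LOG_2PI - 0.5 * z * z))


class GridEvaluator:
    """Reusable likelihood engine for one (grid, noise, angles, T) setting.

    Building the engine precomputes the model response and noise SD at
    every (grid point, angle) pair, so repeated posterior evaluations
    (e.g. across simulation replicates of the same design) cost only a
    few passes over the grid.  When the cache would be too large the
    engine streams over blocks of the C axis instead, recomputing
    predictions on the fly.
    """

    def __init__(self, grid: GridSpec, noise: NoiseModel, angles, T,
                 cache: bool | str = "auto", max_cache_elements: int = 120_000_000):
        self.grid = grid
        self.noise = noise
        self.angles = np.atleast_1d(np.asarray(angles, dtype=float))
        self.T = np.broadcast_to(np.asarray(T, dtype=float), self.angles.shape).copy()
        if np.any(self.T < 1):
            raise ValueError("trial count T must be >= 1")
        n = self.angles.size
        g = grid.n_combinations
        if cache == "auto":
            cache = n * g <= max_cache_elements
        self._cached = bool(cache)
        # per-angle Gaussian lobe factors, shape (n, n_theta, n_sigma)
        dp = angdiff(self.angles[:, None] - grid.theta_pref[None, :])
        dn = angdiff(self.angles[:, None] - (grid.theta_pref[None, :] + 180.0))
        inv2s2 = 1.0 / (2.0 * grid.sigma ** 2)
        self._gp = np.exp(-np.square(dp)[:, :, None] * inv2s2[None, None, :])
        self._gn = np.exp(-np.square(dn)[:, :, None] * inv2s2[None, None, :])
        if self._cached:
            self._rhat = np.empty((n, g), dtype=float)
            self._inv_var = np.empty((n, g), dtype=float)
            self._logsd_sum = np.zeros(g, dtype=float)
            for i in range(n):
                rhat = self._predicted_block(i, slice(None)).ravel()
                sd = noise_sd(rhat, noise) / np.sqrt(self.T[i])
                self._rhat[i] = rhat
                self._inv_var[i] = 1.0 / (sd * sd)
                self._logsd_sum += np.log(sd)

    def _predicted_block(self, i: int, c_slice) -> np.ndarray:
        """Model responses at angle i over a block of the C axis.

        Returns an array of shape (block, n_rp, n_alpha, n_theta, n_sigma).
        """
        g = self.grid
        shape3 = self._gp[i][None, :, :] + g.alpha[:, None, None] * self._gn[i][None, :, :]
        return (
            g.c[c_slice, None, None, None, None]
            + g.rp[None, :, None, None, None] * shape3[None, None, :, :, :]
        )

    def log_likelihood(self, means) -> np.ndarray:
        """Flat (n_combinations,) log likelihood for per-angle mean responses."""
        means = np.atleast_1d(np.asarray(means, dtype=float))
        if means.shape != self.angles.shape:
            raise ValueError("means must have one entry per stimulus angle")
        n = self.angles.size
        if self._cached:
            acc = np.zeros(self.grid.n_combinations, dtype=float)
            tmp = np.empty_like(acc)
            for i in range(n):
                np.subtract(means[i], self._rhat[i], out=tmp)
                np.multiply(tmp, tmp, out=tmp)
                np.multiply(tmp, self._inv_var[i], out=tmp)
                acc += tmp
            return -(0.5 * acc + self._logsd_sum + 0.5 * n * _LOG_2PI)
        return self._log_likelihood_streamed(means)

    def _log_likelihood_streamed(self, means) -> np.ndarray:
        g = self.grid
        nc = g.c.size
        per_c = g.n_combinations // nc
        c_chunk = max(1, int(8_000_000 // max(per_c, 1)))
        out = np.empty(g.n_combinations, dtype=float)
        n = self.angles.size
        for start in range(0, nc, c_chunk):
            sl = slice(start, min(start + c_chunk, nc))
            block = np.full(((sl.stop - sl.start) * per_c,), -0.5 * n * _LOG_2PI)
            for i in range(n):
                rhat = self._predicted_block(i, sl).ravel()
                sd = noise_sd(rhat, self.noise) / np.sqrt(self.T[i])
                d = (means[i] - rhat) / sd
                block -= np.log(sd) + 0.5 * d * d
            out[sl.start * per_c: sl.stop * per_c] = block
        return out

    def posterior(self, data: ResponseData) -> np.ndarray:
        """Normalized joint posterior (uniform prior), shaped like the grid."""
        ll = self.log_likelihood(data.means)
        return _normalize_loglik(ll).reshape(self.grid.shape)

    def summary(self, data: ResponseData, **kwargs) -> "PosteriorSummary":
        return compute_posterior(data, self.grid, self.noise, evaluator=self, **kwargs)


def _normalize_loglik(ll: np.ndarray) -> np.ndarray:
    finite = np.isfinite(ll)
    if not np.any(finite):
        raise FloatingPointError(
            "joint likelihood underflowed everywhere; accumulate in log space "
            "and subtract the maximum before exponentiating"
        )
    m = ll[finite].max()
    w = np.exp(np.where(finite, ll - m, -np.inf))
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("joint likelihood could not be normalized")
    return w / total


# ---------------------------------------------------------------------------
# derived quantities over the grid


def _derived_index_values(grid: GridSpec):
    """OI, DI and derived R_pref over the (C, Rp, alpha, sigma) axes.

    Theta drops out of all three quantities, so they are computed on a
    4-D block and broadcast against the theta-marginalized posterior.
    """
    c = grid.c[:, None, None, None]
    rp = grid.rp[None, :, None, None]
    al = grid.alpha[None, None, :, None]
    e_null = np.exp(-(180.0 ** 2) / (2.0 * grid.sigma ** 2))[None, None, None, :]
    e_orth = np.exp(-(90.0 ** 2) / (2.0 * grid.sigma ** 2))[None, None, None, :]
    r_pref = c + rp * (1.0 + al * e_null)
    r_null = c + rp * (al + e_null)
    r_orth = c + rp * (1.0 + al) * e_orth
    with np.errstate(divide="ignore", invalid="ignore"):
        oi = (r_pref + r_null - 2.0 * r_orth) / (r_pref + r_null)
        di = (r_pref - r_null) / r_pref
    return oi, di, r_pref


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed right-open bins; the last bin is closed on the right.

    Out-of-range and non-finite values map to -1 (their mass is dropped
    with a warning by the caller).
    """
    nb = edges.size - 1
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = nb - 1
    bad = ~np.isfinite(values) | (idx < 0) | (idx >= nb)
    idx = np.where(bad, -1, idx)
    return idx.astype(np.int64)


def _fraction_outside(values: np.ndarray, edges: np.ndarray) -> float:
    ok = np.isfinite(values)
    outside = ok & ((values < edges[0]) | (values > edges[-1]))
    return float(outside.sum()) / values.size


def _accumulate(idx: np.ndarray, weights: np.ndarray, n_bins: int, what: str) -> np.ndarray:
    """Histogram posterior mass by precomputed bin index.

    Mass at idx == -1 (out of range / non-finite) is dropped and the
    histogram renormalized, with a warning when non-negligible.
    """
    flat_idx = idx.ravel()
    valid = flat_idx >= 0
    hist = np.bincount(flat_idx[valid], weights=weights.ravel()[valid], minlength=n_bins)
    dropped = 1.0 - hist.sum()
    if dropped > 1e-9:
        warnings.warn(
            f"{what}: {dropped:.3g} posterior mass fell outside the histogram "
            "range (possible with negative offsets) and was renormalized away"
        )
    total = hist.sum()
    if total <= 0:
        raise FloatingPointError(f"{what}: no posterior mass inside histogram range")
    return hist / total


def marginal(joint: np.ndarray, grid: GridSpec, which: str) -> np.ndarray:
    """Normalized 1-D marginal of the joint posterior for one parameter."""
    axis = PARAM_NAMES.index(which) if which in PARAM_NAMES else None
    if axis is None:
        raise KeyError(f"unknown parameter {which!r}; expected one of {PARAM_NAMES}")
    j = np.asarray(joint).reshape(grid.shape)
    other = tuple(i for i in range(5) if i != axis)
    m = j.sum(axis=other)
    total = m.sum()
    if total <= 0:
        raise FloatingPointError("marginal has no mass")
    return m / total


def mle(joint: np.ndarray, grid: GridSpec):
    """Grid combination with the largest joint posterior mass.

    Ties are broken by first occurrence in C-order over the fixed axis
    order (C, Rp, alpha, theta_pref, sigma ascending); a tie flag is
    returned alongside the parameters.
    """
    j = np.asarray(joint).reshape(grid.shape)
    flat_idx = int(np.argmax(j))
    tied = int(np.count_nonzero(j == j.flat[flat_idx])) > 1
    index = np.unravel_index(flat_idx, grid.shape)
    return grid.params_at(index), float(j.flat[flat_idx]), tied


def index_histograms(joint: np.ndarray, grid: GridSpec, n_bins: int = 20,
                     _evaluator: GridEvaluator | None = None):
    """Posterior histograms of the OI and DI derived from the model curve.

    Every grid combination's OI/DI (computed from the full model
    responses, offset included) contributes its posterior mass to the
    containing bin.  Bins partition [0, 1]; left-closed, right-open,
    last bin closed.  Values outside [0, 1] (possible when C < 0) are
    clamped into the end bins with a warning.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    j = np.asarray(joint).reshape(grid.shape)
    jz = j.sum(axis=3)  # theta drops out of the indices
    oi, di, _ = _derived_index_values(grid)
    oi_hist = _clamped_hist(oi, jz, edges, "OI histogram")
    di_hist = _clamped_hist(di, jz, edges, "DI histogram")
    return oi_hist, di_hist, edges


def _clamped_hist(values, weights, edges, what):
    frac_out = _fraction_outside(values, edges)
    if frac_out > 0:
        warnings.warn(
            f"{what}: {frac_out:.3g} of grid combinations have index values "
            "outside [0, 1]; their mass is clamped into the end bins"
        )
        values = np.clip(values, edges[0], edges[-1])
    idx = _bin_indices(values, edges)
    return _accumulate(idx, weights, edges.size - 1, what)


def rpref_likelihood(joint: np.ndarray, grid: GridSpec, edges=None):
    """Posterior histogram of the derived preferred response R(theta_pref).

    The derived quantity is ``C + Rp + alpha * Rp * exp(-180^2 / (2 sigma^2))``
    (the full model response at the preferred direction).  Returns
    (histogram, edges); the histogram sums to 1.
    """
    j = np.asarray(joint).reshape(grid.shape)
    _, _, rpref = _derived_index_values(grid)
    if edges is None:
        lo, hi = float(rpref.min()), float(rpref.max())
        pad = max(1e-9, 1e-9 * max(abs(lo), abs(hi)))
        edges = np.linspace(lo - pad, hi + pad, 61)
    edges = np.asarray(edges, dtype=float)
    jz = j.sum(axis=3)
    idx = _bin_indices(rpref, edges)
    hist = _accumulate(idx, jz, edges.size - 1, "R_pref histogram")
    return hist, edges


def joint_2d(joint: np.ndarray, grid: GridSpec, param_a: str, param_b: str) -> np.ndarray:
    """Normalized 2-D marginal over a pair of parameters.

    Rows index ``param_a``, columns ``param_b``; sums to 1.
    """
    if param_a == param_b:
        raise ValueError("joint_2d requires two distinct parameter names")
    for p in (param_a, param_b):
        if p not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {p!r}; expected one of {PARAM_NAMES}")
    ia, ib = PARAM_NAMES.index(param_a), PARAM_NAMES.index(param_b)
    j = np.asarray(joint).reshape(grid.shape)
    other = tuple(i for i in range(5) if i not in (ia, ib))
    table = j.sum(axis=other)
    if ia > ib:
        table = table.T
    return table / table.sum()


@dataclass
class PosteriorSummary:
    """Compact storable summary of one cell's grid posterior.

    Holds the per-parameter marginals (each summing to 1), the grid
    MLE, 20-bin OI and DI histograms, the derived R_pref histogram, and
    optional 2-D joint marginals — kilobytes per cell instead of the
    gigabytes the raw joint would need.
    """

    grid: GridSpec
    marginals: dict
    mle: TuningParams
    mle_prob: float
    mle_tied: bool
    oi_hist: np.ndarray
    di_hist: np.ndarray
    index_bin_edges: np.ndarray
    rpref_hist: np.ndarray
    rpref_edges: np.ndarray
    joint2d: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def marginal_values(self, which: str):
        """(grid values, marginal probabilities) for one parameter."""
        return self.grid.axis(which), self.marginals[which]

    def rpref_mode(self) -> float:
        """Center of the most probable derived-R_pref bin."""
        i = int(np.argmax(self.rpref_hist))
        return float(0.5 * (self.rpref_edges[i] + self.rpref_edges[i + 1]))

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "marginals": {k: np.asarray(v).tolist() for k, v in self.marginals.items()},
            "mle": {
                "C": self.mle.C, "Rp": self.mle.Rp, "alpha": self.mle.alpha,
                "theta_pref": self.mle.theta_pref, "sigma": self.mle.sigma,
            },
            "mle_prob": self.mle_prob,
            "mle_tied": self.mle_tied,
            "oi_hist": np.asarray(self.oi_hist).tolist(),
            "di_hist": np.asarray(self.di_hist).tolist(),
            "index_bin_edges": np.asarray(self.index_bin_edges).tolist(),
            "rpref_hist": np.asarray(self.rpref_hist).tolist(),
            "rpref_edges": np.asarray(self.rpref_edges).tolist(),
            "joint2d": {f"{a}|{b}": np.asarray(t).tolist() for (a, b), t in self.joint2d.items()},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorSummary":
        return cls(
            grid=GridSpec.from_dict(d["grid"]),
            marginals={k: np.asarray(v, float) for k, v in d["marginals"].items()},
            mle=TuningParams(**d["mle"]),
            mle_prob=float(d["mle_prob"]),
            mle_tied=bool(d["mle_tied"]),
            oi_hist=np.asarray(d["oi_hist"], float),
            di_hist=np.asarray(d["di_hist"], float),
            index_bin_edges=np.asarray(d["index_bin_edges"], float),
            rpref_hist=np.asarray(d["rpref_hist"], float),
            rpref_edges=np.asarray(d["rpref_edges"], float),
            joint2d={
                tuple(k.split("|")): np.asarray(t, float)
                for k, t in d.get("joint2d", {}).items()
            },
            meta=d.get("meta", {}),
        )


def compute_posterior(
    data: ResponseData,
    grid: GridSpec,
    noise: NoiseModel,
    *,
    rpref_edges=None,
    pairs=(),
    evaluator: GridEvaluator | None = None,
    return_joint: bool = False,
):
    """Full grid posterior for one cell, reduced to a storable summary.

    Parameters
    ----------
    data : ResponseData
        Per-angle mean responses (trial-level data is averaged) and T.
    grid : GridSpec
        Discrete value sets; the prior is uniform over all combinations.
    noise : NoiseModel
        Mean-dependent noise law used as the likelihood SD.
    rpref_edges : array, optional
        Bin edges for the derived R_pref histogram (default: 60 equal
        bins spanning the derived range of the grid).
    pairs : iterable of (name, name), optional
        Parameter pairs for which to keep 2-D joint marginals.
    evaluator : GridEvaluator, optional
        Reusable engine (must match grid/noise/angles/T); building one
        up front amortizes the prediction cost across replicates.
    return_joint : bool
        Also return the normalized joint array (in-memory handle only;
        writing it to disk is intentionally unsupported).
    """
    if evaluator is None:
        evaluator = GridEvaluator(grid, noise, data.angles, data.T)
    else:
        if evaluator.grid is not grid and evaluator.grid.shape != grid.shape:
            raise ValueError("evaluator was built for a different grid")
        if not np.array_equal(evaluator.angles, np.atleast_1d(np.asarray(data.angles, float))):
            raise ValueError("evaluator was built for different stimulus angles")
    joint = evaluator.posterior(data)

    marginals = {name: marginal(joint, grid, name) for name in PARAM_NAMES}
    mle_params, mle_prob, tied = mle(joint, grid)
    oi_hist, di_hist, index_edges = index_histograms(joint, grid)
    rpref_hist, rpref_edges_out = rpref_likelihood(joint, grid, edges=rpref_edges)
    tables = {}
    for a, b in pairs:
        tables[(a, b)] = joint_2d(joint, grid, a, b)

    summary = PosteriorSummary(
        grid=grid,
        marginals=marginals,
        mle=mle_params,
        mle_prob=mle_prob,
        mle_tied=tied,
        oi_hist=oi_hist,
        di_hist=di_hist,
        index_bin_edges=index_edges,
        rpref_hist=rpref_hist,
        rpref_edges=rpref_edges_out,
        joint2d=tables,
        meta={
            "n_angles": int(data.n_angles),
            "T": np.asarray(data.T).tolist(),
            "noise": noise.asdict(),
            "n_combinations": grid.n_combinations,
        },
    )
    if return_joint:
        return summary, joint
    return summary
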