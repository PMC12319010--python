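"""Tuning-curve models and selectivity indices.

The core response model is a double Gaussian on the circle: a constant
offset ``C`` plus Gaussian lobes of amplitude ``Rp`` at the preferred
direction ``theta_pref`` and ``Rn = alpha * Rp`` at the null direction
(``theta_pref + 180``), both with width ``sigma`` (degrees).  The
``alpha`` parameterization (``0 <= alpha <= 1``) guarantees that the
null-direction amplitude never exceeds the preferred one.

All angles are in degrees.  The library is agnostic about the angular
convention (compass vs. Cartesian); angles are taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningParams",
    "VonMisesParams",
    "angdiff",
    "double_gaussian",
    "orientation_index",
    "direction_index",
    "von_mises",
    "circular_variance",
]


def angdiff(delta):
    """Absolute circular difference in degrees, in [0, 180].

    Accepts scalars or arrays of signed angle differences (degrees);
    the result is the shortest distance around the 360-degree circle.
    """
    d = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("angdiff requires finite angle differences")
    d = np.abs(d) % 360.0
    out = np.minimum(d, 360.0 - d)
    if np.isscalar(delta) or np.ndim(delta) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TuningParams:
    """Parameters of the double-Gaussian direction tuning curve.

    Attributes
    ----------
    C : float
        Constant offset (response units).  May be negative for
        baseline-subtracted data such as calcium dF/F.
    Rp : float
        Amplitude above offset at the preferred direction (>= 0).
    alpha : float
        Null/preferred amplitude ratio, in [0, 1].
    theta_pref : float
        Preferred direction in degrees; normalized into [0, 360).
    sigma : float
        Tuning width in degrees (> 0).
    """

    C: float
    Rp: float
    alpha: float
    theta_pref: float
    sigma: float

    def __post_init__(self):
        for name in ("C", "Rp", "alpha", "theta_pref", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.Rp < 0:
            raise ValueError(f"Rp must be >= 0, got {self.Rp}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        object.__setattr__(self, "theta_pref", float(self.theta_pref) % 360.0)

    @property
    def Rn(self) -> float:
        """Null-direction amplitude above offset, ``alpha * Rp``."""
        return self.alpha * self.Rp

    @property
    def theta_null(self) -> float:
        """Null direction, opposite the preferred one."""
        return (self.theta_pref + 180.0) % 360.0

    @property
    def r_pref(self) -> float:
        """Full model response at the preferred direction (offset included)."""
        return float(double_gaussian(self.theta_pref, self))

    @property
    def r_null(self) -> float:
        """Full model response at the null direction (offset included)."""
        return float(double_gaussian(self.theta_null, self))

    def astuple(self):
        return (self.C, self.Rp, self.alpha, self.theta_pref, self.sigma)


@dataclass(frozen=True)
class VonMisesParams:
    """Parameters of a von Mises orientation tuning curve.

    ``A`` is the peak response, ``k >= 0`` the concentration, and
    ``phi`` the preferred orientation in degrees.  The curve has period
    180 degrees (orientation, not direction, tuning).
    """

    A: float
    k: float
    phi: float

    def __post_init__(self):
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


def double_gaussian(theta, params: TuningParams):
    """Evaluate the double-Gaussian tuning curve at ``theta`` (degrees).

    Returns ``C + Rp exp(-angdiff(theta - theta_pref)^2 / (2 sigma^2))
    + alpha Rp exp(-angdiff(theta - theta_null)^2 / (2 sigma^2))``.
    Periodic with period 360 degrees; scalar in, scalar out.
    """
    th = np.asarray(theta, dtype=float)
    dp = angdiff(th - params.theta_pref)
    dn = angdiff(th - params.theta_null)
    s2 = 2.0 * params.sigma ** 2
    r = (
        params.C
        + params.Rp * np.exp(-np.square(dp) / s2)
        + params.alpha * params.Rp * np.exp(-np.square(dn) / s2)
    )
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(r)
    return r


def _index_responses(params: TuningParams):
    """Full responses at preferred, null and the two orthogonal angles."""
    tp = params.theta_pref
    angles = np.array([tp, tp + 180.0, tp + 90.0, tp - 90.0])
    return double_gaussian(angles, params)


def orientation_index(params: TuningParams) -> float:
    """Orientation index: (Rpref + Rnull - (Rorth+ + Rorth-)) / (Rpref + Rnull).

    All four responses are the full model responses (offset included).
    Raises for degenerate cells where ``Rpref + Rnull == 0``.
    """
    rp, rn, ro1, ro2 = _index_responses(params)
    denom = rp + rn
    if denom == 0:
        raise ZeroDivisionError(
            "orientation index undefined: Rpref + Rnull is zero (degenerate cell)"
        )
    return float((rp + rn - (ro1 + ro2)) / denom)


def direction_index(params: TuningParams) -> float:
    """Direction index: (Rpref - Rnull) / Rpref, with full responses."""
    rp, rn, _, _ = _index_responses(params)
    if rp == 0:
        raise ZeroDivisionError(
            "direction index undefined: Rpref is zero (unresponsive cell)"
        )
    return float((rp - rn) / rp)


def von_mises(theta, params: VonMisesParams):
    """Von Mises orientation tuning curve: A exp(k [cos(2(theta - phi)) - 1]).

    Maximum ``A`` at ``theta = phi``; period 180 degrees.
    """
    th = np.asarray(theta, dtype=float)
    r = params.A * np.exp(params.k * (np.cos(2.0 * np.deg2rad(th - params.phi)) - 1.0))
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(r)
    return r


def circular_variance(angles, responses, space: str = "orientation") -> float:
    """Response-weighted circular variance, ``1 - |sum r e^(i m theta)| / sum r``.

    ``m = 2`` in orientation space (period 180) and ``m = 1`` in
    direction space (period 360).  Responses must be nonnegative and
    must not all be zero.
    """
    m = {"orientation": 2.0, "direction": 1.0}.get(space)
    if m is None:
        raise ValueError(f"space must be 'orientation' or 'direction', got {space!r}")
    ang = np.asarray(angles, dtype=float)
    r = np.asarray(responses, dtype=float)
    if ang.shape != r.shape:
        raise ValueError("angles and responses must have the same shape")
    if np.any(r < 0):
        raise ValueError("circular variance requires nonnegative responses")
    total = r.sum()
    if total == 0:
        raise ZeroDivisionError("circular variance undefined: all responses are zero")
    z = np.sum(r * np.exp(1j * m * np.deg2rad(ang)))
    return float(1.0 - np.abs(z) / total)
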