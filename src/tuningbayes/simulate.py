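"""Seeded synthetic tuning-curve data.

Scenarios cover the standard simulation conditions used to validate
grid-posterior estimation of direction tuning: strongly and weakly
tuned cells sampled at 36 directions with 5 trials and 50%
multiplicative Gaussian noise; a temporal-frequency triplet (strong
direction selectivity, pure orientation selectivity, unresponsive) at
16 directions; sweeps of the orientation and direction indices from 0
toward 1; an angle-count sweep; and von Mises curves (a model-mismatch
probe) with constant noise.

Noise modes
-----------
``fractional``
    Per-trial SD is ``level * |R(theta)|`` — "50% Gaussian noise" means
    ``level = 0.5``.  Proportional to the local mean, consistent with
    the mean-dependent noise premise of the estimator.
``noise_model``
    Per-trial SD is ``sigma_noise(R(theta))`` from a NoiseModel; use
    this to simulate data whose generative law exactly matches the
    likelihood.
``constant``
    Per-trial SD is ``level`` everywhere (e.g. 2 spikes/s for the von
    Mises sweep).

Simulated responses are not truncated at zero by default: additive
Gaussian noise can and does produce negative samples, as baseline-
subtracted measurements do.  Truncation is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .grid import ResponseData
from .noise import NoiseModel, noise_sd
from .tuning import (
    TuningParams,
    VonMisesParams,
    direction_index,
    double_gaussian,
    orientation_index,
    von_mises,
)

__all__ = [
    "SimScenario",
    "sample_responses",
    "scenario_library",
    "available_scenarios",
    "params_for_oi",
    "params_for_di",
]

NOISE_MODES = ("fractional", "noise_model", "constant")


def _even_angles(n: int) -> np.ndarray:
    return np.arange(n) * (360.0 / n)


@dataclass(frozen=True)
class SimScenario:
    """One simulated recording condition.

    ``noise_level`` is a float for fractional/constant modes and a
    :class:`NoiseModel` for noise-model mode.
    """

    params: Union[TuningParams, VonMisesParams]
    angles: np.ndarray
    T: int
    noise_mode: str = "fractional"
    noise_level: Union[float, NoiseModel] = 0.5
    seed: int = 0
    truncate_at_zero: bool = False
    name: str = ""

    def __post_init__(self):
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(
                f"unknown noise mode {self.noise_mode!r}; expected one of {NOISE_MODES}"
            )
        if self.T < 1:
            raise ValueError("T must be >= 1")
        ang = np.ascontiguousarray(np.asarray(self.angles, dtype=float))
        ang.setflags(write=False)
        object.__setattr__(self, "angles", ang)
        if self.noise_mode == "noise_model":
            if not isinstance(self.noise_level, NoiseModel):
                raise ValueError("noise_model mode requires a NoiseModel as noise_level")
        elif not np.isscalar(self.noise_level) or self.noise_level < 0:
            raise ValueError("noise level must be a nonnegative scalar")

    def true_curve(self) -> np.ndarray:
        """Noiseless model responses at the scenario's angles."""
        if isinstance(self.params, VonMisesParams):
            return np.asarray(von_mises(self.angles, self.params), dtype=float)
        return np.asarray(double_gaussian(self.angles, self.params), dtype=float)

    def trial_sd(self) -> np.ndarray:
        """Per-trial noise SD at each angle."""
        r = self.true_curve()
        if self.noise_mode == "fractional":
            return float(self.noise_level) * np.abs(r)
        if self.noise_mode == "constant":
            return np.full_like(r, float(self.noise_level))
        return np.asarray(noise_sd(r, self.noise_level), dtype=float)


def sample_responses(scenario: SimScenario, seed: int | None = None) -> ResponseData:
    """Draw one trial-level dataset; deterministic given the seed.

    ``seed`` overrides the scenario's own seed when given.  Each trial
    response is the noiseless curve plus independent Gaussian noise
    with the scenario's per-trial SD.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    r = scenario.true_curve()
    sd = scenario.trial_sd()
    trials = r[:, None] + rng.standard_normal((r.size, scenario.T)) * sd[:, None]
    if scenario.truncate_at_zero:
        trials = np.clip(trials, 0.0, None)
    return ResponseData.from_trials(scenario.angles, trials)


def _oi_of_rp(rp, C, alpha, sigma, theta):
    if rp == 0:
        # flat curve; defined as 0 when the offset is positive
        return 0.0
    return orientation_index(TuningParams(C, rp, alpha, theta, sigma))


def params_for_oi(target: float, C: float = 1.0, alpha: float = 0.5,
                  sigma: float = 30.0, theta_pref: float = 45.0) -> TuningParams:
    """Amplitude Rp that makes the model OI hit ``target``, other params fixed.

    The attainable OI is bounded below 1 by the Gaussian leak into the
    orthogonal angles; for targets at or beyond the bound the offset is
    set to 0 and Rp to 10, which attains the supremum (~0.98 at
    sigma = 30).
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"OI target must be in [0, 1], got {target}")
    if target == 0.0:
        return TuningParams(C, 0.0, alpha, theta_pref, sigma)
    sup = _oi_of_rp(1e9, C, alpha, sigma, theta_pref)
    if target >= sup:
        return TuningParams(0.0, 10.0, alpha, theta_pref, sigma)
    rp = brentq(lambda x: _oi_of_rp(x, C, alpha, sigma, theta_pref) - target, 1e-9, 1e9)
    return TuningParams(C, float(rp), alpha, theta_pref, sigma)


def params_for_di(target: float, C: float = 1.0, Rp: float = 10.0,
                  sigma: float = 30.0, theta_pref: float = 45.0) -> TuningParams:
    """Amplitude ratio alpha that makes the model DI hit ``target``.

    DI is bounded above by its value at alpha = 0 (slightly below 1
    when the offset is positive); for targets at or beyond the bound
    the offset is set to 0, which attains DI ~ 1 at alpha = 0.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"DI target must be in [0, 1], got {target}")

    def di_of_alpha(a, c):
        return direction_index(TuningParams(c, Rp, a, theta_pref, sigma))

    if target >= di_of_alpha(0.0, C):
        return TuningParams(0.0, Rp, 0.0, theta_pref, sigma)
    a = brentq(lambda x: di_of_alpha(x, C) - target, 0.0, 1.0)
    return TuningParams(C, Rp, float(a), theta_pref, sigma)


def _library() -> dict:
    lib: dict[str, SimScenario] = {}
    angles36 = _even_angles(36)
    angles16 = _even_angles(16)

    lib["well_tuned"] = SimScenario(
        params=TuningParams(C=1.0, Rp=10.0, alpha=0.5, theta_pref=90.0, sigma=30.0),
        angles=angles36, T=5, noise_mode="fractional", noise_level=0.5,
        name="well_tuned",
    )
    lib["poorly_tuned"] = SimScenario(
        params=TuningParams(C=1.0, Rp=1.0, alpha=0.0, theta_pref=90.0, sigma=30.0),
        angles=angles36, T=5, noise_mode="fractional", noise_level=0.5,
        name="poorly_tuned",
    )

    # temporal-frequency triplet: direction-selective / orientation-only /
    # unresponsive, sampled at 16 directions
    tf = {
        "tf_low": (7.0, 1.0 / 7.0),
        "tf_medium": (5.0, 1.0),
        "tf_high": (0.0, 0.0),
    }
    for nm, (rp, al) in tf.items():
        lib[nm] = SimScenario(
            params=TuningParams(C=1.0, Rp=rp, alpha=al, theta_pref=45.0, sigma=30.0),
            angles=angles16, T=5, noise_mode="fractional", noise_level=0.5,
            name=nm,
        )

    for n in (4, 8, 16, 32, 36):
        lib[f"angles_{n}"] = SimScenario(
            params=TuningParams(C=2.5, Rp=7.5, alpha=0.5, theta_pref=45.0, sigma=30.0),
            angles=_even_angles(n), T=5, noise_mode="fractional", noise_level=0.5,
            name=f"angles_{n}",
        )

    # selectivity-index sweeps, targets 0, 0.25, 0.5, 0.75, 1
    for pct in (0, 25, 50, 75, 100):
        lib[f"oi_sweep_{pct}"] = SimScenario(
            params=params_for_oi(pct / 100.0),
            angles=angles16, T=5, noise_mode="fractional", noise_level=0.5,
            name=f"oi_sweep_{pct}",
        )
        lib[f"di_sweep_{pct}"] = SimScenario(
            params=params_for_di(pct / 100.0),
            angles=angles16, T=5, noise_mode="fractional", noise_level=0.5,
            name=f"di_sweep_{pct}",
        )

    # von Mises model-mismatch probe: peak rate swept 0..10 in steps of
    # 2.5 sp/s, constant noise of 2 sp/s
    for a in (0.0, 2.5, 5.0, 7.5, 10.0):
        nm = f"vonmises_A{a:g}"
        lib[nm] = SimScenario(
            params=VonMisesParams(A=a, k=2.0, phi=90.0),
            angles=angles36, T=5, noise_mode="constant", noise_level=2.0,
            name=nm,
        )
    return lib


def available_scenarios() -> list[str]:
    return sorted(_library())


def scenario_library(name: str, seed: int = 0, **overrides) -> SimScenario:
    """Named scenario from the library, optionally with field overrides."""
    lib = _library()
    if name not in lib:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(lib))}"
        )
    return replace(lib[name], seed=seed, **overrides)
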