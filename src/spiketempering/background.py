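"""Background-input configurations and the rate -> temperature map.

The stochastic background of every neuron is summarized by one aggregate
excitatory and one aggregate inhibitory Poisson source with rates
``nu_exc``/``nu_inh`` (kHz) and weights ``w_exc``/``w_inh``.  Rates can
follow time-dependent schedules (sinusoidal oscillations of the rates
themselves, or of the scaling parameter alpha of a conductance-based
scenario).  The total background rate sets the sampling temperature of the
neuron: along a balanced rate line the activation-function offset stays
constant and only the slope 1/beta — i.e. the temperature — changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import yaml
from scipy.optimize import least_squares

__all__ = [
    "RateSchedule",
    "BackgroundConfig",
    "AlphaScenario",
    "BalanceLine",
    "rate_at",
    "balance_inh",
    "scenario_rates",
    "temperature_from_rates",
    "temperature_model_sqrt_alpha",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateSchedule:
    """Time course of a rate (or of the scenario scaling alpha).

    ``sinusoid`` follows  nu(t) = (nu_max-nu_min)/2 * sin(2 pi f t)
    + (nu_max+nu_min)/2,  so t=0 sits at mid-rising phase.  ``piecewise``
    interpolates (t, value) knots with zero-order hold.
    """

    kind: Literal["constant", "sinusoid", "piecewise"] = "constant"
    value: float = 0.0  # constant kind
    nu_min: float = 0.0
    nu_max: float = 0.0
    f_osc: float = 0.0  # Hz
    knots_t: tuple = ()  # ms, piecewise kind
    knots_v: tuple = ()

    def __post_init__(self):
        if self.kind == "sinusoid":
            if self.nu_min > self.nu_max:
                raise ValueError("nu_min must not exceed nu_max")
            if self.f_osc < 0:
                raise ValueError("f_osc must be non-negative")
        if self.kind == "piecewise" and len(self.knots_t) != len(self.knots_v):
            raise ValueError("piecewise knots must pair up")

    def __call__(self, t) -> np.ndarray | float:
        """Instantaneous value at time ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        if self.kind == "constant":
            out = np.full_like(t, self.value)
        elif self.kind == "sinusoid":
            amp = 0.5 * (self.nu_max - self.nu_min)
            mid = 0.5 * (self.nu_max + self.nu_min)
            out = amp * np.sin(2e-3 * np.pi * self.f_osc * t) + mid
        else:
            idx = np.clip(
                np.searchsorted(np.asarray(self.knots_t), t, side="right") - 1, 0, None
            )
            out = np.asarray(self.knots_v, dtype=float)[idx]
        return out if out.ndim else float(out)

    def sample(self, n_steps: int, dt: float) -> np.ndarray:
        """Evaluate on the simulation grid (value at each step start)."""
        return np.asarray(self(np.arange(n_steps) * dt), dtype=float)

    def phase(self, t) -> np.ndarray | float:
        """Oscillation phase in [0, 2 pi), zero at the schedule minimum.

        With the sinusoidal convention above the minimum occurs at
        2 pi f t = 3 pi/2, so ``phase = (2 pi f t + pi/2) mod 2 pi`` and the
        maximum sits at phase pi.
        """
        if self.kind != "sinusoid":
            raise ValueError("phase is defined for sinusoidal schedules")
        return np.mod(2e-3 * np.pi * self.f_osc * np.asarray(t) + 0.5 * np.pi, 2 * np.pi)


def rate_at(schedule: RateSchedule, t) -> float | np.ndarray:
    """Instantaneous rate of a schedule at time ``t`` (ms)."""
    return schedule(t)


@dataclass(frozen=True)
class BalanceLine:
    """Linear rate relation nu_inh = nu_0 + m * nu_exc keeping the
    activation-function offset I_0 constant."""

    nu_0: float  # kHz
    m: float
    nu_exc_range: tuple[float, float] = (0.0, np.inf)

    def __call__(self, nu_exc):
        return balance_inh(self, nu_exc)


def balance_inh(line: BalanceLine, nu_exc) -> float | np.ndarray:
    """Inhibitory rate paired with ``nu_exc`` along a balance line.

    Negative extrapolations are clipped to zero with a logged warning (the
    balanced regime is never operated there).
    """
    nu_exc = np.asarray(nu_exc, dtype=float)
    lo, hi = line.nu_exc_range
    if np.any(nu_exc < lo) or np.any(nu_exc > hi):
        warnings.warn("nu_exc outside the balance line's validity range", stacklevel=2)
    nu_inh = line.nu_0 + line.m * nu_exc
    if np.any(nu_inh < 0):
        logger.warning("balance line produced negative nu_inh; clipping to 0")
        nu_inh = np.clip(nu_inh, 0.0, None)
    return nu_inh if nu_inh.ndim else float(nu_inh)


@dataclass(frozen=True)
class AlphaScenario:
    """Alpha-scaled conductance-based background scenario.

    Rates follow ``nu_x = alpha * nu_x_1 + nu_x_0``.  The
    ``mu_balanced_55`` scenario instead derives the inhibitory rate so the
    mean free membrane potential stays at the target potential ``u_hat``,
    which requires alpha >= 1.
    """

    name: str
    nu_exc_1: float
    nu_exc_0: float
    nu_inh_1: float
    nu_inh_0: float
    w_exc: float  # nS
    w_inh: float  # nS
    w_stim_max: float  # nS
    alpha_range: tuple[float, float] = (0.5, 5.0)
    balance_u_hat: float | None = None  # mV; set for mu_balanced_55

    @classmethod
    def from_preset(cls, name: str) -> "AlphaScenario":
        presets = _load_presets()
        if name not in presets:
            raise KeyError(f"no scenario {name!r}; have {sorted(presets)}")
        return cls(name=name, **presets[name])

    def rates(self, alpha):
        return scenario_rates(self, alpha)

    def rate_arrays(
        self, alpha_schedule: RateSchedule, n_steps: int, dt: float
    ) -> tuple[np.ndarray, np.ndarray]:
        alpha = alpha_schedule.sample(n_steps, dt)
        return scenario_rates(self, alpha)


def _load_presets() -> dict:
    text = (
        resources.files("spiketempering")
        .joinpath("data", "background_scenarios.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def scenario_rates(scenario: AlphaScenario, alpha) -> tuple:
    """Excitatory and inhibitory rates (kHz) of a scenario at ``alpha``."""
    alpha = np.asarray(alpha, dtype=float)
    lo, hi = scenario.alpha_range
    if np.any(alpha < lo - 1e-12) or np.any(alpha > hi + 1e-12):
        raise ValueError(f"alpha outside declared range [{lo}, {hi}]")
    if scenario.balance_u_hat is not None and np.any(alpha < 1.0 - 1e-12):
        raise ValueError(
            "the mean-balanced scenario needs alpha >= 1 (minimal background "
            "input is required to hold the mean membrane potential)"
        )
    nu_exc = alpha * scenario.nu_exc_1 + scenario.nu_exc_0
    nu_inh = alpha * scenario.nu_inh_1 + scenario.nu_inh_0
    if np.any(nu_exc < -1e-9) or np.any(nu_inh < -1e-9):
        raise ValueError("scenario produced negative rates")
    nu_inh = np.clip(nu_inh, 0.0, None)
    if nu_exc.ndim:
        return nu_exc, nu_inh
    return float(nu_exc), float(nu_inh)


def balanced_inh_rate(
    nu_exc,
    u_hat: float,
    *,
    g_l: float,
    E_l: float,
    E_exc: float,
    E_inh: float,
    tau_exc: float,
    tau_inh: float,
    w_exc: float,
    w_inh: float,
):
    """Inhibitory rate holding the conductance-based mean potential at
    ``u_hat`` for a given excitatory rate:

    nu_inh = nu_exc * tau_exc w_exc (E_exc - u_hat) / (tau_inh w_inh (u_hat - E_inh))
             + g_l (E_l - u_hat) / (tau_inh w_inh (u_hat - E_inh)).
    """
    denom = tau_inh * w_inh * (u_hat - E_inh)
    return (
        np.asarray(nu_exc) * tau_exc * w_exc * (E_exc - u_hat) / denom
        + g_l * (E_l - u_hat) / denom
    )


@dataclass
class BackgroundConfig:
    """Aggregate Poisson background of each neuron.

    ``nu_exc``/``nu_inh`` are constants (kHz) or :class:`RateSchedule`;
    weights are nA for current-based neurons (``w_inh`` negative) and nS
    (non-negative) for conductance-based ones.  Background realizations are
    independent across neurons; the rate schedule is shared.
    """

    nu_exc: float | RateSchedule
    nu_inh: float | RateSchedule
    w_exc: float
    w_inh: float
    independent: bool = True

    @classmethod
    def constant(cls, nu_exc, nu_inh, w_exc, w_inh) -> "BackgroundConfig":
        return cls(nu_exc=float(nu_exc), nu_inh=float(nu_inh), w_exc=w_exc, w_inh=w_inh)

    @classmethod
    def from_scenario(
        cls, scenario: AlphaScenario, alpha: float | RateSchedule, w_inh: float | None = None
    ) -> "BackgroundConfig":
        """Scenario background at constant or scheduled alpha.

        ``w_inh`` overrides the scenario's inhibitory background weight
        (used when scanning the inhibitory/excitatory weight ratio).
        """
        w_i = scenario.w_inh if w_inh is None else w_inh
        if isinstance(alpha, RateSchedule):
            cfg = cls(nu_exc=0.0, nu_inh=0.0, w_exc=scenario.w_exc, w_inh=w_i)
            cfg._scenario = scenario
            cfg._alpha_schedule = alpha
            return cfg
        nu_exc, nu_inh = scenario_rates(scenario, alpha)
        return cls(nu_exc=nu_exc, nu_inh=nu_inh, w_exc=scenario.w_exc, w_inh=w_i)

    _scenario: AlphaScenario | None = field(default=None, repr=False)
    _alpha_schedule: RateSchedule | None = field(default=None, repr=False)
    _balance_line: BalanceLine | None = field(default=None, repr=False)

    @classmethod
    def balanced(
        cls,
        nu_exc: "float | RateSchedule",
        line: BalanceLine,
        w_exc: float,
        w_inh: float,
    ) -> "BackgroundConfig":
        """Background whose inhibitory rate follows the balance line
        ``nu_inh = nu_0 + m * nu_exc`` at every instant."""
        if isinstance(nu_exc, RateSchedule):
            cfg = cls(nu_exc=nu_exc, nu_inh=0.0, w_exc=w_exc, w_inh=w_inh)
            cfg._balance_line = line
            return cfg
        return cls(nu_exc=float(nu_exc), nu_inh=balance_inh(line, nu_exc),
                   w_exc=w_exc, w_inh=w_inh)

    def weights(self) -> tuple[float, float]:
        return self.w_exc, self.w_inh

    def constant_rates(self) -> tuple[float, float]:
        if self._scenario is not None or isinstance(
            self.nu_exc, RateSchedule
        ) or isinstance(self.nu_inh, RateSchedule):
            raise ValueError("background rates are time-dependent")
        if self.nu_exc < 0 or self.nu_inh < 0:
            raise ValueError("rates must be non-negative")
        return float(self.nu_exc), float(self.nu_inh)

    def rate_arrays(self, n_steps: int, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-step rate arrays (kHz) on the simulation grid."""
        if self._scenario is not None:
            return self._scenario.rate_arrays(self._alpha_schedule, n_steps, dt)
        if self._balance_line is not None:
            nu_exc = self.nu_exc.sample(n_steps, dt)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nu_inh = np.asarray(balance_inh(self._balance_line, nu_exc))
            return nu_exc, nu_inh
        out = []
        for nu in (self.nu_exc, self.nu_inh):
            if isinstance(nu, RateSchedule):
                out.append(nu.sample(n_steps, dt))
            else:
                if nu < 0:
                    raise ValueError("rates must be non-negative")
                out.append(np.full(n_steps, float(nu)))
        return out[0], out[1]


def temperature_from_rates(
    nu_exc, nu_inh, reference: tuple[float, float]
) -> float | np.ndarray:
    """Ensemble temperature implied by background rates.

    With equal background weights and synaptic time constants the inverse
    slope of the activation function grows with the square root of the
    total rate, so

    ``T = sqrt((nu_exc + nu_inh) / (nu_exc_ref + nu_inh_ref))``,

    equal to 1 at the reference rates and monotone in the total rate.
    """
    nu_exc = np.asarray(nu_exc, dtype=float)
    nu_inh = np.asarray(nu_inh, dtype=float)
    ref_e, ref_i = reference
    if ref_e + ref_i <= 0:
        raise ValueError("reference rates must be positive")
    if np.any(nu_exc < 0) or np.any(nu_inh < 0):
        raise ValueError("rates must be non-negative")
    T = np.sqrt((nu_exc + nu_inh) / (ref_e + ref_i))
    return T if T.ndim else float(T)


def temperature_weighted(
    nu_exc, nu_inh, w_exc, w_inh, reference_rates, reference_weights
) -> float | np.ndarray:
    """Weight-aware temperature, invariant under nu -> s*nu, w -> w/sqrt(s):
    ``T = sqrt((w_exc^2 nu_exc + w_inh^2 nu_inh) / ref)``."""
    num = w_exc**2 * np.asarray(nu_exc, dtype=float) + w_inh**2 * np.asarray(
        nu_inh, dtype=float
    )
    re, ri = reference_rates
    we, wi = reference_weights
    den = we**2 * re + wi**2 * ri
    T = np.sqrt(num / den)
    return T if T.ndim else float(T)


def temperature_model_sqrt_alpha(
    alphas, temperatures, robust: bool = False
) -> tuple[float, float]:
    """Least-squares fit of T = c * sqrt(alpha).

    Returns ``(c, residual_norm)``.  With ``robust=True`` a soft-L1 loss
    downweights outliers.
    """
    a = np.asarray(alphas, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if a.size < 2 or a.size != T.size:
        raise ValueError("need at least 2 (alpha, T) pairs")
    x = np.sqrt(a)
    if robust:
        res = least_squares(
            lambda c: c[0] * x - T,
            x0=[np.dot(x, T) / np.dot(x, x)],
            loss="soft_l1",
            f_scale=0.1,
        )
        c = float(res.x[0])
    else:
        c = float(np.dot(x, T) / np.dot(x, x))
    resid = float(np.linalg.norm(c * x - T))
    return c, resid
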