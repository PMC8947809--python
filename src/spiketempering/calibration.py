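"""Response-function measurement, logistic fits, balance line, and the
translation of Boltzmann parameters into LIF weights and currents.

A sampling neuron under Poisson background responds to a constant injected
current with an activation probability p(z=1 | I_in) = nu_out * tau_ref
(the fraction of time it is refractory) that is well described by the
logistic  p = 1 / (1 + exp(-beta (I_in - I_0))).  The slope beta plays the
role of an inverse temperature, beta = 1/(k_B T), with k_B (in nA) fixed by
the response function at a chosen reference background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import curve_fit
from skimage import measure as _skmeasure

from .background import BackgroundConfig, BalanceLine
from .boltzmann import BoltzmannModel
from .lif_core import Network, NeuronParams, simulate

__all__ = [
    "ResponseCurve",
    "CalibrationResult",
    "measure_response",
    "fit_logistic",
    "calibrate_reference",
    "fit_balance_line",
    "balance_line_from_surface",
    "psp_shape_factor",
    "boltzmann_to_lif",
]


@dataclass
class ResponseCurve:
    """Measured activation probabilities on a grid of injected currents."""

    I_in: np.ndarray  # nA, strictly increasing
    p_on: np.ndarray  # activation probability nu_out * tau_ref
    duration: float  # ms per grid point
    background: BackgroundConfig | None = None

    def __post_init__(self):
        self.I_in = np.asarray(self.I_in, dtype=float)
        self.p_on = np.asarray(self.p_on, dtype=float)
        if np.any(np.diff(self.I_in) <= 0):
            raise ValueError("I_in must be strictly increasing")
        if np.any((self.p_on < 0) | (self.p_on > 1)):
            raise ValueError("p_on must lie in [0, 1]")


@dataclass
class CalibrationResult:
    """Fitted logistic activation: slope ``beta`` (1/nA), offset ``I_0``
    (nA), and the reference constant ``k_B = 1/beta_ref`` (nA) linking
    background rates to temperature."""

    beta: float
    I_0: float
    k_B: float
    background: BackgroundConfig | None = None
    cov: np.ndarray | None = None

    def __post_init__(self):
        if self.beta <= 0 or self.k_B <= 0:
            raise ValueError("beta and k_B must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta_per_nA": self.beta,
                    "I_0_nA": self.I_0,
                    "k_B_nA": self.k_B,
                    "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
                },
                fh,
                indent=2,
            )


def measure_response(
    params: NeuronParams,
    background: BackgroundConfig,
    I_grid,
    duration: float = 20_000.0,
    seed: int = 0,
    dt: float | None = None,
) -> ResponseCurve:
    """Measure the activation probability at each current in ``I_grid``.

    Each grid point is an independent neuron simulated for ``duration`` ms
    under its own background realization (one kernel call covers the whole
    grid).  The activation probability is estimated as
    ``spike_count * tau_ref / duration``.
    """
    I_grid = np.asarray(I_grid, dtype=float)
    if params.tau_ref <= 0:
        raise ValueError("activation readout needs tau_ref > 0")
    net = Network(
        params=params,
        n_neurons=I_grid.size,
        background=background,
        I_in=I_grid,
    )
    run = simulate(net, duration=duration, dt=dt, seed=seed)
    p_on = run.raster.counts() * params.tau_ref / duration
    if np.all(p_on < 0.01) or np.all(p_on > 0.99):
        raise RuntimeError(
            "uninformative current grid: activation saturated at every point"
        )
    return ResponseCurve(I_in=I_grid, p_on=np.clip(p_on, 0.0, 1.0), duration=duration,
                         background=background)


def _logistic(I, beta, I0):
    return 1.0 / (1.0 + np.exp(-beta * (I - I0)))


def fit_logistic(curve: ResponseCurve, reference: "CalibrationResult | None" = None
                 ) -> CalibrationResult:
    """Nonlinear least squares of the logistic activation function.

    ``reference`` supplies k_B when this fit is not its own reference;
    otherwise k_B is set to 1/beta of this fit.
    """
    p = curve.p_on
    if p.min() > 0.2 or p.max() < 0.8:
        warnings.warn(
            "response curve does not span both tails; fit may be ill-conditioned",
            stacklevel=2,
        )
    # initial guesses from the half-activation crossing and the 0.25..0.75 span
    I0_guess = float(np.interp(0.5, p, curve.I_in)) if np.any(np.diff(p) > 0) else float(
        np.median(curve.I_in)
    )
    span = np.ptp(curve.I_in)
    beta_guess = 4.0 / max(span / 3.0, 1e-6)
    try:
        popt, pcov = curve_fit(
            _logistic,
            curve.I_in,
            p,
            p0=[beta_guess, I0_guess],
            maxfev=20_000,
        )
    except RuntimeError as err:
        resid = np.abs(p - _logistic(curve.I_in, beta_guess, I0_guess))
        raise RuntimeError(
            f"logistic fit did not converge (max residual {resid.max():.3g})"
        ) from err
    beta, I0 = float(popt[0]), float(popt[1])
    k_B = reference.k_B if reference is not None else 1.0 / beta
    return CalibrationResult(beta=beta, I_0=I0, k_B=k_B, background=curve.background,
                             cov=pcov)


def _auto_grid(
    params: NeuronParams,
    background: BackgroundConfig,
    seed: int,
    n_points: int,
    coarse_duration: float,
) -> np.ndarray:
    """Locate the sigmoid with a coarse scan and return a centered grid.

    The coarse scan is centered on the current that brings the free-mean
    membrane potential to threshold (mean-matching) and spans a window
    proportional to the free-membrane standard deviation expressed as a
    current; the final grid is centered on the measured half-activation
    point with a width of about +-2.5/beta from a coarse logistic fit.
    """
    from .lif_core import free_membrane_moments_cuba

    if params.synapse_kind == "current":
        mu0, sigma2 = free_membrane_moments_cuba(params, background, 0.0)
        center = (params.v_th - mu0) * params.g_l / 1000.0  # nA
        width = max(4.0 * np.sqrt(sigma2) * params.g_l / 1000.0, 0.5)  # nA
    else:
        center, width = 0.0, 2.0
    coarse = np.linspace(center - 0.5 * width, center + 2.0 * width, 25)
    curve = measure_response(
        params, background, coarse, duration=coarse_duration, seed=seed
    )
    fit = fit_logistic(curve)
    lo = fit.I_0 - 2.5 / fit.beta
    hi = fit.I_0 + 2.5 / fit.beta
    return np.linspace(lo, hi, n_points)


def calibrate_reference(
    params: NeuronParams,
    background: BackgroundConfig,
    n_points: int = 15,
    duration: float = 20_000.0,
    coarse_duration: float = 4_000.0,
    seed: int = 0,
) -> CalibrationResult:
    """Two-stage reference calibration at a constant background.

    A short coarse scan locates the sigmoid; the final ``n_points``-point
    grid spanning both tails is then measured for ``duration`` ms per point
    and fitted.  The result carries ``k_B = 1/beta``.
    """
    grid = _auto_grid(params, background, seed, n_points, coarse_duration)
    curve = measure_response(params, background, grid, duration=duration, seed=seed + 1)
    return fit_logistic(curve)


def fit_balance_line(
    params: NeuronParams,
    nu_exc_grid,
    nu_inh_grid,
    w_exc: float,
    w_inh: float,
    reference: tuple[float, float] = (2.0, 2.0),
    duration: float = 20_000.0,
    coarse_duration: float = 4_000.0,
    n_points: int = 15,
    seed: int = 0,
):
    """Constant-offset balance line from response fits on a rate grid.

    Fits ``beta`` and ``I_0`` at every (nu_exc, nu_inh) grid point,
    bilinearly interpolates the offset surface, extracts the iso-offset
    contour through the reference rates by marching squares, and fits
    ``nu_inh = nu_0 + m * nu_exc`` along it.

    Returns ``(BalanceLine, r_squared, info)`` with ``info`` holding the
    fitted surfaces and contour points.
    """
    nu_exc_grid = np.asarray(nu_exc_grid, dtype=float)
    nu_inh_grid = np.asarray(nu_inh_grid, dtype=float)
    I0 = np.empty((nu_exc_grid.size, nu_inh_grid.size))
    beta = np.empty_like(I0)
    s = seed
    for i, ne in enumerate(nu_exc_grid):
        for j, ni in enumerate(nu_inh_grid):
            bg = BackgroundConfig.constant(ne, ni, w_exc, w_inh)
            grid = _auto_grid(params, bg, s, n_points, coarse_duration)
            curve = measure_response(params, bg, grid, duration=duration, seed=s + 1)
            fit = fit_logistic(curve)
            I0[i, j] = fit.I_0
            beta[i, j] = fit.beta
            s += 2

    line, r2, info = balance_line_from_surface(I0, nu_exc_grid, nu_inh_grid,
                                               reference)
    info["beta_surface"] = beta
    return line, r2, info


def balance_line_from_surface(
    I0_surface: np.ndarray,
    nu_exc_grid: np.ndarray,
    nu_inh_grid: np.ndarray,
    reference: tuple[float, float],
):
    """Extract the iso-offset contour through ``reference`` from a fitted
    offset surface (bilinear interpolation + marching squares) and fit the
    line nu_inh = nu_0 + m * nu_exc along it."""
    nu_exc_grid = np.asarray(nu_exc_grid, dtype=float)
    nu_inh_grid = np.asarray(nu_inh_grid, dtype=float)
    interp = RegularGridInterpolator((nu_exc_grid, nu_inh_grid), I0_surface)
    level = float(interp(reference))
    contours = _skmeasure.find_contours(I0_surface, level)
    if not contours:
        raise RuntimeError("iso-offset contour not found on the rate grid")

    idx_e = np.arange(nu_exc_grid.size)
    idx_i = np.arange(nu_inh_grid.size)

    def to_rates(contour):
        ne = np.interp(contour[:, 0], idx_e, nu_exc_grid)
        ni = np.interp(contour[:, 1], idx_i, nu_inh_grid)
        return ne, ni

    def dist_to_ref(contour):
        ne, ni = to_rates(contour)
        return np.hypot(ne - reference[0], ni - reference[1]).min()

    contour = min(contours, key=dist_to_ref)
    ne, ni = to_rates(contour)
    if ne.size < 3:
        warnings.warn("iso-offset contour only partially crosses the grid",
                      stacklevel=2)
    coeff = np.polyfit(ne, ni, 1)
    m, nu_0 = float(coeff[0]), float(coeff[1])
    resid = ni - (nu_0 + m * ne)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ni - ni.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    line = BalanceLine(nu_0=nu_0, m=m,
                       nu_exc_range=(float(ne.min()), float(ne.max())))
    info = {
        "I0_surface": I0_surface,
        "contour_nu_exc": ne,
        "contour_nu_inh": ni,
        "level": level,
    }
    return line, r2, info


def psp_shape_factor(params: NeuronParams) -> float:
    """Current scale factor of the Boltzmann-to-LIF weight translation.

    A presynaptic unit that stays ON fires regularly at 1/tau_ref, so its
    exponential PSCs accumulate into a sawtooth whose steady-state mean is
    ``w * tau_s / tau_ref``.  Matching that mean current to the desired
    activation shift W/beta gives

        factor = tau_ref / tau_s,

    i.e. unity in the standard regime tau_s = tau_ref.  (Matching a single
    isolated pulse instead would give tau_ref/(tau_s (1 - e^{-tau_ref/
    tau_s})), which overdrives sustained interactions; the sampled
    pairwise couplings then come out ~60% too strong.)
    """
    return params.tau_ref / params.tau_s


def boltzmann_to_lif(
    model: BoltzmannModel,
    calib: CalibrationResult,
    params: NeuronParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Translate Boltzmann parameters (W, B) into synaptic weights and
    injected currents for a current-based sampling network.

    Currents follow ``I_in,k = B_k / beta + I_0`` exactly; weights are
    ``w_kj = (W_kj / beta) * s`` with the PSP shape factor ``s`` chosen so
    that one presynaptic on-period shifts the postsynaptic activation by
    W_kj/beta on average.  Returns ``(weights [nA, KxK], currents [nA])``.
    """
    if params.synapse_kind != "current":
        raise ValueError("the exact translation applies to current-based neurons")
    s = psp_shape_factor(params)
    w = model.W / calib.beta * s
    I_in = model.B / calib.beta + calib.I_0
    return w, I_in
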