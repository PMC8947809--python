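"""Exponential escape-rate neuron model and the histogram-based fitting
procedure that extracts an effective temperature from deterministic LIF
runs.

The stochastic model shares the LIF membrane, reset and refractoriness but
replaces the hard threshold with an instantaneous firing intensity
``rho(u) = exp((u - u_T)/T) / dt`` (temperature T and soft threshold u_T in
mV).  Fitting proceeds by replaying identical input into a passive,
threshold-free twin that is reset at every spike of the driven neuron;
histograms of the twin potential at armed times and at spike times give the
per-step firing probability p(spike|u), and a linear regression of
``log(-log(1 - p))`` on ``u`` below the probability peak yields 1/T and
-u_T/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import _kernels
from .background import AlphaScenario, BackgroundConfig, scenario_rates
from .lif_core import NeuronParams, SpikeRaster

__all__ = [
    "EscapeRateModel",
    "StimulusSpec",
    "FitResult",
    "make_stimulus",
    "escape_simulate",
    "fit_escape_model",
    "md_criterion",
    "evaluate_md",
]


@dataclass(frozen=True)
class EscapeRateModel:
    """Stochastic neuron: LIF membrane with exponential escape rate."""

    params: NeuronParams
    T: float  # mV
    u_T: float  # mV
    dt: float = 0.05  # ms

    def __post_init__(self):
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")

    def spike_probability(self, u) -> np.ndarray | float:
        """Per-step spike probability 1 - exp(-rho dt) with
        rho dt = exp((u - u_T)/T); saturates at 1 for large u."""
        rho_dt = np.exp(np.minimum((np.asarray(u, float) - self.u_T) / self.T, 30.0))
        out = -np.expm1(-rho_dt)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class StimulusSpec:
    """Poisson stimulus ensemble used for fitting: ``n_inputs`` sources at
    ``rate_hz`` each, a fraction ``frac_exc`` excitatory, weights drawn
    uniformly from [0, w_max] nS."""

    n_inputs: int = 100
    frac_exc: float = 0.8
    rate_hz: float = 5.0
    w_max: float = 30.0  # nS

    def n_exc(self) -> int:
        return int(round(self.frac_exc * self.n_inputs))


def make_stimulus(
    spec: StimulusSpec, duration: float, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step conductance increments (nS) of one stimulus realization.

    Returns ``(ge_jump, gi_jump)`` arrays of length duration/dt; replaying
    them reproduces the identical input spike trains.
    """
    n_steps = int(round(duration / dt))
    ge = np.zeros(n_steps)
    gi = np.zeros(n_steps)
    rate_khz = spec.rate_hz * 1e-3
    weights = rng.uniform(0.0, spec.w_max, size=spec.n_inputs)
    for j in range(spec.n_inputs):
        n_sp = rng.poisson(rate_khz * duration)
        steps = rng.integers(0, n_steps, size=n_sp)
        target = ge if j < spec.n_exc() else gi
        np.add.at(target, steps, weights[j])
    return ge, gi


@dataclass
class FitResult:
    """Escape-model fit with per-repeat dispersion and diagnostics."""

    T: float  # mV, mean over repeats
    u_T: float  # mV
    T_std: float
    u_T_std: float
    repeats: list = field(default_factory=list)  # (T, u_T) per repeat
    alpha: float | None = None
    scenario: str | None = None
    stimulus: StimulusSpec | None = None
    diagnostics: dict = field(default_factory=dict)

    def model(self, params: NeuronParams, dt: float = 0.05) -> EscapeRateModel:
        return EscapeRateModel(params=params, T=self.T, u_T=self.u_T, dt=dt)


def _run_single(
    params: NeuronParams,
    nu_exc_t: np.ndarray,
    nu_inh_t: np.ndarray,
    w_bg: tuple[float, float],
    ge_jump: np.ndarray,
    gi_jump: np.ndarray,
    dt: float,
    I_in_pA: float = 0.0,
    stochastic: bool = False,
    T: float = 1.0,
    u_T: float = 0.0,
    record_twin: bool = False,
    seed: int = 0,
):
    p = params
    n_steps = ge_jump.size
    ref_steps = int(round(p.tau_ref / dt))
    max_spikes = int(n_steps / max(ref_steps, 1)) + 64
    spikes, twin = _kernels.coba_single_twin(
        n_steps,
        dt,
        p.C_m,
        p.g_l,
        p.E_l,
        p.E_exc,
        p.E_inh,
        p.tau_exc,
        p.tau_inh,
        p.v_th,
        p.v_reset,
        ref_steps,
        I_in_pA,
        nu_exc_t,
        nu_inh_t,
        w_bg[0],
        w_bg[1],
        ge_jump,
        gi_jump,
        1 if stochastic else 0,
        T,
        u_T,
        record_twin,
        seed,
        max_spikes,
    )
    return spikes, twin


def escape_simulate(
    model: EscapeRateModel,
    background: BackgroundConfig,
    duration: float,
    seed: int = 0,
    ge_jump: np.ndarray | None = None,
    gi_jump: np.ndarray | None = None,
) -> SpikeRaster:
    """Simulate the stochastic neuron under background (plus an optional
    replayed stimulus) and return its spike raster."""
    dt = model.dt
    n_steps = int(round(duration / dt))
    nu_exc_t, nu_inh_t = background.rate_arrays(n_steps, dt)
    if ge_jump is None:
        ge_jump = np.zeros(n_steps)
    if gi_jump is None:
        gi_jump = np.zeros(n_steps)
    spikes, _ = _run_single(
        model.params,
        nu_exc_t,
        nu_inh_t,
        background.weights(),
        ge_jump,
        gi_jump,
        dt,
        stochastic=True,
        T=model.T,
        u_T=model.u_T,
        seed=seed,
    )
    return SpikeRaster(times=(spikes + 1) * dt, ids=np.zeros(spikes.size, np.int64),
                       duration=duration, dt=dt, n_neurons=1)


def _fit_from_histograms(
    u_twin: np.ndarray,
    spike_steps: np.ndarray,
    ref_steps: int,
    dt: float,
    bin_mv: float = 0.5,
    min_count: int = 10,
) -> tuple[float, float, dict]:
    """Histogram u at armed times and at spike times; regress the
    double-log link on u below the probability peak."""
    n_steps = u_twin.size
    armed = np.ones(n_steps, dtype=bool)
    for s in spike_steps:
        armed[s + 1 : s + 1 + ref_steps] = False  # refractory steps are unarmed
    u_armed = u_twin[armed]
    u_spk = u_twin[spike_steps]
    if u_spk.size == 0:
        raise RuntimeError("no spikes recorded; cannot fit the escape model")
    lo = np.floor(u_armed.min() / bin_mv) * bin_mv
    hi = np.ceil(u_armed.max() / bin_mv) * bin_mv
    edges = np.arange(lo, hi + bin_mv, bin_mv)
    h_all, _ = np.histogram(u_armed, bins=edges)
    h_spk, _ = np.histogram(u_spk, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(h_all > 0, h_spk / np.maximum(h_all, 1), 0.0)
    usable = (h_all >= min_count) & (p > 0) & (p < 1)
    if usable.sum() < 3:
        raise RuntimeError("insufficient histogram data for the escape fit")
    peak_u = centers[usable][np.argmax(p[usable])]
    sel = usable & (centers < peak_u)
    if sel.sum() < 3:
        sel = usable  # degenerate peak at the low end; use all usable bins
    y = np.log(-np.log1p(-p[sel]))
    slope, intercept = np.polyfit(centers[sel], y, 1)
    if slope <= 0:
        raise RuntimeError("non-positive regression slope; fit failed")
    T = 1.0 / slope
    u_T = -intercept * T
    diag = {
        "n_bins_used": int(sel.sum()),
        "peak_u": float(peak_u),
        "n_spikes": int(len(spike_steps)),
        "bin_mv": bin_mv,
    }
    return float(T), float(u_T), diag


def fit_escape_model(
    params: NeuronParams,
    scenario: AlphaScenario,
    alpha: float,
    stimulus: StimulusSpec | None = None,
    duration: float = 100_000.0,
    n_repeats: int = 10,
    dt: float = 0.05,
    seed: int = 0,
    w_inh_override: float | None = None,
) -> FitResult:
    """Fit the escape-rate model to a conductance-based LIF neuron.

    Protocol per repeat: (1) drive the deterministic LIF neuron with a
    fresh Poisson stimulus plus the scenario background and record spikes,
    simultaneously integrating the passive twin (identical input, reset at
    each LIF spike); (2) histogram the twin potential at armed times and at
    spike times; (3) regress the double-log link to obtain (T, u_T).
    Dispersion is reported over ``n_repeats`` independent repeats.
    """
    if stimulus is None:
        stimulus = StimulusSpec(w_max=scenario.w_stim_max)
    nu_exc, nu_inh = scenario_rates(scenario, alpha)
    n_steps = int(round(duration / dt))
    nu_exc_t = np.full(n_steps, nu_exc)
    nu_inh_t = np.full(n_steps, nu_inh)
    w_inh = scenario.w_inh if w_inh_override is None else w_inh_override
    ref_steps = int(round(params.tau_ref / dt))

    master = np.random.SeedSequence(seed)
    results = []
    rates = []
    for rep, child in enumerate(master.spawn(n_repeats)):
        rng = np.random.default_rng(child)
        ge, gi = make_stimulus(stimulus, duration, dt, rng)
        kseed = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        spikes, twin = _run_single(
            params, nu_exc_t, nu_inh_t, (scenario.w_exc, w_inh), ge, gi, dt,
            record_twin=True, seed=kseed,
        )
        rates.append(spikes.size / duration * 1e3)  # Hz
        T, u_T, diag = _fit_from_histograms(twin, spikes, ref_steps, dt)
        results.append((T, u_T))
    Ts = np.array([r[0] for r in results])
    uTs = np.array([r[1] for r in results])
    return FitResult(
        T=float(Ts.mean()),
        u_T=float(uTs.mean()),
        T_std=float(Ts.std(ddof=1)) if n_repeats > 1 else 0.0,
        u_T_std=float(uTs.std(ddof=1)) if n_repeats > 1 else 0.0,
        repeats=results,
        alpha=alpha,
        scenario=scenario.name,
        stimulus=stimulus,
        diagnostics={"stimulus_rate_hz": float(np.mean(rates))},
    )


def md_criterion(nu_lif: np.ndarray, nu_fit: np.ndarray) -> float:
    """Similarity of two firing-intensity traces on a common grid:

    M_d = 2 * int(nu_lif nu_fit) / (int(nu_lif^2) + int(nu_fit^2)),

    equal to 1 for identical traces and 0 for disjoint support.
    """
    a = np.asarray(nu_lif, dtype=float)
    b = np.asarray(nu_fit, dtype=float)
    if a.shape != b.shape:
        raise ValueError("intensity traces must share a grid")
    denom = float(np.sum(a**2) + np.sum(b**2))
    if denom == 0:
        raise ValueError("M_d undefined: both intensities are identically zero")
    return float(2.0 * np.sum(a * b) / denom)


def _psth(spike_steps_list, n_steps, dt, kernel_ms: float = 5.0) -> np.ndarray:
    """Trial-averaged firing intensity (kHz) with Gaussian smoothing."""
    counts = np.zeros(n_steps)
    for s in spike_steps_list:
        counts[s] += 1.0
    rate = counts / (len(spike_steps_list) * dt)
    return gaussian_filter1d(rate, sigma=kernel_ms / dt)


def evaluate_md(
    fit: FitResult,
    params: NeuronParams,
    scenario: AlphaScenario,
    alpha: float,
    n_trials: int = 100,
    trial_duration: float = 1_000.0,
    dt: float = 0.05,
    kernel_ms: float = 5.0,
    seed: int = 0,
    w_inh_override: float | None = None,
) -> float:
    """M_d between trial-averaged intensities of the LIF neuron and its
    fitted escape model on a fresh stimulus.

    One fresh stimulus realization is presented to ``n_trials``
    deterministic-LIF and ``n_trials`` stochastic trials (independent
    background per trial); intensities are estimated with a Gaussian kernel
    of width ``kernel_ms``.
    """
    stimulus = fit.stimulus or StimulusSpec(w_max=scenario.w_stim_max)
    nu_exc, nu_inh = scenario_rates(scenario, alpha)
    n_steps = int(round(trial_duration / dt))
    nu_exc_t = np.full(n_steps, nu_exc)
    nu_inh_t = np.full(n_steps, nu_inh)
    w_inh = scenario.w_inh if w_inh_override is None else w_inh_override
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    ge, gi = make_stimulus(stimulus, trial_duration, dt, rng)

    lif_trials = []
    esc_trials = []
    for k in range(n_trials):
        spikes, _ = _run_single(
            params, nu_exc_t, nu_inh_t, (scenario.w_exc, w_inh), ge, gi, dt,
            seed=100_000 + 2 * k + (seed & 0xFFFF) * 7919,
        )
        lif_trials.append(spikes)
        # the escape model replaces the background with its intrinsic
        # stochasticity: its membrane is driven by the stimulus alone
        spikes, _ = _run_single(
            params, np.zeros(n_steps), np.zeros(n_steps), (0.0, 0.0), ge, gi, dt,
            stochastic=True, T=fit.T, u_T=fit.u_T,
            seed=100_001 + 2 * k + (seed & 0xFFFF) * 7919,
        )
        esc_trials.append(spikes)
    nu_lif = _psth(lif_trials, n_steps, dt, kernel_ms)
    nu_fit = _psth(esc_trials, n_steps, dt, kernel_ms)
    return md_criterion(nu_lif, nu_fit)
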