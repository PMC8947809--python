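"""Preconfigured desk-scale task circuits.

Four experiments, each a thin composition of the simulator, the
calibration machinery and the readout metrics:

* ``run_entropy_demo`` — a 4-neuron current-based sampling network whose
  background oscillates along the balance line; the entropy of the sampled
  distribution tracks the exact entropy at the instantaneous temperature.
* ``run_wta_demo`` — a 4-neuron conductance-based winner-take-all circuit;
  raising the background scaling alpha flattens the mode distribution.
* ``run_disambiguation`` — a 27-neuron circuit (3 WTA groups x 3 assemblies
  x 3 neurons) that samples coherent interpretations of ambiguous input;
  oscillating background structures the computation into sampling episodes.
* ``run_flickering`` — a 2-assembly circuit reproducing place-cell
  flickering; the inhibitory/excitatory background conductance ratio sets
  the phase relation between network activity and the background rhythm.

All defaults are the reference task parameters; every field is overridable
through the config dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .background import (
    AlphaScenario,
    BackgroundConfig,
    BalanceLine,
    RateSchedule,
    temperature_from_rates,
)
from .boltzmann import (
    BoltzmannModel,
    dkl,
    entropy,
    exact_distribution,
    random_model,
)
from .calibration import CalibrationResult, boltzmann_to_lif
from .lif_core import Network, NeuronParams, Synapse, simulate
from .readout_metrics import (
    AssemblyActivity,
    detect_solutions,
    empirical_distribution,
    states_from_raster,
)

__all__ = [
    "EntropyDemoConfig",
    "WtaDemoConfig",
    "DisambiguationConfig",
    "FlickeringConfig",
    "run_entropy_demo",
    "run_wta_demo",
    "run_disambiguation",
    "scan_background_weight_ratio",
    "run_flickering",
    "build_disambiguation_network",
    "build_flickering_network",
]


def _spawn_kernel_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s & 0x7FFFFFFF) for s in ss.generate_state(n, np.uint32)]


# --------------------------------------------------------------------------
# entropy demo (current-based, exactly calibrated)
# --------------------------------------------------------------------------


@dataclass
class EntropyDemoConfig:
    """4-neuron sampling network under a balanced background oscillation."""

    K: int = 4
    nu_exc_min: float = 0.25  # kHz
    nu_exc_max: float = 10.0
    f_osc: float = 1.0  # Hz
    w_exc: float = 0.5  # nA
    w_inh: float = -0.5
    balance_line: BalanceLine = field(
        default_factory=lambda: BalanceLine(nu_0=-0.13, m=1.04, nu_exc_range=(0.1, 30))
    )
    reference_rates: tuple = (2.0, 2.0)  # kHz, defines T = 1
    n_cycles: int = 20
    n_phase_bins: int = 40
    readout_dt: float = 1.0  # ms
    dt: float = 0.1


def run_entropy_demo(
    config: EntropyDemoConfig,
    calib: CalibrationResult,
    params: NeuronParams,
    model: BoltzmannModel | None = None,
    seed: int = 0,
) -> dict:
    """Simulated versus calculated entropy over the oscillation cycle.

    The random Boltzmann model is translated into LIF weights/currents at
    the reference calibration; the background oscillates along the balance
    line so only the temperature changes.  Returns per-phase simulated
    entropy, the exact entropy at the instantaneous temperature, and the
    divergence to the T=1 target.
    """
    if model is None:
        model = random_model(config.K, seed=seed)
    w, I_in = boltzmann_to_lif(model, calib, params)
    synapses = [
        Synapse(pre=j, post=k, weight=w[k, j])
        for k in range(config.K)
        for j in range(config.K)
        if j != k and w[k, j] != 0.0
    ]
    schedule = RateSchedule(
        kind="sinusoid", nu_min=config.nu_exc_min, nu_max=config.nu_exc_max,
        f_osc=config.f_osc,
    )
    bg = BackgroundConfig.balanced(
        schedule, config.balance_line, config.w_exc, config.w_inh
    )
    net = Network(
        params=params, n_neurons=config.K, background=bg,
        synapses=synapses, I_in=I_in,
    )
    duration = config.n_cycles * 1e3 / config.f_osc
    kseed = _spawn_kernel_seeds(seed, 1)[0]
    run = simulate(net, duration=duration, dt=config.dt, seed=kseed)
    trace = states_from_raster(
        run.raster, kind="refractory", tau_ref=params.tau_ref,
        grid_dt=config.readout_dt,
    )

    # oscillation phase of every readout (0 = schedule minimum)
    phases = schedule.phase(trace.times)
    edges = np.linspace(0, 2 * np.pi, config.n_phase_bins + 1)
    idx = np.clip(np.digitize(phases, edges) - 1, 0, config.n_phase_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    target = exact_distribution(model)
    S_sim = np.full(config.n_phase_bins, np.nan)
    S_exact = np.empty(config.n_phase_bins)
    dkl_to_target = np.full(config.n_phase_bins, np.nan)
    T_at = np.empty(config.n_phase_bins)
    # schedule value at each phase-bin center: invert phase -> time in cycle
    period = 1e3 / config.f_osc
    t_of_phase = np.mod((centers - 0.5 * np.pi) / (2 * np.pi), 1.0) * period
    nu_exc_c = np.asarray(schedule(t_of_phase))
    nu_inh_c = np.clip(
        config.balance_line.nu_0 + config.balance_line.m * nu_exc_c, 0.0, None
    )
    for b in range(config.n_phase_bins):
        T_at[b] = temperature_from_rates(
            nu_exc_c[b], nu_inh_c[b], config.reference_rates
        )
        S_exact[b] = entropy(exact_distribution(model.at_temperature(T_at[b])), base=2)
        sel = idx == b
        if sel.sum() > 0:
            emp = empirical_distribution(trace, mask=sel)
            S_sim[b] = entropy(emp, base=2)
            # divergence of the phase-conditioned sample to the T=1 target
            # (the exact target is strictly positive, so this is finite)
            dkl_to_target[b] = dkl(emp, target)
    return {
        "phase": centers,
        "temperature": T_at,
        "entropy_sim_bits": S_sim,
        "entropy_exact_bits": S_exact,
        "dkl_to_target_nats": dkl_to_target,
        "model": model,
        "raster": run.raster,
    }


# --------------------------------------------------------------------------
# winner-take-all demo (conductance-based)
# --------------------------------------------------------------------------


@dataclass
class WtaDemoConfig:
    """4-neuron WTA circuit with lateral inhibition and bias currents."""

    bias_currents_pA: tuple = (40.0, 60.0, 80.0, 40.0)
    stim_rate_hz: float = 75.0
    w_inh_factor: float = 3.0  # lateral inhibition = factor * w_in
    duration: float = 100_000.0  # ms
    window_ms: float = 10.0
    readout_dt: float = 1.0
    dt: float = 0.05


def run_wta_demo(
    scenario: AlphaScenario,
    alphas,
    params: NeuronParams,
    config: WtaDemoConfig | None = None,
    seed: int = 0,
) -> dict:
    """Mode distribution and mode entropy of the WTA circuit per alpha.

    Each neuron receives its bias current, a stimulus spike train (Poisson
    at the stimulus rate, conductance ``w_stim_max``, shared across the
    four neurons so the bias currents decide the race), and the scenario
    background at the given alpha; lateral inhibitory connections enforce
    the winner-take-all competition.  The entropy (bits) is computed over
    the exclusive one-hot modes only.
    """
    config = config or WtaDemoConfig()
    K = 4
    w_in = scenario.w_stim_max
    synapses = [
        Synapse(pre=j, post=k, weight=config.w_inh_factor * w_in, channel="inh")
        for j in range(K)
        for k in range(K)
        if j != k
    ]
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    modes = (1 << np.arange(K)).astype(np.int64)  # one-hot states
    out = {"alphas": alphas, "entropy_bits": [], "mode_probs": []}
    seeds = _spawn_kernel_seeds(seed, alphas.size)
    for a, ks in zip(alphas, seeds):
        bg = BackgroundConfig.from_scenario(scenario, float(a))
        net = Network(
            params=params,
            n_neurons=K,
            background=bg,
            synapses=synapses,
            I_in=np.asarray(config.bias_currents_pA) / 1e3,
            nu_extra=config.stim_rate_hz * 1e-3,
            w_extra=w_in,
            share_extra=True,
        )
        run = simulate(net, duration=config.duration, dt=config.dt, seed=ks)
        trace = states_from_raster(
            run.raster, kind="window", window_ms=config.window_ms,
            grid_dt=config.readout_dt,
        )
        dist = empirical_distribution(trace, restrict_to=modes)
        out["mode_probs"].append(dist.p)
        out["entropy_bits"].append(entropy(dist, base=2))
    out["entropy_bits"] = np.asarray(out["entropy_bits"])
    out["mode_probs"] = np.asarray(out["mode_probs"])
    return out


# --------------------------------------------------------------------------
# stimulus disambiguation (3 x 3 x 3)
# --------------------------------------------------------------------------


@dataclass
class DisambiguationConfig:
    """27-neuron stimulus-disambiguation circuit.

    Groups represent sensory modalities; each holds three 3-neuron
    assemblies encoding mutually exclusive interpretations.  Within-
    assembly excitation, within-group lateral inhibition, and cross-group
    links between same-interpretation assemblies (through two designated
    neurons per assembly) define the attractor landscape.
    """

    n_groups: int = 3
    n_assemblies: int = 3
    n_per_assembly: int = 3
    w_within: float = 8.5  # nS, within assembly
    w_between: float = 17.0  # nS, cross-group assembly links
    w_lateral_inh: float = 17.0  # nS
    delay_exc: float = 2.0  # ms
    delay_inh: float = 0.1  # ms
    I_in_pA: float = 350.0
    bias_assemblies: tuple = ((0, 0), (1, 1), (2, 2))  # (group, assembly)
    bias_mode: str = "current"  # "current" (pA) or "conductance" (nS to E_exc)
    bias_value: float = 40.0
    bias_values: tuple | None = None  # per biased assembly, overrides bias_value
    scenario_name: str = "mu_unbalanced"
    w_bg_exc: float = 0.5  # nS
    w_bg_inh: float = 0.675  # nS (ratio 1.35)
    alpha_min: float = 0.5
    alpha_max: float = 5.0
    f_osc: float = 10.0  # Hz
    duration: float = 20_000.0  # ms per run
    n_runs: int = 3
    window_ms: float = 10.0
    readout_dt: float = 1.0
    dt: float = 0.05

    def neuron_id(self, g: int, a: int, m: int) -> int:
        per_group = self.n_assemblies * self.n_per_assembly
        return g * per_group + a * self.n_per_assembly + m

    def assembly_members(self) -> list[np.ndarray]:
        """Assemblies in (group-major) order: index g * n_assemblies + a."""
        out = []
        for g in range(self.n_groups):
            for a in range(self.n_assemblies):
                out.append(
                    np.array(
                        [self.neuron_id(g, a, m) for m in range(self.n_per_assembly)]
                    )
                )
        return out

    def solution_linkage(self) -> list[list[int]]:
        """Solution n links assembly n of every group."""
        return [
            [g * self.n_assemblies + n for g in range(self.n_groups)]
            for n in range(self.n_assemblies)
        ]


def build_disambiguation_network(
    config: DisambiguationConfig, alpha_schedule: "RateSchedule | float" = None
) -> Network:
    cfg = config
    n = cfg.n_groups * cfg.n_assemblies * cfg.n_per_assembly
    syns: list[Synapse] = []
    # within-assembly excitation: all ordered pairs
    for g in range(cfg.n_groups):
        for a in range(cfg.n_assemblies):
            ids = [cfg.neuron_id(g, a, m) for m in range(cfg.n_per_assembly)]
            for i in ids:
                for j in ids:
                    if i != j:
                        syns.append(
                            Synapse(pre=i, post=j, weight=cfg.w_within,
                                    channel="exc", delay=cfg.delay_exc)
                        )
    # within-group lateral inhibition: all neuron pairs across assemblies
    for g in range(cfg.n_groups):
        for a in range(cfg.n_assemblies):
            for b in range(cfg.n_assemblies):
                if a == b:
                    continue
                for i in range(cfg.n_per_assembly):
                    for j in range(cfg.n_per_assembly):
                        syns.append(
                            Synapse(
                                pre=cfg.neuron_id(g, a, i),
                                post=cfg.neuron_id(g, b, j),
                                weight=cfg.w_lateral_inh,
                                channel="inh",
                                delay=cfg.delay_inh,
                            )
                        )
    # cross-group links between same-interpretation assemblies: each
    # assembly dedicates neuron 0 to the next group and neuron 1 to the
    # previous group; links are bidirectional
    for a in range(cfg.n_assemblies):
        for g in range(cfg.n_groups):
            g_next = (g + 1) % cfg.n_groups
            i = cfg.neuron_id(g, a, 0)
            j = cfg.neuron_id(g_next, a, 1)
            for pre, post in ((i, j), (j, i)):
                syns.append(
                    Synapse(pre=pre, post=post, weight=cfg.w_between,
                            channel="exc", delay=cfg.delay_exc)
                )

    scenario = AlphaScenario.from_preset(cfg.scenario_name)
    scenario = replace(scenario, w_exc=cfg.w_bg_exc)
    if alpha_schedule is None:
        alpha_schedule = RateSchedule(
            kind="sinusoid", nu_min=cfg.alpha_min, nu_max=cfg.alpha_max,
            f_osc=cfg.f_osc,
        )
    bg = BackgroundConfig.from_scenario(scenario, alpha_schedule, w_inh=cfg.w_bg_inh)

    g_bias = np.zeros(n)
    I_in = np.full(n, cfg.I_in_pA / 1e3)  # nA
    bias_values = cfg.bias_values or (cfg.bias_value,) * len(cfg.bias_assemblies)
    for (g, a), val in zip(cfg.bias_assemblies, bias_values):
        for m in range(cfg.n_per_assembly):
            k = cfg.neuron_id(g, a, m)
            if cfg.bias_mode == "conductance":
                g_bias[k] += val
            elif cfg.bias_mode == "current":
                I_in[k] += val / 1e3
            else:
                raise ValueError(f"unknown bias_mode {cfg.bias_mode!r}")
    params = NeuronParams.from_preset("coba")
    return Network(
        params=params, n_neurons=n, background=bg, synapses=syns,
        I_in=I_in, g_bias_exc=g_bias,
    )


def run_disambiguation(
    config: DisambiguationConfig | None = None,
    seed: int = 0,
    alpha_constant: float | None = None,
) -> dict:
    """Run the disambiguation circuit and collect sampling statistics.

    With ``alpha_constant`` the background is held at that scaling instead
    of oscillating.  Returns mean firing rate, solution probability by
    background phase, visitation frequencies, time-to-all-solutions and
    switching times over ``config.n_runs`` independent runs.
    """
    cfg = config or DisambiguationConfig()
    if alpha_constant is not None:
        sched: RateSchedule | float = float(alpha_constant)
    else:
        sched = RateSchedule(kind="sinusoid", nu_min=cfg.alpha_min,
                             nu_max=cfg.alpha_max, f_osc=cfg.f_osc)
    net = build_disambiguation_network(cfg, alpha_schedule=sched)
    members = cfg.assembly_members()
    linkage = cfg.solution_linkage()
    n_bins = 20
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)

    rates = []
    labels_all = []
    phase_counts = np.zeros(n_bins)
    phase_solution = np.zeros(n_bins)
    visits = np.zeros(cfg.n_assemblies)
    t_all_solutions = []
    switching = []
    discarded = 0
    for ks in _spawn_kernel_seeds(seed, cfg.n_runs):
        run = simulate(net, duration=cfg.duration, dt=cfg.dt, seed=ks)
        rates.append(float(run.raster.rates().mean() * 1e3))  # Hz
        act = AssemblyActivity.from_raster(
            run.raster, members, window_ms=cfg.window_ms, grid_dt=cfg.readout_dt
        )
        labels = detect_solutions(act, linkage)
        labels_all.append(labels)
        if alpha_constant is None and isinstance(sched, RateSchedule):
            ph = sched.phase(act.times)
            idx = np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1)
            np.add.at(phase_counts, idx, 1.0)
            np.add.at(phase_solution, idx, (labels >= 0).astype(float))
        for nsol in range(cfg.n_assemblies):
            visits[nsol] += float((labels == nsol).sum())
        # time until every solution was visited at least once
        seen = set()
        t_all = None
        for t_i, lab in zip(act.times, labels):
            if lab >= 0:
                seen.add(int(lab))
                if len(seen) == cfg.n_assemblies:
                    t_all = t_i
                    break
        if t_all is None:
            discarded += 1
        else:
            t_all_solutions.append(t_all)
        # switching times between distinct-solution onsets
        onsets = [
            (t_i, lab)
            for t_i, lab, prev in zip(act.times[1:], labels[1:], labels[:-1])
            if lab >= 0 and lab != prev
        ]
        last_t, last_lab = None, None
        for t_i, lab in onsets:
            if last_lab is not None and lab != last_lab:
                switching.append(t_i - last_t)
            last_t, last_lab = t_i, lab

    total_labeled = visits.sum()
    with np.errstate(invalid="ignore"):
        p_solution_by_phase = np.where(
            phase_counts > 0, phase_solution / np.maximum(phase_counts, 1), np.nan
        )
    return {
        "mean_rate_hz": float(np.mean(rates)),
        "rates_hz": np.asarray(rates),
        "p_solution": float(np.mean([np.mean(l >= 0) for l in labels_all])),
        "phase_bins": 0.5 * (edges[:-1] + edges[1:]),
        "p_solution_by_phase": p_solution_by_phase,
        "visitation": visits / total_labeled if total_labeled else visits,
        "time_to_all_solutions_ms": np.asarray(t_all_solutions),
        "switching_times_ms": np.asarray(switching),
        "n_discarded": discarded,
        "labels": labels_all,
    }


def scan_background_weight_ratio(
    ratios,
    config: DisambiguationConfig | None = None,
    seed: int = 0,
    n_runs: int = 2,
    duration: float = 10_000.0,
    alpha_levels: tuple = (0.5, 2.5, 5.0),
) -> dict:
    """Background-weight tuning of the disambiguation circuit.

    For each inhibitory-to-excitatory background weight ratio the network
    is run at constant background scalings ``alpha_levels``; the reported
    quantity is the *relative* variance (squared coefficient of
    variation) of the mean firing rate across the levels.  At the
    minimizing ratio the background's excitatory and inhibitory effects on
    the operating point cancel, so the activity level is insensitive to
    the background intensity — the regime in which oscillating and
    constant background can be compared fairly.  The relative measure is
    essential: strong inhibition silences the network at every level,
    which trivially minimizes the absolute variance but maximizes the
    relative one.

    Returns the scanned ratios, relative variances, per-level mean rates,
    and the minimizing grid ratio.
    """
    cfg = config or DisambiguationConfig()
    ratios = np.asarray(ratios, dtype=float)
    levels = tuple(alpha_levels)
    variances = np.empty(ratios.size)
    level_rates = np.empty((ratios.size, len(levels)))
    seeds = _spawn_kernel_seeds(seed, ratios.size * len(levels) * n_runs)
    s = 0
    for i, r in enumerate(ratios):
        c = replace(cfg, w_bg_inh=r * cfg.w_bg_exc, duration=duration)
        for j, a in enumerate(levels):
            net = build_disambiguation_network(c, alpha_schedule=float(a))
            rr = []
            for _ in range(n_runs):
                run = simulate(net, duration=duration, dt=cfg.dt, seed=seeds[s])
                s += 1
                rr.append(float(run.raster.rates().mean() * 1e3))  # Hz
            level_rates[i, j] = np.mean(rr)
        mean_rate = level_rates[i].mean()
        variances[i] = float(
            level_rates[i].var() / max(mean_rate, 1e-9) ** 2
        )
    i_min = int(np.argmin(variances))
    best = ratios[i_min]
    return {
        "ratios": ratios,
        "variances": variances,
        "level_rates_hz": level_rates,
        "alpha_levels": levels,
        "best_ratio": float(best),
    }


# --------------------------------------------------------------------------
# flickering (2 assemblies, theta-band background)
# --------------------------------------------------------------------------


@dataclass
class FlickeringConfig:
    """Two-assembly place-cell flickering circuit."""

    n_per_assembly: int = 20
    p_rec: float = 0.1  # within-assembly connection probability
    w_rec: float = 2.5  # nS
    p_inh: float = 0.5  # across-assembly connection probability
    w_inh: float = 5.0  # nS
    delay_rec: tuple = (1.0, 3.0)  # ms, uniform range
    delay_inh: float = 0.1
    bias_pA: float = 10.0  # to assembly 1
    f_osc: float = 8.0  # Hz
    alpha_min: float = 0.5
    alpha_max: float = 5.0
    scenario_name: str = "mu_unbalanced"
    w_bg_exc: float = 0.5  # nS
    # injected current interpolated over the conductance ratio:
    I_at_ratio: tuple = ((0.75, 40.0), (3.0, 880.0))  # (g-ratio, pA)
    duration: float = 20_000.0
    n_runs: int = 5
    window_ms: float = 10.0
    readout_dt: float = 1.0
    mixed_threshold: float = 0.2
    dt: float = 0.05


def _interp_current(cfg: FlickeringConfig, g_ratio: float) -> float:
    (r0, i0), (r1, i1) = cfg.I_at_ratio
    return float(np.interp(g_ratio, [r0, r1], [i0, i1]))


def build_flickering_network(
    config: FlickeringConfig, g_ratio: float, wiring_seed: int = 0
) -> Network:
    """Flickering circuit at mean background conductance ratio ``g_ratio``.

    The background weight ratio follows from the scenario's rate and time
    constants: with equal rates, E[g_inh/g_exc] = (w_inh tau_inh) /
    (w_exc tau_exc), so w_inh = g_ratio * w_exc * tau_exc / tau_inh.
    Random wiring is drawn per ordered neuron pair from ``wiring_seed``.
    """
    cfg = config
    params = NeuronParams.from_preset("coba")
    n = 2 * cfg.n_per_assembly
    rng = np.random.default_rng(wiring_seed)
    syns: list[Synapse] = []
    assemblies = [np.arange(cfg.n_per_assembly),
                  np.arange(cfg.n_per_assembly, n)]
    for members in assemblies:
        for i in members:
            for j in members:
                if i != j and rng.random() < cfg.p_rec:
                    delay = np.round(
                        rng.uniform(*cfg.delay_rec) / cfg.dt
                    ) * cfg.dt
                    syns.append(Synapse(pre=int(i), post=int(j), weight=cfg.w_rec,
                                        channel="exc", delay=float(delay)))
    for i in assemblies[0]:
        for j in assemblies[1]:
            for pre, post in ((int(i), int(j)), (int(j), int(i))):
                if rng.random() < cfg.p_inh:
                    syns.append(Synapse(pre=pre, post=post, weight=cfg.w_inh,
                                        channel="inh", delay=cfg.delay_inh))
    scenario = AlphaScenario.from_preset(cfg.scenario_name)
    scenario = replace(scenario, w_exc=cfg.w_bg_exc)
    w_bg_inh = g_ratio * cfg.w_bg_exc * params.tau_exc / params.tau_inh
    sched = RateSchedule(kind="sinusoid", nu_min=cfg.alpha_min,
                         nu_max=cfg.alpha_max, f_osc=cfg.f_osc)
    bg = BackgroundConfig.from_scenario(scenario, sched, w_inh=w_bg_inh)
    I_in = np.full(n, _interp_current(cfg, g_ratio) / 1e3)
    I_in[assemblies[0]] += cfg.bias_pA / 1e3
    return Network(params=params, n_neurons=n, background=bg, synapses=syns,
                   I_in=I_in)


def _phase_rate_profile(raster, schedule, n_bins=24, smooth_bins=2):
    """Mean firing rate (Hz per neuron) by background phase."""
    ph = schedule.phase(raster.times)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram(ph, bins=edges)
    # observation time per bin is uniform for integer cycle counts
    t_per_bin = raster.duration / n_bins
    rate = counts / (t_per_bin * raster.n_neurons) * 1e3
    if smooth_bins:
        rate = gaussian_filter1d(rate, smooth_bins, mode="wrap")
    return 0.5 * (edges[:-1] + edges[1:]), rate


def run_flickering(
    ratios,
    config: FlickeringConfig | None = None,
    seed: int = 0,
) -> dict:
    """Scan the mean background conductance ratio.

    For each ratio the circuit is simulated for ``n_runs`` independent
    runs; reported are the rate-versus-background-phase profile, the phase
    of the rate minimum, the half-cycle mixed-state probabilities (phase
    re-anchored to the network rate minimum), and the interpolated ratio at
    which the activity/background phase relation flips (where the rate
    contrast between the high- and low-background half-cycle changes sign).
    """
    cfg = config or FlickeringConfig()
    ratios = np.asarray(ratios, dtype=float)
    sched = RateSchedule(kind="sinusoid", nu_min=cfg.alpha_min,
                         nu_max=cfg.alpha_max, f_osc=cfg.f_osc)
    n_bins = 24
    contrasts = np.empty(ratios.size)
    phase_min = np.empty(ratios.size)
    p_first = np.empty(ratios.size)
    p_second = np.empty(ratios.size)
    profiles = []
    seeds = _spawn_kernel_seeds(seed, ratios.size * cfg.n_runs)
    for i, r in enumerate(ratios):
        net = build_flickering_network(cfg, float(r), wiring_seed=seed + 17 * i)
        rate_sum = np.zeros(n_bins)
        mixed_flags = []
        phases_net = []
        for k in range(cfg.n_runs):
            run = simulate(net, duration=cfg.duration, dt=cfg.dt,
                           seed=seeds[i * cfg.n_runs + k])
            centers, rate = _phase_rate_profile(run.raster, sched, n_bins)
            rate_sum += rate
            act = AssemblyActivity.from_raster(
                run.raster,
                [np.arange(cfg.n_per_assembly),
                 np.arange(cfg.n_per_assembly, 2 * cfg.n_per_assembly)],
                window_ms=cfg.window_ms, grid_dt=cfg.readout_dt,
            )
            mixed_flags.append((act.fractions > cfg.mixed_threshold).all(axis=1))
            phases_net.append(sched.phase(act.times))
        profile = rate_sum / cfg.n_runs
        profiles.append(profile)
        # phase of the rate minimum relative to the background (0 = bg min)
        phase_min[i] = centers[int(np.argmin(profile))]
        # contrast: high-background half (phase around pi) minus low half
        high = (centers > 0.5 * np.pi) & (centers < 1.5 * np.pi)
        contrasts[i] = float(profile[high].mean() - profile[~high].mean())
        # re-anchor phase zero to the network rate minimum, then compare
        # mixed probability between the two half-cycles
        mixed = np.concatenate(mixed_flags)
        ph = np.mod(np.concatenate(phases_net) - phase_min[i], 2 * np.pi)
        p_first[i] = float(mixed[ph < np.pi].mean())
        p_second[i] = float(mixed[ph >= np.pi].mean())
    transition = np.nan
    for i in range(ratios.size - 1):
        if contrasts[i] > 0 >= contrasts[i + 1]:
            transition = float(
                np.interp(0.0, [contrasts[i + 1], contrasts[i]],
                          [ratios[i + 1], ratios[i]])
            )
            break
    return {
        "ratios": ratios,
        "contrast": contrasts,
        "phase_of_rate_min": phase_min,
        "transition_ratio": transition,
        "p_mixed_first_half": p_first,
        "p_mixed_second_half": p_second,
        "rate_profiles": np.asarray(profiles),
        "phase_bins": np.linspace(0, 2 * np.pi, n_bins + 1)[:-1]
        + np.pi / n_bins,
    }
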