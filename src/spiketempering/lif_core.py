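"""Clock-driven simulation of current- and conductance-based LIF networks.

The simulator integrates networks of leaky integrate-and-fire neurons with
exponential synapses, per-neuron Poisson background input (one aggregate
excitatory and one aggregate inhibitory source per neuron, drawn
independently across neurons), constant injected currents and transmission
delays.  Synaptic state variables are advanced with exact exponential
updates; the current-based membrane equation is solved exactly per step and
the conductance-based one with exponential Euler, which is unconditionally
stable.

User-facing units: mV, ms, kHz, nA (currents and current-based weights),
nS (conductances).  Internally everything runs in mV/pA/nS/pF/ms/kHz.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import yaml

from . import _kernels
from .background import BackgroundConfig

__all__ = [
    "NeuronParams",
    "Synapse",
    "SpikeRaster",
    "NetworkRun",
    "Network",
    "simulate",
    "free_membrane_moments_cuba",
    "free_membrane_moments_coba",
]

NA_TO_PA = 1000.0


def _load_yaml_resource(name: str) -> dict:
    text = resources.files("spiketempering").joinpath("data", name).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class NeuronParams:
    """Physical constants of a LIF neuron.

    Parameters
    ----------
    C_m : membrane capacitance (pF)
    g_l : leak conductance (nS)
    E_l : leak potential (mV)
    v_th : firing threshold (mV)
    v_reset : reset potential (mV)
    tau_ref : refractory period (ms)
    synapse_kind : ``"current"`` or ``"conductance"``
    tau_s : synaptic time constant (ms), current-based kind
    E_exc, E_inh : reversal potentials (mV), conductance-based kind
    tau_exc, tau_inh : synaptic time constants (ms), conductance-based kind
    """

    C_m: float
    g_l: float
    E_l: float
    v_th: float
    v_reset: float
    tau_ref: float
    synapse_kind: Literal["current", "conductance"]
    tau_s: float | None = None
    E_exc: float | None = None
    E_inh: float | None = None
    tau_exc: float | None = None
    tau_inh: float | None = None

    def __post_init__(self):
        if self.C_m <= 0 or self.g_l <= 0:
            raise ValueError("C_m and g_l must be positive")
        if self.v_reset > self.v_th:
            raise ValueError("v_reset must not exceed v_th")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.synapse_kind == "current":
            if self.tau_s is None or self.tau_s <= 0:
                raise ValueError("current-based neurons need tau_s > 0")
        elif self.synapse_kind == "conductance":
            for name in ("E_exc", "E_inh", "tau_exc", "tau_inh"):
                if getattr(self, name) is None:
                    raise ValueError(f"conductance-based neurons need {name}")
            if self.tau_exc <= 0 or self.tau_inh <= 0:
                raise ValueError("synaptic time constants must be positive")
            if self.E_inh >= self.E_exc:
                raise ValueError("E_inh must lie below E_exc")
        else:
            raise ValueError(f"unknown synapse_kind {self.synapse_kind!r}")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_l (ms)."""
        return self.C_m / self.g_l

    @classmethod
    def from_preset(cls, name: str) -> "NeuronParams":
        """Load a named parameter set (``"cuba"`` or ``"coba"``)."""
        presets = _load_yaml_resource("neuron_presets.yaml")
        if name not in presets:
            raise KeyError(f"no neuron preset {name!r}; have {sorted(presets)}")
        return cls(**presets[name])


@dataclass(frozen=True)
class Synapse:
    """A single recurrent connection.

    ``weight`` is a current increment in nA (current-based postsynaptic
    neuron; its sign selects the channel) or a conductance increment in nS
    (conductance-based; must be non-negative, ``channel`` selects the
    reversal potential).  ``delay`` is in ms and must be a multiple of the
    simulation step.
    """

    pre: int
    post: int
    weight: float
    channel: Literal["exc", "inh"] = "exc"
    delay: float = 0.0

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass
class SpikeRaster:
    """Timed spike events of a network run."""

    times: np.ndarray  # ms
    ids: np.ndarray
    duration: float  # ms
    dt: float  # ms
    n_neurons: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def counts(self) -> np.ndarray:
        return np.bincount(self.ids, minlength=self.n_neurons)

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron in kHz (spikes per ms)."""
        return self.counts() / self.duration

    def population_rate(self, bin_ms: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
        """Population rate per neuron (kHz) in bins of ``bin_ms``."""
        edges = np.arange(0.0, self.duration + bin_ms, bin_ms)
        counts, _ = np.histogram(self.times, bins=edges)
        rate = counts / (bin_ms * self.n_neurons)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, rate

    def validate(self, tau_ref: float | None = None) -> None:
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")
        if np.any(np.diff(self.times) < -1e-9):
            raise ValueError("spike times must be non-decreasing")
        if tau_ref is not None:
            for k in range(self.n_neurons):
                st = self.spike_times(k)
                if st.size > 1 and np.any(np.diff(st) < tau_ref - 1e-9):
                    raise ValueError(f"neuron {k} violates the refractory period")
        if self.ids.size and self.ids.max() >= self.n_neurons:
            raise ValueError("neuron id out of range")

    def to_tsv(self, path) -> None:
        header = (
            f"# duration_ms={self.duration} dt_ms={self.dt} "
            f"n_neurons={self.n_neurons}\ntime_ms\tneuron_id\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for t, i in zip(self.times, self.ids):
                fh.write(f"{t:.6g}\t{i}\n")

    @classmethod
    def from_tsv(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            meta_line = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in meta_line)
            body = fh.read()
        arr = np.loadtxt(io.StringIO(body), skiprows=1, ndmin=2)
        times = arr[:, 0] if arr.size else np.empty(0)
        ids = arr[:, 1].astype(np.int64) if arr.size else np.empty(0, dtype=np.int64)
        return cls(
            times=times,
            ids=ids,
            duration=float(meta["duration_ms"]),
            dt=float(meta["dt_ms"]),
            n_neurons=int(meta["n_neurons"]),
        )


@dataclass
class NetworkRun:
    """Result of one simulation: raster plus optional traces."""

    raster: SpikeRaster
    u: np.ndarray | None = None  # (n_steps, n) mV
    g_exc: np.ndarray | None = None  # (n_steps, n) nS
    g_inh: np.ndarray | None = None
    rng_seed: int = 0


@dataclass
class Network:
    """A homogeneous LIF network specification.

    All neurons share ``params``; per-neuron heterogeneity enters through
    injected currents ``I_in`` (nA), leak-potential shifts ``E_l_shift``
    (mV), constant excitatory conductance offsets ``g_bias_exc`` (nS,
    conductance-based only) and an optional per-neuron constant-rate
    Poisson drive on the excitatory channel (``nu_extra`` in kHz,
    ``w_extra`` in the weight unit of the synapse kind).
    """

    params: NeuronParams
    n_neurons: int
    background: BackgroundConfig
    synapses: Sequence[Synapse] = field(default_factory=list)
    I_in: np.ndarray | float = 0.0  # nA
    E_l_shift: np.ndarray | float = 0.0  # mV
    g_bias_exc: np.ndarray | float = 0.0  # nS
    nu_extra: np.ndarray | float = 0.0  # kHz
    w_extra: np.ndarray | float = 0.0
    share_extra: bool = False  # one spike train drives all neurons

    def _per_neuron(self, value) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=float), (self.n_neurons,)).copy()


def _csr_synapses(network: Network, dt: float):
    n = network.n_neurons
    syns = sorted(network.synapses, key=lambda s: s.pre)
    ptr = np.zeros(n + 1, dtype=np.int64)
    post = np.empty(len(syns), dtype=np.int64)
    w = np.empty(len(syns))
    is_inh = np.zeros(len(syns), dtype=np.int64)
    delay = np.empty(len(syns), dtype=np.int64)
    for j, s in enumerate(syns):
        if not (0 <= s.pre < n and 0 <= s.post < n):
            raise ValueError("synapse endpoint out of range")
        steps = s.delay / dt
        if abs(steps - round(steps)) > 1e-6:
            raise ValueError(f"delay {s.delay} ms is not a multiple of dt={dt} ms")
        delay[j] = round(steps)
        post[j] = s.post
        if network.params.synapse_kind == "current":
            w[j] = s.weight * NA_TO_PA
        else:
            if s.weight < 0:
                raise ValueError("conductance-based weights must be non-negative")
            w[j] = s.weight
            is_inh[j] = 1 if s.channel == "inh" else 0
        ptr[s.pre + 1] += 1
    ptr = np.cumsum(ptr)
    return ptr, post, w, is_inh, delay


def simulate(
    network: Network,
    duration: float,
    dt: float | None = None,
    seed: int = 0,
    record_u: bool = False,
    record_g: bool = False,
    u0: np.ndarray | None = None,
) -> NetworkRun:
    """Run a clock-driven simulation for ``duration`` ms.

    Identical ``(network, duration, dt, seed)`` produce bit-identical
    output.  ``dt`` defaults to 0.1 ms for current-based and 0.05 ms for
    conductance-based networks.
    """
    p = network.params
    if dt is None:
        dt = 0.1 if p.synapse_kind == "current" else 0.05
    if dt <= 0:
        raise ValueError("dt must be positive")
    # the membrane update is exact (current-based) or unconditionally
    # stable (exponential Euler), so the resolution constraint comes from
    # the synaptic kinetics and refractory quantization, not tau_m
    taus = (
        [p.tau_s] if p.synapse_kind == "current" else [p.tau_exc, p.tau_inh]
    )
    if p.tau_ref > 0:
        taus = taus + [p.tau_ref]
    if dt > min(taus) / 5:
        warnings.warn(
            f"dt={dt} ms is coarse relative to the smallest synaptic or "
            "refractory time constant",
            stacklevel=2,
        )
    n = network.n_neurons
    n_steps = int(round(duration / dt))
    ref_steps = int(round(p.tau_ref / dt))

    nu_exc_t, nu_inh_t = network.background.rate_arrays(n_steps, dt)
    w_bg_exc, w_bg_inh = network.background.weights()

    I_in = network._per_neuron(network.I_in) * NA_TO_PA
    E_l = network._per_neuron(p.E_l + np.asarray(network.E_l_shift, dtype=float))
    u_init = E_l.copy() if u0 is None else np.asarray(u0, dtype=float).copy()

    ptr, post, w, is_inh, delay = _csr_synapses(network, dt)

    per_ref = max(ref_steps, 1)
    max_spikes = int(n * (n_steps / per_ref + 16))

    if p.synapse_kind == "current":
        status, steps, ids, u_out = _kernels.cuba_net(
            n_steps,
            dt,
            np.full(n, p.tau_m),
            np.full(n, p.tau_s),
            np.full(n, p.g_l),
            E_l,
            np.full(n, p.v_th),
            np.full(n, p.v_reset),
            np.full(n, ref_steps, dtype=np.int64),
            I_in,
            nu_exc_t,
            nu_inh_t,
            np.full(n, w_bg_exc * NA_TO_PA),
            np.full(n, w_bg_inh * NA_TO_PA),
            ptr,
            post,
            w,
            delay,
            u_init,
            record_u,
            seed,
            max_spikes,
        )
        ge_out = gi_out = np.empty((0, n))
    else:
        status, steps, ids, u_out, ge_out, gi_out = _kernels.coba_net(
            n_steps,
            dt,
            np.full(n, p.C_m),
            np.full(n, p.g_l),
            E_l,
            np.full(n, p.E_exc),
            np.full(n, p.E_inh),
            np.full(n, p.tau_exc),
            np.full(n, p.tau_inh),
            np.full(n, p.v_th),
            np.full(n, p.v_reset),
            np.full(n, ref_steps, dtype=np.int64),
            I_in,
            network._per_neuron(network.g_bias_exc),
            nu_exc_t,
            nu_inh_t,
            np.full(n, w_bg_exc),
            np.full(n, w_bg_inh),
            network._per_neuron(network.nu_extra),
            network._per_neuron(network.w_extra),
            1 if network.share_extra else 0,
            ptr,
            post,
            w,
            is_inh,
            delay,
            u_init,
            record_u,
            record_g,
            seed,
            max_spikes,
        )
    if status == _kernels.NONFINITE:
        raise FloatingPointError(
            "non-finite membrane potential; check weights, rates and dt"
        )
    raster = SpikeRaster(
        times=(steps + 1) * dt, ids=ids, duration=duration, dt=dt, n_neurons=n
    )
    return NetworkRun(
        raster=raster,
        u=u_out if record_u else None,
        g_exc=ge_out if record_g else None,
        g_inh=gi_out if record_g else None,
        rng_seed=seed,
    )


def free_membrane_moments_cuba(
    params: NeuronParams, background: BackgroundConfig, I_in: float = 0.0
) -> tuple[float, float]:
    """Gaussian moments of the free (threshold-less) membrane potential.

    For a current-based neuron under constant Poisson background the
    stationary distribution of the free membrane potential is Gaussian with

    .. math::
        \\mu_u = E_l + (I_{in} + \\sum_i w_i \\nu_i \\tau_s) / g_l,
        \\qquad
        \\sigma_u^2 = \\sum_i \\nu_i w_i^2 \\tau_s^2 /
                       (2 g_l^2 (\\tau_m + \\tau_s)).

    Returns ``(mu_u [mV], sigma2_u [mV^2])``; ``I_in`` in nA.
    """
    if params.synapse_kind != "current":
        raise ValueError("free_membrane_moments_cuba needs a current-based neuron")
    nu_exc, nu_inh = background.constant_rates()
    w_exc, w_inh = background.weights()  # nA, w_inh < 0
    tau_s, tau_m, g_l = params.tau_s, params.tau_m, params.g_l
    mean_pA = I_in * NA_TO_PA + (
        w_exc * nu_exc * tau_s + w_inh * nu_inh * tau_s
    ) * NA_TO_PA
    mu = params.E_l + mean_pA / g_l
    sigma2 = 0.0
    for nu, w in ((nu_exc, w_exc), (nu_inh, w_inh)):
        w_pA = w * NA_TO_PA
        sigma2 += nu * w_pA**2 * tau_s**2 / (2 * g_l**2 * (tau_m + tau_s))
    return mu, sigma2


def free_membrane_moments_coba(
    params: NeuronParams, background: BackgroundConfig
) -> tuple[float, float, float]:
    """Free-membrane moments and effective time constant, conductance-based.

    Mean total conductance shortens the membrane time constant to

    .. math:: \\tau_{eff} = C_m / (g_l + \\sum_x w_x \\nu_x \\tau_x),

    and the stationary free membrane potential is Gaussian with the
    conductance-weighted mean and the shot-noise variance

    .. math::
        \\sigma_u^2 = \\sum_x \\frac{\\nu_x w_x^2 (E_x - \\mu_u)^2}
        {2 (\\tau_{eff} + \\tau_x)}
        \\left(\\frac{\\tau_{eff} \\tau_x}{C_m}\\right)^2 .

    Returns ``(mu_u [mV], sigma2_u [mV^2], tau_eff [ms])``.
    """
    p = params
    if p.synapse_kind != "conductance":
        raise ValueError("free_membrane_moments_coba needs a conductance-based neuron")
    nu_exc, nu_inh = background.constant_rates()
    w_exc, w_inh = background.weights()  # nS, both >= 0
    if nu_exc < 0 or nu_inh < 0 or w_exc < 0 or w_inh < 0:
        raise ValueError("rates and conductance weights must be non-negative")
    ge = w_exc * nu_exc * p.tau_exc
    gi = w_inh * nu_inh * p.tau_inh
    g_tot = p.g_l + ge + gi
    tau_eff = p.C_m / g_tot
    mu = (p.g_l * p.E_l + ge * p.E_exc + gi * p.E_inh) / g_tot
    sigma2 = 0.0
    for nu, w, E, tau in (
        (nu_exc, w_exc, p.E_exc, p.tau_exc),
        (nu_inh, w_inh, p.E_inh, p.tau_inh),
    ):
        sigma2 += (
            nu
            * w**2
            * (E - mu) ** 2
            / (2 * (tau_eff + tau))
            * (tau_eff * tau / p.C_m) ** 2
        )
    return mu, sigma2, tau_eff
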