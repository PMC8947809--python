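"""Binary state readout from spike rasters and sampling-quality metrics.

A spiking neuron encodes a binary random variable: its state is 1 while it
is refractory (refractory readout) or if it spiked within a trailing
window (windowed readout).  The resulting state traces feed empirical
distributions, mode-duration statistics, the indirect sampling likelihood
(ISL), autocorrelation summaries, and the assembly-level detectors used by
the task circuits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .boltzmann import DiscreteDistribution
from .lif_core import SpikeRaster

__all__ = [
    "StateTrace",
    "AssemblyActivity",
    "states_from_raster",
    "empirical_distribution",
    "mode_durations",
    "isl",
    "autocorrelation",
    "detect_solutions",
    "detect_mixed_states",
    "metrics_frame",
]


@dataclass
class StateTrace:
    """Binary network-state time series on a readout grid."""

    times: np.ndarray  # ms
    states: np.ndarray  # (n_times, n_neurons) in {0,1}
    kind: str  # "refractory" or "window"
    window_ms: float | None = None

    @property
    def n_neurons(self) -> int:
        return self.states.shape[1]

    def as_ints(self) -> np.ndarray:
        """Integer encoding of each state, neuron 0 as least significant bit."""
        if self.n_neurons > 62:
            raise ValueError("integer encoding limited to 62 neurons")
        weights = (1 << np.arange(self.n_neurons, dtype=np.int64))
        return self.states.astype(np.int64) @ weights


def states_from_raster(
    raster: SpikeRaster,
    kind: str = "window",
    window_ms: float = 10.0,
    tau_ref: float | None = None,
    grid_dt: float = 1.0,
) -> StateTrace:
    """Binary state trace from a raster, sampled every ``grid_dt`` ms.

    Refractory readout: neuron k is 1 on [t_spike, t_spike + tau_ref).
    Windowed readout: neuron k is 1 at t iff it spiked in (t - window, t].
    """
    if kind == "refractory":
        if tau_ref is None:
            raise ValueError("refractory readout needs tau_ref")
        window = tau_ref
        half_open = "left"  # ON on [t_s, t_s + tau_ref)
    elif kind == "window":
        if window_ms <= 0:
            raise ValueError("window_ms must be positive")
        window = window_ms
        half_open = "right"  # ON on (t_s, t_s + window]
    else:
        raise ValueError(f"unknown readout kind {kind!r}")

    times = np.arange(0.0, raster.duration + 0.5 * grid_dt, grid_dt)
    states = np.zeros((times.size, raster.n_neurons), dtype=np.uint8)
    inv = 1.0 / grid_dt
    for t_s, k in zip(raster.times, raster.ids):
        if half_open == "left":
            lo = int(np.ceil(t_s * inv - 1e-9))
            hi = int(np.ceil((t_s + window) * inv - 1e-9))  # exclusive
        else:
            lo = int(np.ceil(t_s * inv - 1e-9))
            hi = int(np.floor((t_s + window) * inv + 1e-9)) + 1
        lo = max(lo, 0)
        hi = min(hi, times.size)
        if hi > lo:
            states[lo:hi, int(k)] = 1
    return StateTrace(times=times, states=states, kind=kind,
                      window_ms=None if kind == "refractory" else window_ms)


def empirical_distribution(
    trace: StateTrace,
    restrict_to: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> DiscreteDistribution:
    """Relative state frequencies over the full 2^K space.

    ``restrict_to`` limits counting to a set of integer-encoded states
    (e.g. the exclusive one-hot modes); ``mask`` selects readout times.
    """
    if trace.n_neurons > 20 and restrict_to is None:
        raise ValueError("full state space limited to K <= 20; pass restrict_to")
    codes = trace.as_ints()
    if mask is not None:
        codes = codes[np.asarray(mask, dtype=bool)]
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to, dtype=np.int64)
        codes = codes[np.isin(codes, restrict_to)]
        if codes.size == 0:
            raise ValueError("no usable samples after restriction")
        counts = np.array([(codes == s).sum() for s in restrict_to], dtype=float)
        return DiscreteDistribution(counts / counts.sum(), labels=restrict_to)
    if codes.size == 0:
        raise ValueError("no usable samples")
    counts = np.bincount(codes, minlength=2**trace.n_neurons).astype(float)
    return DiscreteDistribution(counts / counts.sum())


def mode_durations(labels: Sequence, readout_dt: float = 1.0) -> dict:
    """Durations between successive changes of the winning mode label.

    The final (censored) interval is excluded.  A constant label sequence
    has no complete interval and is flagged with ``mean = nan``.
    """
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 readouts")
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    if change.size == 0:
        return {"durations": np.empty(0), "mean": np.nan, "censored_only": True}
    bounds = np.concatenate(([0], change))
    durations = np.diff(bounds) * readout_dt
    # the first interval is complete only if the trace started at a switch;
    # keep it (onset at t=0), drop the censored tail after the last switch
    return {
        "durations": durations.astype(float),
        "mean": float(durations.mean()),
        "censored_only": False,
    }


def isl(generated: np.ndarray, test: np.ndarray, gamma: float = 0.95) -> float:
    """Indirect sampling likelihood of ``test`` under a kernel density
    centered on the ``generated`` binary vectors.

    For each test vector y, P(y) = 1/N sum_i gamma^(d - h_i) (1-gamma)^h_i
    with h_i the Hamming distance to generated sample x_i; the returned
    value is log P(y) averaged over the test set, computed in log space.
    """
    if not 0.5 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0.5, 1)")
    G = np.asarray(generated, dtype=np.float64)
    Y = np.asarray(test, dtype=np.float64)
    if G.ndim != 2 or Y.ndim != 2 or G.shape[1] != Y.shape[1]:
        raise ValueError("generated and test must be 2-D with equal dimension")
    d = G.shape[1]
    # Hamming distances via matmul: h = d - matches
    matches = Y @ G.T + (1.0 - Y) @ (1.0 - G.T)
    h = d - matches
    log_terms = (d - h) * np.log(gamma) + h * np.log1p(-gamma)
    logp = logsumexp(log_terms, axis=1) - np.log(G.shape[0])
    return float(logp.mean())


def autocorrelation(trace: np.ndarray, max_lag: int) -> dict:
    """Pearson autocorrelation by lag and its area under the curve.

    The AUC (trapezoidal, lags 0..max_lag) summarizes mixing speed: a
    smaller area means faster decorrelation.
    """
    x = np.asarray(trace, dtype=float)
    if x.size <= max_lag:
        raise ValueError("trace shorter than max_lag")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("constant trace has undefined autocorrelation")
    r = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: x.size - lag]
        b = x[lag:]
        sa = a.std()
        sb = b.std()
        if sa == 0 or sb == 0:
            r[lag] = 0.0
        else:
            r[lag] = float(np.corrcoef(a, b)[0, 1])
    auc = float(np.trapezoid(r, dx=1.0))
    return {"lags": np.arange(max_lag + 1), "r": r, "auc": auc}


@dataclass
class AssemblyActivity:
    """Per-assembly active fractions over time."""

    times: np.ndarray  # ms
    fractions: np.ndarray  # (n_times, n_assemblies)
    members: tuple  # tuple of index arrays, a partition of the network

    @classmethod
    def from_raster(
        cls,
        raster: SpikeRaster,
        members: Sequence[np.ndarray],
        window_ms: float = 10.0,
        grid_dt: float = 1.0,
    ) -> "AssemblyActivity":
        flat = np.concatenate([np.asarray(m) for m in members])
        if np.unique(flat).size != flat.size:
            raise ValueError("assembly membership must not overlap")
        trace = states_from_raster(raster, kind="window", window_ms=window_ms,
                                   grid_dt=grid_dt)
        fr = np.stack(
            [trace.states[:, np.asarray(m)].mean(axis=1) for m in members], axis=1
        )
        return cls(times=trace.times, fractions=fr,
                   members=tuple(np.asarray(m) for m in members))


def detect_solutions(
    activity: AssemblyActivity,
    linkage: Sequence[Sequence[int]],
    threshold: float = 0.5,
) -> np.ndarray:
    """Per-time solution label, or -1 when no valid solution is encoded.

    Solution n is encoded at time t iff every assembly in ``linkage[n]``
    is active (active fraction > ``threshold``) and every other assembly is
    inactive.  Exact threshold ties count as inactive, so ambiguous states
    yield no solution.
    """
    active = activity.fractions > threshold
    n_assemblies = activity.fractions.shape[1]
    labels = np.full(activity.times.size, -1, dtype=np.int64)
    for n, linked in enumerate(linkage):
        linked = np.asarray(linked)
        others = np.setdiff1d(np.arange(n_assemblies), linked)
        ok = active[:, linked].all(axis=1) & ~active[:, others].any(axis=1)
        labels[ok] = n
    return labels


def detect_mixed_states(
    activity: AssemblyActivity,
    threshold: float = 0.2,
    phases: np.ndarray | None = None,
    n_phase_bins: int = 20,
) -> dict:
    """Mixed-state trace for a two-assembly circuit.

    A state is mixed when both assemblies are more than ``threshold``
    active.  With ``phases`` given (radians, already re-anchored so phase
    zero is the network-rate minimum), the per-phase mixed probability and
    the first- versus second-half-cycle comparison are returned too.
    """
    if activity.fractions.shape[1] != 2:
        raise ValueError("mixed-state detection needs exactly two assemblies")
    mixed = (activity.fractions > threshold).all(axis=1)
    out = {"mixed": mixed, "p_mixed": float(mixed.mean())}
    if phases is not None:
        phases = np.mod(np.asarray(phases, dtype=float), 2 * np.pi)
        edges = np.linspace(0, 2 * np.pi, n_phase_bins + 1)
        idx = np.clip(np.digitize(phases, edges) - 1, 0, n_phase_bins - 1)
        p_by_phase = np.array(
            [mixed[idx == b].mean() if np.any(idx == b) else np.nan
             for b in range(n_phase_bins)]
        )
        first = mixed[phases < np.pi].mean() if np.any(phases < np.pi) else np.nan
        second = mixed[phases >= np.pi].mean() if np.any(phases >= np.pi) else np.nan
        out.update(
            phase_bins=0.5 * (edges[:-1] + edges[1:]),
            p_by_phase=p_by_phase,
            p_first_half=float(first),
            p_second_half=float(second),
        )
    return out


def metrics_frame(run_id: str, metrics: dict) -> pd.DataFrame:
    """Tidy (run_id, metric, value) frame for TSV export."""
    rows = [(run_id, k, v) for k, v in metrics.items() if np.isscalar(v)]
    return pd.DataFrame(rows, columns=["run_id", "metric", "value"])
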