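"""Exact reference machinery for small binary Boltzmann distributions.

A Boltzmann machine over K binary units z in {0,1}^K has energy
E(z) = -1/2 z^T W z - B^T z with symmetric zero-diagonal W, and tempered
distribution p_T(z) proportional to exp(-E(z)/T) (the abstract domain uses
k_B = 1; the physical constant linking current units to temperature lives
in the calibration result).  States are encoded as integers with unit 0 as
the least significant bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoltzmannModel",
    "DiscreteDistribution",
    "exact_distribution",
    "conditional_on_prob",
    "entropy",
    "dkl",
    "random_model",
    "state_table",
]

_ENUM_LIMIT = 20
_NORM_TOL = 1e-12


@dataclass(frozen=True)
class BoltzmannModel:
    W: np.ndarray
    B: np.ndarray
    T: float = 1.0

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "B", B)
        if W.ndim != 2 or W.shape[0] != W.shape[1] or W.shape[0] != B.shape[0]:
            raise ValueError("W must be KxK and B length K")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("W must have zero diagonal")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def K(self) -> int:
        return self.B.shape[0]

    def energy(self, z: np.ndarray) -> float | np.ndarray:
        """E(z) = -1/2 z^T W z - B^T z for one state or a stack of states."""
        z = np.asarray(z, dtype=float)
        return -0.5 * np.einsum("...k,kj,...j->...", z, self.W, z) - z @ self.B

    def at_temperature(self, T: float) -> "BoltzmannModel":
        return BoltzmannModel(self.W, self.B, T=T)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"W": self.W.tolist(), "B": self.B.tolist(), "T": self.T}, fh)

    @classmethod
    def from_json(cls, path) -> "BoltzmannModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["W"]), np.asarray(d["B"]), d.get("T", 1.0))


@dataclass
class DiscreteDistribution:
    """Probabilities over 2^K binary states (or a labeled mode set)."""

    p: np.ndarray
    labels: np.ndarray | None = None
    normalized: bool = field(init=False, default=False)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        self.normalized = abs(self.p.sum() - 1.0) <= _NORM_TOL

    def normalize(self) -> "DiscreteDistribution":
        total = self.p.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return DiscreteDistribution(self.p / total, self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("state\tprobability\n")
            labels = self.labels if self.labels is not None else np.arange(self.p.size)
            for s, q in zip(labels, self.p):
                fh.write(f"{s}\t{q:.12g}\n")


def state_table(K: int) -> np.ndarray:
    """All 2^K binary states; row s is the bits of s, unit 0 = LSB."""
    if K > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to K <= {_ENUM_LIMIT}")
    s = np.arange(2**K, dtype=np.int64)
    return ((s[:, None] >> np.arange(K)) & 1).astype(float)


def exact_distribution(model: BoltzmannModel) -> DiscreteDistribution:
    """Full enumeration of p_T(z) = exp(-E(z)/T)/Z."""
    if model.K > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to K <= {_ENUM_LIMIT}")
    z = state_table(model.K)
    logp = -model.energy(z) / model.T
    logp -= logp.max()
    p = np.exp(logp)
    return DiscreteDistribution(p / p.sum())


def conditional_on_prob(model: BoltzmannModel, k: int, z_rest: np.ndarray) -> float:
    """p(z_k = 1 | rest): logistic of the temperature-scaled local field
    (sum_j W_kj z_j + B_k) / T.  ``z_rest`` is the full state vector; its
    k-th entry is ignored."""
    z = np.asarray(z_rest, dtype=float).copy()
    if not 0 <= k < model.K:
        raise IndexError("unit index out of range")
    z[k] = 0.0
    field_k = (model.W[k] @ z + model.B[k]) / model.T
    return float(1.0 / (1.0 + np.exp(-field_k)))


def entropy(dist: DiscreteDistribution, base: float = np.e) -> float:
    """Shannon entropy; 0*log 0 := 0.  base=2 gives bits, base=e nats."""
    if not dist.normalized:
        raise ValueError("distribution must be normalized")
    p = dist.p[dist.p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def dkl(P: DiscreteDistribution, Q: DiscreteDistribution) -> float:
    """Kullback-Leibler divergence D(P||Q) in nats; Q must be strictly
    positive wherever P is."""
    if P.p.shape != Q.p.shape:
        raise ValueError("distributions must share a state space")
    if not (P.normalized and Q.normalized):
        raise ValueError("both distributions must be normalized")
    mask = P.p > 0
    if np.any(Q.p[mask] <= 0):
        raise ValueError("infinite divergence: Q has zero mass where P > 0")
    return float((P.p[mask] * np.log(P.p[mask] / Q.p[mask])).sum())


def random_model(
    K: int = 4, seed: int | np.random.Generator = 0, pinned_biases: bool = True
) -> BoltzmannModel:
    """Random ensemble model: W-hat and B entries i.i.d. N(0, 0.5), W
    symmetrized as (W-hat + W-hat^T)/2 with zero diagonal.  With
    ``pinned_biases`` (and K >= 4) the third and fourth biases are set to
    +1 and -1, yielding one leak-over- and one leak-below-threshold unit.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    What = rng.normal(0.0, 0.5, size=(K, K))
    W = 0.5 * (What + What.T)
    np.fill_diagonal(W, 0.0)
    B = rng.normal(0.0, 0.5, size=K)
    if pinned_biases and K >= 4:
        B[2] = 1.0
        B[3] = -1.0
    return BoltzmannModel(W, B)
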