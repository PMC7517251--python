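"""The stochastic binary latent-variable encoder (restricted Boltzmann machine).

The model assigns every joint state (h, v) of binary hidden ("codeword")
and visible ("stimulus") units the energy

    E(h, v) = -beta * (Bv·v + Bh·h + hᵀ W v),

with probability proportional to exp(-E).  Because the graph is bipartite,
both conditionals factorize over units: P(h_i=1 | v) = sigma(beta*(W_i v +
Bh_i)) and symmetrically for the visible layer.  An inverse temperature
beta scales all parameters jointly, sweeping the model between the
disordered (beta -> 0, uniform) and frozen (beta -> inf) phases.

Training uses one-step contrastive divergence with a staged learning-rate
schedule; sampling uses vectorized block Gibbs chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .patterns import PatternDataset

__all__ = [
    "ModelParams",
    "StateSampleSet",
    "DEFAULT_SCHEDULE",
    "unit_activation",
    "joint_energy",
    "scale_temperature",
    "gibbs_sample",
    "train_cd1",
]

#: staged CD1 learning rates
DEFAULT_SCHEDULE: tuple[float, ...] = (0.2, 0.1, 0.05, 0.01, 5e-3, 1e-3)


@dataclass
class ModelParams:
    """Weights, biases and inverse temperature of one encoder.

    W has shape (n_hidden, n_visible); row j is hidden unit j's projective
    field over the visible layer.  All parameters are dimensionless
    log-odds; beta multiplies the whole energy.
    """

    W: np.ndarray
    Bh: np.ndarray
    Bv: np.ndarray
    beta: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.Bh = np.asarray(self.Bh, dtype=np.float64)
        self.Bv = np.asarray(self.Bv, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be a matrix of shape (n_hidden, n_visible)")
        if self.Bh.shape != (self.W.shape[0],) or self.Bv.shape != (self.W.shape[1],):
            raise ValueError("bias lengths inconsistent with W")
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.Bh))
            and np.all(np.isfinite(self.Bv))
        ):
            raise ValueError("parameters must be finite")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_params(self) -> int:
        return self.W.size + self.n_visible + self.n_hidden

    @classmethod
    def zeros(cls, n_hidden: int, n_visible: int, beta: float = 1.0) -> "ModelParams":
        return cls(
            W=np.zeros((n_hidden, n_visible)),
            Bh=np.zeros(n_hidden),
            Bv=np.zeros(n_visible),
            beta=beta,
        )


@dataclass
class StateSampleSet:
    """Joint (hidden, visible) samples from one model."""

    hidden_states: np.ndarray  # (n, n_hidden) uint8
    visible_states: np.ndarray  # (n, n_visible) uint8
    chain_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.hidden_states, dtype=np.uint8)
        v = np.asarray(self.visible_states, dtype=np.uint8)
        if h.ndim != 2 or v.ndim != 2 or h.shape[0] != v.shape[0]:
            raise ValueError("hidden and visible sample matrices must have equal row counts")
        if h.max(initial=0) > 1 or v.max(initial=0) > 1:
            raise ValueError("states must be binary")
        self.hidden_states = h
        self.visible_states = v

    @property
    def n_samples(self) -> int:
        return self.hidden_states.shape[0]


def _as_batch(state: np.ndarray, length: int, name: str) -> tuple[np.ndarray, bool]:
    arr = np.atleast_2d(np.asarray(state, dtype=np.float64))
    if arr.shape[1] != length:
        raise ValueError(f"{name} has length {arr.shape[1]}, expected {length}")
    return arr, np.asarray(state).ndim == 1


def unit_activation(
    params: ModelParams,
    state: np.ndarray,
    direction: str = "hidden-given-visible",
) -> np.ndarray:
    """Conditional firing probabilities of one layer given the other.

    For ``direction="hidden-given-visible"`` returns sigma(beta*(W v + Bh))
    elementwise; the reverse direction uses the transpose-symmetric form.
    Accepts a single state vector or a (batch, length) matrix.
    """
    if direction == "hidden-given-visible":
        v, single = _as_batch(state, params.n_visible, "visible state")
        act = params.beta * (v @ params.W.T + params.Bh)
    elif direction == "visible-given-hidden":
        h, single = _as_batch(state, params.n_hidden, "hidden state")
        act = params.beta * (h @ params.W + params.Bv)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    p = expit(act)
    return p[0] if single else p


def joint_energy(params: ModelParams, h: np.ndarray, v: np.ndarray) -> np.ndarray | float:
    """Joint energy -beta*(Bv·v + Bh·h + hᵀWv), in nats (additive constant 0).

    exp(-energy) is proportional to the joint probability.  Batched inputs
    are paired row by row.
    """
    hb, single_h = _as_batch(h, params.n_hidden, "hidden state")
    vb, single_v = _as_batch(v, params.n_visible, "visible state")
    if hb.shape[0] != vb.shape[0]:
        raise ValueError("h and v batches must have equal length")
    e = -params.beta * (
        vb @ params.Bv + hb @ params.Bh + np.einsum("bi,ij,bj->b", hb, params.W, vb)
    )
    return float(e[0]) if (single_h and single_v) else e


def scale_temperature(params: ModelParams, beta: float) -> ModelParams:
    """Fold an inverse temperature into the parameters.

    Returns a model whose W, Bh, Bv are the originals multiplied by
    ``beta`` (times any beta already folded into ``params``) and whose own
    beta field is 1, so downstream code never double-scales.  The returned
    model's distribution equals the original's at inverse temperature beta.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    s = beta * params.beta
    return ModelParams(
        W=params.W * s,
        Bh=params.Bh * s,
        Bv=params.Bv * s,
        beta=1.0,
        meta={**params.meta, "folded_beta": s},
    )


def gibbs_sample(
    params: ModelParams,
    n_chains: int = 500,
    n_keep: int = 100_000,
    thin: int = 1,
    burn_in: int = 1000,
    seed: int = 0,
) -> StateSampleSet:
    """Block Gibbs sampling of joint states.

    One step updates all hidden units given the visible layer, then all
    visible units given the new hidden layer.  Chains start from iid fair
    bits; after ``burn_in`` steps, each chain contributes one joint state
    every ``thin`` steps until ``n_keep`` states are collected.
    """
    if min(n_chains, n_keep, thin, burn_in) < 1:
        raise ValueError("n_chains, n_keep, thin and burn_in must be positive")
    rng = np.random.default_rng(seed)
    m = scale_temperature(params, 1.0)  # fold beta once
    v = (rng.random((n_chains, m.n_visible)) < 0.5).astype(np.float64)
    rounds = -(-n_keep // n_chains)
    H = np.empty((rounds * n_chains, m.n_hidden), dtype=np.uint8)
    V = np.empty((rounds * n_chains, m.n_visible), dtype=np.uint8)
    kept = 0
    total = burn_in + rounds * thin
    for step in range(total):
        ph = expit(v @ m.W.T + m.Bh)
        h = (rng.random(ph.shape) < ph).astype(np.float64)
        pv = expit(h @ m.W + m.Bv)
        v = (rng.random(pv.shape) < pv).astype(np.float64)
        if step >= burn_in and (step - burn_in + 1) % thin == 0:
            H[kept : kept + n_chains] = h
            V[kept : kept + n_chains] = v
            kept += n_chains
    return StateSampleSet(
        hidden_states=H[:n_keep],
        visible_states=V[:n_keep],
        chain_meta={
            "n_chains": n_chains,
            "steps_per_sample": thin,
            "burn_in": burn_in,
            "seed": seed,
        },
    )


def train_cd1(
    data: PatternDataset,
    n_hidden: int,
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
    epochs_per_stage: int = 8,
    minibatch: int = 4,
    seed: int = 0,
    init_std: float = 0.01,
) -> ModelParams:
    """Fit an encoder by one-step contrastive divergence (CD1).

    The learning rate steps through ``schedule`` (default 0.2, 0.1, 0.05,
    0.01, 5e-3, 1e-3), training ``epochs_per_stage`` epochs at each rate.
    Per minibatch, the positive phase uses data-clamped hidden
    probabilities and the negative phase one full Gibbs step from the
    data: dW ∝ <h v>_data - <h v>_recon, analogously for both biases.
    Weights start from iid N(0, init_std²), biases from zero.  The result
    is reproducible given the seed and is returned at beta = 1.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be at least 1")
    if minibatch < 1 or epochs_per_stage < 1 or len(schedule) < 1:
        raise ValueError("schedule, epochs_per_stage and minibatch must be non-empty/positive")
    rng = np.random.default_rng(seed)
    X = data.vectors.astype(np.float64)
    n, n_visible = X.shape
    W = rng.normal(0.0, init_std, size=(n_hidden, n_visible))
    Bh = np.zeros(n_hidden)
    Bv = np.zeros(n_visible)
    for rate in schedule:
        for _ in range(epochs_per_stage):
            order = rng.permutation(n)
            for start in range(0, n, minibatch):
                V0 = X[order[start : start + minibatch]]
                ph0 = expit(V0 @ W.T + Bh)
                h0 = (rng.random(ph0.shape) < ph0).astype(np.float64)
                pv1 = expit(h0 @ W + Bv)
                V1 = (rng.random(pv1.shape) < pv1).astype(np.float64)
                ph1 = expit(V1 @ W.T + Bh)
                b = V0.shape[0]
                dW = (ph0.T @ V0 - ph1.T @ V1) / b
                dBh = (ph0 - ph1).mean(axis=0)
                dBv = (V0 - V1).mean(axis=0)
                if not (
                    np.all(np.isfinite(dW))
                    and np.all(np.isfinite(dBh))
                    and np.all(np.isfinite(dBv))
                ):
                    raise FloatingPointError(
                        f"non-finite CD1 gradient at learning rate {rate}"
                    )
                W += rate * dW
                Bh += rate * dBh
                Bv += rate * dBv
    return ModelParams(
        W=W,
        Bh=Bh,
        Bv=Bv,
        beta=1.0,
        meta={
            "trained": "cd1",
            "schedule": tuple(schedule),
            "epochs_per_stage": epochs_per_stage,
            "minibatch": minibatch,
            "seed": seed,
            "n_training_patterns": n,
        },
    )
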