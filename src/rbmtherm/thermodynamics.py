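"""Information and energy of codewords per stimulus.

Because the model graph is bipartite, several quantities that are usually
intractable in energy-based models have closed forms here:

* the stimulus-conditioned entropy of the hidden layer is a sum of
  per-unit binary entropies, H_{h|v} = sum_i [g(a_i) - a_i f(a_i)] with
  a = beta*(W v + Bh), f the logistic sigmoid and g(x) = log(1+e^x);
* the marginal ("codeword") energy of a hidden pattern h is, up to one
  shared constant, E_h = -Bh·h - sum_i g((Wᵀh)_i + Bv_i);
* the visible free energy is the mirror image, E_v = -Bv·v -
  sum_j g((Wv)_j + Bh_j), and satisfies the exact identity
  E_v = <E(h,v)>_{h|v} - H_{h|v}.

Energies are computed in nats; conversion to bits happens at reporting
boundaries.  ``enumerate_model`` is the exact oracle for models small
enough to enumerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .patterns import PatternDataset, pattern_bitstrings
from .rbm_core import ModelParams, StateSampleSet, scale_temperature

__all__ = [
    "LN2",
    "ExactDistribution",
    "all_binary_states",
    "conditional_hidden_entropy",
    "hidden_marginal_energy",
    "visible_free_energy",
    "expected_conditional_energy",
    "empirical_stimulus_energy",
    "enumerate_model",
    "codeword_energy_anchor",
    "stimulus_thermo_table",
]

LN2 = float(np.log(2.0))

ENUM_CAP = 24  # total units; 2^24 joint states is the enumeration limit


def _softplus(x: np.ndarray) -> np.ndarray:
    """log(1+e^x), overflow-safe for |x| up to at least 700."""
    return np.logaddexp(0.0, x)


def all_binary_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, MSB-first.

    Row i spells the binary expansion of i, so the bitstring of row i
    (first unit leftmost) is just i in binary — the shared state-indexing
    convention of every enumeration oracle here.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    idx = np.arange(2**n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1, dtype=np.int64)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def conditional_hidden_entropy(
    params: ModelParams, v: np.ndarray, units: str = "bits"
) -> np.ndarray | float:
    """Entropy of the hidden layer conditioned on stimulus v.

    Factorizes into per-unit binary entropies; computed in nats via the
    softplus form and converted to bits by default.  Stable for
    activations up to |a| ~ 700.  Accepts a single vector or a batch.
    """
    if units not in ("bits", "nats"):
        raise ValueError("units must be 'bits' or 'nats'")
    vb = np.atleast_2d(np.asarray(v, dtype=np.float64))
    if vb.shape[1] != params.n_visible:
        raise ValueError("visible state length mismatch")
    a = params.beta * (vb @ params.W.T + params.Bh)
    h_nats = (_softplus(a) - a * expit(a)).sum(axis=1)
    if units == "bits":
        h_nats = h_nats / LN2
    return float(h_nats[0]) if np.asarray(v).ndim == 1 else h_nats


def hidden_marginal_energy(params: ModelParams, h: np.ndarray) -> np.ndarray | float:
    """Codeword energy: -log of the marginal probability of hidden pattern h,
    up to one additive constant (log Z) shared by all patterns.  Nats."""
    hb = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if hb.shape[1] != params.n_hidden:
        raise ValueError("hidden state length mismatch")
    b = params.beta
    e = -b * (hb @ params.Bh) - _softplus(b * (hb @ params.W + params.Bv)).sum(axis=1)
    return float(e[0]) if np.asarray(h).ndim == 1 else e


def visible_free_energy(params: ModelParams, v: np.ndarray) -> np.ndarray | float:
    """Free energy of stimulus v: -log sum_h exp(-E(h,v)), up to the same
    constant convention as the joint energy.  Nats."""
    vb = np.atleast_2d(np.asarray(v, dtype=np.float64))
    if vb.shape[1] != params.n_visible:
        raise ValueError("visible state length mismatch")
    b = params.beta
    e = -b * (vb @ params.Bv) - _softplus(b * (vb @ params.W.T + params.Bh)).sum(axis=1)
    return float(e[0]) if np.asarray(v).ndim == 1 else e


def expected_conditional_energy(
    params: ModelParams,
    v: np.ndarray,
    mode: str = "enumerate",
    n_samples: int = 10_000,
    seed: int = 0,
    return_stderr: bool = False,
) -> float | tuple[float, float]:
    """Mean codeword energy <E_h>_{h|v} of the patterns evoked by v.  Nats.

    The conditional Q(h|v) is factorial, so "sample" mode draws iid
    Bernoulli codewords from the per-unit activations (no chain needed)
    and converges to "enumerate" mode, which sums over all 2^n_hidden
    patterns and requires n_hidden <= 20.
    """
    vv = np.asarray(v, dtype=np.float64)
    if vv.shape != (params.n_visible,):
        raise ValueError("v must be a single visible vector")
    a = params.beta * (params.W @ vv + params.Bh)
    p = expit(a)
    if mode == "enumerate":
        if params.n_hidden > 20:
            raise ValueError("enumerate mode limited to n_hidden <= 20")
        H = all_binary_states(params.n_hidden).astype(np.float64)
        logq = H @ np.log(np.clip(p, 1e-300, 1.0)) + (1 - H) @ np.log(
            np.clip(1 - p, 1e-300, 1.0)
        )
        q = np.exp(logq - logsumexp(logq))
        val = float(q @ hidden_marginal_energy(params, H))
        return (val, 0.0) if return_stderr else val
    if mode == "sample":
        rng = np.random.default_rng(seed)
        H = (rng.random((n_samples, params.n_hidden)) < p).astype(np.float64)
        e = hidden_marginal_energy(params, H)
        val = float(e.mean())
        if return_stderr:
            return val, float(e.std(ddof=1) / np.sqrt(n_samples))
        return val
    raise ValueError(f"unknown mode {mode!r}")


def empirical_stimulus_energy(data: PatternDataset) -> pd.Series:
    """E_v = -log2(empirical frequency) per distinct observed pattern.

    Indexed by pattern bitstring; unseen patterns have no entry (no
    pseudo-counts at this layer).
    """
    freqs = data.frequencies
    return pd.Series(
        -np.log2(freqs),
        index=pattern_bitstrings(data.unique_patterns),
        name="E_v_bits",
    )


# ----------------------------------------------------------------------
# exact enumeration oracle
# ----------------------------------------------------------------------
@dataclass
class ExactDistribution:
    """Exact joint/marginal distribution of an enumerable model.

    ``joint[i, j]`` is P(h = hidden_states[i], v = visible_states[j]);
    state index i spells the pattern's bits MSB-first.
    """

    joint: np.ndarray
    hidden_states: np.ndarray
    visible_states: np.ndarray
    log_Z: float

    @property
    def visible_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    @property
    def hidden_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    def conditional_hidden(self, v_index: int) -> np.ndarray:
        col = self.joint[:, v_index]
        return col / col.sum()


def enumerate_model(params: ModelParams) -> ExactDistribution:
    """Exact probabilities of every joint state (n_visible + n_hidden <= 24)."""
    if params.n_visible + params.n_hidden > ENUM_CAP:
        raise ValueError(
            f"enumeration limited to {ENUM_CAP} total units, "
            f"got {params.n_visible + params.n_hidden}"
        )
    Hs = all_binary_states(params.n_hidden).astype(np.float64)
    Vs = all_binary_states(params.n_visible).astype(np.float64)
    E = -params.beta * (
        Hs @ params.W @ Vs.T + (Hs @ params.Bh)[:, None] + (Vs @ params.Bv)[None, :]
    )
    log_Z = float(logsumexp(-E))
    return ExactDistribution(
        joint=np.exp(-E - log_Z),
        hidden_states=Hs.astype(np.uint8),
        visible_states=Vs.astype(np.uint8),
        log_Z=log_Z,
    )


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
def codeword_energy_anchor(
    params: ModelParams, reference: StateSampleSet | None = None
) -> float:
    """Energy (nats) of the lowest-energy, i.e. most frequent, codeword.

    Used to re-anchor reported codeword energies so the most probable
    pattern sits at zero.  With a reference sample set the anchor pattern
    is the most frequent sampled hidden pattern; otherwise, for models
    with n_hidden <= 20, the exact minimum of the marginal energy over all
    patterns is used.
    """
    if reference is not None:
        uniq, counts = np.unique(reference.hidden_states, axis=0, return_counts=True)
        mode_pattern = uniq[np.argmax(counts)]
        return float(hidden_marginal_energy(params, mode_pattern))
    if params.n_hidden > 20:
        raise ValueError("anchor without reference samples requires n_hidden <= 20")
    H = all_binary_states(params.n_hidden).astype(np.float64)
    return float(hidden_marginal_energy(params, H).min())


def stimulus_thermo_table(
    params: ModelParams,
    data: PatternDataset,
    mode: str = "sample",
    n_samples: int = 10_000,
    seed: int = 0,
    reference: StateSampleSet | None = None,
) -> pd.DataFrame:
    """Per-stimulus information/energy table over the observed patterns.

    Columns (all energies re-anchored and converted to bits):
    ``pattern``, ``frequency``, ``E_v_bits`` (empirical -log2 frequency),
    ``H_cond_bits`` (conditional codeword entropy), ``E_codeword_bits``
    (mean evoked codeword energy), ``F_visible_bits`` (model free energy
    of the stimulus, anchored at its own minimum over observed patterns).
    """
    patterns = data.unique_patterns.astype(np.float64)
    freqs = data.frequencies
    H_bits = conditional_hidden_entropy(params, patterns, units="bits")
    anchor = codeword_energy_anchor(params, reference)
    seeds = np.random.SeedSequence(seed).generate_state(len(patterns))
    e_code = np.array(
        [
            expected_conditional_energy(
                params, pat, mode=mode, n_samples=n_samples, seed=int(s)
            )
            for pat, s in zip(patterns, seeds)
        ]
    )
    f_vis = visible_free_energy(params, patterns)
    table = pd.DataFrame(
        {
            "pattern": pattern_bitstrings(data.unique_patterns),
            "frequency": freqs,
            "E_v_bits": -np.log2(freqs),
            "H_cond_bits": H_bits,
            "E_codeword_bits": (e_code - anchor) / LN2,
            "F_visible_bits": (f_vis - f_vis.min()) / LN2,
        }
    )
    table.attrs["anchor_energy_nats"] = anchor
    table.attrs["mode"] = mode
    table.attrs["n_samples"] = n_samples
    return table
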