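"""Fisher information of the encoder and criticality diagnostics.

For an energy-based model with energy linear in its parameters, the
Fisher Information Matrix equals the covariance, under the joint model
distribution, of the energy-gradient sufficient statistics — here the
vector t(h, v) = [vec(h vᵀ), v, h].  Its blocks are therefore plain
first/second moments of unit activities, e.g.

    F_{w_ij, w_kl} = <h_i v_j h_k v_l> - <h_i v_j><h_k v_l>,

and the diagonal reduces to Bernoulli variances.  The FIM is a
generalized susceptibility: sweeping an inverse temperature beta through
the parameters, the largest eigenvalue peaks at the model's (finite-size)
critical point.  A trained model whose susceptibility peaks at beta = 1
sits at criticality.

Parameter ordering convention (public): all weights row-major (hidden
index major), then visible biases, then hidden biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rbm_core import ModelParams, StateSampleSet, gibbs_sample, scale_temperature
from .thermodynamics import enumerate_model

__all__ = [
    "FIMResult",
    "SpectrumSweep",
    "flatten_direction",
    "fim_from_samples",
    "fim_exact",
    "spectrum_sweep",
    "parameter_sensitivity",
    "rank_units",
]

DEFAULT_TRUNCATION = 1e-5


@dataclass
class FIMResult:
    """Fisher Information Matrix of one model at one inverse temperature.

    ``matrix`` is indexed by the flattened parameter vector (weights
    row-major, then visible biases, then hidden biases).  Eigenvalues are
    descending; ``diagonal_sensitivities`` holds sqrt(F_kk) per parameter.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column k pairs with eigenvalues[k]
    beta: float
    n_hidden: int
    n_visible: int
    sampling_meta: dict = field(default_factory=dict)

    @property
    def leading_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def diagonal_sensitivities(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.matrix), 0.0, None))

    def weight_block_diag(self) -> np.ndarray:
        """Diagonal sensitivities of the weights, reshaped (n_hidden, n_visible)."""
        nw = self.n_hidden * self.n_visible
        return self.diagonal_sensitivities[:nw].reshape(self.n_hidden, self.n_visible)


@dataclass
class SpectrumSweep:
    """FIM eigen-spectra over a grid of inverse temperatures."""

    betas: np.ndarray
    spectra: list[np.ndarray]  # per beta, descending, truncated at the floor
    lambda_max: np.ndarray
    traces: np.ndarray
    truncation_floor: float
    sampling_meta: dict = field(default_factory=dict)

    @property
    def peak_beta(self) -> float:
        return float(self.betas[int(np.argmax(self.lambda_max))])

    @property
    def peak_is_interior(self) -> bool:
        i = int(np.argmax(self.lambda_max))
        return 0 < i < len(self.betas) - 1

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas,
                "lambda_max": self.lambda_max,
                "n_eigs_above_floor": [len(s) for s in self.spectra],
                "trace": self.traces,
            }
        )


def flatten_direction(
    dW: np.ndarray, dBv: np.ndarray, dBh: np.ndarray
) -> np.ndarray:
    """Pack a parameter-space direction into the public flat ordering."""
    return np.concatenate([np.ravel(dW), np.ravel(dBv), np.ravel(dBh)])


def _suff_stats(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Energy-gradient statistics [vec(h vᵀ) row-major, v, h] per sample."""
    n = h.shape[0]
    hv = np.einsum("ni,nj->nij", h, v).reshape(n, -1)
    return np.concatenate([hv, v, h], axis=1)


def _finalize(
    F: np.ndarray, beta: float, n_hidden: int, n_visible: int, meta: dict
) -> FIMResult:
    F = 0.5 * (F + F.T)
    vals, vecs = np.linalg.eigh(F)
    order = np.argsort(vals)[::-1]
    return FIMResult(
        matrix=F,
        eigenvalues=vals[order],
        eigenvectors=vecs[:, order],
        beta=beta,
        n_hidden=n_hidden,
        n_visible=n_visible,
        sampling_meta=meta,
    )


def fim_from_samples(params: ModelParams, samples: StateSampleSet) -> FIMResult:
    """Estimate the FIM from joint samples drawn from the model.

    Accumulates first and second moments of the sufficient statistics in
    chunks; the samples must come from the model at the same beta.
    """
    h_all = samples.hidden_states
    v_all = samples.visible_states
    if h_all.shape[1] != params.n_hidden or v_all.shape[1] != params.n_visible:
        raise ValueError("sample dimensions do not match the model")
    n = h_all.shape[0]
    d = params.n_params
    S = np.zeros((d, d))
    m = np.zeros(d)
    chunk = max(1, int(2e8 // (8 * d)))
    for start in range(0, n, chunk):
        t = _suff_stats(
            h_all[start : start + chunk].astype(np.float64),
            v_all[start : start + chunk].astype(np.float64),
        )
        S += t.T @ t
        m += t.sum(axis=0)
    m /= n
    F = S / n - np.outer(m, m)
    meta = {"n_samples": n, **samples.chain_meta}
    return _finalize(F, params.beta, params.n_hidden, params.n_visible, meta)


def fim_exact(params: ModelParams) -> FIMResult:
    """Exact FIM from enumerated moments (small models only)."""
    dist = enumerate_model(params)
    Hs = dist.hidden_states.astype(np.float64)
    Vs = dist.visible_states.astype(np.float64)
    nh, nv = Hs.shape[0], Vs.shape[0]
    # all joint states, weighted by their exact probability
    h = np.repeat(Hs, nv, axis=0)
    v = np.tile(Vs, (nh, 1))
    p = dist.joint.reshape(-1)
    t = _suff_stats(h, v)
    m = p @ t
    S = t.T @ (t * p[:, None])
    F = S - np.outer(m, m)
    return _finalize(
        F, params.beta, params.n_hidden, params.n_visible, {"mode": "exact"}
    )


def spectrum_sweep(
    params: ModelParams,
    betas: np.ndarray,
    n_chains: int = 500,
    n_keep: int = 100_000,
    thin: int = 2,
    burn_in: int = 200,
    seed: int = 0,
    truncation_floor: float = DEFAULT_TRUNCATION,
    exact: bool = False,
) -> SpectrumSweep:
    """FIM spectra of the beta-scaled model family over a beta grid.

    Each grid point evaluates the FIM of ``scale_temperature(params,
    beta)`` with respect to its own (scaled) parameters, from fresh Gibbs
    samples at that beta (or exact enumeration for tiny models).  The
    largest eigenvalue as a function of beta is the susceptibility curve
    whose interior peak locates the model family's critical temperature.
    """
    betas = np.asarray(betas, dtype=np.float64)
    if len(betas) < 3:
        raise ValueError("beta grid must have at least 3 points to detect a peak")
    if np.any(np.diff(betas) <= 0):
        raise ValueError("beta grid must be strictly increasing")
    seeds = np.random.SeedSequence(seed).generate_state(len(betas))
    spectra, lam, tr = [], [], []
    for b, s in zip(betas, seeds):
        scaled = scale_temperature(params, float(b))
        if exact:
            res = fim_exact(scaled)
        else:
            samples = gibbs_sample(
                scaled,
                n_chains=n_chains,
                n_keep=n_keep,
                thin=thin,
                burn_in=burn_in,
                seed=int(s),
            )
            res = fim_from_samples(scaled, samples)
        ev = res.eigenvalues
        spectra.append(ev[ev > truncation_floor])
        lam.append(ev[0])
        tr.append(float(np.trace(res.matrix)))
    return SpectrumSweep(
        betas=betas,
        spectra=spectra,
        lambda_max=np.array(lam),
        traces=np.array(tr),
        truncation_floor=truncation_floor,
        sampling_meta={
            "n_keep": n_keep,
            "n_chains": n_chains,
            "thin": thin,
            "burn_in": burn_in,
            "seed": seed,
            "exact": exact,
        },
    )


def parameter_sensitivity(fim: FIMResult, direction: np.ndarray) -> float:
    """Sensitivity sqrt(wᵀ F w) of a parameter-space direction.

    The square-root convention makes a unit-norm eigenvector score
    sqrt(lambda) and the k-th coordinate direction score sqrt(F_kk),
    matching ``diagonal_sensitivities``.
    """
    w = np.asarray(direction, dtype=np.float64)
    if w.shape != (fim.matrix.shape[0],):
        raise ValueError("direction length does not match the parameter ordering")
    return float(np.sqrt(max(w @ fim.matrix @ w, 0.0)))


def rank_units(fim: FIMResult, model: ModelParams) -> pd.DataFrame:
    """Rank hidden units by aggregate parameter sensitivity.

    Each unit j is scored by the RMS of its diagonal sensitivities over
    {Bh_j} ∪ {W_j,:} (equivalently sqrt of the mean FIM diagonal over
    those parameters); ties break by unit index.  The returned frame
    carries each unit's projective field (its weight row) so the ranked
    receptive-field gallery can be rendered directly.
    """
    if model.n_hidden != fim.n_hidden or model.n_visible != fim.n_visible:
        raise ValueError("model shape does not match the FIM")
    diag = np.clip(np.diag(fim.matrix), 0.0, None)
    nw = model.n_hidden * model.n_visible
    w_diag = diag[:nw].reshape(model.n_hidden, model.n_visible)
    bh_diag = diag[nw + model.n_visible :]
    scores = np.sqrt(
        (w_diag.sum(axis=1) + bh_diag) / (model.n_visible + 1)
    )
    order = np.lexsort((np.arange(model.n_hidden), -scores))
    rank = np.empty(model.n_hidden, dtype=np.int64)
    rank[order] = np.arange(1, model.n_hidden + 1)
    return pd.DataFrame(
        {
            "unit": np.arange(model.n_hidden),
            "score": scores,
            "rank": rank,
            "projective_field": [model.W[j].copy() for j in range(model.n_hidden)],
        }
    )
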