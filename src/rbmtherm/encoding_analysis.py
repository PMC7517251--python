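"""Headline encoding analyses.

How does a trained stochastic encoder allocate its coding space?  The
operations here quantify: model-fit quality versus hidden-layer size
(held-out KL divergence), activity statistics (sparsity, pairwise
correlation), how evoked codeword entropy and energy vary with stimulus
information content (binned energy-entropy profiles and their slopes),
the encoding cost I_enc, and Zipf rank-frequency statistics of the
codewords.  A slope of +1 between mean codeword energy and mean evoked
entropy across stimulus-energy bins — equivalently a rank-frequency
slope of -1 — is the statistical-criticality signature that emerges once
the hidden layer is large enough to capture the stimulus distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import PatternDataset
from .rbm_core import ModelParams, StateSampleSet
from .thermodynamics import stimulus_thermo_table

__all__ = [
    "EnergyEntropyProfile",
    "FitQuality",
    "RankFrequency",
    "SlopeTable",
    "model_data_kl",
    "activity_stats",
    "bin_by_stimulus_energy",
    "energy_entropy_profile",
    "slope_vs_model_size",
    "rank_frequency",
]


# ----------------------------------------------------------------------
# fit quality and activity statistics
# ----------------------------------------------------------------------
@dataclass
class FitQuality:
    """Model-fit and activity summary for one hidden-layer size."""

    n_hidden: int
    kl_bits: float
    sparsity: float
    mean_abs_correlation: float


def model_data_kl(
    model_samples: PatternDataset,
    heldout: PatternDataset,
    pseudocount: float = 0.5,
) -> float:
    """KL(heldout || model samples) in bits over the union pattern support.

    Both empirical distributions get an additive ``pseudocount`` per
    distinct pattern in the union support (default 0.5).  At pseudocount
    0 the divergence is computed on the held-out support and is infinite
    if the model never produced a held-out pattern.
    """
    if model_samples.n_visible != heldout.n_visible:
        raise ValueError("datasets are over different pattern spaces")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    k1 = heldout.n_distinct
    union, inverse = np.unique(
        np.concatenate([heldout.unique_patterns, model_samples.unique_patterns]),
        axis=0,
        return_inverse=True,
    )
    cp = np.zeros(len(union))
    cq = np.zeros(len(union))
    cp[inverse[:k1]] = heldout.counts
    cq[inverse[k1:]] = model_samples.counts
    cp += pseudocount
    cq += pseudocount
    p = cp / cp.sum()
    q = cq / cq.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def activity_stats(samples: StateSampleSet) -> tuple[float, float]:
    """(sparsity, mean |pairwise Pearson correlation|) of the hidden layer.

    Sparsity is the grand-mean activation.  Units with zero variance
    contribute 0 correlation (the Pearson denominator is undefined there).
    """
    h = samples.hidden_states.astype(np.float64)
    if h.shape[1] < 2:
        raise ValueError("need at least 2 hidden units for correlations")
    sparsity = float(h.mean())
    sd = h.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(h, rowvar=False)
    corr[~np.isfinite(corr)] = 0.0
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    iu = np.triu_indices(h.shape[1], k=1)
    return sparsity, float(np.abs(corr[iu]).mean())


# ----------------------------------------------------------------------
# stimulus-energy binning and energy-entropy profiles
# ----------------------------------------------------------------------
def bin_by_stimulus_energy(
    energies: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assign stimuli to equal-width bins over the observed energy range.

    Returns (bin index per stimulus, bin edges).  The right edge is
    inclusive in the last bin; a degenerate (constant) energy range puts
    everything in bin 0.
    """
    e = np.asarray(energies, dtype=np.float64)
    if e.size == 0:
        raise ValueError("no energies to bin")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    lo, hi = float(e.min()), float(e.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    if hi == lo:
        return np.zeros(e.shape, dtype=np.int64), edges
    idx = np.minimum(((e - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
    return idx, edges


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x; nan when under-determined."""
    if len(x) < 2 or np.ptp(x) == 0:
        return float("nan")
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


@dataclass
class EnergyEntropyProfile:
    """Binned energy-entropy statistics of evoked codewords for one model.

    All quantities in bits; codeword energies are anchored so the most
    probable codeword sits at zero.  ``I_enc`` is the frequency-weighted
    mean gap between evoked codeword energy and evoked entropy — the
    average KL divergence between the stimulus-conditioned and marginal
    codeword distributions, up to the shared anchoring constant.
    """

    n_hidden: int
    bin_edges: np.ndarray
    per_bin_mean_entropy: np.ndarray
    per_bin_mean_codeword_energy: np.ndarray
    per_bin_count: np.ndarray
    slope_entropy_vs_Ev: float
    slope_energy_vs_Ev: float
    slope_energy_vs_entropy: float
    I_enc: float
    table: pd.DataFrame = field(repr=False, default=None)


def energy_entropy_profile(
    model: ModelParams,
    data: PatternDataset,
    n_bins: int = 14,
    mode: str = "sample",
    n_samples: int = 10_000,
    seed: int = 0,
    reference: StateSampleSet | None = None,
    weighted: bool = True,
    ev_source: str = "free_energy",
) -> EnergyEntropyProfile:
    """Evoked entropy and codeword energy versus stimulus information.

    Computes per-stimulus conditional entropy (closed form) and expected
    codeword energy (enumerated or sampled), bins the distinct observed
    stimuli into ``n_bins`` equal-width bins of stimulus energy, and fits
    ordinary least-squares slopes on the nonempty bin means: entropy vs
    E_v, codeword energy vs E_v, and codeword energy vs entropy (the
    criticality diagnostic; 1 is the Zipf point).  Bin means weight
    stimuli by empirical frequency unless ``weighted=False``.

    ``ev_source`` selects the stimulus-energy axis: ``"free_energy"``
    (default) uses the model's anchored visible free energy, which is
    defined for arbitrarily rare stimuli; ``"empirical"`` uses
    -log2(empirical frequency), which is truncated at log2(n_samples)
    and biases the rare-stimulus bins in moderate-sized samples.
    """
    if ev_source not in ("free_energy", "empirical"):
        raise ValueError("ev_source must be 'free_energy' or 'empirical'")
    thermo = stimulus_thermo_table(
        model, data, mode=mode, n_samples=n_samples, seed=seed, reference=reference
    )
    ev_col = "F_visible_bits" if ev_source == "free_energy" else "E_v_bits"
    ev = thermo[ev_col].to_numpy()
    hh = thermo["H_cond_bits"].to_numpy()
    ee = thermo["E_codeword_bits"].to_numpy()
    fr = thermo["frequency"].to_numpy()
    idx, edges = bin_by_stimulus_energy(ev, n_bins)
    w = fr if weighted else np.ones_like(fr)
    counts = np.bincount(idx, minlength=n_bins)
    wsum = np.bincount(idx, weights=w, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_h = np.bincount(idx, weights=w * hh, minlength=n_bins) / wsum
        mean_e = np.bincount(idx, weights=w * ee, minlength=n_bins) / wsum
        mean_ev = np.bincount(idx, weights=w * ev, minlength=n_bins) / wsum
    ok = counts > 0
    if ok.sum() >= 2:
        s_h = _ols_slope(mean_ev[ok], mean_h[ok])
        s_e = _ols_slope(mean_ev[ok], mean_e[ok])
        s_ee = _ols_slope(mean_h[ok], mean_e[ok])
    else:
        s_h = s_e = s_ee = float("nan")
    i_enc = float(np.sum(fr * (ee - hh)))
    return EnergyEntropyProfile(
        n_hidden=model.n_hidden,
        bin_edges=edges,
        per_bin_mean_entropy=mean_h,
        per_bin_mean_codeword_energy=mean_e,
        per_bin_count=counts,
        slope_entropy_vs_Ev=s_h,
        slope_energy_vs_Ev=s_e,
        slope_energy_vs_entropy=s_ee,
        I_enc=i_enc,
        table=thermo,
    )


@dataclass
class SlopeTable:
    """Slopes and onsets across a family of hidden-layer sizes."""

    table: pd.DataFrame
    suppression_onset: int | None  # smallest size with negative entropy slope
    criticality_onset: int | None  # smallest size with energy-entropy slope ~ 1


def slope_vs_model_size(
    profiles: dict[int, EnergyEntropyProfile], slope_tolerance: float = 0.15
) -> SlopeTable:
    """Tabulate profile slopes and I_enc against hidden-layer size.

    Flags the variability-suppression onset (smallest size whose
    entropy-vs-E_v slope is negative) and the criticality onset (smallest
    size whose codeword-energy-vs-entropy slope is within
    ``slope_tolerance`` of 1); either is None when not reached.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    sizes = sorted(profiles)
    df = pd.DataFrame(
        {
            "n_hidden": sizes,
            "slope_entropy_vs_Ev": [profiles[s].slope_entropy_vs_Ev for s in sizes],
            "slope_energy_vs_Ev": [profiles[s].slope_energy_vs_Ev for s in sizes],
            "slope_energy_vs_entropy": [
                profiles[s].slope_energy_vs_entropy for s in sizes
            ],
            "I_enc": [profiles[s].I_enc for s in sizes],
        }
    )
    supp = df.loc[df["slope_entropy_vs_Ev"] < 0, "n_hidden"]
    crit = df.loc[
        (df["slope_energy_vs_entropy"] - 1.0).abs() <= slope_tolerance, "n_hidden"
    ]
    return SlopeTable(
        table=df,
        suppression_onset=int(supp.iloc[0]) if len(supp) else None,
        criticality_onset=int(crit.iloc[0]) if len(crit) else None,
    )


# ----------------------------------------------------------------------
# rank-frequency (Zipf) statistics
# ----------------------------------------------------------------------
@dataclass
class RankFrequency:
    """Rank-frequency table of codeword patterns and its log-log slope."""

    table: pd.DataFrame
    slope: float  # least-squares slope of log2 f vs log2 rank; Zipf ~ -1
    min_count: int


def rank_frequency(samples: PatternDataset, min_count: int = 5) -> RankFrequency:
    """Zipf statistics of a pattern sample.

    Sorts patterns by descending frequency and fits the least-squares
    slope of log2(frequency) against log2(rank) over ranks whose count is
    at least ``min_count`` (excluding the noisy sampling tail).  The
    slope is nan when fewer than 10 distinct patterns, or fewer than 2
    qualifying ranks, are available.
    """
    tab = samples.frequency_table().reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    slope = float("nan")
    fit = tab[tab["count"] >= min_count]
    if samples.n_distinct >= 10 and len(fit) >= 2:
        slope = _ols_slope(
            np.log2(fit["rank"].to_numpy(dtype=np.float64)),
            np.log2(fit["frequency"].to_numpy()),
        )
    return RankFrequency(table=tab, slope=slope, min_count=min_count)
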