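"""Shared fixtures: tiny enumerable models and the trained model families.

The expensive session fixtures build the scaled-down study conditions once
and share them across analysis and acceptance tests: a 60-hidden encoder
trained on 13-pixel circular patches of Swendsen-Wang Ising samples, and a
hidden-size family at two lattice temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import rbmtherm as rt
from rbmtherm.patterns import PatternDataset


def make_tiny_model(n_hidden=2, n_visible=3, scale=1.0, seed=0) -> rt.ModelParams:
    """Random small model with uniform weights/biases in [-scale, scale]."""
    rng = np.random.default_rng(seed)
    return rt.ModelParams(
        W=rng.uniform(-scale, scale, (n_hidden, n_visible)),
        Bh=rng.uniform(-scale, scale, n_hidden),
        Bv=rng.uniform(-scale, scale, n_visible),
    )


@pytest.fixture
def tiny_model() -> rt.ModelParams:
    return make_tiny_model(seed=0)


# ----------------------------------------------------------------------
# scaled-down study conditions (shared, built once)
# ----------------------------------------------------------------------
@dataclass
class TrainedSixty:
    """60-hidden encoder on 13-pixel Ising patches at T=2.5."""

    data: PatternDataset
    model: rt.ModelParams
    states: rt.StateSampleSet
    profile: rt.EnergyEntropyProfile


@pytest.fixture(scope="session")
def trained_sixty() -> TrainedSixty:
    """Train the headline model: 20k patterns from a 10x10 lattice at T=2.5
    (Swendsen-Wang, 1000 sweeps burn-in, thinned by 100), 13 visible units,
    60 hidden units, CD1 with the staged schedule at 2 epochs per stage and
    minibatch 32."""
    lattice = rt.sample_ising(10, 2.5, 20_000, burn_in=1000, thin=100, seed=11)
    spec = rt.PatchSpec.from_pixel_count(13)
    data = rt.extract_patches(lattice, spec, 20_000, seed=12)
    model = rt.train_cd1(data, 60, epochs_per_stage=2, minibatch=32, seed=13)
    states = rt.gibbs_sample(
        model, n_chains=500, n_keep=50_000, thin=2, burn_in=500, seed=14
    )
    profile = rt.energy_entropy_profile(
        model, data, n_bins=10, mode="sample", n_samples=10_000, seed=15,
        reference=states,
    )
    return TrainedSixty(data=data, model=model, states=states, profile=profile)


@dataclass
class FamilyMember:
    n_hidden: int
    model: rt.ModelParams
    states: rt.StateSampleSet
    kl_bits: float
    sparsity: float
    mean_abs_correlation: float
    profile: rt.EnergyEntropyProfile
    zipf_slope: float


FAMILY_SIZES = (5, 10, 20, 35, 60)
FAMILY_TEMPERATURES = (2.5, 3.5)


@pytest.fixture(scope="session")
def model_family() -> dict[float, list[FamilyMember]]:
    """Hidden-size family {5,10,20,35,60} trained on Ising patches at two
    lattice temperatures, with held-out KL, activity statistics,
    energy-entropy profiles and codeword Zipf slopes per member."""
    spec = rt.PatchSpec.from_pixel_count(13)
    out: dict[float, list[FamilyMember]] = {}
    for T in FAMILY_TEMPERATURES:
        lattice = rt.sample_ising(10, T, 20_000, burn_in=1000, thin=100, seed=41)
        train = rt.extract_patches(lattice, spec, 20_000, seed=42)
        heldout = rt.extract_patches(lattice, spec, 50_000, seed=43)
        members = []
        for nh in FAMILY_SIZES:
            model = rt.train_cd1(
                train, nh, epochs_per_stage=6, minibatch=8, seed=44 + nh
            )
            states = rt.gibbs_sample(
                model, n_chains=500, n_keep=100_000, thin=2, burn_in=300,
                seed=45 + nh,
            )
            kl = rt.model_data_kl(
                PatternDataset.from_vectors(states.visible_states), heldout
            )
            sparsity, corr = rt.activity_stats(states)
            profile = rt.energy_entropy_profile(
                model, train, n_bins=10, mode="sample", n_samples=2_000,
                seed=46 + nh, reference=states,
            )
            zipf = rt.rank_frequency(
                PatternDataset.from_vectors(states.hidden_states)
            )
            members.append(
                FamilyMember(
                    n_hidden=nh,
                    model=model,
                    states=states,
                    kl_bits=kl,
                    sparsity=sparsity,
                    mean_abs_correlation=corr,
                    profile=profile,
                    zipf_slope=zipf.slope,
                )
            )
        out[T] = members
    return out


def exact_ising_distribution(L: int, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force Boltzmann distribution of the L×L periodic Ising model.

    Returns (states, probabilities): states as (2^(L²), L, L) ±1 arrays,
    indexed so that flattening a 0/1 configuration MSB-first recovers the
    state index.  Only feasible for L <= 4.
    """
    n = L * L
    spins = rt.all_binary_states(n).astype(np.int64) * 2 - 1
    grids = spins.reshape(-1, L, L)
    energy = -(
        (grids * np.roll(grids, -1, axis=1)).sum(axis=(1, 2))
        + (grids * np.roll(grids, -1, axis=2)).sum(axis=(1, 2))
    )
    w = np.exp(-(energy - energy.min()) / T)
    return grids, w / w.sum()


def config_index(configurations: np.ndarray) -> np.ndarray:
    """State index of 0/1 lattice configurations (MSB-first flattening)."""
    flat = configurations.reshape(configurations.shape[0], -1).astype(np.int64)
    n = flat.shape[1]
    return flat @ (1 << np.arange(n - 1, -1, -1))
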