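"""Numba kernels for 2-D Ising sampling (periodic boundaries, J=1, k_B=1).

Both kernels target the Boltzmann distribution P(sigma) ∝ exp(+sum_<ij>
sigma_i sigma_j / T) over nearest-neighbour pairs of an L×L torus.  One
Swendsen-Wang step is a full bond percolation + cluster flip; one
Metropolis sweep is L² random single-site proposals.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _union(parent, i, j):
    ri = _find(parent, i)
    rj = _find(parent, j)
    if ri != rj:
        parent[rj] = ri


@njit(cache=True)
def run_swendsen_wang(L, T, n_samples, burn_in, thin, seed):
    np.random.seed(seed)
    n = L * L
    spins = np.empty(n, np.int8)
    for i in range(n):
        spins[i] = 1 if np.random.random() < 0.5 else -1
    p_bond = 1.0 - np.exp(-2.0 / T)
    out = np.empty((n_samples, n), np.int8)
    parent = np.empty(n, np.int64)
    new_spin = np.empty(n, np.int8)
    total = burn_in + n_samples * thin
    k = 0
    for sweep in range(total):
        for i in range(n):
            parent[i] = i
        for r in range(L):
            for c in range(L):
                i = r * L + c
                j = r * L + (c + 1) % L
                if spins[i] == spins[j] and np.random.random() < p_bond:
                    _union(parent, i, j)
                j = ((r + 1) % L) * L + c
                if spins[i] == spins[j] and np.random.random() < p_bond:
                    _union(parent, i, j)
        for i in range(n):
            new_spin[i] = 1 if np.random.random() < 0.5 else -1
        for i in range(n):
            spins[i] = new_spin[_find(parent, i)]
        if sweep >= burn_in and (sweep - burn_in + 1) % thin == 0:
            out[k] = spins
            k += 1
    return out


@njit(cache=True)
def run_metropolis(L, T, n_samples, burn_in, thin, seed):
    np.random.seed(seed)
    n = L * L
    spins = np.empty(n, np.int8)
    for i in range(n):
        spins[i] = 1 if np.random.random() < 0.5 else -1
    out = np.empty((n_samples, n), np.int8)
    total = burn_in + n_samples * thin
    k = 0
    for sweep in range(total):
        for _ in range(n):
            i = np.random.randint(0, n)
            r = i // L
            c = i % L
            nb = (
                spins[r * L + (c + 1) % L]
                + spins[r * L + (c - 1) % L]
                + spins[((r + 1) % L) * L + c]
                + spins[((r - 1) % L) * L + c]
            )
            dE = 2.0 * spins[i] * nb
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                spins[i] = -spins[i]
        if sweep >= burn_in and (sweep - burn_in + 1) % thin == 0:
            out[k] = spins
            k += 1
    return out
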