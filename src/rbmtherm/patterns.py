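"""Binary pattern datasets with empirical frequencies.

A :class:`PatternDataset` holds a stream of binary vectors (stimuli or
codewords) together with the empirical distribution over distinct patterns.
Pattern identity uses the fixed raster convention: element 0 of the vector
is the most significant bit of the pattern's bitstring representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PatternDataset", "pattern_bitstrings"]


def pattern_bitstrings(patterns: np.ndarray) -> list[str]:
    """Render binary row vectors as '0'/'1' strings (first cell leftmost)."""
    patterns = np.asarray(patterns, dtype=np.uint8)
    return ["".join("1" if b else "0" for b in row) for row in patterns]


@dataclass
class PatternDataset:
    """A set of binary visible vectors with empirical pattern frequencies.

    Parameters
    ----------
    vectors : (n, d) uint8 array
        The raw sample stream, one binary pattern per row.  Repetitions
        carry the empirical distribution.
    meta : dict
        Provenance (source type, seed, extraction parameters).
    """

    vectors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vectors, dtype=np.uint8))
        if v.ndim != 2 or v.shape[0] == 0:
            raise ValueError("vectors must be a non-empty 2-D binary array")
        if v.max(initial=0) > 1:
            raise ValueError("vectors must contain only 0/1 entries")
        self.vectors = v
        self._unique: np.ndarray | None = None
        self._counts: np.ndarray | None = None

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_visible(self) -> int:
        return self.vectors.shape[1]

    # -- empirical distribution -----------------------------------------
    def _tabulate(self) -> None:
        if self._unique is None:
            self._unique, self._counts = np.unique(
                self.vectors, axis=0, return_counts=True
            )

    @property
    def unique_patterns(self) -> np.ndarray:
        """Distinct patterns, lexicographically sorted, shape (k, d)."""
        self._tabulate()
        return self._unique

    @property
    def counts(self) -> np.ndarray:
        self._tabulate()
        return self._counts

    @property
    def frequencies(self) -> np.ndarray:
        """Empirical frequencies of the distinct patterns; sums to 1."""
        return self.counts / self.counts.sum()

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def pattern_index(self) -> np.ndarray:
        """Index into ``unique_patterns`` for every row of ``vectors``."""
        _, inverse = np.unique(self.vectors, axis=0, return_inverse=True)
        return inverse

    # -- constructors / views --------------------------------------------
    @classmethod
    def from_vectors(cls, vectors: np.ndarray, **meta) -> "PatternDataset":
        return cls(vectors=np.asarray(vectors, dtype=np.uint8), meta=dict(meta))

    def split(self, train_fraction: float, seed: int) -> tuple["PatternDataset", "PatternDataset"]:
        """Random train/held-out split of the sample stream."""
        if not 0.0 < train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        rng = np.random.default_rng(seed)
        order = rng.permutation(self.n_samples)
        cut = int(round(train_fraction * self.n_samples))
        if cut == 0 or cut == self.n_samples:
            raise ValueError("split leaves an empty part")
        return (
            PatternDataset(self.vectors[order[:cut]], {**self.meta, "split": "train"}),
            PatternDataset(self.vectors[order[cut:]], {**self.meta, "split": "heldout"}),
        )

    def subsample(self, n: int, seed: int) -> "PatternDataset":
        rng = np.random.default_rng(seed)
        idx = rng.choice(self.n_samples, size=min(n, self.n_samples), replace=False)
        return PatternDataset(self.vectors[idx], dict(self.meta))

    # -- export ----------------------------------------------------------
    def frequency_table(self) -> pd.DataFrame:
        """Frequency table sorted by descending count.

        Columns: ``pattern`` (bitstring, most-significant bit = first raster
        cell), ``count``, ``frequency``, ``energy_bits`` (= -log2 frequency).
        """
        freq = self.frequencies
        order = np.argsort(-self.counts, kind="stable")
        return pd.DataFrame(
            {
                "pattern": np.array(pattern_bitstrings(self.unique_patterns))[order],
                "count": self.counts[order],
                "frequency": freq[order],
                "energy_bits": -np.log2(freq[order]),
            }
        )
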