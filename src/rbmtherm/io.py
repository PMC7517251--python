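"""HDF5 serialization for models, sample sets and datasets.

Every container writes one group with array datasets plus scalar/string
attributes for metadata, so artifacts are portable and self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .patterns import PatternDataset
from .rbm_core import ModelParams, StateSampleSet
from .synthetic_data import LatticeSampleSet

__all__ = [
    "save_model",
    "load_model",
    "save_lattice",
    "load_lattice",
    "save_patterns",
    "load_patterns",
    "save_states",
    "load_states",
]


def _write_meta(group: h5py.Group, meta: dict) -> None:
    group.attrs["meta_json"] = json.dumps(meta, default=str)


def _read_meta(group: h5py.Group) -> dict:
    raw = group.attrs.get("meta_json", "{}")
    return json.loads(raw)


def save_model(path: str | Path, params: ModelParams) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("model")
        g.create_dataset("W", data=params.W)
        g.create_dataset("Bh", data=params.Bh)
        g.create_dataset("Bv", data=params.Bv)
        g.attrs["beta"] = params.beta
        _write_meta(g, params.meta)


def load_model(path: str | Path) -> ModelParams:
    with h5py.File(path, "r") as f:
        g = f["model"]
        return ModelParams(
            W=g["W"][()],
            Bh=g["Bh"][()],
            Bv=g["Bv"][()],
            beta=float(g.attrs["beta"]),
            meta=_read_meta(g),
        )


def save_lattice(path: str | Path, lattice: LatticeSampleSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("lattice")
        g.create_dataset("configurations", data=lattice.configurations, compression="gzip")
        g.attrs["temperature"] = lattice.temperature
        _write_meta(g, lattice.sampler_meta)


def load_lattice(path: str | Path) -> LatticeSampleSet:
    with h5py.File(path, "r") as f:
        g = f["lattice"]
        return LatticeSampleSet(
            configurations=g["configurations"][()],
            temperature=float(g.attrs["temperature"]),
            sampler_meta=_read_meta(g),
        )


def save_patterns(path: str | Path, data: PatternDataset) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("patterns")
        g.create_dataset("vectors", data=data.vectors, compression="gzip")
        _write_meta(g, data.meta)


def load_patterns(path: str | Path) -> PatternDataset:
    with h5py.File(path, "r") as f:
        g = f["patterns"]
        return PatternDataset(vectors=g["vectors"][()], meta=_read_meta(g))


def save_states(path: str | Path, states: StateSampleSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("states")
        g.create_dataset("hidden", data=states.hidden_states, compression="gzip")
        g.create_dataset("visible", data=states.visible_states, compression="gzip")
        _write_meta(g, states.chain_meta)


def load_states(path: str | Path) -> StateSampleSet:
    with h5py.File(path, "r") as f:
        g = f["states"]
        return StateSampleSet(
            hidden_states=g["hidden"][()],
            visible_states=g["visible"][()],
            chain_meta=_read_meta(g),
        )
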