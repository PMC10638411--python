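"""Lossless HDF5 snapshots of network state, with embedded configuration."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .config import RunConfig, _from_dict, _to_dict
from .netarch import ArchitectureConfig, NetworkState

__all__ = ["save_network", "load_network", "SchemaError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_ARRAYS = ("out_indptr", "out_tgt", "w", "plastic", "proj_id",
           "in_indptr", "in_pos", "in_src", "pool_indptr", "pool_tgt",
           "V", "O", "adapt", "homeo", "I_pot", "G", "lesion_mask", "area_of")


class SchemaError(RuntimeError):
    """Snapshot missing, corrupted, or written by an incompatible version."""


def save_network(net: NetworkState, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["seed"] = net.seed
        f.attrs["architecture"] = json.dumps(_to_dict(net.config))
        f.attrs["projections"] = json.dumps(net.projections)
        g = f.create_group("state")
        for name in _ARRAYS:
            g.create_dataset(name, data=getattr(net, name))


def load_network(path) -> NetworkState:
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise SchemaError(
                    f"snapshot schema {version} != supported {SCHEMA_VERSION}")
            config = _from_dict(ArchitectureConfig, json.loads(f.attrs["architecture"]))
            projections = [tuple(p) for p in json.loads(f.attrs["projections"])]
            arrays = {name: f["state"][name][...] for name in _ARRAYS}
            for name in ("plastic", "lesion_mask"):
                arrays[name] = arrays[name].astype(bool)
            seed = int(f.attrs["seed"])
    except (OSError, KeyError) as exc:
        raise SchemaError(f"cannot read network snapshot {path}: {exc}") from exc
    return NetworkState(
        config=config, areas=config.area_specs(), seed=seed,
        projections=projections,
        **{name: np.asarray(arr) for name, arr in arrays.items()},
    )
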