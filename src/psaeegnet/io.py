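"""File formats: epoch archives (HDF5 / NPZ), network checkpoints, YAML config.

Epoch files carry datasets ``epochs`` (float32, trials x channels x samples)
and ``labels`` (int8) plus the sampling rate and optional channel ids.
Checkpoints are single NPZ archives holding every named parameter array,
batch-norm running statistics, the network configuration as YAML text and a
format version, so a network reloads without re-specifying its config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .attention import PSAConfig
from .network import Network, NetworkConfig
from .preprocessing import EpochSet
from .training import TrainConfig

CHECKPOINT_VERSION = 1


# ---- epoch files ----------------------------------------------------------

def save_epochs(path, epochs: EpochSet, channel_ids=None) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, epochs=epochs.epochs.astype(np.float32),
                 labels=epochs.labels.astype(np.int8),
                 sampling_rate=np.float64(epochs.sampling_rate),
                 channel_ids=np.asarray(channel_ids if channel_ids is not None
                                        else range(1, epochs.n_channels + 1)))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int8))
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["channel_ids"] = np.asarray(
            channel_ids if channel_ids is not None
            else range(1, epochs.n_channels + 1))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return EpochSet(z["epochs"], z["labels"], float(z["sampling_rate"]))
    with h5py.File(path, "r") as f:
        return EpochSet(f["epochs"][...], f["labels"][...],
                        float(f.attrs["sampling_rate"]))


# ---- network checkpoints --------------------------------------------------

def _config_to_dict(config: NetworkConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("psa_psfe", "psa_dtfe"):
        if d[key] is not None:
            d[key]["kernel_sizes"] = list(d[key]["kernel_sizes"])
    if d["pool_out_lengths"] is not None:
        d["pool_out_lengths"] = list(d["pool_out_lengths"])
    return d


def config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    for key in ("psa_psfe", "psa_dtfe"):
        if d.get(key) is not None:
            sub = dict(d[key])
            sub["kernel_sizes"] = tuple(sub["kernel_sizes"])
            d[key] = PSAConfig(**sub)
    if d.get("pool_out_lengths") is not None:
        d["pool_out_lengths"] = tuple(d["pool_out_lengths"])
    return NetworkConfig(**d)


def save_checkpoint(path, net: Network) -> None:
    state = net.get_state()
    meta = {"config_yaml": yaml.safe_dump(_config_to_dict(net.config)),
            "version": CHECKPOINT_VERSION}
    arrays = {f"state/{k}": v for k, v in state.items()}
    np.savez(path, __meta__=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_checkpoint(path) -> Network:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = config_from_dict(yaml.safe_load(meta["config_yaml"]))
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    net = Network(config, seed=0)
    net.set_state(state)
    return net


# ---- YAML run configuration ----------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def network_config_from_yaml(section: dict | None) -> NetworkConfig:
    """Build a NetworkConfig from the ``network:`` YAML section.

    Recognised keys mirror the dataclass fields; ``psa_psfe`` / ``psa_dtfe``
    may be kernel lists, full mappings, or null to disable a block.
    """
    section = dict(section or {})
    for key in ("psa_psfe", "psa_dtfe"):
        if key in section:
            v = section[key]
            if v is None:
                section[key] = None
            elif isinstance(v, (list, tuple)):
                section[key] = PSAConfig(tuple(v))
            elif isinstance(v, dict):
                v = dict(v)
                v["kernel_sizes"] = tuple(v.get("kernel_sizes", (3, 5, 7, 9)))
                section[key] = PSAConfig(**v)
    if section.get("pool_out_lengths") is not None:
        section["pool_out_lengths"] = tuple(section["pool_out_lengths"])
    return NetworkConfig(**section)


def train_config_from_yaml(section: dict | None) -> TrainConfig:
    return TrainConfig(**(section or {}))
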