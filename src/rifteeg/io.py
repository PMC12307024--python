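"""Reading and writing epochs, montages and simulation configs.

Epoch container (HDF5, one file per participant)
------------------------------------------------
dataset  ``data``       float64, (trial, channel, sample), µV
dataset  ``condition``  UTF-8 strings, one label per trial
attrs    ``sample_rate`` Hz, ``t_start`` s, ``participant_id``,
         ``montage_json`` (the montage serialized as JSON)

Configs are plain YAML or JSON mappings of :class:`~rifteeg.simulate.SimConfig`
fields; ``seed`` is mandatory.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .montage import Montage
from .simulate import CONDITIONS, EpochSet, SimConfig, TagConfig

__all__ = ["write_epochs", "read_epochs", "load_sim_config", "dump_sim_config"]


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write one participant's EpochSet to the documented HDF5 layout."""
    montage_payload = {
        "channels": list(epochs.montage.channel_names),
        "adjacency": sorted(sorted(p) for p in epochs.montage.adjacency),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "condition",
            data=np.array([str(c) for c in epochs.condition],
                          dtype=h5py.string_dtype("utf-8")),
        )
        f.attrs["sample_rate"] = epochs.sample_rate
        f.attrs["t_start"] = epochs.t_start
        f.attrs["participant_id"] = epochs.participant_id
        f.attrs["montage_json"] = json.dumps(montage_payload)


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`.

    Raises ``ValueError`` naming the offending field on malformed files.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot open epoch container {path}: {exc}") from exc
    with f:
        for name in ("data", "condition"):
            if name not in f:
                raise ValueError(f"epoch container missing dataset {name!r}")
        for name in ("sample_rate", "t_start", "participant_id", "montage_json"):
            if name not in f.attrs:
                raise ValueError(f"epoch container missing attribute {name!r}")
        data = f["data"][()]
        condition = np.array([c.decode() if isinstance(c, bytes) else str(c)
                              for c in f["condition"][()]], dtype=object)
        unknown = set(condition) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition label(s) {sorted(unknown)}")
        payload = json.loads(f.attrs["montage_json"])
        montage = Montage(channel_names=tuple(payload["channels"]),
                          adjacency=frozenset(frozenset(p)
                                              for p in payload["adjacency"]))
        return EpochSet(data=data, condition=condition,
                        participant_id=str(f.attrs["participant_id"]),
                        sample_rate=float(f.attrs["sample_rate"]),
                        t_start=float(f.attrs["t_start"]), montage=montage)


_TAG_FIELDS = ("f_audio", "f_visual", "modulation_depth", "phase_at_onset",
               "sample_rate")
_CFG_FIELDS = ("n_participants", "n_trials_per_condition", "amp_audio",
               "amp_visual", "g_related", "g_unrelated", "noise_exponent",
               "alpha_amp", "noise_sd", "participant_sigma", "seed",
               "baseline_duration", "tagging_duration", "sample_rate")


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from YAML/JSON; ``seed`` is required."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    if "seed" not in raw:
        raise ValueError("config must specify an integer 'seed'")
    kwargs = {k: raw[k] for k in _CFG_FIELDS if k in raw}
    if "tag" in raw:
        kwargs["tag"] = TagConfig(**{k: raw["tag"][k] for k in _TAG_FIELDS
                                     if k in raw["tag"]})
    for name in ("topo_audio", "topo_visual", "topo_im"):
        if raw.get(name) is not None:
            kwargs[name] = np.asarray(raw[name], dtype=float)
    return SimConfig(**kwargs)


def dump_sim_config(cfg: SimConfig, path: str | Path) -> None:
    """Write a SimConfig (without the montage) back to YAML."""
    payload: dict = {k: getattr(cfg, k) for k in _CFG_FIELDS}
    payload["tag"] = {k: getattr(cfg.tag, k) for k in _TAG_FIELDS}
    for name in ("topo_audio", "topo_visual", "topo_im"):
        payload[name] = [float(x) for x in getattr(cfg, name)]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
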