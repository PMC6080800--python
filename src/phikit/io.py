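"""Network files and result serialization.

Network files are JSON or YAML mappings with keys:

``tpm``
    Nested lists in state-by-node (``2^n x n``), state-by-state
    (``2^n x 2^n``), or multidimensional form.  The form is auto-detected
    from the shape; a 4x4 matrix requires an explicit ``tpm_format`` key
    (``"sbn"`` or ``"sbs"``).
``cm``
    Optional nested lists (n x n binary).
``labels``
    Optional list of node names.

Results (system analyses, concepts) serialize to JSON-compatible dicts that
round-trip losslessly through :func:`load_result`.
"""

from __future__ import annotations

import json
import os

import numpy as np
import yaml

from .network import Network

__all__ = [
    "network_from_dict",
    "network_to_dict",
    "load_network",
    "save_network",
    "save_result",
    "load_result",
]


def network_from_dict(data: dict) -> Network:
    if "tpm" not in data:
        raise ValueError("network description must contain a 'tpm' key")
    unknown = set(data) - {"tpm", "cm", "labels", "tpm_format"}
    if unknown:
        raise ValueError(f"unknown network file keys: {sorted(unknown)}")
    return Network(
        np.array(data["tpm"], dtype=float),
        cm=np.array(data["cm"]) if data.get("cm") is not None else None,
        labels=data.get("labels"),
        tpm_format=data.get("tpm_format"),
    )


def network_to_dict(network: Network, tpm_form: str = "sbn") -> dict:
    from .tpm import multidim_to_sbn, sbn_to_sbs

    sbn = multidim_to_sbn(network.tpm)
    tpm = sbn if tpm_form == "sbn" else sbn_to_sbs(sbn)
    out = {
        "tpm": tpm.tolist(),
        "cm": network.cm.tolist(),
        "labels": list(network.labels),
    }
    if tpm.shape == (4, 4):
        out["tpm_format"] = tpm_form
    return out


def load_network(path: str | os.PathLike) -> Network:
    """Read a network from a JSON or YAML file."""
    with open(path) as f:
        text = f.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"network file {path} must contain a mapping")
    return network_from_dict(data)


def save_network(network: Network, path: str | os.PathLike, tpm_form: str = "sbn"):
    data = network_to_dict(network, tpm_form=tpm_form)
    with open(path, "w") as f:
        if str(path).endswith((".yml", ".yaml")):
            yaml.safe_dump(data, f)
        else:
            json.dump(data, f, indent=2)


def save_result(result: dict, path: str | os.PathLike):
    with open(path, "w") as f:
        json.dump(result, f, indent=2)


def load_result(path: str | os.PathLike) -> dict:
    with open(path) as f:
        return json.load(f)
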