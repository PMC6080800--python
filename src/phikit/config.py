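"""Analysis configuration.

The defaults reproduce the canonical worked example: exact EMD repertoire
distance with a Hamming ground metric, the extended-EMD distance between
cause-effect structures, exhaustive unidirectional bipartition system cuts,
and φ/Φ rounded to 6 decimal places.  Alternative distance measures and
partition schemes are registry hooks: selecting an unregistered name raises.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import yaml

__all__ = [
    "Config",
    "load_config",
    "DEFAULT_CONFIG_FILENAME",
    "REPERTOIRE_DISTANCES",
    "CES_DISTANCES",
    "PARTITION_SCHEMES",
]

#: File auto-discovered in the working directory unless discovery is disabled.
DEFAULT_CONFIG_FILENAME = "phikit_config.yml"

# Registries: names -> implemented flag.  Only the defaults ship; the hooks
# exist so configurations naming an alternative fail loudly, not silently.
REPERTOIRE_DISTANCES = {"emd": True, "kld": False, "l1": False}
CES_DISTANCES = {"extended_emd": True, "sum_small_phi": False}
PARTITION_SCHEMES = {"bipartition": True, "wedge": False, "all": False}


@dataclass(frozen=True)
class Config:
    repertoire_distance: str = "emd"
    ces_distance: str = "extended_emd"
    partition_scheme: str = "bipartition"
    cut_one: bool = False
    no_new_concepts: bool = False
    precision: int = 6
    parallel: bool = False
    seed: int | None = None

    def __post_init__(self):
        for name, registry in (
            ("repertoire_distance", REPERTOIRE_DISTANCES),
            ("ces_distance", CES_DISTANCES),
            ("partition_scheme", PARTITION_SCHEMES),
        ):
            value = getattr(self, name)
            if value not in registry:
                raise ValueError(
                    f"unknown {name} {value!r}; registered: {sorted(registry)}"
                )
            if not registry[value]:
                raise NotImplementedError(
                    f"{name} {value!r} is a registry hook without an implementation"
                )
        if self.precision < 0:
            raise ValueError("precision must be nonnegative")

    def with_updates(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


_VALID_KEYS = {f.name for f in fields(Config)}


def _from_mapping(mapping: Mapping[str, Any]) -> Config:
    unknown = set(mapping) - _VALID_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration keys {sorted(unknown)}; "
            f"valid keys are {sorted(_VALID_KEYS)}"
        )
    return Config(**dict(mapping))


def load_config(source: str | os.PathLike | Mapping[str, Any] | None = None,
                auto_discover: bool = True) -> Config:
    """Build a :class:`Config` from a mapping, a YAML/JSON file, or defaults.

    With ``source=None`` and ``auto_discover=True``, a file named
    ``phikit_config.yml`` in the current directory is loaded if present;
    otherwise the defaults are used.  Unknown keys are rejected with the list
    of valid keys.
    """
    if source is None:
        if auto_discover and os.path.exists(DEFAULT_CONFIG_FILENAME):
            source = DEFAULT_CONFIG_FILENAME
        else:
            return Config()
    if isinstance(source, Mapping):
        return _from_mapping(source)
    with open(source) as f:
        data = yaml.safe_load(f)  # YAML is a superset of JSON
    if data is None:
        return Config()
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {source} must contain a mapping")
    return _from_mapping(data)
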