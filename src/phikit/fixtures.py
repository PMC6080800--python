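"""Example and seeded random networks.

:func:`example_network` builds the canonical 3-node deterministic system

* A = OR(B, C)
* B = AND(A, C)
* C = XOR(A, B)

with no self-connections, analyzed in state (A, B, C) = (1, 0, 0).

:func:`random_network` generates reproducible fixtures from a
:class:`FixtureSpec`:

* ``random_boolean`` -- each node draws its parent set (each candidate
  parent included with probability ``density``) and a random Boolean truth
  table over those parents; the output is flipped with probability
  ``noise``.
* ``noisy_majority_chain`` -- a circular chain of bidirectional edges where
  each node computes the majority of its two neighbors (ties -> 0.5) and
  flips its output with probability ``noise``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network
from .tpm import all_states

__all__ = ["FixtureSpec", "example_network", "random_network", "EXAMPLE_STATE"]

#: The canonical analysis state of the example network.
EXAMPLE_STATE = (1, 0, 0)


def example_network() -> Network:
    """The 3-node OR/AND/XOR network (labels A, B, C; no self-loops)."""
    rows = []
    for a, b, c in all_states(3):
        rows.append([int(b or c), int(a and c), int(a != b)])
    cm = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
    return Network(np.array(rows, dtype=float), cm=cm, labels=("A", "B", "C"))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible random network fixture."""

    kind: str = "random_boolean"
    n: int = 3
    density: float = 0.5
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("example", "random_boolean", "noisy_majority_chain"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if not 0 <= self.density <= 1:
            raise ValueError("density must be in [0, 1]")
        if not 0 <= self.noise <= 0.5:
            raise ValueError("noise (flip probability) must be in [0, 0.5]")
        if self.n < 1:
            raise ValueError("n must be positive")


def _flip(p_on: np.ndarray, noise: float) -> np.ndarray:
    return p_on * (1 - noise) + (1 - p_on) * noise


def _random_boolean(spec: FixtureSpec) -> Network:
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cm = np.zeros((n, n), dtype=int)
    # parent sets first so the draw order is stable
    parents = []
    for j in range(n):
        mask = rng.random(n) < spec.density
        parents.append(np.flatnonzero(mask))
        cm[mask, j] = 1
    tables = [rng.integers(0, 2, size=2 ** len(p)).astype(float) for p in parents]
    rows = np.zeros((2**n, n))
    for i, state in enumerate(all_states(n)):
        for j in range(n):
            sub = sum(state[p] << k for k, p in enumerate(parents[j]))
            rows[i, j] = _flip(tables[j][sub], spec.noise)
    return Network(rows, cm=cm)


def _majority_chain(spec: FixtureSpec) -> Network:
    n = spec.n
    if n < 3:
        raise ValueError("a circular chain needs at least 3 nodes")
    cm = np.zeros((n, n), dtype=int)
    for j in range(n):
        cm[(j - 1) % n, j] = 1
        cm[(j + 1) % n, j] = 1
    rows = np.zeros((2**n, n))
    for i, state in enumerate(all_states(n)):
        for j in range(n):
            on = state[(j - 1) % n] + state[(j + 1) % n]
            p = 1.0 if on == 2 else (0.0 if on == 0 else 0.5)
            rows[i, j] = _flip(p, spec.noise)
    return Network(rows, cm=cm)


def random_network(spec: FixtureSpec) -> Network:
    """Build the network described by a :class:`FixtureSpec` (same seed,
    same network)."""
    if spec.kind == "example":
        return example_network()
    if spec.kind == "random_boolean":
        return _random_boolean(spec)
    return _majority_chain(spec)
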