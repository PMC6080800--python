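"""Transition-probability-matrix algebra for binary-element networks.

A discrete Markovian dynamical system of ``n`` binary elements is fully
specified by its transition probability matrix (TPM).  Three interconvertible
representations are supported:

* **state-by-state** -- a ``2^n x 2^n`` matrix whose entry ``(i, k)`` is
  ``Pr(S_{t+1} = k | S_t = i)``;
* **state-by-node** -- a ``2^n x n`` matrix whose entry ``(i, j)`` is
  ``Pr(node j ON at t+1 | S_t = i)``; valid only under conditional
  independence of the elements' next states;
* **multidimensional state-by-node** -- the state-by-node matrix reshaped to
  an ``(2,)*n + (n,)`` tensor so a state tuple indexes it directly.

State indexing is little-endian throughout: the *first* node's state is the
least-significant bit, so state ``(0, 0, 0, 1)`` has index 8.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "PROB_TOL",
    "state_to_index",
    "index_to_state",
    "all_states",
    "check_conditional_independence",
    "sbs_to_sbn",
    "sbn_to_sbs",
    "sbn_to_multidim",
    "multidim_to_sbn",
    "condition_tpm",
    "marginalize_out",
    "infer_tpm_form",
    "to_multidim",
]

#: Absolute tolerance for row-sum and conditional-independence checks.
PROB_TOL = 1e-10

SystemState = tuple[int, ...]


def _validate_state(state: Sequence[int]) -> SystemState:
    state = tuple(int(s) for s in state)
    if any(s not in (0, 1) for s in state):
        raise ValueError(f"invalid state {state!r}: entries must be 0 or 1")
    return state


def state_to_index(state: Sequence[int]) -> int:
    """Map a binary state tuple to its little-endian row index.

    The first node is the least-significant bit: ``(0, 0, 0, 1) -> 8``.
    """
    state = _validate_state(state)
    return sum(s << k for k, s in enumerate(state))


def index_to_state(index: int, n: int) -> SystemState:
    """Inverse of :func:`state_to_index` for an ``n``-node system."""
    index = int(index)
    if not 0 <= index < 2**n:
        raise ValueError(f"index {index} out of range for {n} nodes")
    return tuple((index >> k) & 1 for k in range(n))


def all_states(n: int) -> Iterator[SystemState]:
    """Iterate over all ``2^n`` states in little-endian index order."""
    for i in range(2**n):
        yield index_to_state(i, n)


def _validate_sbs(tpm: np.ndarray) -> np.ndarray:
    tpm = np.asarray(tpm, dtype=float)
    if tpm.ndim != 2 or tpm.shape[0] != tpm.shape[1]:
        raise ValueError(f"state-by-state TPM must be square, got {tpm.shape}")
    n = int(np.log2(tpm.shape[0]))
    if 2**n != tpm.shape[0] or n == 0:
        raise ValueError(f"state count {tpm.shape[0]} is not a power of 2 (>= 2)")
    if np.any(tpm < -PROB_TOL) or np.any(tpm > 1 + PROB_TOL):
        raise ValueError("TPM entries must lie in [0, 1]")
    if not np.allclose(tpm.sum(axis=1), 1.0, atol=PROB_TOL, rtol=0):
        raise ValueError("state-by-state TPM rows must sum to 1")
    return tpm


def _validate_sbn(tpm: np.ndarray) -> np.ndarray:
    tpm = np.asarray(tpm, dtype=float)
    if tpm.ndim != 2:
        raise ValueError(f"state-by-node TPM must be 2-D, got shape {tpm.shape}")
    rows, n = tpm.shape
    if n == 0 or rows != 2**n:
        raise ValueError(
            f"state-by-node TPM must have 2^n rows for n columns, got {tpm.shape}"
        )
    if np.any(tpm < -PROB_TOL) or np.any(tpm > 1 + PROB_TOL):
        raise ValueError("TPM entries must lie in [0, 1]")
    return tpm


def _sbs_node_marginals(tpm: np.ndarray) -> np.ndarray:
    """Per-row ON-probability of each node implied by a state-by-state TPM."""
    n = int(np.log2(tpm.shape[0]))
    # column k of the next-state axis has node j ON iff bit j of k is set
    bits = np.array([[(k >> j) & 1 for j in range(n)] for k in range(2**n)])
    return tpm @ bits  # (2^n, n)


def check_conditional_independence(tpm: np.ndarray) -> bool:
    """Whether each row's joint next-state distribution factorizes over nodes.

    Conditional independence -- every element's next state depends only on the
    current system state, not on the other elements' next states -- is what
    licenses the compact state-by-node representation.
    """
    tpm = _validate_sbs(tpm)
    return bool(np.allclose(tpm, sbn_to_sbs(_sbs_node_marginals(tpm)), atol=PROB_TOL, rtol=0))


def sbs_to_sbn(tpm: np.ndarray) -> np.ndarray:
    """Convert a state-by-state TPM to state-by-node form.

    Raises ``ValueError`` if the TPM violates conditional independence (the
    Markov factorization over elements), since the state-by-node form cannot
    represent correlated next-state noise.
    """
    tpm = _validate_sbs(tpm)
    if not check_conditional_independence(tpm):
        raise ValueError(
            "TPM violates conditional independence: the joint next-state "
            "distribution does not factorize over nodes, so it has no "
            "state-by-node representation"
        )
    return _sbs_node_marginals(tpm)


def sbn_to_sbs(tpm: np.ndarray) -> np.ndarray:
    """Expand a state-by-node TPM to state-by-state form under independence."""
    tpm = _validate_sbn(tpm)
    rows, n = tpm.shape
    sbs = np.ones((rows, rows))
    for k in range(rows):
        bits = index_to_state(k, n)
        for j, b in enumerate(bits):
            sbs[:, k] *= tpm[:, j] if b else 1 - tpm[:, j]
    return sbs


def sbn_to_multidim(tpm: np.ndarray) -> np.ndarray:
    """Reshape a 2-D state-by-node TPM to its multidimensional form.

    Column-major (Fortran) order makes the first node's axis the
    fastest-varying, preserving the little-endian convention.
    """
    tpm = _validate_sbn(tpm)
    n = tpm.shape[1]
    return tpm.reshape([2] * n + [n], order="F")


def multidim_to_sbn(tpm: np.ndarray) -> np.ndarray:
    """Inverse of :func:`sbn_to_multidim` (requires full, unconditioned axes)."""
    tpm = np.asarray(tpm, dtype=float)
    n = tpm.shape[-1]
    if tpm.ndim != n + 1 or tpm.shape[:-1] != (2,) * n:
        raise ValueError(
            f"multidimensional TPM must have shape {(2,) * n + (n,)}, got {tpm.shape}"
        )
    return tpm.reshape((2**n, n), order="F")


def condition_tpm(
    tpm: np.ndarray, fixed_nodes: Iterable[int], state: Sequence[int]
) -> np.ndarray:
    """Condition a multidimensional TPM on the current state of some nodes.

    The fixed nodes' axes are sliced to the matching state value and kept as
    singleton dimensions; already-singleton axes are left alone.  ``state`` is
    the state of the *whole* system (only the fixed nodes' entries are read).
    """
    tpm = np.asarray(tpm, dtype=float)
    n_axes = tpm.ndim - 1
    for node in fixed_nodes:
        node = int(node)
        if not 0 <= node < n_axes:
            raise IndexError(f"node index {node} out of range for {n_axes} state axes")
        if tpm.shape[node] == 1:
            continue
        # one axis at a time: np.take keeps the axis as a singleton and
        # avoids numpy's advanced-index broadcasting across multiple axes
        tpm = np.take(tpm, [int(state[node])], axis=node)
    return tpm


def marginalize_out(tpm: np.ndarray, nodes: Iterable[int]) -> np.ndarray:
    """Average a multidimensional TPM over the named nodes' current-state axes.

    Uses the unweighted mean, i.e. the uniform interventional distribution
    over perturbed states; axes are kept as singletons.
    """
    tpm = np.asarray(tpm, dtype=float)
    n_axes = tpm.ndim - 1
    nodes = sorted({int(i) for i in nodes})
    for node in nodes:
        if not 0 <= node < n_axes:
            raise IndexError(f"node index {node} out of range for {n_axes} state axes")
    if not nodes:
        return tpm
    return tpm.mean(axis=tuple(nodes), keepdims=True)


def infer_tpm_form(tpm: np.ndarray, tpm_format: str | None = None) -> str:
    """Classify a raw TPM array as ``'sbn'``, ``'sbs'`` or ``'multidim'``.

    A 4x4 matrix requires an explicit ``tpm_format`` ('sbn' or 'sbs').
    """
    tpm = np.asarray(tpm, dtype=float)
    if tpm_format is not None:
        if tpm_format not in ("sbn", "sbs", "multidim"):
            raise ValueError(f"unknown tpm_format {tpm_format!r}")
        return tpm_format
    if tpm.ndim > 2:
        return "multidim"
    if tpm.ndim != 2:
        raise ValueError(f"TPM must be at least 2-D, got shape {tpm.shape}")
    rows, cols = tpm.shape
    if (rows, cols) == (4, 4):
        raise ValueError(
            "a 4x4 TPM is ambiguous; pass tpm_format='sbn' or 'sbs' explicitly"
        )
    if rows == cols:
        return "sbs"
    if rows == 2**cols:
        return "sbn"
    raise ValueError(f"cannot interpret TPM of shape {tpm.shape}")


def to_multidim(tpm: np.ndarray, tpm_format: str | None = None) -> np.ndarray:
    """Canonicalize any supported TPM form to the multidimensional form."""
    tpm = np.asarray(tpm, dtype=float)
    form = infer_tpm_form(tpm, tpm_format)
    if form == "sbs":
        tpm = sbs_to_sbn(tpm)
        form = "sbn"
    if form == "sbn":
        return sbn_to_multidim(_validate_sbn(tpm))
    # multidim: validate via round-trip
    return sbn_to_multidim(multidim_to_sbn(tpm))
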