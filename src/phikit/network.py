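"""Networks, candidate subsystems, per-node TPMs, and system-cut surgery.

A :class:`Network` holds the full system's TPM (canonically in
multidimensional state-by-node form), a connectivity matrix, and node labels.
A :class:`Subsystem` is a candidate system: a subset of the network's nodes
analyzed in a particular system state, with the nodes outside the subset
treated as *background conditions* -- fixed in their current state at ``t``
(the TPM is conditioned on them) and ignored at ``t+1`` (their columns are
dropped).

Each subsystem node carries its own :class:`NodeTPM`: the probability that
the node is ON at ``t+1`` as a tensor over its parents' current states.  A
:class:`SystemCut` severs all edges from one part of the subsystem into the
other; cutting is performed by marginalizing the severed sources out of the
target nodes' TPMs, which makes each severed source appear as independent
noise to its target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tpm as _tpm
from .tpm import SystemState, condition_tpm, marginalize_out, to_multidim

__all__ = ["Network", "Subsystem", "NodeTPM", "SystemCut", "apply_cut"]


def default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


@dataclass(frozen=True)
class Network:
    """A discrete dynamical system of binary elements.

    Parameters
    ----------
    tpm:
        Any supported TPM form; stored canonically as the multidimensional
        state-by-node tensor.
    cm:
        Optional n x n binary connectivity matrix, ``cm[i, j] = 1`` iff there
        is an edge from node ``i`` to node ``j``.  Defaults to full
        connectivity, which is always safe (an over-complete CM can only
        forgo optimizations; an incorrect one can corrupt the analysis).
    labels:
        Optional node names; cosmetic only.
    """

    tpm: np.ndarray
    cm: np.ndarray
    labels: tuple[str, ...]

    def __init__(self, tpm, cm=None, labels=None, tpm_format: str | None = None):
        md = to_multidim(tpm, tpm_format)
        n = md.shape[-1]
        if cm is None:
            cm = np.ones((n, n), dtype=int)
        else:
            cm = np.asarray(cm)
            if cm.shape != (n, n):
                raise ValueError(f"cm shape {cm.shape} does not match n={n}")
            if not np.isin(cm, (0, 1)).all():
                raise ValueError("cm entries must be 0 or 1")
            cm = cm.astype(int)
        if labels is None:
            labels = default_labels(n)
        else:
            labels = tuple(str(l) for l in labels)
            if len(labels) != n:
                raise ValueError(f"{len(labels)} labels given for {n} nodes")
        object.__setattr__(self, "tpm", md)
        object.__setattr__(self, "cm", cm)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.tpm.shape[-1]

    @property
    def node_indices(self) -> tuple[int, ...]:
        return tuple(range(self.n))

    def parse_nodes(self, nodes) -> tuple[int, ...]:
        """Resolve a mixed list of labels/indices to sorted node indices."""
        out = []
        for node in nodes:
            if isinstance(node, str):
                if node not in self.labels:
                    raise ValueError(f"unknown node label {node!r}")
                out.append(self.labels.index(node))
            else:
                idx = int(node)
                if not 0 <= idx < self.n:
                    raise IndexError(f"node index {idx} out of range")
                out.append(idx)
        return tuple(sorted(set(out)))

    def __eq__(self, other):
        return (
            isinstance(other, Network)
            and np.array_equal(self.tpm, other.tpm)
            and np.array_equal(self.cm, other.cm)
        )

    def __hash__(self):
        return hash((self.tpm.tobytes(), self.cm.tobytes()))


@dataclass(frozen=True)
class NodeTPM:
    """Per-node TPM: Pr(node ON at t+1) over its parents' current states.

    ``tensor`` has one axis per network node; axes are of size 2 exactly at
    the node's parents (per the subsystem's connectivity matrix) and
    singletons elsewhere.
    """

    node: int
    tensor: np.ndarray

    @property
    def parents(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.tensor.shape) if s == 2)


@dataclass(frozen=True)
class SystemCut:
    """A unidirectional bipartition cut severing all edges from_part -> to_part."""

    from_part: tuple[int, ...]
    to_part: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "from_part", tuple(sorted(self.from_part)))
        object.__setattr__(self, "to_part", tuple(sorted(self.to_part)))
        if not self.from_part or not self.to_part:
            raise ValueError("both cut parts must be nonempty")
        if set(self.from_part) & set(self.to_part):
            raise ValueError("cut parts must be disjoint")

    def severed_edges(self, cm: np.ndarray) -> list[tuple[int, int]]:
        """Edges actually removed by this cut, given a connectivity matrix."""
        return [
            (a, b) for a in self.from_part for b in self.to_part if cm[a, b]
        ]

    def indices(self) -> tuple[int, ...]:
        return tuple(sorted(self.from_part + self.to_part))


class Subsystem:
    """A candidate system: node subset + state + background-conditioned TPM.

    The subsystem TPM keeps one (possibly singleton) state axis per *network*
    node -- external nodes' axes are conditioned down to singletons -- and its
    last axis ranges over the member nodes in ascending index order.
    Mechanisms and purviews are given as network node indices.
    """

    def __init__(self, network: Network, state, nodes=None, _internal=None):
        self.network = network
        self.state: SystemState = _tpm._validate_state(state)
        if len(self.state) != network.n:
            raise ValueError(
                f"state length {len(self.state)} does not match network n={network.n}"
            )
        if nodes is None:
            nodes = network.node_indices
        self.nodes: tuple[int, ...] = network.parse_nodes(nodes)
        if not self.nodes:
            raise ValueError("subsystem must contain at least one node")
        self.external: tuple[int, ...] = tuple(
            i for i in network.node_indices if i not in self.nodes
        )

        if _internal is not None:
            # used by apply_cut: node TPMs and cm already prepared
            self.tpm, self.cm, self.node_tpms = _internal
        else:
            tpm = condition_tpm(network.tpm, self.external, self.state)
            self.tpm = tpm[..., list(self.nodes)]
            self.cm = network.cm.copy()
            # sever edges from/to external nodes in the restricted view
            for i in self.external:
                self.cm[i, :] = 0
                self.cm[:, i] = 0
            self.node_tpms = {i: self._extract_node_tpm(i) for i in self.nodes}
        self._repertoire_cache: dict = {}

    # ------------------------------------------------------------------
    def _extract_node_tpm(self, node: int) -> NodeTPM:
        if node not in self.nodes:
            raise ValueError(f"node {node} is not a subsystem member")
        pos = self.nodes.index(node)
        p_on = self.tpm[..., pos]
        # canonicalize: nodes that the cm says are not parents are averaged
        # out (a no-op when the cm is accurate, since the tensor cannot then
        # depend on them)
        non_parents = [
            j for j in self.nodes if not self.cm[j, node] and p_on.shape[j] == 2
        ]
        p_on = marginalize_out(p_on[..., np.newaxis], non_parents)[..., 0]
        assert np.all((p_on >= 0) & (p_on <= 1))
        return NodeTPM(node=node, tensor=p_on)

    def node_tpm(self, node: int) -> NodeTPM:
        """The node's own TPM, restricted to its parents per the cm."""
        if node not in self.node_tpms:
            raise ValueError(f"node {node} is not a subsystem member")
        return self.node_tpms[node]

    # ------------------------------------------------------------------
    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def member_cm(self) -> np.ndarray:
        """Connectivity matrix restricted to member nodes (size x size)."""
        idx = list(self.nodes)
        return self.cm[np.ix_(idx, idx)]

    def labels_for(self, nodes) -> tuple[str, ...]:
        return tuple(self.network.labels[i] for i in nodes)

    def __repr__(self):
        return f"Subsystem({', '.join(self.labels_for(self.nodes))})"

    def __eq__(self, other):
        return (
            isinstance(other, Subsystem)
            and self.network == other.network
            and self.state == other.state
            and self.nodes == other.nodes
            and all(
                np.array_equal(self.node_tpms[i].tensor, other.node_tpms[i].tensor)
                for i in self.nodes
            )
        )

    def __hash__(self):
        return hash(
            (self.network, self.state, self.nodes)
            + tuple(self.node_tpms[i].tensor.tobytes() for i in self.nodes)
        )

    # ------------------------------------------------------------------
    def recompose_tpm(self) -> np.ndarray:
        """Rebuild the subsystem TPM from the per-node TPMs."""
        shape = tuple(
            2 if i in self.nodes else 1 for i in range(self.network.n)
        )
        cols = [
            np.broadcast_to(self.node_tpms[i].tensor, shape) for i in self.nodes
        ]
        return np.stack(cols, axis=-1)


def apply_cut(subsystem: Subsystem, cut: SystemCut) -> Subsystem:
    """Return a new subsystem with all edges from_part -> to_part severed.

    For each severed edge ``a -> b`` the source ``a`` is marginalized out of
    ``b``'s node TPM (so ``a`` appears noised to ``b``), the subsystem TPM is
    recomposed from the modified node TPMs, and the cm is updated.
    """
    if set(cut.indices()) != set(subsystem.nodes):
        raise ValueError("cut parts must partition the subsystem's nodes")
    cm = subsystem.cm.copy()
    node_tpms = {}
    for b in subsystem.nodes:
        tensor = subsystem.node_tpms[b].tensor
        if b in cut.to_part:
            severed = [a for a in cut.from_part if cm[a, b]]
            tensor = marginalize_out(tensor[..., np.newaxis], severed)[..., 0]
            for a in severed:
                cm[a, b] = 0
        node_tpms[b] = NodeTPM(node=b, tensor=tensor)
    cut_sub = Subsystem(
        subsystem.network,
        subsystem.state,
        subsystem.nodes,
        _internal=(None, cm, node_tpms),
    )
    cut_sub.tpm = cut_sub.recompose_tpm()
    cut_sub.cut = cut
    return cut_sub
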