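"""System-level analysis: cause-effect structures, Φ, and complexes.

The cause-effect structure (CES) of a subsystem is the set of all concepts
(φ > 0) it specifies.  Its irreducibility Φ is the minimal extended
earth-mover's distance between the unpartitioned CES and the CES recomputed
after a unidirectional system cut; the minimizing cut is the system's
minimum-information partition.  A subsystem whose connectivity graph is not
strongly connected has Φ = 0 (some unidirectional cut severs no edges, so
the partitioned CES is identical).

The CES distance is an earth mover's distance in *concept space*: each
concept is a point with mass φ; the ground distance between two concepts is
the repertoire EMD between their cause repertoires (expanded to the full
subsystem) plus the same for their effect repertoires; surplus mass moves to
the *null concept*, whose repertoires are the unconstrained cause and effect
distributions of the subsystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .config import Config
from .distance import repertoire_distance, transport_cost
from .mechanism import (
    PRECISION,
    Concept,
    MaximallyIrreducibleCause,
    MaximallyIrreducibleEffect,
    RepertoireIrreducibilityAnalysis,
    _null_ria,
    concept,
    powerset,
)
from .network import Network, Subsystem, SystemCut, apply_cut
from .repertoire import Direction, expand_repertoire, repertoire

log = logging.getLogger(__name__)

__all__ = [
    "CauseEffectStructure",
    "SystemIrreducibilityAnalysis",
    "ces",
    "system_cuts",
    "null_concept",
    "concept_distance",
    "ces_distance",
    "sia",
    "major_complex",
    "complexes",
]


def _round(x: float) -> float:
    return round(float(x), PRECISION)


@dataclass(frozen=True)
class CauseEffectStructure:
    """The set of concepts (φ > 0) specified by a subsystem."""

    concepts: tuple[Concept, ...]
    subsystem: Subsystem

    def __len__(self):
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    def mechanisms(self) -> list[tuple[int, ...]]:
        return [c.mechanism for c in self.concepts]

    def to_dict(self) -> dict:
        return {"concepts": [c.to_dict() for c in self.concepts]}


def ces(subsystem: Subsystem, mechanisms=None) -> CauseEffectStructure:
    """Compute the concept of every candidate mechanism; keep those with φ > 0.

    Mechanisms are evaluated in deterministic order (by size, then
    lexicographically).  ``mechanisms`` restricts the candidates (used by the
    "no new concepts" approximation).
    """
    if mechanisms is None:
        mechanisms = sorted(
            powerset(subsystem.nodes, nonempty=True), key=lambda m: (len(m), m)
        )
    found = []
    for mechanism in mechanisms:
        c = concept(subsystem, mechanism)
        if c.phi > 0:
            found.append(c)
    return CauseEffectStructure(tuple(found), subsystem)


def system_cuts(subsystem: Subsystem, cut_one: bool = False) -> list[SystemCut]:
    """All unidirectional bipartition cuts of the subsystem.

    ``2^n - 2`` cuts for ``n`` nodes (each ordered pair of nonempty
    complementary parts); in ``cut_one`` mode only the ``2n`` cuts that
    isolate a single node (severing its outputs, or its inputs) are
    evaluated.  Single-node subsystems admit no cut.
    """
    nodes = subsystem.nodes
    if len(nodes) < 2:
        return []
    if cut_one:
        cuts = []
        for i in nodes:
            rest = tuple(j for j in nodes if j != i)
            cuts.append(SystemCut((i,), rest))
            cuts.append(SystemCut(rest, (i,)))
        return list(dict.fromkeys(cuts))  # n=2: both orders coincide
    cuts = []
    for from_part in sorted(powerset(nodes, nonempty=True), key=lambda s: (len(s), s)):
        to_part = tuple(i for i in nodes if i not in from_part)
        if not to_part:
            continue
        cuts.append(SystemCut(from_part, to_part))
    return cuts


def null_concept(subsystem: Subsystem) -> Concept:
    """The reference point of concept space: the empty mechanism's
    unconstrained cause and effect repertoires over the whole subsystem."""
    cause_rep = repertoire(subsystem, Direction.CAUSE, (), subsystem.nodes)
    effect_rep = repertoire(subsystem, Direction.EFFECT, (), subsystem.nodes)
    return Concept(
        mechanism=(),
        cause=MaximallyIrreducibleCause(
            _null_ria(Direction.CAUSE, (), subsystem.nodes, cause_rep)
        ),
        effect=MaximallyIrreducibleEffect(
            _null_ria(Direction.EFFECT, (), subsystem.nodes, effect_rep)
        ),
    )


def concept_distance(
    c1: Concept, sub1: Subsystem, c2: Concept, sub2: Subsystem
) -> float:
    """Ground distance between concepts: cause-side EMD plus effect-side EMD,
    both with repertoires expanded to the full subsystem.

    Each concept is expanded with the unconstrained repertoires of *its own*
    subsystem: a concept of a partitioned CES fills in non-purview nodes with
    the cut system's unconstrained distributions.
    """
    nodes = sub1.nodes
    cause1 = expand_repertoire(sub1, c1.cause.repertoire, nodes)
    cause2 = expand_repertoire(sub2, c2.cause.repertoire, nodes)
    effect1 = expand_repertoire(sub1, c1.effect.repertoire, nodes)
    effect2 = expand_repertoire(sub2, c2.effect.repertoire, nodes)
    return repertoire_distance(Direction.CAUSE, cause1, cause2) + repertoire_distance(
        Direction.EFFECT, effect1, effect2
    )


def ces_distance(c1: CauseEffectStructure, c2: CauseEffectStructure) -> float:
    """Extended EMD between two cause-effect structures over the same nodes.

    Concepts are transport bins with mass φ; the ground metric is
    :func:`concept_distance`; each side also gets a null-concept bin that
    absorbs surplus mass (concepts destroyed or created by a partition).
    """
    sub1, sub2 = c1.subsystem, c2.subsystem
    if sub1.nodes != sub2.nodes:
        raise ValueError("cause-effect structures are over different node sets")
    # Concepts identical on both sides transport at zero cost; cancel them.
    left = list(c1.concepts)
    right = list(c2.concepts)
    for cc in list(left):
        match = next((d for d in right if cc.eq_repertoires(d)), None)
        if match is not None:
            left.remove(cc)
            right.remove(match)
    if not left and not right:
        return 0.0
    null1 = null_concept(sub1)
    null2 = null_concept(sub2)
    bins1 = [(c, sub1) for c in left] + [(null1, sub1)]
    bins2 = [(c, sub2) for c in right] + [(null2, sub2)]
    mass1 = np.array([c.phi for c in left] + [0.0])
    mass2 = np.array([c.phi for c in right] + [0.0])
    residual = mass1.sum() - mass2.sum()
    if residual > 0:
        mass2[-1] = residual
    else:
        mass1[-1] = -residual
    cost = np.array(
        [
            [concept_distance(a, sa, b, sb) for (b, sb) in bins2]
            for (a, sa) in bins1
        ]
    )
    cost[-1, -1] = 0.0  # null-to-null transport is free by definition
    return _round(transport_cost(mass1, mass2, cost))


@dataclass(frozen=True)
class SystemIrreducibilityAnalysis:
    """The unpartitioned CES, the minimal cut, its partitioned CES, and Φ."""

    phi: float
    ces: CauseEffectStructure
    partitioned_ces: CauseEffectStructure
    cut: SystemCut | None
    subsystem: Subsystem

    def to_dict(self) -> dict:
        sub = self.subsystem
        return {
            "subsystem": list(sub.nodes),
            "labels": list(sub.labels_for(sub.nodes)),
            "state": list(sub.state),
            "phi": self.phi,
            "cut": (
                {"from": list(self.cut.from_part), "to": list(self.cut.to_part)}
                if self.cut
                else None
            ),
            "ces": self.ces.to_dict()["concepts"],
            "partitioned_ces": self.partitioned_ces.to_dict()["concepts"],
        }


def _strongly_connected(subsystem: Subsystem) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(subsystem.nodes)
    for i in subsystem.nodes:
        for j in subsystem.nodes:
            if i != j and subsystem.cm[i, j]:
                g.add_edge(i, j)
    return nx.is_strongly_connected(g)


def _null_sia(subsystem, unpartitioned=None) -> SystemIrreducibilityAnalysis:
    if unpartitioned is None:
        unpartitioned = CauseEffectStructure((), subsystem)
    return SystemIrreducibilityAnalysis(
        phi=0.0,
        ces=unpartitioned,
        partitioned_ces=unpartitioned,
        cut=None,
        subsystem=subsystem,
    )


def _cut_distance(subsystem, unpartitioned, cut, config) -> tuple[float, object]:
    """Distance between the CES and the CES recomputed under one cut."""
    if not cut.severed_edges(subsystem.cm):
        # the cut removes no edges: the partitioned system is identical
        return 0.0, unpartitioned
    cut_sub = apply_cut(subsystem, cut)
    mechanisms = (
        unpartitioned.mechanisms() if config.no_new_concepts else None
    )
    partitioned = ces(cut_sub, mechanisms=mechanisms)
    return ces_distance(unpartitioned, partitioned), partitioned


def sia(
    subsystem: Subsystem,
    config: Config | None = None,
    connectivity_shortcut: bool = True,
) -> SystemIrreducibilityAnalysis:
    """Full system-irreducibility analysis of a subsystem.

    Evaluates the partitioned CES under every system cut (recomputed from
    scratch from the cut TPM unless ``config.no_new_concepts``), and returns
    the minimal-distance cut and Φ.  ``connectivity_shortcut`` enables the
    Φ = 0 short-circuit for subsystems that are not strongly connected.
    """
    config = config or Config()
    if connectivity_shortcut and not _strongly_connected(subsystem):
        log.info("subsystem %s is not strongly connected: Φ = 0", subsystem)
        return _null_sia(subsystem)
    unpartitioned = ces(subsystem)
    if not unpartitioned.concepts:
        return _null_sia(subsystem)
    cuts = system_cuts(subsystem, cut_one=config.cut_one)
    if not cuts:
        return _null_sia(subsystem, unpartitioned)
    log.info("evaluating %d system cuts for %s", len(cuts), subsystem)

    if config.parallel:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=-1)(
            delayed(_cut_distance)(subsystem, unpartitioned, cut, config)
            for cut in cuts
        )
    else:
        results = None

    best = None
    for idx, cut in enumerate(cuts):
        dist, partitioned = (
            results[idx]
            if results is not None
            else _cut_distance(subsystem, unpartitioned, cut, config)
        )
        dist = _round(dist)
        if best is None or dist < best.phi:
            best = SystemIrreducibilityAnalysis(
                phi=dist,
                ces=unpartitioned,
                partitioned_ces=partitioned,
                cut=cut,
                subsystem=subsystem,
            )
            if dist == 0.0:
                break
    return best


def _candidate_subsystems(network: Network, state) -> list[Subsystem]:
    """All subsystems, largest first then lexicographic (the tie-break order)."""
    subsets = sorted(
        powerset(network.node_indices, nonempty=True), key=lambda s: (-len(s), s)
    )
    return [Subsystem(network, state, nodes) for nodes in subsets]


def major_complex(
    network: Network, state, config: Config | None = None
) -> SystemIrreducibilityAnalysis:
    """The subsystem with maximal Φ (ties: larger, then lexicographically
    smaller, node set).  Non-strongly-connected candidates have Φ = 0."""
    config = config or Config()
    best = None
    for subsystem in _candidate_subsystems(network, state):
        if not _strongly_connected(subsystem):
            log.info("skipping %s: not strongly connected", subsystem)
            analysis = _null_sia(subsystem)
        else:
            analysis = sia(subsystem, config)
        if best is None or analysis.phi > best.phi:
            best = analysis
    return best


def complexes(
    network: Network, state, config: Config | None = None
) -> list[SystemIrreducibilityAnalysis]:
    """Greedy non-overlapping decomposition into complexes (Φ > 0).

    The major complex is taken first; all subsets overlapping it are
    excluded, and the search recurses on the remaining nodes.
    """
    config = config or Config()
    remaining = set(network.node_indices)
    found = []
    while remaining:
        candidates = [
            s
            for s in _candidate_subsystems(network, state)
            if set(s.nodes) <= remaining
        ]
        best = None
        for subsystem in candidates:
            analysis = (
                sia(subsystem, config)
                if _strongly_connected(subsystem)
                else _null_sia(subsystem)
            )
            if best is None or analysis.phi > best.phi:
                best = analysis
        if best is None or best.phi <= 0:
            break
        found.append(best)
        remaining -= set(best.subsystem.nodes)
    return found
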