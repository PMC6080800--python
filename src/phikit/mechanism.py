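"""Mechanism-level irreducibility: partitions, MIPs, MIC/MIE, and concepts.

A mechanism-purview pair is *integrated* to the extent that its repertoire
cannot be factored into independent parts.  Every bipartition of the pair is
evaluated; the partition whose factored (partitioned) repertoire is closest
to the unpartitioned one is the minimum-information partition (MIP), and the
distance is the pair's integrated information φ.  Maximizing φ over purviews
gives the mechanism's maximally-irreducible cause (MIC) and effect (MIE); a
mechanism with φ > 0 on both sides specifies a *concept*.

Block reducibility: if the connectivity matrix admits a split of mechanism
and purview into two blocks with no cross-edges (in the direction under
analysis), the repertoire factors exactly and φ = 0 without any search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import chain, combinations

import networkx as nx
import numpy as np

from .distance import repertoire_distance
from .network import Subsystem
from .repertoire import Direction, Repertoire, repertoire

log = logging.getLogger(__name__)

__all__ = [
    "PRECISION",
    "MechanismPartition",
    "RepertoireIrreducibilityAnalysis",
    "MaximallyIrreducibleCause",
    "MaximallyIrreducibleEffect",
    "Concept",
    "mechanism_partitions",
    "partitioned_repertoire",
    "purview_reducible_by_cm",
    "cause_mip",
    "effect_mip",
    "mic",
    "mie",
    "concept",
]

#: Decimal places to which φ/Φ values are rounded before comparison.
PRECISION = 6


def _round(phi: float) -> float:
    return round(float(phi), PRECISION)


def powerset(nodes, nonempty=False):
    nodes = tuple(nodes)
    rng = range(1 if nonempty else 0, len(nodes) + 1)
    return chain.from_iterable(combinations(nodes, r) for r in rng)


@dataclass(frozen=True)
class MechanismPartition:
    """An unordered bipartition of a mechanism-purview pair.

    ``part1 = (M1, P1)`` and ``part2 = (M2, P2)`` with ``M1 ⊔ M2 = M`` and
    ``P1 ⊔ P2 = P``; neither part may be (∅, ∅).
    """

    mechanism1: tuple[int, ...]
    purview1: tuple[int, ...]
    mechanism2: tuple[int, ...]
    purview2: tuple[int, ...]

    def __str__(self):
        def fmt(m, p):
            return f"{','.join(map(str, m)) or '∅'}/{','.join(map(str, p)) or '∅'}"

        return f"[{fmt(self.mechanism1, self.purview1)} x {fmt(self.mechanism2, self.purview2)}]"

    def to_dict(self) -> dict:
        return {
            "part1": {"mechanism": list(self.mechanism1), "purview": list(self.purview1)},
            "part2": {"mechanism": list(self.mechanism2), "purview": list(self.purview2)},
        }


def mechanism_partitions(mechanism, purview) -> list[MechanismPartition]:
    """All admissible bipartitions of a mechanism-purview pair.

    The pair of parts is unordered; each partition is returned once, in a
    deterministic order with the lexicographically smaller part first.
    """
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    if not mechanism or not purview:
        raise ValueError("mechanism and purview must both be nonempty")
    seen = set()
    out = []
    for m1 in powerset(mechanism):
        m2 = tuple(i for i in mechanism if i not in m1)
        for p1 in powerset(purview):
            p2 = tuple(i for i in purview if i not in p1)
            if (not m1 and not p1) or (not m2 and not p2):
                continue
            parts = tuple(sorted([(m1, p1), (m2, p2)]))
            if parts in seen:
                continue
            seen.add(parts)
            out.append(MechanismPartition(parts[0][0], parts[0][1], parts[1][0], parts[1][1]))
    return out


def _part_repertoire(
    subsystem: Subsystem, direction: Direction, mechanism, purview
) -> np.ndarray:
    """A part's contribution to a partitioned repertoire (identity if the
    part's purview is empty; unconstrained if its mechanism is empty)."""
    if not purview:
        return np.ones((1,) * subsystem.network.n)
    return repertoire(subsystem, direction, mechanism, purview).tensor


def partitioned_repertoire(
    subsystem: Subsystem, direction: Direction, partition: MechanismPartition
) -> Repertoire:
    """The product of the two parts' repertoires over the full purview."""
    t1 = _part_repertoire(subsystem, direction, partition.mechanism1, partition.purview1)
    t2 = _part_repertoire(subsystem, direction, partition.mechanism2, partition.purview2)
    purview = tuple(sorted(partition.purview1 + partition.purview2))
    mechanism = tuple(sorted(partition.mechanism1 + partition.mechanism2))
    tensor = t1 * t2
    total = tensor.sum()
    is_zero = bool(total <= 0)
    return Repertoire(direction, mechanism, purview, tensor, is_zero=is_zero)


def purview_reducible_by_cm(
    mechanism, purview, cm: np.ndarray, direction: Direction
) -> bool:
    """Whether missing connections force φ = 0 for this mechanism-purview pair.

    True iff the bipartite graph between mechanism and purview -- with an
    edge wherever the cm has a connection in the causal direction under
    analysis (mechanism→purview for effects, purview→mechanism for causes)
    -- is disconnected, in which case the repertoire factors exactly across
    the connected components.
    """
    mechanism = tuple(mechanism)
    purview = tuple(purview)
    if not mechanism or not purview:
        return True
    key = (mechanism, purview, direction, cm.tobytes())
    cached = _REDUCIBILITY_CACHE.get(key)
    if cached is not None:
        return cached
    g = nx.Graph()
    g.add_nodes_from(("m", i) for i in mechanism)
    g.add_nodes_from(("p", j) for j in purview)
    for i in mechanism:
        for j in purview:
            connected = cm[i, j] if direction is Direction.EFFECT else cm[j, i]
            if connected:
                g.add_edge(("m", i), ("p", j))
    result = nx.number_connected_components(g) > 1
    _REDUCIBILITY_CACHE[key] = result
    return result


_REDUCIBILITY_CACHE: dict = {}


@dataclass(frozen=True)
class RepertoireIrreducibilityAnalysis:
    """The MIP of a mechanism over a purview and its φ value."""

    phi: float
    direction: Direction
    mechanism: tuple[int, ...]
    purview: tuple[int, ...]
    partition: MechanismPartition | None
    repertoire: Repertoire | None
    partitioned_repertoire: Repertoire | None

    def to_dict(self) -> dict:
        return {
            "phi": self.phi,
            "direction": self.direction.value,
            "mechanism": list(self.mechanism),
            "purview": list(self.purview),
            "partition": self.partition.to_dict() if self.partition else None,
            "repertoire": self.repertoire.to_dict() if self.repertoire else None,
            "partitioned_repertoire": (
                self.partitioned_repertoire.to_dict()
                if self.partitioned_repertoire
                else None
            ),
        }


def _null_ria(direction, mechanism, purview, rep=None) -> RepertoireIrreducibilityAnalysis:
    return RepertoireIrreducibilityAnalysis(
        phi=0.0,
        direction=direction,
        mechanism=tuple(mechanism),
        purview=tuple(purview),
        partition=None,
        repertoire=rep,
        partitioned_repertoire=rep,
    )


def _mip(
    subsystem: Subsystem,
    direction: Direction,
    mechanism,
    purview,
    cm_shortcut: bool = True,
) -> RepertoireIrreducibilityAnalysis:
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    if not mechanism or not purview:
        raise ValueError("mechanism and purview must both be nonempty")
    if cm_shortcut and purview_reducible_by_cm(
        mechanism, purview, subsystem.cm, direction
    ):
        log.debug(
            "block-reducible by cm: %s over %s (%s), φ = 0 without search",
            mechanism, purview, direction.value,
        )
        return _null_ria(direction, mechanism, purview)
    unpart = repertoire(subsystem, direction, mechanism, purview)
    if unpart.is_zero:
        # the mechanism state is unreachable: trivially reducible by convention
        return _null_ria(direction, mechanism, purview, unpart)
    best: RepertoireIrreducibilityAnalysis | None = None
    for partition in mechanism_partitions(mechanism, purview):
        part = partitioned_repertoire(subsystem, direction, partition)
        if part.is_zero:
            # a zero part cannot be compared as a distribution; such a
            # partition is treated as maximally distant and never minimal
            phi = float(len(purview))
        elif unpart.allclose(part):
            phi = 0.0
        else:
            phi = _round(repertoire_distance(direction, unpart, part))
        if best is None or phi < best.phi:
            best = RepertoireIrreducibilityAnalysis(
                phi=phi,
                direction=direction,
                mechanism=mechanism,
                purview=purview,
                partition=partition,
                repertoire=unpart,
                partitioned_repertoire=part,
            )
            if phi == 0.0:
                break
    assert best is not None
    return best


def cause_mip(
    subsystem: Subsystem, mechanism, purview, cm_shortcut: bool = True
) -> RepertoireIrreducibilityAnalysis:
    """Minimum-information partition of the mechanism's cause over a purview.

    ``cm_shortcut=False`` disables the connectivity-based reducibility
    short-circuit and forces the full partition search (used to audit the
    shortcut's soundness).
    """
    return _mip(subsystem, Direction.CAUSE, mechanism, purview, cm_shortcut)


def effect_mip(
    subsystem: Subsystem, mechanism, purview, cm_shortcut: bool = True
) -> RepertoireIrreducibilityAnalysis:
    """Minimum-information partition of the mechanism's effect over a purview."""
    return _mip(subsystem, Direction.EFFECT, mechanism, purview, cm_shortcut)


@dataclass(frozen=True)
class MaximallyIrreducibleCause:
    ria: RepertoireIrreducibilityAnalysis

    @property
    def phi(self) -> float:
        return self.ria.phi

    @property
    def purview(self) -> tuple[int, ...]:
        return self.ria.purview

    @property
    def repertoire(self) -> Repertoire | None:
        return self.ria.repertoire

    def to_dict(self) -> dict:
        return self.ria.to_dict()


class MaximallyIrreducibleEffect(MaximallyIrreducibleCause):
    pass


def _mice(subsystem: Subsystem, direction: Direction, mechanism):
    """Search all purviews for the maximal-φ RIA.

    Ties are broken toward the larger purview, then the lexicographically
    smallest; purviews are visited in that preference order so the first
    strict maximum wins.
    """
    mechanism = tuple(sorted(mechanism))
    if not mechanism:
        raise ValueError("mechanism must be nonempty")
    purviews = sorted(
        powerset(subsystem.nodes, nonempty=True), key=lambda p: (-len(p), p)
    )
    best = None
    for purview in purviews:
        ria = _mip(subsystem, direction, mechanism, purview)
        if best is None or ria.phi > best.phi:
            best = ria
    cls = MaximallyIrreducibleCause if direction is Direction.CAUSE else MaximallyIrreducibleEffect
    return cls(best)


def mic(subsystem: Subsystem, mechanism) -> MaximallyIrreducibleCause:
    """The mechanism's maximally-irreducible cause over all purviews."""
    return _mice(subsystem, Direction.CAUSE, mechanism)


def mie(subsystem: Subsystem, mechanism) -> MaximallyIrreducibleEffect:
    """The mechanism's maximally-irreducible effect over all purviews."""
    return _mice(subsystem, Direction.EFFECT, mechanism)


@dataclass(frozen=True)
class Concept:
    """A mechanism's MIC and MIE; φ is the minimum of the two sides."""

    mechanism: tuple[int, ...]
    cause: MaximallyIrreducibleCause
    effect: MaximallyIrreducibleEffect

    @property
    def phi(self) -> float:
        return _round(min(self.cause.phi, self.effect.phi))

    def __bool__(self) -> bool:
        return self.phi > 0

    def eq_repertoires(self, other: "Concept") -> bool:
        return (
            self.mechanism == other.mechanism
            and self.phi == other.phi
            and self.cause.purview == other.cause.purview
            and self.effect.purview == other.effect.purview
            and self.cause.repertoire.allclose(other.cause.repertoire)
            and self.effect.repertoire.allclose(other.effect.repertoire)
        )

    def to_dict(self) -> dict:
        return {
            "mechanism": list(self.mechanism),
            "phi": self.phi,
            "cause": self.cause.to_dict(),
            "effect": self.effect.to_dict(),
        }


def concept(subsystem: Subsystem, mechanism) -> Concept:
    """The concept specified by a mechanism (returned even when φ = 0)."""
    mechanism = tuple(sorted(mechanism))
    return Concept(
        mechanism=mechanism,
        cause=mic(subsystem, mechanism),
        effect=mie(subsystem, mechanism),
    )
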