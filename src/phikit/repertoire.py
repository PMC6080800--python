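"""Cause and effect repertoires.

A repertoire is the interventional conditional distribution over the states
of a *purview* (a set of subsystem nodes) at ``t-1`` (cause) or ``t+1``
(effect), given the current state of a *mechanism* (another set of subsystem
nodes).  Non-mechanism inputs are noised with *independent* noise per target
("virtual nodes"), which is exactly what the per-node factorization below
computes without ever materializing the virtual nodes:

* the effect repertoire over a multi-node purview is the tensor product of
  the single-node effect repertoires;
* the cause repertoire of a multi-node mechanism is the normalized tensor
  product of the single-mechanism-node cause repertoires (the normalization
  constant K restores a probability distribution; K = 0 flags a mechanism
  state that no purview state can produce).

Repertoire tensors internally keep one (possibly singleton) axis per network
node so that products across disjoint purviews are plain broadcast
multiplications; :meth:`Repertoire.squeezed` and
:meth:`Repertoire.flatten` give the purview-only views.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .network import Subsystem
from .tpm import marginalize_out

__all__ = [
    "Direction",
    "Repertoire",
    "cause_repertoire",
    "effect_repertoire",
    "repertoire",
    "unconstrained_repertoire",
    "expand_repertoire",
    "flatten_repertoire",
]

#: Tolerance for the sums-to-one repertoire invariant.
SUM_TOL = 1e-6


class Direction(enum.Enum):
    CAUSE = "cause"
    EFFECT = "effect"


@dataclass(frozen=True)
class Repertoire:
    """A probability distribution over purview states at t-1 or t+1."""

    direction: Direction
    mechanism: tuple[int, ...]
    purview: tuple[int, ...]
    tensor: np.ndarray  # one axis per network node, size 2 at purview nodes
    is_zero: bool = False  # K = 0: mechanism state unreachable (cause only)
    mechanism_state: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.is_zero:
            assert abs(self.tensor.sum() - 1.0) < SUM_TOL, "repertoire must sum to 1"

    def squeezed(self) -> np.ndarray:
        """The tensor with only the purview axes (in ascending node order)."""
        keep = [i for i in self.purview]
        drop = [ax for ax in range(self.tensor.ndim) if ax not in keep]
        return self.tensor.reshape(
            [self.tensor.shape[i] for i in keep] or [1]
        ) if not drop else np.squeeze(self.tensor, axis=tuple(drop))

    def flatten(self) -> np.ndarray:
        """Little-endian probability vector of length ``2^|purview|``.

        Column-major (Fortran) flattening keeps the first purview node's
        state as the least-significant bit.
        """
        return np.asarray(self.squeezed()).reshape(-1, order="F")

    def sum(self) -> float:
        return float(self.tensor.sum())

    def node_on_marginals(self) -> dict[int, float]:
        """Marginal Pr(node ON) for each purview node."""
        total = self.tensor.sum()
        out = {}
        for node in self.purview:
            axes = tuple(ax for ax in range(self.tensor.ndim) if ax != node)
            marg = self.tensor.sum(axis=axes)
            out[node] = float(marg[1] / total) if total > 0 else 0.0
        return out

    def allclose(self, other: "Repertoire", atol: float = 1e-12) -> bool:
        return self.purview == other.purview and np.allclose(
            self.tensor, other.tensor, atol=atol, rtol=0
        )

    def to_dict(self) -> dict:
        return {
            "direction": self.direction.value,
            "purview": list(self.purview),
            "probabilities": [float(x) for x in self.flatten()],
        }


def _full_shape(subsystem: Subsystem) -> tuple[int, ...]:
    return (1,) * subsystem.network.n


def _ones(subsystem: Subsystem) -> np.ndarray:
    return np.ones(_full_shape(subsystem))


def _axis_dist(subsystem: Subsystem, node: int, p_on: float) -> np.ndarray:
    """Distribution [1-p, p] laid out along ``node``'s axis."""
    shape = [1] * subsystem.network.n
    shape[node] = 2
    return np.array([1.0 - p_on, p_on]).reshape(shape)


def _check_members(subsystem: Subsystem, nodes) -> tuple[int, ...]:
    nodes = tuple(sorted(int(i) for i in nodes))
    for i in nodes:
        if i not in subsystem.nodes:
            raise ValueError(f"node {i} is not a subsystem member")
    return nodes


def _single_effect_on_probability(
    subsystem: Subsystem, mechanism: tuple[int, ...], purview_node: int
) -> float:
    """Pr(purview node ON at t+1 | mechanism state), inputs noised per-node."""
    t = subsystem.node_tpm(purview_node).tensor[..., np.newaxis]
    # condition on the mechanism nodes that are parents of this purview node
    for m in mechanism:
        if t.shape[m] == 2:
            t = np.take(t, [subsystem.state[m]], axis=m)
    # noise the remaining (non-mechanism) parents: uniform marginalization
    rest = [i for i in subsystem.nodes if i not in mechanism and t.shape[i] == 2]
    t = marginalize_out(t, rest)
    return float(t.reshape(()))


def effect_repertoire(
    subsystem: Subsystem, mechanism, purview
) -> Repertoire:
    """Distribution over purview states at t+1 given the mechanism's state.

    An empty mechanism yields the unconstrained effect repertoire (every
    input noised).
    """
    mechanism = _check_members(subsystem, mechanism)
    purview = _check_members(subsystem, purview)
    if not purview:
        raise ValueError("purview must be nonempty")
    tensor = _ones(subsystem)
    for p in purview:
        q = _single_effect_on_probability(subsystem, mechanism, p)
        tensor = tensor * _axis_dist(subsystem, p, q)
    return Repertoire(
        Direction.EFFECT, mechanism, purview, tensor,
        mechanism_state=tuple(subsystem.state[m] for m in mechanism),
    )


def _single_cause_factor(
    subsystem: Subsystem, mech_node: int, purview: tuple[int, ...]
) -> np.ndarray:
    """Unnormalized likelihood Pr(mechanism node in its state | purview state)."""
    p_on = subsystem.node_tpm(mech_node).tensor
    like = p_on if subsystem.state[mech_node] == 1 else 1.0 - p_on
    like = like[..., np.newaxis]
    # noise parents outside the purview
    rest = [i for i in subsystem.nodes if i not in purview and like.shape[i] == 2]
    like = marginalize_out(like, rest)[..., 0]
    # broadcast over purview nodes the likelihood does not depend on
    shape = [1] * subsystem.network.n
    for p in purview:
        shape[p] = 2
    return like * np.ones(shape)


def cause_repertoire(
    subsystem: Subsystem, mechanism, purview
) -> Repertoire:
    """Distribution over purview states at t-1 given the mechanism's state.

    Bayes' rule with a uniform interventional prior over previous states.  An
    empty mechanism yields the unconstrained (uniform) cause repertoire.  If
    no purview state can produce the mechanism's state (K = 0) the repertoire
    is identically zero and flagged via ``is_zero``.
    """
    mechanism = _check_members(subsystem, mechanism)
    purview = _check_members(subsystem, purview)
    if not purview:
        raise ValueError("purview must be nonempty")
    shape = [1] * subsystem.network.n
    for p in purview:
        shape[p] = 2
    mech_state = tuple(subsystem.state[m] for m in mechanism)
    if not mechanism:
        tensor = np.full(shape, 1.0 / 2 ** len(purview))
        return Repertoire(Direction.CAUSE, mechanism, purview, tensor)
    tensor = np.ones(shape)
    for m in mechanism:
        tensor = tensor * _single_cause_factor(subsystem, m, purview)
    k = tensor.sum()
    if k <= 0:
        return Repertoire(
            Direction.CAUSE, mechanism, purview, np.zeros(shape),
            is_zero=True, mechanism_state=mech_state,
        )
    return Repertoire(
        Direction.CAUSE, mechanism, purview, tensor / k, mechanism_state=mech_state
    )


def repertoire(
    subsystem: Subsystem, direction: Direction, mechanism, purview
) -> Repertoire:
    """Dispatch to the cause or effect repertoire, with per-subsystem memoization."""
    key = (direction, tuple(mechanism), tuple(purview))
    cache = subsystem._repertoire_cache
    if key not in cache:
        fn = cause_repertoire if direction is Direction.CAUSE else effect_repertoire
        cache[key] = fn(subsystem, mechanism, purview)
    return cache[key]


def unconstrained_repertoire(
    subsystem: Subsystem, direction: Direction, purview
) -> Repertoire:
    """The empty-mechanism (maximum-entropy-constrained) repertoire."""
    return repertoire(subsystem, direction, (), purview)


def expand_repertoire(
    subsystem: Subsystem, rep: Repertoire, target
) -> Repertoire:
    """Expand a repertoire to a superset purview.

    Missing nodes contribute the unconstrained repertoire of the same
    direction (uniform for cause; each node's mean activation for effect), so
    the marginal over the original purview is preserved exactly.
    """
    target = _check_members(subsystem, target)
    if not set(rep.purview) <= set(target):
        raise ValueError("target must be a superset of the repertoire's purview")
    extra = tuple(i for i in target if i not in rep.purview)
    if not extra:
        return rep
    background = unconstrained_repertoire(subsystem, rep.direction, extra)
    return Repertoire(
        rep.direction,
        rep.mechanism,
        target,
        rep.tensor * background.tensor,
        is_zero=rep.is_zero,
        mechanism_state=rep.mechanism_state,
    )


def flatten_repertoire(rep: Repertoire) -> np.ndarray:
    """Little-endian probability vector over purview states (ascending nodes)."""
    return rep.flatten()
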