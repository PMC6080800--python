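"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths:

* :func:`lp_emd` solves the transportation problem with scipy's LP solver
  instead of the package's successive-shortest-path routine.
* :func:`oracle_effect_repertoire` / :func:`oracle_cause_repertoire`
  enumerate all system states from the 2-D state-by-node TPM and apply the
  noising/fixing semantics literally, with explicit independent virtual
  noise per purview node (effect) / per mechanism node (cause) -- no node
  TPMs, no tensor broadcasting, no connectivity information.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from phikit.tpm import all_states, index_to_state, multidim_to_sbn, state_to_index


def lp_emd(p: np.ndarray, q: np.ndarray, cost: np.ndarray) -> float:
    """Transportation LP: reference earth mover's distance."""
    p = np.asarray(p, dtype=float).reshape(-1)
    q = np.asarray(q, dtype=float).reshape(-1)
    ns, nt = len(p), len(q)
    a_eq = np.zeros((ns + nt, ns * nt))
    for i in range(ns):
        a_eq[i, i * nt : (i + 1) * nt] = 1
    for j in range(nt):
        a_eq[ns + j, j::nt] = 1
    res = linprog(
        np.asarray(cost, dtype=float).ravel(),
        A_eq=a_eq[:-1],
        b_eq=np.concatenate([p, q])[:-1],
        bounds=(0, None),
        method="highs",
    )
    assert res.success, res.message
    return float(res.fun)


def hamming_cost(n: int) -> np.ndarray:
    states = list(all_states(n))
    return np.array(
        [[sum(x != y for x, y in zip(s, t)) for t in states] for s in states],
        dtype=float,
    )


def member_sbn(network, state, members) -> np.ndarray:
    """Background-conditioned state-by-node TPM over the member nodes only.

    Row ``u`` (little-endian over members) is obtained by writing the member
    state into the full system state (externals keep their given state) and
    reading the full TPM's row.
    """
    sbn = multidim_to_sbn(network.tpm)
    members = tuple(members)
    k = len(members)
    out = np.zeros((2**k, k))
    for u in range(2**k):
        bits = index_to_state(u, k)
        full = list(state)
        for pos, node in enumerate(members):
            full[node] = bits[pos]
        out[u] = sbn[state_to_index(full), list(members)]
    return out


def _rows_matching(k: int, positions, values):
    for u in range(2**k):
        bits = index_to_state(u, k)
        if all(bits[p] == v for p, v in zip(positions, values)):
            yield u


def oracle_effect_repertoire(network, state, members, mechanism, purview):
    """Flattened effect repertoire by state enumeration with virtual noise.

    For each purview node independently: fix the mechanism in its state,
    perturb every other member uniformly, and average the node's
    ON-probability; the joint is the product over purview nodes.
    """
    members = tuple(members)
    sbn = member_sbn(network, state, members)
    k = len(members)
    mpos = [members.index(i) for i in mechanism]
    mvals = [state[i] for i in mechanism]
    ppos = [members.index(i) for i in sorted(purview)]
    on = []
    for p in ppos:
        rows = list(_rows_matching(k, mpos, mvals))
        on.append(np.mean([sbn[u, p] for u in rows]))
    vec = np.zeros(2 ** len(ppos))
    for idx, bits in enumerate(all_states(len(ppos))):
        vec[idx] = np.prod([on[t] if b else 1 - on[t] for t, b in enumerate(bits)])
    return vec


def oracle_cause_repertoire(network, state, members, mechanism, purview):
    """Flattened cause repertoire by state enumeration with virtual noise.

    For each mechanism node independently: the likelihood of its current
    state given each previous purview state, averaged uniformly over
    non-purview members; likelihoods multiply across mechanism nodes
    (independent virtual inputs) and are normalized by Bayes' rule with a
    uniform prior.  Returns the all-zero vector if the mechanism state is
    unreachable.
    """
    members = tuple(members)
    sbn = member_sbn(network, state, members)
    k = len(members)
    ppos = [members.index(i) for i in sorted(purview)]
    total = np.ones(2 ** len(ppos))
    if not mechanism:
        return total / total.sum()
    for m in mechanism:
        mp = members.index(m)
        s = state[m]
        like = np.zeros(2 ** len(ppos))
        for idx, bits in enumerate(all_states(len(ppos))):
            rows = list(_rows_matching(k, ppos, bits))
            vals = [sbn[v, mp] if s else 1 - sbn[v, mp] for v in rows]
            like[idx] = np.mean(vals)
        total = total * like
    z = total.sum()
    if z <= 0:
        return np.zeros_like(total)
    return total / z
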