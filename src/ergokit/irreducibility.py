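"""Heuristic irreducibility check on a finite state-space truncation.

Ergodicity conclusions require the state space to be irreducible -- no
proper subset may trap the process forever.  Deciding this in general is
outside the scope of a drift-certificate tool, so the check here is a
truncated-reachability heuristic: explore the states reachable from
``x0`` inside a finite box, build the directed transition graph (edges
where the propensity is positive; bounded-function channels count as
firable whenever their supremum is positive), and examine its strongly
connected components.

* ``verified_on_truncation``: all explored states form one strongly
  connected component.  Transitions leaving the box are tolerated but
  make the verdict a truncation statement, not a proof.
* ``counterexample``: a terminal component that is closed under *all*
  reactions in the full lattice (not merely a boundary artifact) --
  e.g. the absorbing origin of a pure-death network.
* ``inconclusive``: anything else.

Reachability automatically respects conservation laws (the explored set
is the invariant slice through ``x0``), which handles e.g. closed
conversion networks without special-casing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .drift import _envelope_propensities
from .network import ReactionNetwork

__all__ = ["TruncationCheck", "truncated_irreducibility_check"]

MAX_BOX_STATES = 10_000_000
DEFAULT_BOX = 30


@dataclass
class TruncationCheck:
    box: np.ndarray
    status: str                       # verified_on_truncation | counterexample | inconclusive
    witness: list | None
    n_states_explored: int
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "box": [int(b) for b in self.box],
            "status": self.status,
            "witness": self.witness,
            "n_states_explored": self.n_states_explored,
            "notes": self.notes,
        }


def _firable(net: ReactionNetwork, x) -> np.ndarray:
    lam = _envelope_propensities(net, x)
    # a bounded channel with positive sup *may* fire; reactant
    # sufficiency still applies
    for k, r in enumerate(net.reactions):
        for nm, m in r.propensity.reactant_multiset.items():
            if x[net.species_index(nm)] < m:
                lam[k] = 0.0
    return lam > 0


def truncated_irreducibility_check(net: ReactionNetwork, box, x0) -> TruncationCheck:
    """Explore the box-truncated reachability graph from ``x0``.

    ``box`` is a per-species upper bound (scalar broadcast allowed).
    Raises when the box volume exceeds the resource guard (1e7 states).
    """
    d = net.d
    box = np.broadcast_to(np.asarray(box, dtype=int), (d,)).copy()
    x0 = np.asarray(x0, dtype=int)
    if np.any(x0 < 0) or np.any(x0 > box):
        raise ValueError("x0 must lie inside the box")
    volume = float(np.prod(box + 1.0))
    if volume > MAX_BOX_STATES:
        raise ValueError(
            f"box volume {volume:.3g} exceeds the {MAX_BOX_STATES:.0e}-state guard"
        )
    Z = net.stoichiometry_matrix().T  # (K, d)

    index: dict[tuple, int] = {}
    states: list[tuple] = []
    edges_src, edges_dst = [], []
    exits_box = []

    def _id(s: tuple) -> int:
        i = index.get(s)
        if i is None:
            i = len(states)
            index[s] = i
            states.append(s)
            exits_box.append(False)
        return i

    frontier = [_id(tuple(int(v) for v in x0))]
    head = 0
    while head < len(frontier):
        i = frontier[head]
        head += 1
        x = np.array(states[i])
        fire = _firable(net, x)
        for k in np.nonzero(fire)[0]:
            y = x + Z[k]
            if np.any(y < 0):
                continue
            if np.any(y > box):
                exits_box[i] = True
                continue
            j = _id(tuple(int(v) for v in y))
            edges_src.append(i)
            edges_dst.append(j)
        # enqueue any new states
        while len(frontier) < len(states):
            frontier.append(len(frontier))

    n = len(states)
    if n == 1 and not edges_src:
        # the reachable set is a single state: trivially irreducible on it
        return TruncationCheck(box=box, status="verified_on_truncation",
                               witness=None, n_states_explored=1,
                               notes="single reachable state")

    graph = csr_matrix((np.ones(len(edges_src)), (edges_src, edges_dst)),
                       shape=(n, n))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    if n_comp == 1:
        return TruncationCheck(box=box, status="verified_on_truncation",
                               witness=None, n_states_explored=n)

    # look for a terminal component closed in the full lattice
    out_edges = {}
    for s, t in zip(edges_src, edges_dst):
        if labels[s] != labels[t]:
            out_edges.setdefault(labels[s], set()).add(labels[t])
    for comp in range(n_comp):
        if comp in out_edges:
            continue
        members = [i for i in range(n) if labels[i] == comp]
        if any(exits_box[i] for i in members):
            continue  # closure not verifiable inside the box
        # closed terminal component; a proper trap unless it is everything
        if len(members) < n:
            witness = [list(states[i]) for i in members[:50]]
            return TruncationCheck(
                box=box, status="counterexample", witness=witness,
                n_states_explored=n,
                notes=f"trapping subset of {len(members)} state(s), closed in the full lattice",
            )
    return TruncationCheck(box=box, status="inconclusive", witness=None,
                           n_states_explored=n,
                           notes="multiple strongly connected components; "
                                 "no lattice-closed trap identified inside the box")
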