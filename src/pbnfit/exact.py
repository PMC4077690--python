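"""Brute-force Markov-chain oracle for small PBNs.

The state space is the set of assignments to the non-clamped nodes; clamped
nodes are substituted into every predictor.  State ``s`` is the integer
whose binary rendering, first non-clamped node leftmost, spells the bits.

The one-step transition probability from ``s`` to ``t`` decomposes into a
perturbation part and a function part:

    P(s, t) = p^h (1-p)^(m-h) * [h >= 1]
              + (1-p)^m * prod_i P(x_i' = t_i | s)

with ``h`` the Hamming distance, ``m`` the number of non-clamped nodes and
the per-node probability a mixture over that node's predictors.  Unclamped
input nodes hold their value in the function part.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .rules import PBN

__all__ = [
    "ChainRepresentation",
    "StateSpaceError",
    "ReducibleChainError",
    "enumerate_constituents",
    "transition_matrix",
    "stationary_distribution",
    "marginal_probability",
    "bottom_sccs",
    "influence",
    "exact_marginal",
]

#: Default cap on transition-matrix entries (2^(2m)); 2^20 entries = m <= 10.
DEFAULT_MAX_ENTRIES = 1 << 20

_STAT_TOL = 1e-12


class StateSpaceError(ValueError):
    """The requested chain exceeds the brute-force state-space cap."""


class ReducibleChainError(ValueError):
    """No unique stationary distribution (reducible chain at p = 0)."""


@dataclass(frozen=True)
class ChainRepresentation:
    """Transition chain over the non-clamped nodes of a PBN."""

    pbn: PBN
    clamps: Mapping[str, int]
    free_nodes: tuple[str, ...]          # declaration order
    matrix: np.ndarray                   # row-stochastic, 2^m x 2^m

    def __post_init__(self):
        object.__setattr__(self, "clamps", dict(self.clamps))

    @property
    def m(self) -> int:
        return len(self.free_nodes)

    def state_bits(self, state: int) -> dict[str, int]:
        m = self.m
        bits = {node: (state >> (m - 1 - i)) & 1
                for i, node in enumerate(self.free_nodes)}
        bits.update(self.clamps)
        return bits

    def node_bit(self, states: np.ndarray, node: str) -> np.ndarray:
        i = self.free_nodes.index(node)
        return (np.asarray(states) >> (self.m - 1 - i)) & 1


def enumerate_constituents(pbn: PBN, cap: int = DEFAULT_MAX_ENTRIES):
    """All deterministic constituent networks of an independent PBN.

    Returns a list of ``(choice, probability)`` where ``choice`` maps each
    non-input node to its chosen :class:`PredictorFunction`; probabilities
    are the products of the per-node selection probabilities and sum to 1.
    """
    if pbn.is_free:
        raise ValueError("PBN has free selection probabilities")
    updating = [node for node in pbn.nodes if node in pbn.function_sets]
    total = 1
    for node in updating:
        total *= pbn.function_sets[node].n_predictors
        if total > cap:
            raise StateSpaceError(
                f"more than {cap} constituent networks")
    out = []
    for combo in itertools.product(
            *(range(pbn.function_sets[node].n_predictors) for node in updating)):
        choice = {}
        prob = 1.0
        for node, j in zip(updating, combo):
            fs = pbn.function_sets[node]
            choice[node] = fs.predictors[j]
            prob *= fs.probs[j]
        out.append((choice, prob))
    return out


def _next_prob_one(pbn: PBN, clamps: Mapping[str, int]):
    """Per-state vector of P(x_i' = 1 | s) for each non-clamped node.

    Returns ``(free_nodes, Q)`` with ``Q`` of shape (m, 2^m).
    """
    free_nodes = tuple(n for n in pbn.nodes if n not in clamps)
    m = len(free_nodes)
    S = 1 << m
    states = np.arange(S)
    bit = {node: (states >> (m - 1 - i)) & 1
           for i, node in enumerate(free_nodes)}
    Q = np.empty((m, S))
    for i, node in enumerate(free_nodes):
        fs = pbn.function_sets.get(node)
        if fs is None:                       # unclamped input: holds value
            Q[i] = bit[node].astype(float)
            continue
        q = np.zeros(S)
        for c, pred in zip(fs.probs, fs.predictors):
            k = len(pred.parents)
            idx = np.zeros(S, dtype=np.int64)
            for pos, par in enumerate(pred.parents):
                b = clamps[par] if par in clamps else bit[par]
                idx |= np.asarray(b, dtype=np.int64) << (k - 1 - pos)
            q += c * np.asarray(pred.table)[idx]
        Q[i] = q
    return free_nodes, Q


def transition_matrix(pbn: PBN, clamps: Mapping[str, int] | None = None,
                      p: float | None = None,
                      max_entries: int = DEFAULT_MAX_ENTRIES
                      ) -> ChainRepresentation:
    """Dense transition matrix of the clamped subchain.

    ``p`` overrides the PBN's perturbation parameter (``p=0`` gives the pure
    function-driven chain).  Raises :class:`StateSpaceError` beyond the
    entry cap and :class:`ValueError` when free parameters remain.
    """
    if pbn.is_free:
        raise ValueError("PBN has free selection probabilities")
    clamps = dict(clamps or {})
    for node in clamps:
        if node not in pbn.nodes:
            raise KeyError(f"clamp on unknown node {node!r}")
    p = pbn.perturbation_p if p is None else float(p)
    free_nodes, Q = _next_prob_one(pbn, clamps)
    m = len(free_nodes)
    S = 1 << m
    if S * S > max_entries:
        raise StateSpaceError(
            f"chain needs {S}x{S} entries > cap {max_entries}")
    states = np.arange(S)
    t_bits = np.stack([(states >> (m - 1 - i)) & 1 for i in range(m)])  # (m,S)

    # function part: (1-p)^m * prod_i (Q_i if t_i else 1-Q_i)
    F = np.ones((S, S))
    for i in range(m):
        qi = Q[i][:, None]                      # over source states s
        ti = t_bits[i][None, :]                 # over target states t
        F *= np.where(ti == 1, qi, 1.0 - qi)
    P = ((1.0 - p) ** m) * F

    if p > 0.0:
        ham = np.zeros((S, S), dtype=np.int64)
        xor = states[:, None] ^ states[None, :]
        for i in range(m):
            ham += (xor >> i) & 1
        pert = np.where(ham >= 1, (p ** ham) * ((1.0 - p) ** (m - ham)), 0.0)
        P = P + pert

    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise AssertionError("transition matrix rows do not sum to 1")
    return ChainRepresentation(pbn, clamps, free_nodes, P)


def stationary_distribution(chain: ChainRepresentation,
                            tol: float = _STAT_TOL) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1, pi >= 0 by linear algebra.

    Uses the eigenvector of P^T at eigenvalue 1; raises
    :class:`ReducibleChainError` when the eigenvalue is not simple (multiple
    bottom components, p = 0) and falls back to power iteration if the eigen
    solve fails to converge numerically.
    """
    P = chain.matrix
    w, v = np.linalg.eig(P.T)
    close = np.where(np.abs(w - 1.0) < 1e-8)[0]
    if len(close) == 0:
        raise AssertionError("stochastic matrix without eigenvalue 1")
    if len(close) > 1:
        raise ReducibleChainError(
            "multiple stationary distributions: chain is reducible; "
            "use p > 0 or restrict to an ergodic subchain")
    vec = np.real(v[:, close[0]])
    pi = vec / vec.sum()
    if pi.min() < -1e-9 or np.max(np.abs(pi @ P - pi)) > 1e-8:
        # ill-conditioned eigen solve; refine by power iteration
        pi = np.full(P.shape[0], 1.0 / P.shape[0])
        for _ in range(200_000):
            nxt = pi @ P
            if np.max(np.abs(nxt - pi)) < tol:
                pi = nxt
                break
            pi = nxt
        pi = pi / pi.sum()
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def marginal_probability(pi: np.ndarray, chain: ChainRepresentation,
                         node: str) -> float:
    """P(node = 1) under the stationary distribution; a clamped node simply
    returns its clamp value."""
    if node in chain.clamps:
        return float(chain.clamps[node])
    states = np.arange(len(pi))
    return float(pi[chain.node_bit(states, node) == 1].sum())


def exact_marginal(pbn: PBN, node: str, clamps: Mapping[str, int] | None = None,
                   p: float | None = None,
                   max_entries: int = DEFAULT_MAX_ENTRIES) -> float:
    """Convenience: stationary marginal of ``node`` under ``clamps``."""
    clamps = dict(clamps or {})
    if node in clamps:
        return float(clamps[node])
    chain = transition_matrix(pbn, clamps, p=p, max_entries=max_entries)
    return marginal_probability(stationary_distribution(chain), chain, node)


def bottom_sccs(pbn: PBN, clamps: Mapping[str, int] | None = None,
                max_entries: int = DEFAULT_MAX_ENTRIES) -> list[set[int]]:
    """Bottom strongly connected components of the p = 0 state graph.

    Returned as sets of packed states of the non-clamped subspace (same
    indexing as :class:`ChainRepresentation`); these are the absorbing
    attractors of the unperturbed PBN.
    """
    chain = transition_matrix(pbn, clamps, p=0.0, max_entries=max_entries)
    G = nx.DiGraph()
    S = chain.matrix.shape[0]
    G.add_nodes_from(range(S))
    src, dst = np.nonzero(chain.matrix > 0)
    G.add_edges_from(zip(src.tolist(), dst.tolist()))
    cond = nx.condensation(G)
    out = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            out.append(set(cond.nodes[comp_id]["members"]))
    return sorted(out, key=min)


def influence(pbn: PBN, source: str, target: str, pi: np.ndarray,
              chain: ChainRepresentation) -> float:
    """Influence of ``source`` on ``target``:

        sum_j c_j * P_pi( f_j(x) != f_j(x with source toggled) ).

    ``pi``/``chain`` supply the stationary distribution over which the
    toggle probability is taken.  A node that is not a parent of any
    predictor has influence 0.
    """
    fs = pbn.function_sets.get(target)
    if fs is None:
        raise KeyError(f"{target!r} is an input node: no predictors")
    if fs.is_free:
        raise ValueError("free selection probabilities present")
    total = 0.0
    for c, pred in zip(fs.probs, fs.predictors):
        if source not in pred.parents:
            continue
        agree = 0.0
        for s in range(len(pi)):
            env = chain.state_bits(s)
            flipped = dict(env)
            flipped[source] = 1 - flipped[source]
            if pred(env) != pred(flipped):
                agree += pi[s]
        total += c * agree
    return float(total)
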