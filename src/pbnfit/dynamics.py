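"""Synchronous simulation of instantaneously random PBNs.

At every time step, independently for each non-clamped node, a Bernoulli(p)
flip indicator is drawn.  If any indicator fires, the next state is the
current state with exactly those bits flipped and no update function is
applied ("flip wins").  Otherwise every non-clamped, non-input node draws
one of its predictors according to the selection probabilities and takes
that predictor's output; input nodes hold their value.  Clamped nodes never
change, and are exempt from perturbation.

Draw order is fixed so trajectories are bit-reproducible for a given seed:
``step`` draws the flip indicators for all non-clamped nodes in node order
first, then (if no flip fired) one predictor choice per non-input node in
node order.  ``Simulation`` uses an equivalent but block-vectorised scheme
(its own documented order) and is the engine behind the convergence module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .rules import PBN, state_to_string

__all__ = ["SimulationSpec", "step", "simulate", "binary_trace", "Simulation"]

# engine guard-rails: precomputed constituent maps need 2^n * K entries
_ENGINE_MAX_NODES = 16
_ENGINE_MAX_CELLS = 1 << 22


@dataclass
class SimulationSpec:
    """Settings for one trajectory.

    ``initial_state`` is either the string ``"random"`` (uniform over
    non-clamped bits — estimates are insensitive to this choice once the
    chain has converged) or an explicit bit vector in node order.
    """

    clamps: Mapping[str, int] = field(default_factory=dict)
    initial_state: str | Sequence[int] = "random"
    steps: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def _check_clamps(pbn: PBN, clamps: Mapping[str, int],
                  allow_non_input: bool = False):
    inputs = set(pbn.inputs)
    for node, v in clamps.items():
        if node not in pbn.nodes:
            raise KeyError(f"clamp on unknown node {node!r}")
        if v not in (0, 1):
            raise ValueError(f"clamp value for {node!r} must be 0 or 1")
        if node not in inputs and not allow_non_input:
            raise ValueError(
                f"clamp on non-input node {node!r}; pass allow_non_input=True "
                "to force it")


def step(pbn: PBN, state: np.ndarray, clamps: Mapping[str, int],
         rng: np.random.Generator, allow_non_input: bool = False) -> np.ndarray:
    """One synchronous update (reference implementation, literal draw order)."""
    if pbn.is_free:
        raise ValueError("PBN has free selection probabilities; fix them first")
    _check_clamps(pbn, clamps, allow_non_input)
    n = pbn.n
    state = np.asarray(state, dtype=np.uint8)
    if state.shape != (n,):
        raise ValueError(f"state length {state.shape} != {n}")
    free_idx = [i for i, node in enumerate(pbn.nodes) if node not in clamps]
    nxt = state.copy()
    for node, v in clamps.items():
        nxt[pbn.node_index(node)] = v
    # flips first, for every non-clamped node in node order
    flips = rng.random(len(free_idx)) < pbn.perturbation_p
    if flips.any():
        for i, f in zip(free_idx, flips):
            if f:
                nxt[i] ^= 1
        return nxt
    env = {node: int(state[i]) for i, node in enumerate(pbn.nodes)}
    for node, v in clamps.items():
        env[node] = v
    for i in free_idx:
        node = pbn.nodes[i]
        fs = pbn.function_sets.get(node)
        if fs is None:           # unclamped input: holds its value
            continue
        if fs.n_predictors == 1:
            j = 0
        else:
            u = rng.random()
            cum = np.cumsum(fs.probs)
            j = int(np.searchsorted(cum, u, side="right"))
            j = min(j, fs.n_predictors - 1)
        nxt[i] = fs.predictors[j](env)
    return nxt


class Simulation:
    """An extendable trajectory of one PBN under fixed clamps.

    States are kept packed as integers (first declared node = most
    significant bit).  When the model is small enough, per-constituent
    next-state lookup tables are precomputed and steps are drawn in blocks;
    otherwise each step falls back to :func:`step`.  Either way the
    trajectory is fully determined by the seed.
    """

    def __init__(self, pbn: PBN, clamps: Mapping[str, int] | None = None,
                 seed: int | np.random.Generator | None = None,
                 initial_state: str | Sequence[int] = "random",
                 allow_non_input_clamps: bool = False):
        if pbn.is_free:
            raise ValueError("PBN has free selection probabilities")
        pbn.validate()
        clamps = dict(clamps or {})
        _check_clamps(pbn, clamps, allow_non_input_clamps)
        self.pbn = pbn
        self.clamps = clamps
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        n = pbn.n
        self._shifts = {node: n - 1 - i for i, node in enumerate(pbn.nodes)}
        self._free_mask_int = 0
        for node in pbn.nodes:
            if node not in clamps:
                self._free_mask_int |= 1 << self._shifts[node]
        self._m = bin(self._free_mask_int).count("1")

        state = self._initial_packed(initial_state)
        self.states: list[int] = [state]
        self._engine = None
        if n <= _ENGINE_MAX_NODES:
            K = 1
            for node, fs in pbn.function_sets.items():
                if node not in clamps:
                    K *= fs.n_predictors
            if (1 << n) * K <= _ENGINE_MAX_CELLS:
                self._engine = self._build_engine(K)

    # -- construction helpers ------------------------------------------------

    def _initial_packed(self, initial_state) -> int:
        pbn, clamps = self.pbn, self.clamps
        if isinstance(initial_state, str) and initial_state == "random":
            bits = self.rng.integers(0, 2, size=pbn.n)
        else:
            bits = np.asarray(initial_state, dtype=np.uint8)
            if bits.shape != (pbn.n,):
                raise ValueError("initial state has wrong length")
        s = 0
        for i, node in enumerate(pbn.nodes):
            v = clamps.get(node, int(bits[i]))
            s |= (v & 1) << self._shifts[node]
        return s

    def _build_engine(self, K: int):
        pbn, clamps = self.pbn, self.clamps
        n = pbn.n
        S = 1 << n
        states = np.arange(S, dtype=np.int64)
        # per-node, per-predictor output over all packed states
        free_updating = [node for node in pbn.nodes
                         if node not in clamps and node in pbn.function_sets]
        pred_out = {}
        for node in free_updating:
            fs = pbn.function_sets[node]
            outs = []
            for pred in fs.predictors:
                k = len(pred.parents)
                idx = np.zeros(S, dtype=np.int64)
                for pos, par in enumerate(pred.parents):
                    bit = (states >> self._shifts[par]) & 1
                    # clamped parents are already fixed inside packed states
                    idx |= bit << (k - 1 - pos)
                outs.append(np.asarray(pred.table, dtype=np.int64)[idx])
            pred_out[node] = outs

        hold_mask = 0  # clamped nodes + unclamped inputs keep their bit
        for node in pbn.nodes:
            if node in clamps or node not in pbn.function_sets:
                hold_mask |= 1 << self._shifts[node]

        maps = np.empty((K, S), dtype=np.int64)
        probs = np.empty(K)
        combos = [[]]
        for node in free_updating:
            fs = pbn.function_sets[node]
            combos = [c + [j] for c in combos for j in range(fs.n_predictors)]
        for k_idx, combo in enumerate(combos):
            nxt = states & hold_mask
            prob = 1.0
            for node, j in zip(free_updating, combo):
                fs = pbn.function_sets[node]
                nxt = nxt | (pred_out[node][j] << self._shifts[node])
                prob *= fs.probs[j]
            maps[k_idx] = nxt
            probs[k_idx] = prob
        p = pbn.perturbation_p
        q_any_flip = 1.0 - (1.0 - p) ** self._m
        free_shifts = [self._shifts[node] for node in pbn.nodes
                       if node not in clamps]
        return {"maps": maps, "cum": np.cumsum(probs), "q": q_any_flip,
                "free_shifts": free_shifts}

    # -- simulation ----------------------------------------------------------

    @property
    def steps(self) -> int:
        return len(self.states) - 1

    def extend(self, n_steps: int):
        """Simulate ``n_steps`` further, appending to the trajectory."""
        if n_steps <= 0:
            return
        if self._engine is not None:
            self._extend_engine(n_steps)
        else:
            self._extend_fallback(n_steps)

    def _extend_engine(self, n_steps: int):
        eng = self._engine
        maps, cum, q = eng["maps"], eng["cum"], eng["q"]
        free_shifts = eng["free_shifts"]
        p = self.pbn.perturbation_p
        rng = self.rng
        s = self.states[-1]
        out = self.states
        remaining = n_steps
        maps_list = [m.tolist() for m in maps] if maps.shape[0] <= 64 else None
        while remaining > 0:
            B = min(remaining, 8192)
            flip_u = rng.random(B)
            ks = np.searchsorted(cum, rng.random(B), side="right")
            np.clip(ks, 0, maps.shape[0] - 1, out=ks)
            ks_l = ks.tolist()
            flips_l = (flip_u < q).tolist()
            for t in range(B):
                if flips_l[t]:
                    # conditional on >= 1 flip: rejection-sample the flip set
                    while True:
                        mask = 0
                        fl = rng.random(len(free_shifts)) < p
                        if fl.any():
                            for sh, f in zip(free_shifts, fl):
                                if f:
                                    mask |= 1 << sh
                            break
                    s ^= mask
                elif maps_list is not None:
                    s = maps_list[ks_l[t]][s]
                else:
                    s = int(maps[ks_l[t], s])
                out.append(s)
            remaining -= B

    def _extend_fallback(self, n_steps: int):
        pbn = self.pbn
        n = pbn.n
        cur = np.array([(self.states[-1] >> self._shifts[node]) & 1
                        for node in pbn.nodes], dtype=np.uint8)
        for _ in range(n_steps):
            cur = step(pbn, cur, self.clamps, self.rng, allow_non_input=True)
            s = 0
            for i, node in enumerate(pbn.nodes):
                s |= int(cur[i]) << self._shifts[node]
            self.states.append(s)

    def trace(self, node: str) -> np.ndarray:
        """Binary trace of one node over the whole trajectory."""
        sh = self._shifts[node]   # KeyError for unknown node
        return (np.asarray(self.states, dtype=np.int64) >> sh) & 1

    def trajectory(self) -> np.ndarray:
        """(steps+1, n) array of bits in node order."""
        arr = np.asarray(self.states, dtype=np.int64)
        cols = [(arr >> self._shifts[node]) & 1 for node in self.pbn.nodes]
        return np.stack(cols, axis=1).astype(np.uint8)


def simulate(pbn: PBN, spec: SimulationSpec) -> np.ndarray:
    """Run a trajectory; returns a (steps+1, n) bit array including the
    initial state.  Reproducible given ``spec.seed``."""
    sim = Simulation(pbn, spec.clamps, seed=spec.seed,
                     initial_state=spec.initial_state)
    sim.extend(spec.steps)
    return sim.trajectory()


def binary_trace(trajectory: np.ndarray, pbn: PBN, node: str) -> np.ndarray:
    """Extract one node's 0/1 sequence from a trajectory array."""
    return np.asarray(trajectory)[:, pbn.node_index(node)]
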