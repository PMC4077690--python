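"""Two-state Markov chain run-length method for steady-state marginals.

To estimate the stationary probability that one node is active, the full
chain is projected onto the two meta-states {node=0, node=1}.  From a
trajectory one estimates the transition probabilities alpha = P(0 -> 1) and
beta = P(1 -> 0), from which follow

    m0 = ceil( log( eps*(alpha+beta) / max(alpha, beta) ) / log|lambda| ),
         lambda = 1 - alpha - beta   (m0 = 1 when lambda = 0)

    N  = ceil( alpha*beta*(2 - alpha - beta) / (alpha+beta)^3
               * ( PhiInv((s+1)/2) / r )^2 )

where m0 is the burn-in to discard, N the run length needed to estimate the
marginal to precision r with confidence s, and PhiInv the standard normal
quantile.  Note the absolute value of lambda (an oscillating chain,
alpha + beta > 1, forgets its start just as fast) and the INVERSE normal
CDF in N — two easy-to-miss details of the derivation.

The estimation protocol starts from (m0, N) = (0, 100), simulates m0 + N
steps, re-estimates alpha and beta from the last N states, recomputes
(m0, N), and extends the SAME trajectory whenever the new m0 + N exceeds
the current length, until it no longer grows.  The marginal is then the
frequency of the active meta-state over the last N states.  A constant
(degenerate) window triggers doubling of the trajectory length, at most 10
times and never beyond ``max_length``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .dynamics import Simulation
from .rules import PBN

__all__ = [
    "ConvergenceSettings",
    "TwoStateDiagnostic",
    "DegenerateTraceError",
    "ConvergenceError",
    "estimate_alpha_beta",
    "burn_in_m0",
    "run_length_N",
    "estimate_marginal",
    "estimate_marginals_multi",
]

_MAX_DOUBLINGS = 10


class DegenerateTraceError(ValueError):
    """Trace is constant (or has no transitions from one of the states)."""


class ConvergenceError(RuntimeError):
    """The iterative protocol could not converge within ``max_length``."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class ConvergenceSettings:
    """Parameters of the run-length method.

    perturbation_p : per-node per-step bit-flip probability (ergodicity)
    r              : required precision of the marginal estimate
    epsilon        : tolerance on the residual influence of the start state
    s              : confidence level for precision r
    """

    perturbation_p: float = 0.001
    r: float = 0.025
    epsilon: float = 0.01
    s: float = 0.95
    initial_m0: int = 0
    initial_N: int = 100
    max_length: int = 1_000_000

    def __post_init__(self):
        if not 0.0 < self.perturbation_p < 1.0:
            raise ValueError("perturbation_p must be in (0, 1)")
        if not 0.0 < self.r < 0.5:
            raise ValueError("r must be in (0, 0.5)")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if not 0.5 < self.s < 1.0:
            raise ValueError("s must be in (0.5, 1)")


@dataclass(frozen=True)
class TwoStateDiagnostic:
    """Result of one marginal estimation."""

    node: str
    alpha: float
    beta: float
    m0: int
    N: int
    estimate: float
    total_length: int

    @property
    def lam(self) -> float:
        """lambda = 1 - alpha - beta of the fitted two-state chain."""
        return 1.0 - self.alpha - self.beta


def estimate_alpha_beta(trace: Sequence[int]) -> tuple[float, float]:
    """Empirical transition probabilities of the 0/1 trace.

    alpha = #(0->1) / #(transitions out of 0), beta likewise from 1.
    Raises :class:`DegenerateTraceError` when either denominator is zero
    (constant trace, or a state visited only at the final position).
    """
    x = np.asarray(trace, dtype=np.int8)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("trace must be a 1-d sequence of length >= 2")
    a, b = x[:-1], x[1:]
    from0 = int((a == 0).sum())
    from1 = int((a == 1).sum())
    if from0 == 0 or from1 == 0:
        raise DegenerateTraceError("no transitions out of one of the states")
    alpha = int(((a == 0) & (b == 1)).sum()) / from0
    beta = int(((a == 1) & (b == 0)).sum()) / from1
    return alpha, beta


def burn_in_m0(alpha: float, beta: float, epsilon: float) -> int:
    """Burn-in length; uses |1 - alpha - beta| so oscillatory chains
    (alpha + beta > 1) are handled correctly."""
    if alpha + beta <= 0.0:
        raise ValueError("alpha + beta must be positive")
    lam = abs(1.0 - alpha - beta)
    if lam == 0.0 or lam >= 1.0:
        # lam = 0: one-step forgetting; lam = 1 only for the deterministic
        # alternation alpha = beta = 1, whose window mean is exact anyway
        return 1
    arg = epsilon * (alpha + beta) / max(alpha, beta)
    if arg >= 1.0:
        return 0
    return max(0, math.ceil(math.log(arg) / math.log(lam)))


def run_length_N(alpha: float, beta: float, r: float, s: float) -> int:
    """Required run length for precision r at confidence s."""
    if alpha + beta <= 0.0:
        raise ValueError("alpha + beta must be positive")
    if not (0.0 < alpha <= 1.0 and 0.0 < beta <= 1.0):
        # alpha or beta = 1 (deterministic reset) is a valid chain; 0 means
        # one transition type was never observed and the window is too short
        raise ValueError("alpha and beta must lie in (0, 1]")
    z = norm.ppf((s + 1.0) / 2.0)
    factor = alpha * beta * (2.0 - alpha - beta) / (alpha + beta) ** 3
    return max(2, math.ceil(factor * (z / r) ** 2))


# --------------------------------------------------------------------------
# Iterative estimation on a growing trajectory
# --------------------------------------------------------------------------

def _requirement(trace: np.ndarray, N: int, settings: ConvergenceSettings):
    """(alpha, beta, m0, N) from the last ``N`` states of ``trace``; raises
    DegenerateTraceError when the window cannot support the formulas."""
    window = trace[-N:]
    alpha, beta = estimate_alpha_beta(window)
    try:
        m0 = burn_in_m0(alpha, beta, settings.epsilon)
        N_new = run_length_N(alpha, beta, settings.r, settings.s)
    except ValueError as exc:
        raise DegenerateTraceError(str(exc)) from exc
    return alpha, beta, m0, N_new


def estimate_marginals_multi(pbn: PBN, nodes: Sequence[str],
                             clamps: Mapping[str, int] | None = None,
                             settings: ConvergenceSettings | None = None,
                             seed: int | np.random.Generator | None = None,
                             sim: Simulation | None = None,
                             ) -> dict[str, TwoStateDiagnostic]:
    """Estimate marginal steady-state probabilities for several nodes from a
    single shared trajectory.

    The trajectory is extended until every node's recomputed m0 + N fits
    within the current length; each node's estimate is the mean of its own
    last-N window.  With a single node this is exactly
    :func:`estimate_marginal`.  Passing an existing ``sim`` continues that
    trajectory instead of starting a new one (e.g. to re-estimate at a
    tighter precision without discarding the samples already drawn); its
    perturbation must match the settings.
    """
    settings = settings or ConvergenceSettings()
    if not nodes:
        raise ValueError("no nodes requested")
    pbn = pbn.with_perturbation(settings.perturbation_p).validate()
    if sim is None:
        sim = Simulation(pbn, clamps, seed=seed)
    elif abs(sim.pbn.perturbation_p - settings.perturbation_p) > 1e-15:
        raise ValueError("existing trajectory uses a different perturbation")

    state: dict[str, dict] = {
        node: {"N": settings.initial_N, "m0": settings.initial_m0,
               "alpha": None, "beta": None, "doublings": 0}
        for node in nodes}
    for node in nodes:
        pbn.node_index(node)  # raise early on unknown nodes

    L = settings.initial_m0 + settings.initial_N
    while True:
        if L > settings.max_length:
            raise ConvergenceError(
                f"required trajectory length {L} exceeds max_length "
                f"{settings.max_length}", diagnostics=state)
        sim.extend(L - sim.steps)
        required = L
        any_degenerate = False
        for node in nodes:
            st = state[node]
            trace = sim.trace(node)
            window = min(st["N"], len(trace))
            try:
                alpha, beta, m0, N_new = _requirement(trace, window, settings)
            except DegenerateTraceError:
                if st["alpha"] is not None and st["m0"] + st["N"] <= L:
                    # already satisfied from an earlier, longer window; a
                    # tiny constant re-estimation window is uninformative,
                    # not a reason to extend
                    continue
                # constant window: double the trajectory (and let this
                # node's window cover all of it) until transitions appear
                any_degenerate = True
                st["doublings"] += 1
                if st["doublings"] > _MAX_DOUBLINGS:
                    raise ConvergenceError(
                        f"trace of {node!r} still degenerate after "
                        f"{_MAX_DOUBLINGS} doublings (length {L})",
                        diagnostics=state)
                st["N"] = 2 * max(window, sim.steps)
                required = max(required, st["m0"] + st["N"])
                continue
            st.update(alpha=alpha, beta=beta, m0=m0, N=N_new)
            required = max(required, m0 + N_new)
        if required <= L and not any_degenerate:
            break
        L = max(required, L)

    out = {}
    for node in nodes:
        st = state[node]
        trace = sim.trace(node)
        N = min(st["N"], len(trace))
        est = float(trace[-N:].mean())
        out[node] = TwoStateDiagnostic(
            node=node, alpha=st["alpha"], beta=st["beta"], m0=st["m0"],
            N=st["N"], estimate=est, total_length=sim.steps)
    return out


def estimate_marginal(pbn: PBN, node: str,
                      clamps: Mapping[str, int] | None = None,
                      settings: ConvergenceSettings | None = None,
                      seed: int | np.random.Generator | None = None,
                      ) -> TwoStateDiagnostic:
    """Marginal steady-state probability of one node (see module docstring
    for the protocol)."""
    return estimate_marginals_multi(pbn, [node], clamps, settings, seed)[node]
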