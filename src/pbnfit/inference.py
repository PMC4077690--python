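"""Fitting selection probabilities to multi-experiment steady-state data.

The estimation problem: a PBN template in which some selection
probabilities are free, plus a set of experimental conditions, each given
by input-node clamps and normalised measurements in [0, 1] of a subset of
nodes.  The objective is the sum of squared errors between the model's
marginal steady-state probabilities and the measurements, summed over all
experiments and measured nodes.

Two parameterisations are supported.  In *discrete* mode every free
predictor is switched on or off; the selected predictors of a node share
the node's probability mass equally (a candidate that switches off all
predictors of some node is scored +inf, not repaired).  In *continuous*
mode the optimiser works on the box [0, 1]^k and each node's raw values are
normalised to the node's mass (an all-zero node falls back to uniform).

The user-facing surface follows the Model/Results idiom:

>>> model = PBNInference(pbn, experiments, mode="continuous")
>>> res = model.fit(budget=5000, seed=1)
>>> res.params, res.cost, res.summary()
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import differential_evolution

from . import ensemble as _ensemble
from .convergence import ConvergenceSettings, estimate_marginals_multi
from .exact import exact_marginal
from .rules import PBN

__all__ = [
    "ExperimentCondition",
    "OptimizationProblem",
    "ParameterSample",
    "assemble_problem",
    "decode_discrete",
    "decode_continuous",
    "sse_cost",
    "optimize",
    "resimulate",
    "load_experiments",
    "PBNInference",
    "PBNInferenceResults",
]

_ZERO_COST_TOL = 1e-12


@dataclass(frozen=True)
class ExperimentCondition:
    """One experimental condition: clamps on input nodes and measured
    steady-state activities (normalised to [0, 1])."""

    name: str
    clamps: Mapping[str, int]
    measurements: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "clamps", dict(self.clamps))
        object.__setattr__(self, "measurements", dict(self.measurements))
        for node, v in self.measurements.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(
                    f"experiment {self.name!r}: measurement for {node!r} "
                    f"outside [0, 1]")


@dataclass(frozen=True)
class ParameterSample:
    """One evaluated candidate with provenance."""

    raw: tuple[float, ...]
    decoded: Mapping[tuple[str, int], float]
    cost: float
    seed: int | None
    iteration: int

    def __post_init__(self):
        object.__setattr__(self, "decoded", dict(self.decoded))


@dataclass(frozen=True)
class OptimizationProblem:
    """Assembled estimation problem (immutable)."""

    pbn: PBN
    free_index: tuple[tuple[str, int], ...]   # (node, predictor j), ordered
    experiments: tuple[ExperimentCondition, ...]
    mode: str                                  # "discrete" | "continuous"
    settings: ConvergenceSettings
    backend: str = "exact"                     # "exact" | "simulation"
    exact_p: float = 0.0

    @property
    def k(self) -> int:
        return len(self.free_index)

    def free_groups(self):
        """Per-node grouping: list of (node, positions, mass).

        ``positions`` indexes into the flat parameter vector; ``mass`` is
        the probability left for the node's free predictors (1 minus the
        node's fixed probabilities)."""
        groups = []
        by_node: dict[str, list[int]] = {}
        for pos, (node, _) in enumerate(self.free_index):
            by_node.setdefault(node, []).append(pos)
        for node in self.pbn.nodes:
            if node not in by_node:
                continue
            fs = self.pbn.function_sets[node]
            fixed = sum(c for c, f in zip(fs.probs, fs.free_mask) if not f)
            groups.append((node, by_node[node], 1.0 - fixed))
        return groups

    def param_labels(self) -> list[str]:
        labels = []
        for node, j in self.free_index:
            expr = self.pbn.function_sets[node].predictors[j].expression()
            labels.append(f"{node}[{j}] {expr}")
        return labels


def assemble_problem(pbn: PBN, experiments: Sequence[ExperimentCondition],
                     mode: str = "continuous",
                     settings: ConvergenceSettings | None = None,
                     backend: str = "exact",
                     exact_p: float = 0.0) -> OptimizationProblem:
    """Validate and combine a free-parameter PBN with experiments.

    Free parameters are ordered by node declaration order, then predictor
    order, which fixes the optimiser vector layout.
    """
    pbn.validate()
    if mode not in ("discrete", "continuous"):
        raise ValueError("mode must be 'discrete' or 'continuous'")
    if backend not in ("exact", "simulation"):
        raise ValueError("backend must be 'exact' or 'simulation'")
    if not experiments:
        raise ValueError("at least one experiment is required")
    free_index = []
    for node in pbn.nodes:
        fs = pbn.function_sets.get(node)
        if fs is None:
            continue
        for j, f in enumerate(fs.free_mask):
            if f:
                free_index.append((node, j))
    if not free_index:
        raise ValueError("no free selection probabilities to optimise")
    inputs = set(pbn.inputs)
    for exp in experiments:
        for node in exp.clamps:
            if node not in pbn.nodes:
                raise KeyError(
                    f"experiment {exp.name!r}: clamp on unknown node {node!r}")
            if node not in inputs:
                raise ValueError(
                    f"experiment {exp.name!r}: clamp on non-input node {node!r}")
        for node, v in exp.measurements.items():
            if node not in pbn.nodes:
                raise KeyError(
                    f"experiment {exp.name!r}: measurement on unknown node "
                    f"{node!r}")
            if node in exp.clamps and float(v) != float(exp.clamps[node]):
                raise ValueError(
                    f"experiment {exp.name!r}: node {node!r} measured as {v} "
                    f"but clamped to {exp.clamps[node]}")
    return OptimizationProblem(
        pbn=pbn, free_index=tuple(free_index), experiments=tuple(experiments),
        mode=mode, settings=settings or ConvergenceSettings(),
        backend=backend, exact_p=exact_p)


# --------------------------------------------------------------------------
# Decoding optimiser variables into selection probabilities
# --------------------------------------------------------------------------

def decode_discrete(bits: Sequence[int], problem: OptimizationProblem):
    """Equal-split decoding of a 0/1 selection vector.

    Returns ``(decoded, valid)``: selected predictors of a node share the
    node's free mass equally; a node with no selected predictor makes the
    candidate invalid (``valid=False``, to be scored +inf).
    """
    bits = [int(round(b)) for b in bits]
    if len(bits) != problem.k:
        raise ValueError("wrong parameter vector length")
    decoded: dict[tuple[str, int], float] = {}
    valid = True
    for node, positions, mass in problem.free_groups():
        sel = [p for p in positions if bits[p] == 1]
        if not sel:
            valid = False
            for p in positions:
                decoded[problem.free_index[p]] = 0.0
            continue
        share = mass / len(sel)
        for p in positions:
            decoded[problem.free_index[p]] = share if p in sel else 0.0
    return decoded, valid


def decode_continuous(raw: Sequence[float], problem: OptimizationProblem,
                      warn_all_zero: bool = False):
    """Per-node normalisation of box-constrained raw variables onto the
    node's free probability mass; an all-zero node decodes to uniform."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (problem.k,):
        raise ValueError("wrong parameter vector length")
    if raw.min() < -1e-12 or raw.max() > 1.0 + 1e-12:
        raise ValueError("raw parameters must lie in [0, 1]")
    decoded: dict[tuple[str, int], float] = {}
    for node, positions, mass in problem.free_groups():
        vals = raw[positions]
        total = vals.sum()
        if total <= 0.0:
            if warn_all_zero:
                warnings.warn(
                    f"all-zero raw vector for node {node!r}; decoding to "
                    "uniform selection probabilities")
            vals = np.full(len(positions), 1.0 / len(positions))
            total = 1.0
        for p, v in zip(positions, vals):
            decoded[problem.free_index[p]] = float(v / total * mass)
    return decoded


# --------------------------------------------------------------------------
# Objective
# --------------------------------------------------------------------------

def _experiment_marginals(pbn: PBN, exp: ExperimentCondition,
                          problem: OptimizationProblem,
                          rng_seed) -> dict[str, float]:
    nodes = sorted(exp.measurements)
    if problem.backend == "exact":
        return {node: exact_marginal(pbn, node, exp.clamps, p=problem.exact_p)
                for node in nodes}
    diags = estimate_marginals_multi(pbn, nodes, exp.clamps,
                                     problem.settings, seed=rng_seed)
    return {node: diags[node].estimate for node in nodes}


def sse_cost(decoded: Mapping[tuple[str, int], float],
             problem: OptimizationProblem, seed: int | None = None) -> float:
    """Sum over experiments and measured nodes of squared deviations between
    estimated steady-state marginals and measurements."""
    pbn = problem.pbn.with_probs(decoded)
    total = 0.0
    base = np.random.SeedSequence(0 if seed is None else seed)
    children = base.spawn(len(problem.experiments))
    for exp, child in zip(problem.experiments, children):
        try:
            marg = _experiment_marginals(
                pbn, exp, problem, np.random.default_rng(child))
        except Exception as exc:
            raise RuntimeError(
                f"marginal estimation failed for experiment {exp.name!r}: "
                f"{exc}") from exc
        for node, y in exp.measurements.items():
            total += (marg[node] - float(y)) ** 2
    return total


# --------------------------------------------------------------------------
# Optimisers
# --------------------------------------------------------------------------

def _eval_seed(global_seed: int | None, iteration: int) -> int:
    ss = np.random.SeedSequence([0 if global_seed is None else global_seed,
                                 iteration])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _optimize_discrete_exhaustive(problem, seed):
    samples = []
    for it, bits in enumerate(itertools.product((0, 1), repeat=problem.k)):
        decoded, valid = decode_discrete(bits, problem)
        if valid:
            cost = sse_cost(decoded, problem, seed=_eval_seed(seed, it))
        else:
            cost = math.inf
        samples.append(ParameterSample(tuple(float(b) for b in bits),
                                       decoded, cost, seed, it))
    return samples


def _optimize_discrete_ga(problem, seed, budget, pop_size=32,
                          mutation_rate=None):
    """Simple generational GA over bit strings (tournament selection,
    uniform crossover, per-bit mutation, elitism)."""
    rng = np.random.default_rng(seed)
    k = problem.k
    mutation_rate = mutation_rate or 1.0 / k
    samples = []
    it = 0

    def evaluate(bits):
        nonlocal it
        decoded, valid = decode_discrete(bits, problem)
        cost = (sse_cost(decoded, problem, seed=_eval_seed(seed, it))
                if valid else math.inf)
        samples.append(ParameterSample(tuple(float(b) for b in bits),
                                       decoded, cost, seed, it))
        it += 1
        return cost

    pop = [rng.integers(0, 2, size=k) for _ in range(pop_size)]
    costs = [evaluate(ind) for ind in pop]
    while it < budget:
        order = np.argsort(costs, kind="stable")
        elite = pop[order[0]].copy()
        new_pop = [elite]
        while len(new_pop) < pop_size:
            picks = rng.integers(0, pop_size, size=4)
            pa = pop[min(picks[:2], key=lambda i: costs[i])]
            pb = pop[min(picks[2:], key=lambda i: costs[i])]
            mask = rng.integers(0, 2, size=k).astype(bool)
            child = np.where(mask, pa, pb)
            flip = rng.random(k) < mutation_rate
            child = child ^ flip
            new_pop.append(child.astype(int))
        pop = new_pop
        costs = [evaluate(ind) for ind in pop]
        if it >= budget:
            break
    return samples


def _optimize_continuous_de(problem, seed, budget, de_options=None):
    """Differential evolution (rand/1/bin, F=0.8, CR=0.9) over [0,1]^k.

    All cost evaluations are recorded; if DE converges before the budget is
    spent, the remainder is filled with uniform random samples so the
    returned ensemble always holds >= budget evaluations.
    """
    k = problem.k
    samples = []
    it = 0

    def func(x):
        nonlocal it
        decoded = decode_continuous(np.clip(x, 0.0, 1.0), problem)
        cost = sse_cost(decoded, problem, seed=_eval_seed(seed, it))
        samples.append(ParameterSample(tuple(float(v) for v in x),
                                       decoded, cost, seed, it))
        it += 1
        return cost

    opts = dict(strategy="rand1bin", mutation=0.8, recombination=0.9,
                popsize=15, tol=0.0, polish=False, init="latinhypercube")
    opts.update(de_options or {})
    pop_members = max(5, opts["popsize"] * k)
    maxiter = max(1, math.ceil(budget / pop_members))
    differential_evolution(
        func, bounds=[(0.0, 1.0)] * k, maxiter=maxiter,
        seed=None if seed is None else seed, **opts)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    while it < budget:
        func(rng.random(k))
    return samples


def optimize(problem: OptimizationProblem, seed: int | None = None,
             budget: int = 5000, method: str | None = None,
             **options) -> list[ParameterSample]:
    """Run the mode-appropriate optimiser and return all evaluated samples
    ranked by cost (ties by iteration order).

    Discrete mode enumerates every selection vector when there are at most
    2^20 candidates and falls back to a genetic bit-string search beyond
    that; continuous mode uses differential evolution.  ``method`` can force
    ``"exhaustive"``, ``"ga"`` or ``"de"``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if problem.mode == "discrete":
        if method == "ga" or (method is None and problem.k > 20):
            samples = _optimize_discrete_ga(problem, seed, budget, **options)
        else:
            samples = _optimize_discrete_exhaustive(problem, seed)
    else:
        samples = _optimize_continuous_de(problem, seed, budget,
                                          de_options=options or None)
    ranked = sorted(samples, key=lambda smp: (smp.cost, smp.iteration))
    if not ranked or not math.isfinite(ranked[0].cost):
        raise RuntimeError("optimisation produced no finite-cost sample")
    return ranked


def resimulate(sample: ParameterSample, problem: OptimizationProblem,
               seed: int | None = None) -> pd.DataFrame:
    """Re-evaluate a fitted candidate: per experiment and measured node the
    estimated marginal, the measurement and the squared error.  With the
    simulation backend a fresh seed gives slightly different estimates."""
    pbn = problem.pbn.with_probs(sample.decoded)
    rows = []
    base = np.random.SeedSequence(0 if seed is None else seed)
    children = base.spawn(len(problem.experiments))
    for exp, child in zip(problem.experiments, children):
        marg = _experiment_marginals(pbn, exp, problem,
                                     np.random.default_rng(child))
        for node in sorted(exp.measurements):
            est = marg[node]
            y = float(exp.measurements[node])
            rows.append({"experiment": exp.name, "node": node,
                         "estimate": est, "measured": y,
                         "squared_error": (est - y) ** 2})
    return pd.DataFrame(rows)


def load_experiments(path) -> list[ExperimentCondition]:
    """Read experiments from a YAML/JSON file: a list of
    ``{name, clamps: {node: 0|1}, measurements: {node: float}}``."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ValueError("experiments file must contain a list of conditions")
    out = []
    for entry in data:
        out.append(ExperimentCondition(
            name=str(entry["name"]),
            clamps={str(k): int(v) for k, v in (entry.get("clamps") or {}).items()},
            measurements={str(k): float(v)
                          for k, v in (entry.get("measurements") or {}).items()}))
    return out


# --------------------------------------------------------------------------
# Model / Results facade
# --------------------------------------------------------------------------

class PBNInference:
    """Selection-probability inference model.

    Parameters
    ----------
    pbn : PBN
        Template with free (``?``) selection probabilities.
    experiments : sequence of ExperimentCondition
    mode : "continuous" or "discrete"
    settings : ConvergenceSettings, used by the simulation backend
    backend : "exact" (brute-force stationary solve, small models) or
        "simulation" (trajectory + two-state run-length method)
    exact_p : perturbation used by the exact backend (0 = unperturbed limit)
    """

    def __init__(self, pbn: PBN, experiments: Sequence[ExperimentCondition],
                 mode: str = "continuous",
                 settings: ConvergenceSettings | None = None,
                 backend: str = "exact", exact_p: float = 0.0):
        self.problem = assemble_problem(pbn, experiments, mode=mode,
                                        settings=settings, backend=backend,
                                        exact_p=exact_p)

    @classmethod
    def from_files(cls, model_path, experiments_path, **kwargs):
        from .rules import load_model
        return cls(load_model(model_path), load_experiments(experiments_path),
                   **kwargs)

    def fit(self, budget: int = 5000, seed: int | None = None,
            method: str | None = None, **options) -> "PBNInferenceResults":
        samples = optimize(self.problem, seed=seed, budget=budget,
                           method=method, **options)
        return PBNInferenceResults(self, samples, seed)


class PBNInferenceResults:
    """Fit results: the best candidate plus the full evaluated ensemble."""

    def __init__(self, model: PBNInference, samples: list[ParameterSample],
                 seed: int | None):
        self.model = model
        self.problem = model.problem
        self.samples = samples          # ranked by (cost, iteration)
        self.seed = seed
        self.best = samples[0]
        self.cost = self.best.cost
        labels = self.problem.param_labels()
        self.params = pd.Series(
            [self.best.decoded[key] for key in self.problem.free_index],
            index=labels, name="c")

    # -- ensemble statistics (analysis module) ------------------------------

    def top_k(self, K: int = 500) -> list[ParameterSample]:
        return _ensemble.top_k(self.samples, K)

    def ensemble_summary(self, K: int = 500) -> pd.DataFrame:
        return _ensemble.summarise(self.top_k(K), self.problem).table

    def scatter_data(self, parameters: Sequence[str] | None = None,
                     K: int = 500) -> pd.DataFrame:
        params = (list(parameters) if parameters is not None
                  else self.problem.param_labels())
        return _ensemble.scatter_export(self.top_k(K), params, self.problem)

    # -- diagnostics --------------------------------------------------------

    def resimulate(self, seed: int | None = None) -> pd.DataFrame:
        return resimulate(self.best, self.problem, seed=seed)

    def zero_cost_support(self, tol: float = _ZERO_COST_TOL) -> pd.Series:
        """Discrete mode: the decoded probabilities of the largest
        zero-cost candidate (all individually consistent predictors with
        equal share), mirroring per-experiment consistency reporting."""
        if self.problem.mode != "discrete":
            raise ValueError("zero_cost_support is defined for discrete mode")
        zero = [smp for smp in self.samples if smp.cost <= tol]
        if not zero:
            raise ValueError("no zero-cost candidate")
        best = max(zero, key=lambda smp: sum(smp.raw))
        return pd.Series([best.decoded[key] for key in self.problem.free_index],
                         index=self.problem.param_labels(), name="c")

    def n_zero_cost(self, tol: float = _ZERO_COST_TOL) -> int:
        return sum(1 for smp in self.samples if smp.cost <= tol)

    def summary(self, K: int = 500) -> str:
        prob = self.problem
        lines = [
            "PBN selection-probability inference",
            "=" * 51,
            f"mode:        {prob.mode}",
            f"backend:     {prob.backend}",
            f"experiments: {len(prob.experiments)}",
            f"free params: {prob.k}",
            f"samples:     {len(self.samples)}",
            f"best cost:   {self.cost:.6g}",
            "",
        ]
        table = self.ensemble_summary(K=min(K, len(self.samples)))
        lines.append(table.to_string(float_format=lambda v: f"{v:8.4f}"))
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PBNInferenceResults mode={self.problem.mode} "
                f"k={self.problem.k} cost={self.cost:.4g}>")
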