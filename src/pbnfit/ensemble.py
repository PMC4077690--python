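"""Statistics over ensembles of fitted parameter samples.

A parameter whose distribution over the best-K samples is tightly
clustered (SD small against its mean) is identifiable and the model output
is sensitive to it; a wide spread flags a parameter the data cannot pin
down.  No formal test is attached — the summary reports mean/SD/min/max and
long-format scatter data for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EnsembleSummary", "top_k", "summarise", "scatter_export"]


@dataclass(frozen=True)
class EnsembleSummary:
    K: int
    table: pd.DataFrame          # index: parameter; mean, sd, min, max
    best_cost: float
    worst_cost: float


def top_k(samples: Sequence, K: int) -> list:
    """K lowest-cost samples; ties broken by iteration order.  Asking for
    more samples than exist returns everything with a warning."""
    if K < 1:
        raise ValueError("K must be >= 1")
    ordered = sorted(samples, key=lambda smp: (smp.cost, smp.iteration))
    if K > len(ordered):
        warnings.warn(f"requested top {K} of only {len(ordered)} samples")
        return ordered
    return ordered[:K]


def _sample_matrix(subset, problem):
    labels = problem.param_labels()
    data = np.array([[smp.decoded[key] for key in problem.free_index]
                     for smp in subset])
    return labels, data


def summarise(subset: Sequence, problem) -> EnsembleSummary:
    """Per-parameter mean, population SD, min and max over the subset."""
    if not subset:
        raise ValueError("empty sample subset")
    labels, data = _sample_matrix(subset, problem)
    table = pd.DataFrame({
        "mean": data.mean(axis=0),
        "sd": data.std(axis=0),          # population SD (divide by K)
        "min": data.min(axis=0),
        "max": data.max(axis=0),
    }, index=labels)
    costs = [smp.cost for smp in subset]
    return EnsembleSummary(K=len(subset), table=table,
                           best_cost=min(costs), worst_cost=max(costs))


def scatter_export(subset: Sequence, parameters: Sequence[str],
                   problem) -> pd.DataFrame:
    """Long-format table (sample, parameter, value, cost) for scatter
    plots of the fitted ensemble."""
    if not subset:
        raise ValueError("empty sample subset")
    if not parameters:
        raise ValueError("at least one parameter must be named")
    labels = problem.param_labels()
    for name in parameters:
        if name not in labels:
            raise KeyError(f"unknown parameter {name!r}")
    key_of = dict(zip(labels, problem.free_index))
    rows = []
    for i, smp in enumerate(subset):
        for name in parameters:
            rows.append({"sample": i, "parameter": name,
                         "value": smp.decoded[key_of[name]],
                         "cost": smp.cost})
    return pd.DataFrame(rows)
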