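"""Bundled benchmark models and data for the inference pipeline.

Three small signalling case studies with known generating parameters, the
printed model-vs-measurement table of a large hepatocyte apoptosis study,
and a random-PBN generator for property tests.  Every bundle's data values
equal the exact stationary marginals of its generating ("truth") model in
the unperturbed limit, so recovery can be checked against a known answer.

The condition letterings (A-D, A-F) are reconstructions: the published
input tables are figures, so the assignments here are inferred from the
per-condition consistency patterns and worked arithmetic the studies report
rather than read cell-for-cell from the figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import ExperimentCondition
from .rules import PBN, build_pbn, parse_rules

__all__ = ["CaseStudyBundle", "example_pbn", "case1", "case2", "case3",
           "table5_data", "table5_sse", "random_pbn"]


@dataclass(frozen=True)
class CaseStudyBundle:
    """A rule file, its experiments, and the generating parameters."""

    name: str
    rules: str
    experiments: tuple[ExperimentCondition, ...]
    truth: Mapping[tuple[str, int], float]    # (node, predictor j) -> c
    node_order: tuple[str, ...] | None = None

    def pbn(self, perturbation_p: float = 0.001) -> PBN:
        """The template PBN with free selection probabilities."""
        return build_pbn(parse_rules(self.rules), perturbation_p,
                         node_order=self.node_order)

    def truth_pbn(self, perturbation_p: float = 0.001) -> PBN:
        """The generating PBN with the truth parameters substituted."""
        return self.pbn(perturbation_p).with_probs(self.truth)


def example_pbn(perturbation_p: float = 0.001) -> PBN:
    """The canonical three-node example: N1 activates N3 (c = 0.6), N1 with
    N2's inhibition drives it with c = 0.4.  With both inputs clamped ON the
    chain restricted to N3 is an ergodic two-state chain with stationary
    P(N3 = 1) = 0.6."""
    rules = "N3 = N1 : 0.6\nN3 = N1 & ~N2 : 0.4\n"
    return build_pbn(parse_rules(rules), perturbation_p,
                     node_order=("N1", "N2", "N3"))


def case1() -> CaseStudyBundle:
    """Rule selection for NFkB from PI3K and TNFa (discrete mode).

    Five candidate rules (OR, AND, PI3K alone, TNFa alone, constant 0); the
    generating network uses the AND gate only.  The four conditions cover
    all input combinations; the (inferred) assignment (0,0)->0, (1,0)->0,
    (0,1)->0, (1,1)->1 is the unique one consistent with the published
    per-condition rule-consistency pattern.
    """
    rules = (
        "NFkB = PI3K | TNFa : ?\n"
        "NFkB = PI3K & TNFa : ?\n"
        "NFkB = PI3K : ?\n"
        "NFkB = TNFa : ?\n"
        "NFkB = 0 : ?\n"
    )
    combos = {"A": (0, 0, 0.0), "B": (1, 0, 0.0), "C": (0, 1, 0.0),
              "D": (1, 1, 1.0)}
    experiments = tuple(
        ExperimentCondition(name, {"PI3K": pi, "TNFa": tn}, {"NFkB": y})
        for name, (pi, tn, y) in combos.items())
    truth = {("NFkB", 0): 0.0, ("NFkB", 1): 1.0, ("NFkB", 2): 0.0,
             ("NFkB", 3): 0.0, ("NFkB", 4): 0.0}
    return CaseStudyBundle("case1", rules, experiments, truth,
                           node_order=("PI3K", "TNFa", "NFkB"))


def case2() -> CaseStudyBundle:
    """PIP3 regulation by PI3K and PTEN (continuous mode).

    Same topology as :func:`example_pbn` with biological labels.  Candidate
    rules: PI3K alone, PTEN alone, PI3K & ~PTEN, constant 0; generating
    weights (0.6, 0, 0.4, 0).  Data are the exact stationary marginals:
    (0,0)->0, (1,0)->1, (0,1)->0, (1,1)->0.6.  Conditions A=(0,0) and
    D=(1,1) are fixed by the published A,D-only degeneracy analysis; the
    B/C assignment is this package's convention.
    """
    rules = (
        "PIP3 = PI3K : ?\n"
        "PIP3 = PTEN : ?\n"
        "PIP3 = PI3K & ~PTEN : ?\n"
        "PIP3 = 0 : ?\n"
    )
    combos = {"A": (0, 0, 0.0), "B": (1, 0, 1.0), "C": (0, 1, 0.0),
              "D": (1, 1, 0.6)}
    experiments = tuple(
        ExperimentCondition(name, {"PI3K": pi, "PTEN": pt}, {"PIP3": y})
        for name, (pi, pt, y) in combos.items())
    truth = {("PIP3", 0): 0.6, ("PIP3", 1): 0.0, ("PIP3", 2): 0.4,
             ("PIP3", 3): 0.0}
    return CaseStudyBundle("case2", rules, experiments, truth,
                           node_order=("PI3K", "PTEN", "PIP3"))


def case3() -> CaseStudyBundle:
    """Weighted toy signalling model with inhibitor treatments (continuous).

    Eight nodes: inputs TGFa and TNFa plus two inhibitor-treatment inputs
    PI3Ki and Rafi; TGFa activates PI3K and Raf; NFkB integrates disjoint
    activating signals from PI3K (weight 0.7) and TNFa (0.3); ERK from Raf
    (0.6) and NFkB (0.4).  The weight pairs on NFkB and ERK are the free
    parameters.

    Each inhibitor removes 70% of its target's activation.  This is encoded
    inside one fixed PBN by giving the target two predictors,
    ``TGFa`` with c = 0.3 and ``TGFa & ~inhibitor`` with c = 0.7: with the
    inhibitor input clamped ON the second predictor is constantly 0, which
    is exactly an extra constant-0 predictor with selection probability
    equal to the efficacy, and with the inhibitor OFF both predictors
    coincide with plain activation.

    Data are the exact stationary marginals of the truth model, which equal
    the disjoint signal-summing arithmetic (e.g. condition D, both ligands
    ON with the PI3K inhibitor: NFkB = 0.7*0.3 + 0.3*1 = 0.51).  The ERK
    weights (0.6, 0.4) and the 0.7 inhibitor efficacy are inferred from the
    published best-fit values and the worked example.
    """
    rules = (
        "PI3K = TGFa : 0.3\n"
        "PI3K = TGFa & ~PI3Ki : 0.7\n"
        "Raf = TGFa : 0.3\n"
        "Raf = TGFa & ~Rafi : 0.7\n"
        "NFkB = PI3K : ?\n"
        "NFkB = TNFa : ?\n"
        "ERK = Raf : ?\n"
        "ERK = NFkB : ?\n"
    )
    truth = {("NFkB", 0): 0.7, ("NFkB", 1): 0.3,
             ("ERK", 0): 0.6, ("ERK", 1): 0.4}

    # (TGFa, TNFa, PI3Ki, Rafi) per condition; measurements are the exact
    # stationary marginals of the truth model (disjoint signal summing).
    conditions = {
        "A": (1, 0, 0, 0),
        "B": (0, 1, 0, 0),
        "C": (1, 1, 0, 0),
        "D": (1, 1, 1, 0),   # worked example: NFkB = 0.3*0.7 + 0.3 = 0.51
        "E": (1, 1, 0, 1),
        "F": (1, 0, 1, 0),
    }
    experiments = []
    for name, (tgfa, tnfa, pi3ki, rafi) in conditions.items():
        pi3k = tgfa * (1.0 - 0.7 * pi3ki)
        raf = tgfa * (1.0 - 0.7 * rafi)
        nfkb = 0.7 * pi3k + 0.3 * tnfa
        erk = 0.6 * raf + 0.4 * nfkb
        experiments.append(ExperimentCondition(
            name,
            {"TGFa": tgfa, "TNFa": tnfa, "PI3Ki": pi3ki, "Rafi": rafi},
            {"PI3K": pi3k, "Raf": raf, "NFkB": nfkb, "ERK": erk}))
    return CaseStudyBundle(
        "case3", rules, tuple(experiments), truth,
        node_order=("TGFa", "TNFa", "PI3Ki", "Rafi",
                    "PI3K", "Raf", "NFkB", "ERK"))


# --------------------------------------------------------------------------
# Printed model-vs-measurement table of the apoptosis study
# --------------------------------------------------------------------------

_TABLE5_CONDITIONS = ["Mock", "FasL (2)", "IL-1", "TNF", "UV1", "UV2"]

# (output, column) -> six values in condition order
_TABLE5 = {
    ("Apoptosis", "Orig."): [0, 1, 0, 0, 1, 0],
    ("Apoptosis", "Init."): [0.0000, 0.9208, 0.0028, 0.0020, 0.9920, 0.4681],
    ("Apoptosis", "Ext."):  [0.0054, 0.7170, 0.0063, 0.0018, 0.9868, 0.4914],
    ("Apoptosis", "Meas."): [0.00, 0.63, 0.00, 0.10, 1.00, 0.49],
    ("C3ap17", "Orig."):    [0, 1, 0, 0, 1, 0],
    ("C3ap17", "Init."):    [0.0168, 0.9505, 0.0042, 0.4073, 0.9966, 0.0016],
    ("C3ap17", "Ext."):     [0.0082, 0.8491, 0.0013, 0.4049, 0.9901, 0.0012],
    ("C3ap17", "Meas."):    [0.00, 1.00, 0.03, 0.39, 1.00, 0.00],
    ("NFkB", "Orig."):      [0, 0, 1, 1, 0, 1],
    ("NFkB", "Init."):      [0.0168, 0.0198, 0.8873, 0.7889, 0.0023, 0.3083],
    ("NFkB", "Ext."):       [0.0027, 0.1501, 0.8481, 0.8723, 0.0033, 0.2932],
    ("NFkB", "Meas."):      [0.00, 0.32, 1.00, 0.98, 0.26, 0.46],
}


def table5_data() -> pd.DataFrame:
    """Steady-state activities of the apoptosis model's three measured
    outputs under six stimulation conditions: the original Boolean model
    (Orig.), the fitted initial and extended PBN variants (Init., Ext.) and
    the normalised measurements (Meas.).  72 printed values, embedded
    verbatim; index = condition, columns = (output, model)."""
    frame = pd.DataFrame(_TABLE5, index=_TABLE5_CONDITIONS)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["output", "model"])
    return frame


def table5_sse(model: str) -> float:
    """SSE of one model column ('Orig.', 'Init.' or 'Ext.') against the
    measurements, summed over the three outputs and six conditions."""
    frame = table5_data()
    total = 0.0
    for output in frame.columns.levels[0]:
        diff = frame[(output, model)].to_numpy(float) \
            - frame[(output, "Meas.")].to_numpy(float)
        total += float((diff ** 2).sum())
    return total


# --------------------------------------------------------------------------
# Random PBNs for property tests
# --------------------------------------------------------------------------

def random_pbn(n_nodes: int, max_rules: int = 3, seed: int | None = None,
               perturbation_p: float = 0.001) -> PBN:
    """Random PBN for property tests: every node gets 1..max_rules
    predictors over <= 3 random parents with non-constant truth tables and
    Dirichlet(1) selection probabilities.

    Constant truth-table rows are rejected — a constant predictor encodes
    no interaction and produces nearly-frozen traces whose run-length
    requirement explodes; random *interactions* are the intent here.  With
    any positive perturbation the resulting chain is ergodic.
    """
    if not 2 <= n_nodes <= 10:
        raise ValueError("n_nodes must be between 2 and 10")
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_nodes)]
    from .rules import NodeFunctionSet, PredictorFunction

    sets = {}
    for node in names:
        l = int(rng.integers(1, max_rules + 1))
        preds, seen = [], set()
        while len(preds) < l:
            k = int(rng.integers(1, min(3, n_nodes) + 1))
            parents = tuple(rng.choice(names, size=k, replace=False))
            table = tuple(int(b) for b in rng.integers(0, 2, size=2 ** k))
            if len(set(table)) < 2:
                continue          # reject constant rows
            cand = PredictorFunction(node, parents, table)
            sig = cand.canonical()
            if sig in seen:
                continue
            seen.add(sig)
            preds.append(cand)
        c = rng.dirichlet(np.ones(l))
        c = c / c.sum()
        sets[node] = NodeFunctionSet(node, tuple(preds),
                                     tuple(float(x) for x in c),
                                     (False,) * l)
    return PBN(tuple(names), sets, perturbation_p).validate()
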