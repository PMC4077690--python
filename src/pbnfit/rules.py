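"""Rule-based specification of probabilistic Boolean networks.

A PBN is declared one Boolean predictor per line::

    NFkB = PI3K & TNFa : 0.4     # fixed selection probability
    NFkB = PI3K | TNFa : ?       # free parameter, to be inferred
    PIP3 = PI3K & ~PTEN          # probability omitted -> 1.0

The expression grammar supports identifiers, ``&`` (and), ``|`` (or), ``~``
(not), parentheses and the literals ``0``/``1``.  Lines starting with ``#``
and blank lines are ignored.  Identifiers that never appear on a left-hand
side are input nodes: they carry no update function and take their value
from experimental clamping (or hold their initial value).

Node order is declaration order and fixes the state-vector layout: the
first declared node is the leftmost bit of a rendered state string.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FREE",
    "ParseError",
    "PredictorFunction",
    "NodeFunctionSet",
    "PBN",
    "ParsedRule",
    "parse_rule",
    "parse_rules",
    "build_pbn",
    "load_model",
    "truth_table",
    "state_to_string",
    "string_to_state",
]

#: Sentinel marking a selection probability as a free optimisation parameter.
FREE = "?"

_PROB_TOL = 1e-9


class ParseError(ValueError):
    """Syntax error in a rule line; carries line/column information."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {col}" if col is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


# --------------------------------------------------------------------------
# Expression parsing
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<lit>[01])"
                       r"|(?P<op>[&|~()]))")


def _tokenize(expr: str, line_no: int | None):
    pos, tokens = 0, []
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {expr[pos:].strip()[0]!r}",
                             line_no, pos + 1)
        if m.group("ident"):
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        elif m.group("lit"):
            tokens.append(("lit", int(m.group("lit")), m.start("lit")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive descent over  expr := term ('|' term)* ; term := factor ('&' factor)* ;
    factor := '~' factor | '(' expr ')' | IDENT | 0 | 1."""

    def __init__(self, tokens, line_no):
        self.tokens = tokens
        self.i = 0
        self.line_no = line_no
        self.parents: list[str] = []  # order of first appearance

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.line_no)
        self.i += 1
        return tok

    def parse(self):
        if not self.tokens:
            raise ParseError("empty expression", self.line_no)
        node = self._expr()
        if self._peek() is not None:
            tok = self._peek()
            raise ParseError(f"unexpected token {tok[1]!r}", self.line_no, tok[2] + 1)
        return node

    def _expr(self):
        node = self._term()
        while (tok := self._peek()) and tok[:2] == ("op", "|"):
            self._next()
            rhs = self._term()
            node = ("or", node, rhs)
        return node

    def _term(self):
        node = self._factor()
        while (tok := self._peek()) and tok[:2] == ("op", "&"):
            self._next()
            rhs = self._factor()
            node = ("and", node, rhs)
        return node

    def _factor(self):
        tok = self._next()
        kind, val, col = tok
        if kind == "op" and val == "~":
            return ("not", self._factor())
        if kind == "op" and val == "(":
            node = self._expr()
            nxt = self._next()
            if nxt[:2] != ("op", ")"):
                raise ParseError("expected ')'", self.line_no, nxt[2] + 1)
            return node
        if kind == "ident":
            if val not in self.parents:
                self.parents.append(val)
            return ("var", val)
        if kind == "lit":
            return ("const", val)
        raise ParseError(f"unexpected token {val!r}", self.line_no, col + 1)


def _eval_ast(ast, env: Mapping[str, int]) -> int:
    op = ast[0]
    if op == "var":
        return env[ast[1]]
    if op == "const":
        return ast[1]
    if op == "not":
        return 1 - _eval_ast(ast[1], env)
    if op == "and":
        return _eval_ast(ast[1], env) & _eval_ast(ast[2], env)
    if op == "or":
        return _eval_ast(ast[1], env) | _eval_ast(ast[2], env)
    raise AssertionError(op)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorFunction:
    """A Boolean predictor for one target node.

    ``table`` has length ``2**len(parents)``; the row index is formed with
    the FIRST parent as the most significant bit, so rows enumerate parent
    assignments (0,..,0), (0,..,1), ..., (1,..,1).  A constant predictor has
    no parents and a single-entry table.
    """

    target: str
    parents: tuple[str, ...]
    table: tuple[int, ...]
    source_text: str = ""

    def __post_init__(self):
        if len(self.table) != 2 ** len(self.parents):
            raise ValueError(
                f"predictor for {self.target!r}: table length {len(self.table)} "
                f"!= 2^{len(self.parents)}")
        if any(v not in (0, 1) for v in self.table):
            raise ValueError("truth table entries must be 0/1")

    def __call__(self, env: Mapping[str, int]) -> int:
        idx = 0
        for p in self.parents:
            idx = (idx << 1) | (env[p] & 1)
        return self.table[idx]

    def canonical(self) -> tuple:
        """Parent-order-independent signature used for duplicate detection."""
        order = sorted(range(len(self.parents)), key=lambda i: self.parents[i])
        parents = tuple(self.parents[i] for i in order)
        k = len(parents)
        tab = []
        for bits in itertools.product((0, 1), repeat=k):
            env = dict(zip(parents, bits))
            tab.append(self(env))
        return parents, tuple(tab)

    def expression(self) -> str:
        """A rule expression equivalent to this predictor (DNF over minterms)."""
        if self.source_text:
            return self.source_text
        if not self.parents:
            return str(self.table[0])
        if all(v == 0 for v in self.table):
            return "0"
        if all(v == 1 for v in self.table):
            return "1"
        terms = []
        for idx, v in enumerate(self.table):
            if not v:
                continue
            lits = []
            for pos, p in enumerate(self.parents):
                bit = (idx >> (len(self.parents) - 1 - pos)) & 1
                lits.append(p if bit else f"~{p}")
            terms.append(" & ".join(lits) if len(lits) == 1
                         else "(" + " & ".join(lits) + ")")
        return " | ".join(terms)


@dataclass(frozen=True)
class NodeFunctionSet:
    """All candidate predictors of a node with their selection probabilities.

    ``free_mask[j]`` flags ``probs[j]`` as an optimisation parameter; the
    stored value of a free probability is meaningless until decoded.
    """

    node: str
    predictors: tuple[PredictorFunction, ...]
    probs: tuple[float, ...]
    free_mask: tuple[bool, ...]

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def is_free(self) -> bool:
        return any(self.free_mask)

    def validate(self):
        l = len(self.predictors)
        if l < 1:
            raise ValueError(f"node {self.node!r}: empty function set")
        if not (len(self.probs) == len(self.free_mask) == l):
            raise ValueError(f"node {self.node!r}: inconsistent function set")
        fixed = [c for c, f in zip(self.probs, self.free_mask) if not f]
        if any(c < -_PROB_TOL for c in fixed):
            raise ValueError(f"node {self.node!r}: negative selection probability")
        if not self.is_free and abs(sum(fixed) - 1.0) > _PROB_TOL:
            raise ValueError(
                f"node {self.node!r}: selection probabilities sum to "
                f"{sum(fixed):.12g}, expected 1")
        if self.is_free and sum(fixed) > 1.0 + _PROB_TOL:
            raise ValueError(
                f"node {self.node!r}: fixed probabilities exceed 1 on a "
                "partially free node")
        seen = set()
        for pred in self.predictors:
            sig = pred.canonical()
            if sig in seen:
                raise ValueError(
                    f"node {self.node!r}: duplicate identical predictor "
                    f"{pred.expression()!r}")
            seen.add(sig)


@dataclass(frozen=True)
class PBN:
    """A probabilistic Boolean network.

    ``nodes`` is the declaration-ordered tuple fixing the state layout.
    ``function_sets`` maps every non-input node to its candidate predictors.
    Input nodes (no predictors) take values from clamping and otherwise hold
    their current value; ``perturbation_p`` is the per-node, per-step random
    bit-flip probability that makes clamped subchains ergodic.
    """

    nodes: tuple[str, ...]
    function_sets: Mapping[str, NodeFunctionSet]
    perturbation_p: float = 0.001

    def __post_init__(self):
        object.__setattr__(self, "function_sets", dict(self.function_sets))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(v for v in self.nodes if v not in self.function_sets)

    @property
    def is_free(self) -> bool:
        return any(fs.is_free for fs in self.function_sets.values())

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def validate(self) -> "PBN":
        if self.n < 1:
            raise ValueError("a PBN needs at least one node")
        if not 0.0 <= self.perturbation_p <= 1.0:
            raise ValueError("perturbation_p must be a probability")
        if len(set(self.nodes)) != self.n:
            raise ValueError("duplicate node names")
        for node, fs in self.function_sets.items():
            if node not in self.nodes:
                raise ValueError(f"function set for undeclared node {node!r}")
            fs.validate()
            for pred in fs.predictors:
                for p in pred.parents:
                    if p not in self.nodes:
                        raise ValueError(
                            f"predictor for {node!r} references unknown node {p!r}")
        return self

    def with_probs(self, probs: Mapping[tuple[str, int], float],
                   perturbation_p: float | None = None) -> "PBN":
        """Return a copy with the given ``(node, predictor_index) -> c`` values
        substituted and the corresponding free flags cleared."""
        new_sets = {}
        for node, fs in self.function_sets.items():
            c = list(fs.probs)
            free = list(fs.free_mask)
            for j in range(fs.n_predictors):
                if (node, j) in probs:
                    c[j] = float(probs[(node, j)])
                    free[j] = False
            new_sets[node] = NodeFunctionSet(node, fs.predictors, tuple(c),
                                             tuple(free))
        p = self.perturbation_p if perturbation_p is None else perturbation_p
        return PBN(self.nodes, new_sets, p).validate()

    def with_perturbation(self, p: float) -> "PBN":
        return PBN(self.nodes, self.function_sets, p)

    def to_rules(self) -> str:
        """Serialise back to rule text (round-trips the truth tables)."""
        lines = []
        for node in self.nodes:
            fs = self.function_sets.get(node)
            if fs is None:
                continue
            for pred, c, free in zip(fs.predictors, fs.probs, fs.free_mask):
                tail = FREE if free else repr(float(c))
                lines.append(f"{node} = {pred.expression()} : {tail}")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsedRule:
    predictor: PredictorFunction
    prob: float | None      # None when free
    free: bool


def parse_rule(line: str, line_no: int | None = None) -> ParsedRule:
    """Parse one rule line ``NODE = EXPR [: prob | : ?]``.

    A missing probability means 1.0 (single deterministic rule); ``?`` marks
    the selection probability as a free optimisation parameter.
    """
    body = line.split("#", 1)[0].strip()
    if not body:
        raise ParseError("empty rule line", line_no)
    if "=" not in body:
        raise ParseError("expected '=' in rule", line_no)
    lhs, rhs = body.split("=", 1)
    target = lhs.strip()
    if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", target):
        raise ParseError(f"invalid target identifier {target!r}", line_no)
    prob: float | None = 1.0
    free = False
    if ":" in rhs:
        expr_text, prob_text = rhs.rsplit(":", 1)
        prob_text = prob_text.strip()
        if prob_text == FREE:
            prob, free = None, True
        else:
            try:
                prob = float(prob_text)
            except ValueError:
                raise ParseError(f"invalid probability {prob_text!r}", line_no)
            if not 0.0 <= prob <= 1.0:
                raise ParseError(f"probability {prob} outside [0, 1]", line_no)
    else:
        expr_text = rhs
    expr_text = expr_text.strip()
    parser = _ExprParser(_tokenize(expr_text, line_no), line_no)
    ast = parser.parse()
    parents = tuple(parser.parents)
    k = len(parents)
    table = []
    for idx in range(2 ** k):
        env = {p: (idx >> (k - 1 - pos)) & 1 for pos, p in enumerate(parents)}
        table.append(_eval_ast(ast, env))
    pred = PredictorFunction(target, parents, tuple(table), expr_text)
    return ParsedRule(pred, prob, free)


def parse_rules(text: str) -> list[ParsedRule]:
    """Parse a whole rule file; '#' comments and blank lines are skipped."""
    rules = []
    for i, raw in enumerate(text.splitlines(), start=1):
        body = raw.split("#", 1)[0].strip()
        if not body:
            continue
        rules.append(parse_rule(raw, line_no=i))
    return rules


def build_pbn(rules: Iterable[ParsedRule], perturbation_p: float = 0.001,
              node_order: Sequence[str] | None = None) -> PBN:
    """Assemble a validated PBN from parsed rules.

    Nodes are ordered by first appearance (targets and then any parent not
    yet seen) unless ``node_order`` lists every referenced node explicitly;
    identifiers that never occur as a target become input nodes.  Feedback
    (cyclic definitions) is allowed.  Per node, probabilities must either
    all be fixed and sum to 1, or include free markers.
    """
    rules = list(rules)
    order: list[str] = list(node_order or [])

    def note(name: str):
        if name not in order:
            if node_order is not None:
                raise ValueError(
                    f"node {name!r} referenced by rules but missing from "
                    "node_order")
            order.append(name)

    for r in rules:
        note(r.predictor.target)
        for p in r.predictor.parents:
            note(p)

    grouped: dict[str, list[ParsedRule]] = {}
    for r in rules:
        grouped.setdefault(r.predictor.target, []).append(r)

    sets = {}
    for node, rs in grouped.items():
        probs = tuple(1.0 if r.free else float(r.prob) for r in rs)
        free = tuple(r.free for r in rs)
        if any(free):
            # free probabilities carry no value yet; zero them for clarity
            probs = tuple(0.0 if f else c for c, f in zip(probs, free))
        sets[node] = NodeFunctionSet(node, tuple(r.predictor for r in rs),
                                     probs, free)
    return PBN(tuple(order), sets, perturbation_p).validate()


def load_model(path, perturbation_p: float = 0.001) -> PBN:
    """Read a rule file and build the PBN."""
    with open(path, "r", encoding="utf-8") as fh:
        return build_pbn(parse_rules(fh.read()), perturbation_p)


def truth_table(pbn: PBN, node: str):
    """Probabilistic truth table of ``node``: for every assignment of its
    parents, ``P(node' = 1) = sum_j c_j * f_j(assignment)``.

    Returns ``(parents, probs)`` where ``probs[i]`` corresponds to the parent
    assignment whose bits spell ``i`` (first parent = most significant bit).
    Raises if the node still has free selection probabilities.
    """
    fs = pbn.function_sets.get(node)
    if fs is None:
        raise KeyError(f"{node!r} is an input node: no truth table")
    if fs.is_free:
        raise ValueError(f"node {node!r} has free selection probabilities")
    parents: list[str] = []
    for pred in fs.predictors:
        for p in pred.parents:
            if p not in parents:
                parents.append(p)
    k = len(parents)
    probs = np.zeros(2 ** k)
    for idx in range(2 ** k):
        env = {p: (idx >> (k - 1 - pos)) & 1 for pos, p in enumerate(parents)}
        probs[idx] = sum(c * pred(env)
                         for c, pred in zip(fs.probs, fs.predictors))
    return tuple(parents), probs


def state_to_string(bits: Sequence[int]) -> str:
    """Render a state vector; leftmost character = first declared node."""
    return "".join(str(int(b)) for b in bits)


def string_to_state(s: str) -> np.ndarray:
    return np.array([int(ch) for ch in s], dtype=np.uint8)
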