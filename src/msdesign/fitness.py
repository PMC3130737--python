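"""The fitness-function definition language.

A fitness file is a tiny program, one command per line, that declares the
states being modelled and describes how their packed energies are combined
into a single scalar the genetic algorithm minimizes.  Seven commands:

``STATE name [structure corr secondary]``
    declare a scalar state variable (bound to a packed energy at run time)
``STATE_VECTOR name [listfile]``
    declare a vector state variable (an ensemble of conformations)
``SCALAR_EXPRESSION name = expr``
``VECTOR_VARIABLE name = v1 v2 ...``
    collect previously defined values into a vector
``VECTOR_EXPRESSION name = expr``
    evaluate an expression elementwise over its vector operands
``ENTITY_FUNCTION name [file]``
    declare a sequence-only scoring term (see :class:`EntityFunctionDef`)
``FITNESS expr``
    the final scalar (exactly one per program; lower is better)

Expressions support + - * /, unary minus, parentheses, ``min(a,b)``,
``max(a,b)``, ``vmin(v)``, ``vmax(v)``, ``abs(x)``, ``pow(x,y)`` and
``ite(cond, a, b)`` with comparison operators inside ``cond``.  Every
identifier must be defined on an earlier line, which keeps programs acyclic
by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .states import EntitySequence

__all__ = [
    "FitnessProgram",
    "EntityFunctionDef",
    "parse_fitness_file",
    "parse_entity_function_file",
    "evaluate_entity_function",
    "evaluate_fitness",
    "fitness1_text",
    "fitness2_text",
    "ral_fitness_text",
    "heterodimer_entity_function",
]

COMMANDS = {"STATE", "STATE_VECTOR", "SCALAR_EXPRESSION", "VECTOR_VARIABLE",
            "VECTOR_EXPRESSION", "ENTITY_FUNCTION", "FITNESS"}


class FitnessParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# expression AST

_TOKEN_RE = re.compile(r"""
    (?P<num>\d+\.\d*|\.\d+|\d+)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|==|!=|[-+*/(),<>])
  | (?P<ws>\s+)
""", re.VERBOSE)

_FUNCS1 = {"abs", "vmin", "vmax"}
_FUNCS2 = {"min", "max", "pow"}
_CMP = {"<", "<=", ">", ">=", "==", "!="}


def _tokenize(text: str, lineno: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise FitnessParseError(lineno, f"bad character {text[pos]!r}")
        if m.lastgroup != "ws":
            tokens.append(m.group())
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent expression parser producing nested tuples."""

    def __init__(self, tokens: list[str], lineno: int, defined: set[str]):
        self.tokens = tokens
        self.i = 0
        self.lineno = lineno
        self.defined = defined

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise FitnessParseError(self.lineno, "unexpected end of expression")
        self.i += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise FitnessParseError(self.lineno, f"expected {tok!r}, got {got!r}")

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise FitnessParseError(self.lineno, f"trailing tokens: {self.tokens[self.i:]}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() in ("+", "-"):
            op = self.next()
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() in ("*", "/"):
            op = self.next()
            node = (op, node, self.factor())
        return node

    def factor(self):
        if self.peek() == "-":
            self.next()
            return ("neg", self.factor())
        return self.atom()

    def atom(self):
        tok = self.next()
        if re.fullmatch(r"\d+\.\d*|\.\d+|\d+", tok):
            return ("num", float(tok))
        if tok == "(":
            node = self.expr()
            self.expect(")")
            return node
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            if self.peek() == "(":
                return self.call(tok)
            if tok not in self.defined:
                raise FitnessParseError(self.lineno, f"undefined identifier {tok!r}")
            return ("var", tok)
        raise FitnessParseError(self.lineno, f"unexpected token {tok!r}")

    def call(self, name: str):
        self.expect("(")
        if name == "ite":
            cond = self.comparison()
            self.expect(",")
            a = self.expr()
            self.expect(",")
            b = self.expr()
            self.expect(")")
            return ("ite", cond, a, b)
        args = [self.expr()]
        while self.peek() == ",":
            self.next()
            args.append(self.expr())
        self.expect(")")
        if name in _FUNCS1 and len(args) == 1:
            return (name, args[0])
        if name in _FUNCS2 and len(args) == 2:
            return (name, args[0], args[1])
        raise FitnessParseError(self.lineno,
                                f"unknown function or wrong arity: {name}/{len(args)}")

    def comparison(self):
        left = self.expr()
        op = self.next()
        if op not in _CMP:
            raise FitnessParseError(self.lineno, f"expected comparison, got {op!r}")
        return ("cmp", op, left, self.expr())


def _eval(node, env: dict):
    kind = node[0]
    if kind == "num":
        return node[1]
    if kind == "var":
        if node[1] not in env:
            raise KeyError(f"unbound variable {node[1]!r}")
        return env[node[1]]
    if kind == "neg":
        return -_eval(node[1], env)
    if kind in ("+", "-", "*", "/"):
        a, b = _eval(node[1], env), _eval(node[2], env)
        if kind == "+":
            return a + b
        if kind == "-":
            return a - b
        if kind == "*":
            return a * b
        return a / b
    if kind == "min":
        return np.minimum(_eval(node[1], env), _eval(node[2], env))
    if kind == "max":
        return np.maximum(_eval(node[1], env), _eval(node[2], env))
    if kind == "pow":
        return np.power(_eval(node[1], env), _eval(node[2], env))
    if kind == "abs":
        return np.abs(_eval(node[1], env))
    if kind == "vmin":
        return float(np.min(np.asarray(_eval(node[1], env), dtype=float)))
    if kind == "vmax":
        return float(np.max(np.asarray(_eval(node[1], env), dtype=float)))
    if kind == "ite":
        cond = _eval(node[1], env)
        return np.where(cond, _eval(node[2], env), _eval(node[3], env))
    if kind == "cmp":
        op, a, b = node[1], _eval(node[2], env), _eval(node[3], env)
        return {"<": np.less, "<=": np.less_equal, ">": np.greater,
                ">=": np.greater_equal, "==": np.equal, "!=": np.not_equal}[op](a, b)
    raise AssertionError(f"bad AST node {node!r}")


# ---------------------------------------------------------------------------
# entity functions (sequence-only scoring terms)

@dataclass(frozen=True)
class EntityFunctionDef:
    """Sequence constraints: identity penalties and mutation-count penalties.

    ``identity_penalties``: (pairs, free_count, step): pairs of entity
    positions scored by how many carry identical letters; the count beyond
    ``free_count`` costs ``step`` REU each (clipped at zero below it).

    ``mutation_penalties``: (positions, wildtype, free_count, step): one per
    chain; mutations beyond the first ``free_count`` cost ``step`` REU each.
    """

    identity_penalties: tuple[tuple[tuple[tuple[int, int], ...], int, float], ...] = ()
    mutation_penalties: tuple[tuple[tuple[int, ...], str, int, float], ...] = ()

    def __post_init__(self) -> None:
        for pairs, free, step in self.identity_penalties:
            if free < 0 or step < 0:
                raise ValueError("free_count and step must be >= 0")
        for positions, wildtype, free, step in self.mutation_penalties:
            if len(positions) != len(wildtype):
                raise ValueError("positions and wildtype letters differ in length")
            if free < 0 or step < 0:
                raise ValueError("free_count and step must be >= 0")


def evaluate_entity_function(fn: EntityFunctionDef, seq: EntitySequence) -> float:
    """Total sequence-constraint energy (REU) of the entity sequence."""
    total = 0.0
    L = len(seq)
    for pairs, free, step in fn.identity_penalties:
        for p, q in pairs:
            if not (1 <= p <= L and 1 <= q <= L):
                raise ValueError(f"position pair ({p},{q}) outside [1,{L}]")
        k = sum(1 for p, q in pairs if seq[p - 1] == seq[q - 1])
        total += step * max(0, k - free)
    for positions, wildtype, free, step in fn.mutation_penalties:
        for p in positions:
            if not 1 <= p <= L:
                raise ValueError(f"position {p} outside [1,{L}]")
        m = sum(1 for p, wt in zip(positions, wildtype) if seq[p - 1] != wt)
        total += step * max(0, m - free)
    return total


def parse_entity_function_file(text: str) -> EntityFunctionDef:
    """Parse the entity-function text format.

    ``IDENTITY_PENALTY free N step S pairs p:q p:q ...``
    ``MUTATION_PENALTY free N step S positions p p ... wildtype LETTERS``
    """
    identity, mutation = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if parts[0] == "IDENTITY_PENALTY":
                assert parts[1] == "free" and parts[3] == "step" and parts[5] == "pairs"
                free, step = int(parts[2]), float(parts[4])
                pairs = tuple(tuple(int(v) for v in p.split(":")) for p in parts[6:])
                identity.append((pairs, free, step))
            elif parts[0] == "MUTATION_PENALTY":
                assert parts[1] == "free" and parts[3] == "step" and parts[5] == "positions"
                free, step = int(parts[2]), float(parts[4])
                widx = parts.index("wildtype")
                positions = tuple(int(v) for v in parts[6:widx])
                wildtype = parts[widx + 1].upper()
                mutation.append((positions, wildtype, free, step))
            else:
                raise ValueError(f"unknown scorer {parts[0]!r}")
        except (AssertionError, IndexError, ValueError) as e:
            raise ValueError(f"line {lineno}: malformed entity-function line ({e})") from None
    return EntityFunctionDef(tuple(identity), tuple(mutation))


# ---------------------------------------------------------------------------
# programs

@dataclass
class FitnessProgram:
    """A parsed fitness file."""

    state_vars: dict[str, str] = field(default_factory=dict)   # name -> scalar|vector
    scalar_defs: dict[str, object] = field(default_factory=dict)
    vector_defs: dict[str, object] = field(default_factory=dict)
    vector_variables: dict[str, list[str]] = field(default_factory=dict)
    entity_fns: dict[str, EntityFunctionDef | None] = field(default_factory=dict)
    fitness_expr: object = None
    order: list[tuple[str, str]] = field(default_factory=list)  # (command, name)
    state_metadata: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def attach_entity_function(self, name: str, fn: EntityFunctionDef) -> None:
        if name not in self.entity_fns:
            raise KeyError(f"no ENTITY_FUNCTION named {name!r}")
        self.entity_fns[name] = fn


def parse_fitness_file(text: str) -> FitnessProgram:
    prog = FitnessProgram()
    defined: set[str] = set()
    fitness_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        cmd = parts[0]
        rest = parts[1] if len(parts) > 1 else ""
        if cmd not in COMMANDS:
            raise FitnessParseError(lineno, f"unknown command {cmd!r}")
        if cmd == "FITNESS":
            if fitness_seen:
                raise FitnessParseError(lineno, "two FITNESS lines")
            fitness_seen = True
            prog.fitness_expr = _Parser(_tokenize(rest, lineno), lineno, defined).parse()
            prog.order.append((cmd, ""))
            continue
        if cmd in ("STATE", "STATE_VECTOR"):
            tokens = rest.split()
            if not tokens:
                raise FitnessParseError(lineno, f"{cmd} needs a name")
            name = tokens[0]
            _check_new(name, defined, lineno)
            prog.state_vars[name] = "scalar" if cmd == "STATE" else "vector"
            if len(tokens) > 1:
                prog.state_metadata[name] = tuple(tokens[1:])
            defined.add(name)
            prog.order.append((cmd, name))
            continue
        if cmd == "ENTITY_FUNCTION":
            tokens = rest.split()
            if not tokens:
                raise FitnessParseError(lineno, "ENTITY_FUNCTION needs a name")
            name = tokens[0]
            _check_new(name, defined, lineno)
            prog.entity_fns[name] = None
            if len(tokens) > 1:
                prog.state_metadata[name] = tuple(tokens[1:])
            defined.add(name)
            prog.order.append((cmd, name))
            continue
        # name = definition commands
        if "=" not in rest:
            raise FitnessParseError(lineno, f"{cmd} needs 'name = ...'")
        name, definition = (s.strip() for s in rest.split("=", 1))
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
            raise FitnessParseError(lineno, f"bad variable name {name!r}")
        _check_new(name, defined, lineno)
        if cmd == "VECTOR_VARIABLE":
            members = definition.split()
            for m in members:
                if m not in defined:
                    raise FitnessParseError(lineno, f"undefined identifier {m!r}")
            prog.vector_variables[name] = members
        else:
            node = _Parser(_tokenize(definition, lineno), lineno, defined).parse()
            if cmd == "SCALAR_EXPRESSION":
                prog.scalar_defs[name] = node
            else:
                prog.vector_defs[name] = node
        defined.add(name)
        prog.order.append((cmd, name))
    if not fitness_seen:
        raise FitnessParseError(len(text.splitlines()) or 1, "no FITNESS line")
    return prog


def _check_new(name: str, defined: set[str], lineno: int) -> None:
    if name in defined:
        raise FitnessParseError(lineno, f"identifier {name!r} defined twice")


def evaluate_fitness(program: FitnessProgram,
                     state_energies: dict[str, float | list[float] | np.ndarray],
                     seq: EntitySequence | None = None) -> float:
    """Run the program: bind state energies, evaluate commands in order.

    Lower fitness is better; the genetic algorithm propagates the lowest.
    """
    env: dict[str, object] = {}
    for (cmd, name) in program.order:
        if cmd == "STATE":
            if name not in state_energies:
                raise KeyError(f"state variable {name!r} not bound")
            env[name] = float(np.asarray(state_energies[name]).reshape(()))
        elif cmd == "STATE_VECTOR":
            if name not in state_energies:
                raise KeyError(f"state vector {name!r} not bound")
            v = np.atleast_1d(np.asarray(state_energies[name], dtype=float))
            env[name] = v
        elif cmd == "ENTITY_FUNCTION":
            fn = program.entity_fns[name]
            if fn is None:
                raise KeyError(f"entity function {name!r} has no definition attached")
            if seq is None:
                raise ValueError("entity functions need the entity sequence")
            env[name] = evaluate_entity_function(fn, seq)
        elif cmd == "SCALAR_EXPRESSION":
            env[name] = float(np.asarray(_eval(program.scalar_defs[name], env)).reshape(()))
        elif cmd == "VECTOR_VARIABLE":
            env[name] = np.array([np.asarray(env[m], dtype=float).reshape(())
                                  for m in program.vector_variables[name]])
        elif cmd == "VECTOR_EXPRESSION":
            env[name] = np.atleast_1d(np.asarray(
                _eval(program.vector_defs[name], env), dtype=float))
        elif cmd == "FITNESS":
            return float(np.asarray(_eval(program.fitness_expr, env)).reshape(()))
    raise AssertionError("program had no FITNESS command")


# ---------------------------------------------------------------------------
# the shipped fitness functions

def fitness1_text(w: float = 2.0) -> str:
    """Heterodimerization fitness: total energy + weighted binding-energy gaps.

    F = eAB + w * [(dGAB - min(dGAA, 0)) + (dGAB - min(dGBB, 0))] + Eseq,
    with dG's computed from the best energy of each species' ensemble and
    the negative-state binding energies capped at 0.
    """
    return f"""# heterodimerization fitness (binding-energy gaps, weight {w})
STATE_VECTOR vA
STATE_VECTOR vB
STATE_VECTOR vAB
STATE_VECTOR vAA
STATE_VECTOR vBB
ENTITY_FUNCTION seqconst
SCALAR_EXPRESSION eA = vmin(vA)
SCALAR_EXPRESSION eB = vmin(vB)
SCALAR_EXPRESSION eAB = vmin(vAB)
SCALAR_EXPRESSION eAA = vmin(vAA)
SCALAR_EXPRESSION eBB = vmin(vBB)
SCALAR_EXPRESSION dGAB = eAB - eA - eB
SCALAR_EXPRESSION dGAA = min(eAA - 2 * eA, 0)
SCALAR_EXPRESSION dGBB = min(eBB - 2 * eB, 0)
SCALAR_EXPRESSION gapAA = dGAB - dGAA
SCALAR_EXPRESSION gapBB = dGAB - dGBB
FITNESS eAB + {w} * (gapAA + gapBB) + seqconst
"""


def fitness2_text(w2: float = 1.0, gate: float = -20.0,
                  target_ab: float = -24.0, target_homo: float = -12.0) -> str:
    """Alternate heterodimerization fitness with a saturating binding reward.

    The heterodimer binding reward saturates at ``target_ab``; a gated bonus
    drives the homodimer binding energies up toward ``target_homo``.
    """
    return f"""# heterodimerization fitness 2 (saturating reward, gated homodimer bonus)
STATE_VECTOR vA
STATE_VECTOR vB
STATE_VECTOR vAB
STATE_VECTOR vAA
STATE_VECTOR vBB
ENTITY_FUNCTION seqconst
SCALAR_EXPRESSION eA = vmin(vA)
SCALAR_EXPRESSION eB = vmin(vB)
SCALAR_EXPRESSION eAB = vmin(vAB)
SCALAR_EXPRESSION eAA = vmin(vAA)
SCALAR_EXPRESSION eBB = vmin(vBB)
SCALAR_EXPRESSION dGAB = eAB - eA - eB
SCALAR_EXPRESSION dGAA = eAA - 2 * eA
SCALAR_EXPRESSION dGBB = eBB - 2 * eB
SCALAR_EXPRESSION bind = max(dGAB, {target_ab})
SCALAR_EXPRESSION gatevar = ite(dGAB < {gate}, 1, 0)
SCALAR_EXPRESSION penAA = max({target_homo} - dGAA, 0)
SCALAR_EXPRESSION penBB = max({target_homo} - dGBB, 0)
FITNESS eAB + bind + {w2} * gatevar * (penAA + penBB) + seqconst
"""


def ral_fitness_text(w: float = 2.0) -> str:
    """Orthogonal-interface fitness with per-backbone monomer states.

    Binding energies compare each dimer with the monomers sharing its very
    backbone conformation (states A_AB, A_AC, A_AD).
    """
    return f"""# orthogonal interface fitness (weight {w})
STATE_VECTOR vAB
STATE_VECTOR vAC
STATE_VECTOR vAD
STATE_VECTOR vA_AB
STATE_VECTOR vA_AC
STATE_VECTOR vA_AD
STATE_VECTOR vB
STATE_VECTOR vC
STATE_VECTOR vD
SCALAR_EXPRESSION eAB = vmin(vAB)
SCALAR_EXPRESSION eAC = vmin(vAC)
SCALAR_EXPRESSION eAD = vmin(vAD)
SCALAR_EXPRESSION dGAB = eAB - vmin(vA_AB) - vmin(vB)
SCALAR_EXPRESSION dGAC = min(eAC - vmin(vA_AC) - vmin(vC), 0)
SCALAR_EXPRESSION dGAD = min(eAD - vmin(vA_AD) - vmin(vD), 0)
SCALAR_EXPRESSION gapAC = dGAB - dGAC
SCALAR_EXPRESSION gapAD = dGAB - dGAD
FITNESS eAB + {w} * (gapAC + gapAD)
"""


def heterodimer_entity_function(n_pairs: int = 8,
                                wildtype: EntitySequence | None = None,
                                identity_free: int = 6, identity_step: float = 5.0,
                                mutation_free: int = 5, mutation_step: float = 1.0,
                                ) -> EntityFunctionDef:
    """The heterodimerization task's sequence constraint.

    Odd/even entity positions hold the A- and B-chain halves; position pair
    (2k-1, 2k) carrying the same letter counts toward the homodimer-identity
    penalty (free up to ``identity_free``, then ``identity_step`` REU per
    pair).  Each chain may carry ``mutation_free`` mutations from wild type
    before a ``mutation_step`` REU per-mutation penalty applies.
    """
    pairs = tuple((2 * k + 1, 2 * k + 2) for k in range(n_pairs))
    identity = ((pairs, identity_free, identity_step),)
    mutation = ()
    if wildtype is not None:
        odd = tuple(2 * k + 1 for k in range(n_pairs))
        even = tuple(2 * k + 2 for k in range(n_pairs))
        wt_odd = "".join(wildtype[p - 1] for p in odd)
        wt_even = "".join(wildtype[p - 1] for p in even)
        mutation = ((odd, wt_odd, mutation_free, mutation_step),
                    (even, wt_even, mutation_free, mutation_step))
    return EntityFunctionDef(identity, mutation)
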