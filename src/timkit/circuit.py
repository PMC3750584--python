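"""Minimal Boolean survival equation and TIM-circuit extraction.

Thresholding a TIM at a sensitivity level theta turns it into a monotone
Boolean function over target inhibitions: a combination is "effective"
when its (experimental or inferred) sensitivity reaches the threshold.
The minimal Boolean equation is the antichain of minimal effective
combinations -- because of the tumor-promoter rules, any superset of an
effective combination is effective, so minimal terms describe the whole
function.  The search walks combination sizes 1..M breadth-first and cuts
every branch above an accepted term, then admits experimental
combinations of any size.

The circuit view groups terms into blocks for display: parallel lines in
a block must all be cut (AND) while targets on one line are alternatives
(OR); the blocks themselves are alternative treatments.  Grouping is a
greedy common-target factoring whose expansion is machine-checked
against the equation, so the drawing can never change semantics.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .tim_inference import TIM

Term = frozenset[int]


@dataclass(frozen=True)
class BooleanEquation:
    """Antichain of minimal effective target combinations."""

    terms: frozenset[Term]
    n: int
    names: tuple[str, ...] | None = None
    theta_e: float = 0.5
    theta_i: float = 0.5
    max_term: int = 4

    def __post_init__(self) -> None:
        for a in self.terms:
            for b in self.terms:
                if a < b:
                    raise ValueError(f"non-minimal equation: {set(a)} < {set(b)}")

    def sorted_terms(self) -> list[tuple[int, ...]]:
        return sorted(tuple(sorted(t)) for t in self.terms)

    def label(self, j: int) -> str:
        return self.names[j] if self.names is not None else f"T{j}"


def minimal_equation(
    tim: TIM,
    theta_e: float = 0.5,
    theta_i: float = 0.5,
    max_term: int = 4,
) -> BooleanEquation:
    """Extract the minimal effective terms of a TIM.

    A combination of size <= ``max_term`` is accepted when its sensitivity
    reaches the governing threshold: experimental entries are judged
    against ``theta_e``, inferred ones against ``theta_i``.  Accepted
    terms prune their supersets (Rule 1 makes them redundant).
    Experimental combinations of any size are admitted as terms but never
    expanded.  A term supported only by inference but contradicted by an
    experimental superset below ``theta_e`` is dropped with a warning.
    """
    if not (0 <= theta_e <= 1 and 0 <= theta_i <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    n = tim.n
    max_term = min(max_term, n)
    accepted: list[int] = []

    def has_accepted_subset(p: int) -> bool:
        return any(a & p == a for a in accepted)

    for size in range(1, max_term + 1):
        for combo in itertools.combinations(range(n), size):
            p = sum(1 << j for j in combo)
            if has_accepted_subset(p):
                continue  # branch already cut by a minimal term
            if p in tim.known:
                effective = tim.known[p] >= theta_e
            else:
                effective = tim.predict(p) >= theta_i
            if effective:
                accepted.append(p)

    # experimental combinations beyond the size cap, admitted but not expanded
    for p in sorted(tim.known, key=lambda q: (q.bit_count(), q)):
        if p == 0 or p.bit_count() <= max_term:
            continue
        if tim.known[p] >= theta_e and not has_accepted_subset(p):
            accepted.append(p)

    # verification against experimental data: an inferred term whose
    # experimental superset fails theta_e contradicts Rule 1
    verified: list[int] = []
    for p in accepted:
        if p not in tim.known:
            bad = [q for q, y in tim.known.items() if q & p == p and y < theta_e]
            if bad:
                warnings.warn(
                    f"dropping inferred term {p:0{n}b}: experimental superset(s) "
                    f"{[format(q, f'0{n}b') for q in sorted(bad)]} fall below theta_e",
                    stacklevel=2,
                )
                continue
        verified.append(p)

    # final minimality sweep (drops can not create new subset relations,
    # but experimental admissions are order-sensitive; keep the antichain)
    minimal = [
        p for p in verified if not any(q != p and q & p == q for q in verified)
    ]
    terms = frozenset(frozenset(j for j in range(n) if p >> j & 1) for p in minimal)
    return BooleanEquation(
        terms=terms, n=n, names=tim.names, theta_e=theta_e, theta_i=theta_i, max_term=max_term
    )


# ---------------------------------------------------------------------------
# block grouping


@dataclass(frozen=True)
class Circuit:
    """Block-structured rendering of a Boolean equation.

    ``blocks`` is an ordered tuple; each block is a tuple of lines; each
    line is a tuple of target labels.  All lines of one block must be cut
    (AND); targets on a line are alternatives (OR); any fully cut block
    is an effective treatment (blocks are OR alternatives).
    """

    blocks: tuple[tuple[tuple[str, ...], ...], ...]

    def to_dict(self) -> dict:
        return {"blocks": [[list(line) for line in block] for block in self.blocks]}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Circuit":
        return cls(
            blocks=tuple(
                tuple(tuple(line) for line in block) for block in payload["blocks"]
            )
        )


def _expansion(block: Sequence[Sequence[int]]) -> frozenset[Term]:
    """Terms a block stands for: one target from each of its lines."""
    return frozenset(frozenset(pick) for pick in itertools.product(*block))


def _product_form(terms: set[Term]) -> list[list[int]] | None:
    """Express a term set as a cartesian product of alternative-lines.

    Returns lines such that product(lines) == terms, or None when the set
    has no such factoring.  Pivots on the most frequent target; targets
    whose cofactor sets coincide share a line.
    """
    if terms == {frozenset()}:
        return []
    if any(not t for t in terms):
        return None
    counts = Counter(j for t in terms for j in t)
    pivot = min(counts, key=lambda j: (-counts[j], j))
    with_pivot = {t for t in terms if pivot in t}
    cofactors = {t - {pivot} for t in with_pivot}
    if len(cofactors) != len(with_pivot):
        return None
    line = [pivot]
    rest = terms - with_pivot
    while rest:
        rc = Counter(j for t in rest for j in t)
        alt = min(rc, key=lambda j: (-rc[j], j))
        with_alt = {t for t in rest if alt in t}
        if {t - {alt} for t in with_alt} != cofactors:
            return None
        line.append(alt)
        rest -= with_alt
    sub = _product_form(cofactors)
    if sub is None:
        return None
    return [sorted(line)] + sub


def group_blocks(eq: BooleanEquation) -> Circuit:
    """Factor the equation's terms into display blocks.

    Greedy: take the target shared by the most uncovered terms, try to
    factor those terms as a cartesian product of lines; terms that fit no
    factored block fall back to singleton blocks (one line per target).
    The union of block expansions is checked to equal the equation.
    """
    remaining = set(eq.terms)
    index_blocks: list[list[list[int]]] = []
    while remaining:
        counts = Counter(j for t in remaining for j in t)
        block = None
        if counts:
            pivot = min(counts, key=lambda j: (-counts[j], j))
            candidates = {t for t in remaining if pivot in t}
            if len(candidates) > 1:
                block = _product_form(candidates)
                if block is not None and _expansion(block) != candidates:
                    block = None  # factoring failed the equivalence check
        if block is None:
            term = min(remaining, key=lambda t: (len(t), tuple(sorted(t))))
            block = [[j] for j in sorted(term)]
        covered = _expansion(block)
        assert covered <= remaining
        remaining -= covered
        index_blocks.append(block)

    expanded = frozenset().union(*(_expansion(b) for b in index_blocks)) if index_blocks else frozenset()
    assert expanded == eq.terms, "block grouping changed the equation"
    index_blocks.sort(key=lambda b: (-len(_expansion(b)), b))
    blocks = tuple(
        tuple(tuple(eq.label(j) for j in line) for line in block)
        for block in index_blocks
    )
    return Circuit(blocks=blocks)


# ---------------------------------------------------------------------------
# DOT rendering


def render_circuit(circuit: Circuit) -> str:
    """Deterministic Graphviz DOT text for a circuit.

    Signal flows left to right from ``start`` to ``end``; blocks are laid
    out in series with junction points between them; each line of a block
    is a chain of target boxes (inhibiting any one breaks the line).
    """
    lines = [
        "digraph tim_circuit {",
        "  rankdir=LR;",
        '  node [shape=box, style=rounded, fontname="Helvetica"];',
        '  start [shape=point, label=""];',
        '  end [shape=point, label=""];',
    ]
    prev = "start"
    for bi, block in enumerate(circuit.blocks):
        nxt = "end" if bi == len(circuit.blocks) - 1 else f"j{bi}"
        if nxt != "end":
            lines.append(f'  {nxt} [shape=point, label=""];')
        for li, line in enumerate(block):
            chain = [prev]
            for ti, target in enumerate(line):
                node = f"b{bi}_l{li}_t{ti}"
                lines.append(f'  {node} [label="{target}"];')
                chain.append(node)
            chain.append(nxt)
            for a, b in zip(chain, chain[1:]):
                lines.append(f"  {a} -> {b};")
        prev = nxt
    if not circuit.blocks:
        lines.append("  start -> end;")
    lines.append("}")
    return "\n".join(lines) + "\n"
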