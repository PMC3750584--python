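"""Boolean-network dynamics for directional tumor pathways.

A steady-state TIM says nothing about directionality; this layer models a
candidate directional pathway as a deterministic Boolean network over n
target bits plus a phenotype bit (the least significant bit: tumor = 1).
State transitions follow three rules: a target activates when its
upstream activators say so (OR or AND gate), mutated / latently activated
targets rise to 1 on their own, and an unmutated target with silent
upstream falls to 0.  The phenotype bit copies the activation of the
terminal tumor-driving target(s).

Inhibiting a target set S forces those bits to 0 in every successor
state, which rewires the transition function; the attractor reached from
the all-active state then tells whether that inhibition combination
eradicates the tumor, and scanning all 2^n combinations reproduces a TIM
from pure dynamics.  Counting formulas bound how many directional models
share a block structure and how many perturbation experiments separate
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .synthetic import PathwayStructure
from .tim_inference import TIM


@dataclass(frozen=True)
class DirectionalPathway:
    """Directed activation structure over named targets.

    ``activations[t]`` lists the immediate upstream activators of target
    t; ``gates[t]`` ('OR' default, or 'AND') says how they combine.
    ``mutated`` targets carry their own latent activation; ``drivers``
    are the terminal targets whose activation manifests as tumor.
    """

    targets: tuple[str, ...]
    activations: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    gates: Mapping[str, str] = field(default_factory=dict)
    mutated: frozenset[str] = frozenset()
    drivers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        known = set(self.targets)
        if len(known) != len(self.targets):
            raise ValueError("duplicate target names")
        for t, ups in self.activations.items():
            if t not in known or any(u not in known for u in ups):
                raise ValueError(f"activation edge references unknown target: {t} <- {ups}")
        if not self.drivers <= known or not self.mutated <= known:
            raise ValueError("mutated/driver sets must be targets")
        if not self.drivers:
            raise ValueError("need at least one tumor-driving target")
        g = nx.DiGraph()
        g.add_nodes_from(self.targets)
        for t, ups in self.activations.items():
            g.add_edges_from((u, t) for u in ups)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("activation graph must be acyclic")


class BooleanNetwork:
    """Deterministic 2^(n+1)-state dynamics of a directional pathway.

    States are ints: bit 0 is the phenotype (tumor) bit, bit i+1 the i-th
    target.  ``inhibited`` bits are forced to 0 in every successor.
    """

    def __init__(self, pathway: DirectionalPathway, inhibited: frozenset[str] = frozenset()):
        if not inhibited <= set(pathway.targets):
            raise ValueError("inhibited set must be targets")
        self.pathway = pathway
        self.inhibited = frozenset(inhibited)
        self._idx = {t: i for i, t in enumerate(pathway.targets)}

    @property
    def n(self) -> int:
        return len(self.pathway.targets)

    @property
    def n_states(self) -> int:
        return 1 << (self.n + 1)

    # -- state coding ------------------------------------------------------

    def encode(self, text: str) -> int:
        """Parse a display state ``'<t1..tn><phenotype>'`` (as drawn in
        transition diagrams: targets first, tumor bit last)."""
        if len(text) != self.n + 1:
            raise ValueError(f"state string must have {self.n + 1} bits")
        state = int(text[-1])
        for i, ch in enumerate(text[: self.n]):
            state |= int(ch) << (i + 1)
        return state

    def decode(self, state: int) -> str:
        bits = [str(state >> (i + 1) & 1) for i in range(self.n)]
        return "".join(bits) + str(state & 1)

    def _target_bit(self, state: int, name: str) -> int:
        return state >> (self._idx[name] + 1) & 1

    # -- dynamics ----------------------------------------------------------

    def step(self, state: int) -> int:
        p = self.pathway
        nxt = 0
        for name in p.targets:
            if name in self.inhibited:
                bit = 0  # drug holds the target off regardless of signaling
            elif name in p.mutated:
                bit = 1
            else:
                ups = p.activations.get(name, ())
                if not ups:
                    bit = 0
                elif p.gates.get(name, "OR").upper() == "AND":
                    bit = int(all(self._target_bit(state, u) for u in ups))
                else:
                    bit = int(any(self._target_bit(state, u) for u in ups))
            nxt |= bit << (self._idx[name] + 1)
        phenotype = int(any(self._target_bit(state, d) for d in p.drivers))
        return nxt | phenotype

    def transition_vector(self) -> list[int]:
        """Successor of every state (the one-hot matrix Q as an index map)."""
        return [self.step(s) for s in range(self.n_states)]

    def attractor(self, start: int | str | None = None) -> list[int]:
        """States of the cycle eventually reached from ``start``.

        Defaults to the all-active state.  The cycle is rotated to begin
        at its smallest state; a fixed point is a length-1 cycle.  Any
        trajectory in a finite deterministic system must cycle within
        2^(n+1) steps, enforced as a hard stop.
        """
        if start is None:
            start = self.n_states - 1  # all targets and tumor active
        elif isinstance(start, str):
            start = self.encode(start)
        seen: dict[int, int] = {}
        state = start
        for t in range(self.n_states + 1):
            if state in seen:
                cycle_states = list(seen)[seen[state] :]
                pivot = cycle_states.index(min(cycle_states))
                return cycle_states[pivot:] + cycle_states[:pivot]
            seen[state] = t
            state = self.step(state)
        raise RuntimeError("no cycle within the state-space bound; dynamics corrupt")

    def tumorous(self, start: int | str | None = None) -> bool:
        """Whether the attractor reached from ``start`` shows tumor.

        A limit cycle counts as tumorous if any of its states has the
        phenotype bit set (conservative call for oscillating phenotypes).
        """
        return any(s & 1 for s in self.attractor(start))


def pathway_to_bn(pathway: DirectionalPathway) -> BooleanNetwork:
    """Boolean network of an (uninhibited) directional pathway."""
    return BooleanNetwork(pathway)


def apply_inhibition(bn: BooleanNetwork, inhibited: Sequence[str]) -> BooleanNetwork:
    """Rewire the network under inhibition of a target set (idempotent)."""
    return BooleanNetwork(bn.pathway, bn.inhibited | frozenset(inhibited))


def tim_from_bn(bn: BooleanNetwork, max_targets: int = 16) -> TIM:
    """Exhaustive dynamics-derived TIM of a pathway.

    For each of the 2^n inhibition combinations, run the inhibited
    network from the all-active state and score 1 when the attractor is
    tumor-free.  Bit i of a combination inhibits the i-th target.
    """
    n = bn.n
    if n > max_targets:
        raise ValueError(
            f"{n} targets need {1 << n} attractor runs; sample combinations instead"
        )
    names = bn.pathway.targets
    known = {}
    for pattern in range(1 << n):
        hit = frozenset(names[i] for i in range(n) if pattern >> i & 1)
        sub = BooleanNetwork(bn.pathway, bn.inhibited | hit)
        known[pattern] = 0.0 if sub.tumorous() else 1.0
    return TIM(members=tuple(range(n)), known=known, names=names)


def structure_to_pathway(
    structure: PathwayStructure, names: Sequence[str] | None = None
) -> DirectionalPathway:
    """A canonical directional orientation of a block structure.

    Targets on a line activate in sequence; each line of a block is fed
    (OR) by the line-ends of the previous block; line heads of the first
    block are mutated (they must self-start for the tumor to exist); the
    line-ends of the last block drive the tumor.
    """
    active = sorted(structure.active_targets)
    label = {t: (names[t] if names is not None else f"K{t}") for t in active}
    activations: dict[str, tuple[str, ...]] = {}
    mutated: set[str] = set()
    prev_ends: list[int] = []
    for bi, block in enumerate(structure.blocks):
        for line in block:
            head, *restof = line
            if bi == 0:
                mutated.add(label[head])
            else:
                activations[label[head]] = tuple(label[e] for e in prev_ends)
            for a, b in zip(line, line[1:]):
                activations[label[b]] = (label[a],)
        prev_ends = [line[-1] for line in block]
    drivers = frozenset(label[e] for e in prev_ends)
    return DirectionalPathway(
        targets=tuple(label[t] for t in active),
        activations=activations,
        mutated=frozenset(mutated),
        drivers=drivers,
    )


# ---------------------------------------------------------------------------
# experiment-design combinatorics


@dataclass(frozen=True)
class ExperimentPlan:
    """Counting summary for a block structure with unknown directionality."""

    L: int
    line_sizes: tuple[tuple[int, ...], ...]
    model_count: int
    ne_expected: float
    ne_worst_bound: float
    ne_avg_bound: float


def count_models(structure: PathwayStructure) -> int:
    """Distinct directional dynamic models compatible with the structure:
    L! orderings of the serial blocks times b! orderings within each
    line."""
    total = math.factorial(structure.L)
    for block in structure.line_sizes():
        for b in block:
            total *= math.factorial(b)
    return total


def _block_bound(sizes: Sequence[int], a: int, *, averaged: bool) -> float:
    """Per-block experiment bound for resolving within-line order.

    Worst-case form: max(max_j b_j - 2, ceil((sum_j b_j - a)/(a-1)) - 1);
    the averaged form replaces each count x by its expected-value analog.
    Blocks with a single line have no cross-line experiment, so only the
    first term applies.  Bounds are clamped at 0.
    """
    if averaged:
        first = max((2 * b - 4) / 3 for b in sizes)
        second = (
            math.ceil((2 * sum(sizes) - a) / (3 * (a - 1))) - 1 if a > 1 else -math.inf
        )
    else:
        first = max(b - 2 for b in sizes)
        second = math.ceil((sum(sizes) - a) / (a - 1)) - 1 if a > 1 else -math.inf
    return max(first, second, 0.0)


def experiment_bounds(structure: PathwayStructure) -> ExperimentPlan:
    """Experiment counts needed to pin down directionality.

    ``ne_expected`` = (2L - 1)/3 experiments to order L >= 2 serial
    blocks (0 for a single block); the worst-case and expected upper
    bounds add the per-block within-line terms to L - 1 and (2L - 1)/3
    respectively.
    """
    L = structure.L
    sizes = structure.line_sizes()
    ne_expected = (2 * L - 1) / 3 if L >= 2 else 0.0
    worst_inner = max(
        _block_bound(block, len(block), averaged=False) for block in sizes
    )
    avg_inner = max(_block_bound(block, len(block), averaged=True) for block in sizes)
    return ExperimentPlan(
        L=L,
        line_sizes=tuple(tuple(b) for b in sizes),
        model_count=count_models(structure),
        ne_expected=ne_expected,
        ne_worst_bound=worst_inner + (L - 1),
        ne_avg_bound=avg_inner + ne_expected,
    )
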