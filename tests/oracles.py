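"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (dict/loop style, no
shared code with the package internals) so that agreement between oracle
and implementation is meaningful.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

EPS = 1e-9


# -- target-set scoring ------------------------------------------------------


def brute_gamma(patterns: Sequence[tuple[int, ...]], scores: Sequence[float]) -> float:
    """Naive double-loop evaluation of the bin-fit + inconsistency score."""
    bins: dict[tuple[int, ...], list[float]] = {}
    for pat, y in zip(patterns, scores):
        bins.setdefault(pat, []).append(y)
    means = {pat: sum(ys) / len(ys) for pat, ys in bins.items()}

    def is_subset(a, b):  # a subset of b, elementwise on bits
        return all(x <= y for x, y in zip(a, b)) and a != b

    fit = 0.0
    for pat, ys in bins.items():
        for y in ys:
            fit += abs(means[pat] - y)
    penalty = 0.0
    for pat, y in zip(patterns, scores):
        for bpat, p in means.items():
            if is_subset(bpat, pat) and p > y + EPS:
                penalty += abs(p - y)  # subset bin out-scores superset drug
            if is_subset(pat, bpat) and p < y - EPS:
                penalty += abs(p - y)  # superset bin under-scores subset drug
    return fit + penalty


def restrict(dtip: Sequence[int], members: Iterable[int]) -> tuple[int, ...]:
    return tuple(int(dtip[j]) for j in members)


def exhaustive_best_set(
    dtips: Sequence[Sequence[int]], scores: Sequence[float], n: int
) -> tuple[float, tuple[int, ...]]:
    """Minimum gamma over every subset of n targets (2^n scan)."""
    best = (float("inf"), ())
    for r in range(n + 1):
        for members in itertools.combinations(range(n), r):
            g = brute_gamma([restrict(d, members) for d in dtips], scores)
            if g < best[0] - EPS:
                best = (g, members)
    return best


def forward_selection(
    dtips: Sequence[Sequence[int]], scores: Sequence[float], n: int
) -> tuple[float, tuple[int, ...]]:
    """Plain greedy forward selection (no backward steps)."""
    members: list[int] = []
    score = brute_gamma([restrict(d, members) for d in dtips], scores)
    while len(members) < n:
        options = []
        for j in range(n):
            if j in members:
                continue
            g = brute_gamma([restrict(d, members + [j]) for d in dtips], scores)
            options.append((g, j))
        g, j = min(options)
        if g >= score - EPS:
            break
        members.append(j)
        score = g
    return score, tuple(sorted(members))


# -- TIM bounds --------------------------------------------------------------


def brute_bounds(pattern: int, known: dict[int, float], n: int):
    """Scan all known/boundary combinations for the Rule-3 bracket."""
    entries = dict(known)
    entries.setdefault(0, 0.0)
    entries.setdefault((1 << n) - 1, 1.0)
    subs = [(y, p) for p, y in entries.items() if p & pattern == p]
    sups = [(y, p) for p, y in entries.items() if p | pattern == p]
    y_l = max(y for y, _ in subs)
    y_u = min(y for y, _ in sups)
    return y_l, y_u


# -- monotone Boolean functions ----------------------------------------------


def minimal_true_points(truth: dict[int, bool], n: int) -> set[frozenset[int]]:
    """Minimal satisfying sets of a monotone 0/1 function by full scan."""
    true_pats = [p for p in range(1 << n) if truth[p]]
    minimal = [
        p for p in true_pats if not any(q != p and q & p == q for q in true_pats)
    ]
    return {frozenset(i for i in range(n) if p >> i & 1) for p in minimal if p}


# -- synthetic pathways ------------------------------------------------------


def survives_by_path_enumeration(blocks, inhibited: set[int]) -> bool:
    """Tumor survives iff some choice of one line per block is untouched.

    A signal path picks one line in every serial block and traverses all
    of that line's targets; it is broken when any of them is inhibited.
    """
    for choice in itertools.product(*blocks):
        if all(t not in inhibited for line in choice for t in line):
            return True
    return False


# -- Boolean network ---------------------------------------------------------


def brute_step(state_bits, pathway, inhibited: set[str]):
    """Per-bit evaluation of the transition rules on explicit dicts.

    ``state_bits`` maps target name -> 0/1 plus key 'tumor'.
    """
    nxt = {}
    for t in pathway.targets:
        if t in inhibited:
            nxt[t] = 0
        elif t in pathway.mutated:
            nxt[t] = 1
        else:
            ups = pathway.activations.get(t, ())
            if not ups:
                nxt[t] = 0
            elif pathway.gates.get(t, "OR") == "AND":
                nxt[t] = int(all(state_bits[u] for u in ups))
            else:
                nxt[t] = int(any(state_bits[u] for u in ups))
    nxt["tumor"] = int(any(state_bits[d] for d in pathway.drivers))
    return nxt


def count_orderings(blocks) -> int:
    """Enumerate the distinct directional orderings of a block structure.

    Independent of the closed form: multiply the number of permutations
    of the serial blocks by the permutations within every line, by
    explicit enumeration (guarded to small structures in tests).
    """
    import math

    total = 0
    L = len(blocks)
    for _ in itertools.permutations(range(L)):
        ways = 1
        for block in blocks:
            for line in block:
                ways *= sum(1 for _ in itertools.permutations(line))
        total += ways
    return total
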