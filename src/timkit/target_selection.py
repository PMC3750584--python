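"""Relevant-target-set selection from binarized drug profiles.

Any candidate target set T partitions the (non-excluded) drugs into bins
by their inhibition pattern restricted to T.  The set score Gamma(T) sums

* the within-bin absolute deviation of each drug's sensitivity from its
  bin mean, and
* an inconsistency penalty for tumor-promoter-rule violations: a bin whose
  pattern is a strict subset of a drug's pattern must not out-score that
  drug (inhibiting more targets never reopens a blocked path), and a bin
  whose pattern is a strict superset must not under-score it.

Sequential floating forward search (SFFS) minimizes Gamma: forward steps
add the best candidate target, floating backward steps drop any member
whose removal strictly improves the score.  Ties favor smaller sets, so
the selection tends to the minimal set that explains the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import BinarizedDrug

#: slack on score comparisons so float noise never triggers a penalty
EPS = 1e-9


@dataclass(frozen=True)
class TargetSet:
    """A selected subset of kinase-universe indices with its Gamma score."""

    members: tuple[int, ...]
    score: float


@dataclass(frozen=True)
class Bin:
    pattern: tuple[int, ...]  # restricted DTIP over the target set
    drug_ids: tuple[str, ...]
    scores: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))


@dataclass(frozen=True)
class BinPartition:
    members: tuple[int, ...]
    bins: tuple[Bin, ...]


def project_drug(drug: BinarizedDrug, members: Sequence[int]) -> tuple[int, ...]:
    """A drug's DTIP masked to the target set (restricted pattern)."""
    return tuple(int(drug.dtip[j]) for j in members)


def _screen_arrays(drugs: Sequence[BinarizedDrug]) -> tuple[np.ndarray, np.ndarray]:
    active = [d for d in drugs if not d.excluded]
    if not active:
        raise ValueError("no usable (non-excluded) drugs")
    B = np.stack([d.dtip for d in active]).astype(np.int64)
    Y = np.array([d.score for d in active], dtype=float)
    return B, Y


def _local_patterns(B: np.ndarray, members: Sequence[int]) -> np.ndarray:
    """Pack each drug's restricted pattern into an int64 bitmask."""
    if not len(members):
        return np.zeros(B.shape[0], dtype=np.int64)
    if len(members) > 62:
        raise ValueError("target sets beyond 62 members are not supported")
    weights = np.int64(1) << np.arange(len(members), dtype=np.int64)
    return B[:, list(members)] @ weights


def _gamma(patterns: np.ndarray, Y: np.ndarray) -> float:
    U, inv = np.unique(patterns, return_inverse=True)
    counts = np.bincount(inv)
    P = np.bincount(inv, weights=Y) / counts
    fit = float(np.abs(P[inv] - Y).sum())
    # strict subset relation between bin patterns (bitmask containment)
    sub = ((U[:, None] & U[None, :]) == U[:, None]) & (U[:, None] != U[None, :])
    D = P[:, None] - Y[None, :]  # bin-mean minus drug score, (bins x drugs)
    below = sub[:, inv] & (D > EPS)  # subset bin out-scoring a superset drug
    above = sub.T[:, inv] & (D < -EPS)  # superset bin under-scoring a subset drug
    penalty = float(np.abs(D)[below | above].sum())
    return fit + penalty


def score_target_set(drugs: Sequence[BinarizedDrug], members: Sequence[int]) -> float:
    """Gamma(T): bin-fit error plus subset/superset inconsistency penalty."""
    B, Y = _screen_arrays(drugs)
    return _gamma(_local_patterns(B, members), Y)


def bin_partition(drugs: Sequence[BinarizedDrug], members: Sequence[int]) -> BinPartition:
    """Group the usable drugs by their restricted pattern under T."""
    active = [d for d in drugs if not d.excluded]
    groups: dict[tuple[int, ...], list[BinarizedDrug]] = {}
    for d in active:
        groups.setdefault(project_drug(d, members), []).append(d)
    bins = tuple(
        Bin(
            pattern=pat,
            drug_ids=tuple(d.drug_id for d in group),
            scores=tuple(d.score for d in group),
        )
        for pat, group in sorted(groups.items())
    )
    return BinPartition(members=tuple(members), bins=bins)


def sffs_select(
    drugs: Sequence[BinarizedDrug],
    n_targets: int | None = None,
    max_size: int = 20,
) -> TargetSet:
    """Select a minimal relevant target set by floating forward search.

    Forward steps add the candidate minimizing Gamma (ties to the lowest
    target index); after each addition, backward steps repeatedly remove
    any member whose removal strictly lowers Gamma.  The best set seen at
    each cardinality is recorded; the search stops when a full pass stops
    improving any of them or ``max_size`` is reached.  Gamma ties break
    toward smaller then lexicographically smaller sets, and the winner is
    finally pruned of members whose removal leaves Gamma unchanged.
    """
    B, Y = _screen_arrays(drugs)
    if n_targets is None:
        n_targets = B.shape[1]
    # targets hit by no usable drug cannot change the partition
    candidates = [j for j in range(n_targets) if B[:, j].any()]
    gamma_of = lambda mem: _gamma(_local_patterns(B, mem), Y)

    current: list[int] = []
    current_score = gamma_of(current)
    best: dict[int, tuple[float, tuple[int, ...]]] = {0: (current_score, ())}

    def record(members: list[int], score: float) -> bool:
        key = tuple(sorted(members))
        k = len(key)
        if k not in best or score < best[k][0] - EPS:
            best[k] = (score, key)
            return True
        return False

    for _ in range(4 * max_size):  # hard cap on floating passes
        if len(current) >= max_size:
            break
        improved = False
        # forward inclusion
        best_j, best_s = None, np.inf
        for j in candidates:
            if j in current:
                continue
            s = gamma_of(current + [j])
            if s < best_s - EPS:
                best_j, best_s = j, s
        if best_j is None:
            break
        current.append(best_j)
        current_score = best_s
        improved |= record(current, current_score)
        # conditional (floating) backward exclusion: drop the least useful
        # member while that beats the best set recorded at the smaller
        # cardinality (removing the member just added never qualifies,
        # since the previous set is already on record)
        while len(current) > 1:
            best_rm, best_rm_s = None, np.inf
            for t in current:
                s = gamma_of([x for x in current if x != t])
                if s < best_rm_s - EPS:
                    best_rm, best_rm_s = t, s
            k1 = len(current) - 1
            if best_rm is None or (k1 in best and best_rm_s >= best[k1][0] - EPS):
                break
            current.remove(best_rm)
            current_score = best_rm_s
            improved |= record(current, current_score)
        if not improved:
            break

    # plain forward sweep folded into the per-cardinality records: the
    # floating path can wander after an exclusion, so this pins the
    # result to never fall behind straight greedy selection
    greedy: list[int] = []
    while len(greedy) < max_size:
        options = [
            (gamma_of(greedy + [j]), j) for j in candidates if j not in greedy
        ]
        if not options:
            break
        s, j = min(options)
        greedy.append(j)
        record(greedy, s)

    score, members = min(
        ((s, mem) for s, mem in best.values()), key=lambda it: (it[0], len(it[1]), it[1])
    )
    # local minimality: drop members whose removal does not raise Gamma
    members = list(members)
    pruned = True
    while pruned and members:
        pruned = False
        for t in list(members):
            reduced = [x for x in members if x != t]
            s = gamma_of(reduced)
            if s <= score + EPS:
                members, score = reduced, s
                pruned = True
                break
    return TargetSet(members=tuple(sorted(members)), score=float(score))
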