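"""Target Inhibition Map construction and sensitivity inference.

A TIM maps every binary inhibition combination over a selected target set
T to a predicted sensitivity in [0, 1].  Experimental combinations keep
their (bin-mean) sensitivities; everything else is interpolated between
its closest known subset and superset under the tumor-promoter rules:
inhibiting more targets can only help, so the sensitivity of an unknown
combination is at least that of its best-scoring known subset and at most
that of its worst-scoring known superset.  The no-inhibition combination
anchors at 0 and the all-targets combination at 1 unless experimental
data overrides them.

Patterns are int bitmasks: bit i corresponds to the i-th member of the
selected target set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import BinarizedDrug
from .target_selection import TargetSet, bin_partition


class InconsistentDataWarning(UserWarning):
    """Experimental sensitivities violate subset/superset monotonicity."""


@dataclass(frozen=True)
class Bounds:
    """Closest known subset/superset bracket of a combination."""

    c_l: int
    y_l: float
    c_u: int
    y_u: float

    @property
    def h(self) -> int:
        """Hamming distance between the bracketing combinations."""
        return (self.c_l ^ self.c_u).bit_count()


@dataclass
class TIM:
    """Map from target-inhibition combinations over T to sensitivity.

    ``known`` holds the experimental combinations (pattern -> bin-mean
    sensitivity).  ``discount`` is the inference discount exponent n of
    the interpolation ratio (n = 1 is linear; smaller n is optimistic).
    ``weights`` are per-target importance scores; uniform by default.
    """

    members: tuple[int, ...]  # universe indices of the selected targets
    known: dict[int, float]
    names: tuple[str, ...] | None = None
    discount: float = 1.0
    weights: tuple[float, ...] | None = None
    dense_cap: int = 16
    _table: dict[int, float] = field(default_factory=dict, repr=False)
    _warned: set[tuple[int, int]] = field(default_factory=set, repr=False)

    HARD_CAP = 30

    def __post_init__(self) -> None:
        n = self.n
        if self.weights is not None and len(self.weights) != n:
            raise ValueError("need one weight per selected target")
        if self.weights is not None and any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if self.discount <= 0:
            raise ValueError("discount exponent must be positive")
        full = (1 << n) - 1
        for p, y in self.known.items():
            if not 0 <= p <= full:
                raise ValueError(f"known pattern {p:b} outside {n}-target space")
            if not 0.0 <= y <= 1.0:
                raise ValueError(f"sensitivity {y} outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def full_pattern(self) -> int:
        return (1 << self.n) - 1

    # -- Rule 3 bracketing ------------------------------------------------

    def _entries(self) -> dict[int, float]:
        entries = {0: 0.0, self.full_pattern: 1.0}
        entries.update(self.known)  # experimental values override boundary
        return entries

    def bounds(self, pattern: int) -> Bounds:
        """Closest-subset / closest-superset bracket for ``pattern``.

        The lower anchor is the known subset of highest sensitivity (ties:
        the largest, i.e. closest, then lowest bitmask); the upper anchor
        is the known superset of lowest sensitivity (ties: the smallest,
        then lowest bitmask).  If the data itself is non-monotone the
        bracket may invert; the clamp in :meth:`predict` repairs it.
        """
        entries = self._entries()
        c_l = y_l = None
        for p, y in entries.items():
            if p & pattern == p:  # p subset of pattern
                key = (y, p.bit_count(), -p)
                if c_l is None or key > (y_l, c_l.bit_count(), -c_l):
                    c_l, y_l = p, y
        c_u = y_u = None
        for p, y in entries.items():
            if p & pattern == pattern:  # p superset of pattern
                key = (y, p.bit_count(), p)
                if c_u is None or key < (y_u, c_u.bit_count(), c_u):
                    c_u, y_u = p, y
        return Bounds(c_l=c_l, y_l=y_l, c_u=c_u, y_u=y_u)

    # -- inference --------------------------------------------------------

    def _interpolate(self, pattern: int, b: Bounds) -> float:
        y_l, y_u = b.y_l, b.y_u
        if y_l > y_u:  # experimental inconsistency: clamp, keep monotone
            pair = (b.c_l, b.c_u)
            if pair not in self._warned:
                self._warned.add(pair)
                warnings.warn(
                    f"non-monotone experimental data: subset {b.c_l:0{self.n}b} has "
                    f"sensitivity {y_l:.3f} > superset {b.c_u:0{self.n}b} ({y_u:.3f}); "
                    "clamping the upper bound",
                    InconsistentDataWarning,
                    stacklevel=4,
                )
            y_u = y_l
        transition = b.c_u & ~b.c_l
        h = transition.bit_count()
        if h == 0:
            return y_l
        added = pattern & ~b.c_l
        if self.weights is None:
            ratio = added.bit_count() / h
        else:
            w = np.asarray(self.weights)
            bits = lambda x: [i for i in range(self.n) if x >> i & 1]
            ratio = float(w[bits(added)].sum() / w[bits(transition)].sum())
        return y_l + (y_u - y_l) * ratio**self.discount

    def predict(self, pattern: int) -> float:
        """Predicted sensitivity of an inhibition combination (memoized).

        Experimental entries are returned verbatim.  Inferred entries are
        the subset/superset interpolation closed monotonically from
        below: the prediction is the maximum of the pattern's own
        interpolated value and the predictions of its immediate subsets.
        The raw interpolation respects its own bracket but its anchors
        shift between neighboring patterns, which can invert a subset
        pair; the closure restores the tumor-promoter ordering without
        ever leaving the bracket (a subset's prediction never exceeds
        the minimum over known supersets shared with the superset).
        """
        if pattern in self.known:
            return self.known[pattern]
        if pattern not in self._table:
            value = self._interpolate(pattern, self.bounds(pattern))
            for i in range(self.n):
                if pattern >> i & 1:
                    value = max(value, self.predict(pattern & ~(1 << i)))
            self._table[pattern] = value
        return self._table[pattern]

    def materialize(self) -> dict[int, float]:
        """Dense table of all 2^n combinations (n capped at HARD_CAP)."""
        if self.n > self.HARD_CAP:
            raise ValueError(
                f"dense TIM over {self.n} targets is infeasible; use lazy predict()"
            )
        return {p: self.predict(p) for p in range(1 << self.n)}

    # -- drug-facing API --------------------------------------------------

    def project(self, drug: BinarizedDrug) -> int:
        """Pack a drug's DTIP restricted to the selected targets."""
        return sum(int(drug.dtip[j]) << i for i, j in enumerate(self.members))

    def predict_drug(self, drug: BinarizedDrug) -> float:
        """Sensitivity prediction for a binarized drug.

        A drug hitting none of the selected targets projects onto the
        no-inhibition combination (prediction 0 unless experimental data
        says otherwise).
        """
        return self.predict(self.project(drug))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        payload: dict = {
            "members": list(self.members),
            "names": list(self.names) if self.names is not None else None,
            "known": {str(p): y for p, y in sorted(self.known.items())},
            "discount": self.discount,
            "weights": list(self.weights) if self.weights is not None else None,
        }
        if self.n <= self.dense_cap:
            payload["table"] = {str(p): self.predict(p) for p in range(1 << self.n)}
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TIM":
        tim = cls(
            members=tuple(payload["members"]),
            known={int(p): float(y) for p, y in payload["known"].items()},
            names=tuple(payload["names"]) if payload.get("names") else None,
            discount=float(payload.get("discount", 1.0)),
            weights=tuple(payload["weights"]) if payload.get("weights") else None,
        )
        return tim


def build_tim(
    drugs: Sequence[BinarizedDrug],
    target_set: TargetSet,
    names: Sequence[str] | None = None,
    discount: float = 1.0,
    weights: Sequence[float] | None = None,
    dense: bool | None = None,
) -> TIM:
    """Build the TIM of a screen over a selected target set.

    Experimental entries are the bin means of the training drugs'
    restricted patterns (several drugs sharing a pattern contribute their
    mean sensitivity), matching the partition scored during selection.
    ``dense=True`` materializes all 2^n entries eagerly.
    """
    part = bin_partition(drugs, target_set.members)
    known = {
        sum(b << i for i, b in enumerate(bin_.pattern)): bin_.mean for bin_ in part.bins
    }
    member_names = (
        tuple(names[j] for j in target_set.members) if names is not None else None
    )
    tim = TIM(
        members=target_set.members,
        known=known,
        names=member_names,
        discount=discount,
        weights=tuple(weights) if weights is not None else None,
    )
    if dense:
        tim.materialize()
    return tim


# ---------------------------------------------------------------------------
# continuous target-inhibition extension


def continuous_inhibition(
    ec50: Mapping[int, float], x: float, n_targets: int
) -> np.ndarray:
    """Per-target inhibition ratios of a drug applied at concentration x nM.

    A logistic dose response in log-concentration gives target j the
    inhibition z_j = 1 / (1 + exp(ln(EC50_j / x))) = x / (x + EC50_j),
    which is 0.5 exactly at x = EC50_j and increases with dose.  Targets
    with no recorded interaction stay at 0.
    """
    if x <= 0:
        raise ValueError("concentration must be positive")
    z = np.zeros(n_targets)
    for j, e in ec50.items():
        z[j] = x / (x + e)
    return z


def combine_inhibitions(profiles: Sequence[np.ndarray]) -> np.ndarray:
    """Joint inhibition of several drugs at stated doses.

    Assumes independent action per target: the chance a target escapes
    all drugs is the product of the per-drug escape ratios, so the joint
    inhibition is ``1 - prod(1 - z_drug)``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    escape = np.ones_like(profiles[0], dtype=float)
    for z in profiles:
        escape *= 1.0 - np.asarray(z, dtype=float)
    return 1.0 - escape


def threshold_profile(z: np.ndarray, level: float = 0.5) -> np.ndarray:
    """Binarize a continuous inhibition profile (z >= level -> hit)."""
    return (np.asarray(z) >= level).astype(np.uint8)
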