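"""Cross-validation of the TIM pipeline and drug-overlap similarity.

Leave-one-out and repeated k-fold harnesses retrain the selection + TIM
stages on each training split (binarization is a fixed per-drug
preprocessing, so it is done once up front) and score withheld drugs by
the absolute prediction error |y - y_hat|.  Reports mirror the per-drug
error tables of a screen write-up: one row per drug with predicted and
experimental sensitivity, plus MAE and the Pearson correlation between
predictions and experiments.

The similarity measure Lambda compares two drugs' EC50 vectors: shared
targets contribute their smaller EC50 to the numerator, the union of
targets contributes the larger EC50 to the denominator, so identical
profiles score 1 and disjoint ones 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import BinarizedDrug
from .screen_io import DrugProfile
from .target_selection import sffs_select
from .tim_inference import build_tim


@dataclass(frozen=True)
class CVRow:
    drug_id: str
    predicted: float
    experimental: float
    excluded: bool = False

    @property
    def error(self) -> float:
        return abs(self.predicted - self.experimental)


@dataclass(frozen=True)
class CVReport:
    """Per-drug cross-validation outcome plus summary statistics."""

    rows: tuple[CVRow, ...]
    scheme: str
    k: int | None = None
    repeats: int | None = None
    seed: int | None = None
    fold_maes: tuple[float, ...] = field(default_factory=tuple)

    @property
    def scored_rows(self) -> list[CVRow]:
        return [r for r in self.rows if not r.excluded]

    @property
    def mae(self) -> float:
        rows = self.scored_rows
        return float(np.mean([r.error for r in rows])) if rows else math.nan

    @property
    def pearson_r(self) -> float:
        rows = self.scored_rows
        pred = np.array([r.predicted for r in rows])
        exp = np.array([r.experimental for r in rows])
        if len(rows) < 2 or pred.std() == 0 or exp.std() == 0:
            return math.nan
        return float(np.corrcoef(pred, exp)[0, 1])

    def to_frame(self) -> pd.DataFrame:
        """Per-drug table with 'Error', 'Pred. Sens', 'Exp. Sens' columns."""
        return pd.DataFrame(
            {
                "Drug": [r.drug_id for r in self.rows],
                "Error": [round(r.error, 4) for r in self.rows],
                "Pred. Sens": [round(r.predicted, 4) for r in self.rows],
                "Exp. Sens": [round(r.experimental, 4) for r in self.rows],
                "Excluded": [r.excluded for r in self.rows],
            }
        )


def _fit_predict(
    train: Sequence[BinarizedDrug],
    test: Sequence[BinarizedDrug],
    *,
    max_size: int,
    discount: float,
) -> list[CVRow]:
    tset = sffs_select(train, max_size=max_size)
    tim = build_tim(train, tset, discount=discount)
    return [
        CVRow(drug_id=d.drug_id, predicted=tim.predict_drug(d), experimental=d.score)
        for d in test
    ]


def loo_evaluate(
    drugs: Sequence[BinarizedDrug], *, max_size: int = 20, discount: float = 1.0
) -> CVReport:
    """Leave-one-out evaluation: retrain target selection and TIM per drug.

    Drugs excluded by binarization (empty profiles) are reported with a
    prediction of 0 but do not enter MAE or correlation.
    """
    active = [d for d in drugs if not d.excluded]
    if len(active) < 3:
        raise ValueError("need at least 3 usable drugs for cross-validation")
    rows: list[CVRow] = []
    for d in drugs:
        if d.excluded:
            rows.append(
                CVRow(drug_id=d.drug_id, predicted=0.0, experimental=d.score, excluded=True)
            )
            continue
        train = [t for t in active if t.drug_id != d.drug_id]
        rows.extend(_fit_predict(train, [d], max_size=max_size, discount=discount))
    return CVReport(rows=tuple(rows), scheme="loo")


def kfold_evaluate(
    drugs: Sequence[BinarizedDrug],
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    *,
    max_size: int = 20,
    discount: float = 1.0,
) -> CVReport:
    """Repeated k-fold evaluation with seeded random fold assignment.

    Folds are sized within one drug of each other.  The report pools the
    per-drug rows of every repeat; ``fold_maes`` carries each repeat's
    MAE (their mean equals the pooled MAE since every repeat covers every
    usable drug exactly once).
    """
    active = [d for d in drugs if not d.excluded]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(active):
        raise ValueError(f"k={k} exceeds the {len(active)} usable drugs")
    rng = np.random.default_rng(seed)
    rows: list[CVRow] = [
        CVRow(drug_id=d.drug_id, predicted=0.0, experimental=d.score, excluded=True)
        for d in drugs
        if d.excluded
    ]
    repeat_maes: list[float] = []
    for _ in range(repeats):
        order = rng.permutation(len(active))
        folds = np.array_split(order, k)
        repeat_rows: list[CVRow] = []
        for fold in folds:
            held = {active[i].drug_id for i in fold}
            train = [d for d in active if d.drug_id not in held]
            test = [active[i] for i in fold]
            repeat_rows.extend(
                _fit_predict(train, test, max_size=max_size, discount=discount)
            )
        repeat_maes.append(float(np.mean([r.error for r in repeat_rows])))
        rows.extend(repeat_rows)
    return CVReport(
        rows=tuple(rows),
        scheme="kfold",
        k=k,
        repeats=repeats,
        seed=seed,
        fold_maes=tuple(repeat_maes),
    )


# ---------------------------------------------------------------------------
# EC50 overlap similarity


def similarity(d1: DrugProfile, d2: DrugProfile) -> float:
    """Overlap similarity Lambda of two drugs' EC50 profiles.

    Lambda = sum_shared min(E1, E2) / sum_union max(E1, E2), where
    non-inhibited targets count as 0.  Identical profiles give 1,
    disjoint target sets give 0.
    """
    shared = set(d1.ec50) & set(d2.ec50)
    union = set(d1.ec50) | set(d2.ec50)
    if not union:
        warnings.warn(
            f"both {d1.drug_id} and {d2.drug_id} have empty profiles; Lambda = 0",
            stacklevel=2,
        )
        return 0.0
    num = sum(min(d1.ec50[j], d2.ec50[j]) for j in shared)
    den = sum(max(d1.ec50.get(j, 0.0), d2.ec50.get(j, 0.0)) for j in union)
    return num / den


def similarity_matrix(profiles: Sequence[DrugProfile]) -> pd.DataFrame:
    """Symmetric drug-by-drug Lambda matrix (diagonal 1 for non-empty)."""
    ids = [p.drug_id for p in profiles]
    mat = np.zeros((len(profiles), len(profiles)))
    for i, a in enumerate(profiles):
        for j in range(i, len(profiles)):
            mat[i, j] = mat[j, i] = similarity(a, profiles[j])
    return pd.DataFrame(mat, index=ids, columns=ids)
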