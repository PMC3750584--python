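"""IC50 -> sensitivity scoring and log-window binarization of drug targets.

Two preprocessing steps feed the rest of the pipeline:

1. each drug's IC50 is mapped to a sensitivity score y in [0, 1] anchored
   at Cmax (maximum clinically achievable dose, y = 1) and MaxDose
   (maximum screened dose, y = 0), log-linear in between;
2. each drug's EC50 vector is thresholded to a binary Drug Target
   Inhibition Profile (DTIP): target j counts as hit when log(EC50_j)
   falls inside the window [alpha*log(IC50), beta*log(IC50)].

A drug whose window captures no target carries no usable perturbation
information and is flagged ``excluded``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .screen_io import DrugProfile, KinaseUniverse, ScreenDataset


@dataclass(frozen=True)
class BinarizationConfig:
    """Log-window and scoring parameters.

    alpha, beta
        Window multipliers on log(IC50); 0 <= alpha < beta.  beta should
        stay a small constant (2-4) so far-off interactions are not pulled
        into the profile.
    log_base
        Base for all logarithms (concentration scale only; any base > 1
        gives the same window because the inequality is homogeneous).
    floor_nM
        Concentrations are floored here before taking logs so every log is
        strictly positive and the window is well ordered even for
        sub-nanomolar potencies.
    continuous_c
        Use the continuity-preserving normalization of the scoring
        function (y(Cmax) = 1).  The alternative drops the normalization
        constant's reciprocal and leaves a jump at Cmax; it is kept only
        for comparison.
    rescale_scores
        Min-max rescale the scores of each culture to span [0, 1] after
        Cmax/MaxDose scoring.
    """

    alpha: float = 0.0
    beta: float = 2.0
    log_base: float = 10.0
    floor_nM: float = 1.01
    continuous_c: bool = True
    rescale_scores: bool = True
    default_cmax_fraction: float = 0.1  # cmax fallback = fraction * maxdose

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < self.beta:
            raise ValueError(f"need 0 <= alpha < beta, got alpha={self.alpha}, beta={self.beta}")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.floor_nM <= 1:
            raise ValueError("floor_nM must exceed 1 so floored logs are positive")


@dataclass(frozen=True)
class SensitivityScore:
    drug_id: str
    value: float

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 1:
            raise ValueError(f"{self.drug_id}: sensitivity {self.value} outside [0, 1]")


@dataclass
class BinarizedDrug:
    """A drug reduced to its binary inhibition profile and scalar score."""

    drug_id: str
    dtip: np.ndarray  # uint8 vector over the kinase universe
    score: float
    excluded: bool = field(default=False)

    def pattern(self) -> int:
        """DTIP packed into an int bitmask (bit j = target j)."""
        return int(sum(1 << j for j in np.flatnonzero(self.dtip)))


def scale_sensitivity(
    ic50: float | None,
    cmax: float | None,
    maxdose: float,
    cfg: BinarizationConfig = BinarizationConfig(),
) -> float:
    """Map an IC50 to a sensitivity score in [0, 1].

    y = 1 below Cmax, y = 0 at/above MaxDose (or when the IC50 was never
    reached), and log-linear in between::

        y = c * (1 - log(IC50) / log(MaxDose)),   Cmax <= IC50 <= MaxDose

    with c = 1 / (1 - log(Cmax)/log(MaxDose)) so the two branches meet
    continuously at Cmax.  Setting ``continuous_c=False`` uses
    c = 1 - log(Cmax)/log(MaxDose) instead, which leaves a discontinuity.
    """
    if maxdose is None or maxdose <= cfg.floor_nM:
        raise ValueError(f"maxdose must exceed the concentration floor, got {maxdose}")
    if cmax is None:
        cmax = cfg.default_cmax_fraction * maxdose
        warnings.warn(f"no Cmax provided; falling back to {cmax} nM", stacklevel=2)
    if cmax >= maxdose:
        raise ValueError(f"cmax ({cmax}) must be below maxdose ({maxdose})")
    if ic50 is None or ic50 >= maxdose:
        return 0.0
    if ic50 < cmax:
        return 1.0
    log = lambda v: math.log(max(v, cfg.floor_nM), cfg.log_base)
    ratio = 1.0 - log(cmax) / log(maxdose)
    c = 1.0 / ratio if cfg.continuous_c else ratio
    y = c * (1.0 - log(ic50) / log(maxdose))
    return min(1.0, max(0.0, y))


def binarize_targets(
    drug: DrugProfile,
    cfg: BinarizationConfig = BinarizationConfig(),
    universe: KinaseUniverse | None = None,
    *,
    n: int | None = None,
    score: float | None = None,
) -> BinarizedDrug:
    """Threshold a drug's EC50 vector to its binary inhibition profile.

    Target j is hit when ``alpha*log(IC50) <= log(EC50_j) <= beta*log(IC50)``
    with all concentrations floored at ``cfg.floor_nM``.  A drug with a
    "not reached" IC50, or with no target in the window, is flagged
    excluded (its score is 0 / as given but it carries no profile).
    """
    size = universe.n if universe is not None else n
    if size is None:
        size = (max(drug.ec50) + 1) if drug.ec50 else 1
    dtip = np.zeros(size, dtype=np.uint8)
    if drug.ic50_reached:
        log = lambda v: math.log(max(v, cfg.floor_nM), cfg.log_base)
        lic = log(drug.ic50)
        lo, hi = cfg.alpha * lic, cfg.beta * lic
        for j, ec50 in drug.ec50.items():
            if lo <= log(ec50) <= hi:
                dtip[j] = 1
    if score is None:
        score = (
            scale_sensitivity(drug.ic50, drug.cmax, drug.maxdose, cfg)
            if drug.maxdose is not None
            else 0.0
        )
    return BinarizedDrug(
        drug_id=drug.drug_id, dtip=dtip, score=score, excluded=not dtip.any()
    )


def binarize_screen(
    screen: ScreenDataset, cfg: BinarizationConfig = BinarizationConfig()
) -> list[BinarizedDrug]:
    """Binarize every drug of a screen and (optionally) rescale scores.

    With ``cfg.rescale_scores`` the Cmax/MaxDose scores of the culture are
    min-max rescaled to span exactly [0, 1], mirroring per-culture scaling
    of experimental sensitivities.  Excluded drugs keep their flag.
    """
    out = [binarize_targets(d, cfg, screen.universe) for d in screen.drugs]
    if cfg.rescale_scores:
        scores = np.array([b.score for b in out], dtype=float)
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            for b, s in zip(out, (scores - lo) / (hi - lo)):
                b.score = float(s)
    return out


def usable(drugs: list[BinarizedDrug]) -> list[BinarizedDrug]:
    """Drop drugs excluded by binarization (empty inhibition profiles)."""
    return [d for d in drugs if not d.excluded]
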