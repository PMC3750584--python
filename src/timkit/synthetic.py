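"""Synthetic Boolean tumor-survival pathways and drug-screen benchmarks.

The generator emulates block-structured survival pathways: L blocks in
series, each block a set of parallel lines, each line a run of kinase
targets.  A drug kills the synthetic tumor exactly when its inhibited
targets cut every parallel line of at least one block (severing that
stage of the survival signal).  Drug libraries inhibit a small random
subset of a universe that embeds the pathway's active targets among
inert decoys, mimicking screens where most kinases are irrelevant.

The benchmark trains the full selection + TIM pipeline on a random panel
from such a library and scores 0/1 predictions on a disjoint test panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import BinarizedDrug
from .target_selection import sffs_select
from .tim_inference import build_tim


@dataclass(frozen=True)
class PathwayConfig:
    """Shape bounds for random pathways and the drug-library sampler.

    Defaults model compact kinase survival circuits: at most 3 serial
    blocks of at most 3 parallel lines, the pathway's active targets
    hidden among 10 decoy kinases, and drugs inhibiting a Poisson(3)
    (minimum 1) number of targets.
    """

    max_blocks: int = 3
    max_lines: int = 3
    n_decoy: int = 10
    poisson_lambda: float = 3.0


@dataclass(frozen=True)
class PathwayStructure:
    """Block/line layout with concrete target labels.

    ``blocks[i][j]`` is the tuple of target indices on line j of block i.
    ``n_universe`` counts active targets plus decoys.
    """

    blocks: tuple[tuple[tuple[int, ...], ...], ...]
    n_universe: int

    def __post_init__(self) -> None:
        if not self.blocks or any(not b or any(not l for l in b) for b in self.blocks):
            raise ValueError("every block needs >= 1 line and every line >= 1 target")

    @property
    def L(self) -> int:
        return len(self.blocks)

    @property
    def active_targets(self) -> frozenset[int]:
        return frozenset(t for b in self.blocks for l in b for t in l)

    @property
    def n_active(self) -> int:
        return len(self.active_targets)

    def line_sizes(self) -> list[list[int]]:
        """b_j^i layout: targets per line, per block."""
        return [[len(l) for l in b] for b in self.blocks]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _partition(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Random composition of ``total`` into ``parts`` positive integers."""
    if parts > total:
        raise ValueError(f"cannot split {total} targets into {parts} non-empty parts")
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    edges = [0, *cuts.tolist(), total]
    return [b - a for a, b in zip(edges, edges[1:])]


def generate_pathway(
    n_active: int,
    seed: int | np.random.Generator | None = None,
    config: PathwayConfig = PathwayConfig(),
) -> PathwayStructure:
    """Draw a random block-structured pathway over ``n_active`` targets.

    The targets are partitioned into 1..max_blocks serial blocks, each
    block into 1..max_lines parallel lines; labels are a random subset of
    the universe (actives shuffled among decoys).  No target appears in
    two blocks.
    """
    if n_active < 1:
        raise ValueError("n_active must be >= 1")
    rng = _rng(seed)
    n_universe = n_active + config.n_decoy
    labels = rng.choice(n_universe, size=n_active, replace=False)
    L = int(rng.integers(1, min(config.max_blocks, n_active) + 1))
    block_sizes = _partition(n_active, L, rng)
    blocks = []
    cursor = 0
    for size in block_sizes:
        a = int(rng.integers(1, min(config.max_lines, size) + 1))
        lines = []
        for line_size in _partition(size, a, rng):
            lines.append(tuple(int(t) for t in labels[cursor : cursor + line_size]))
            cursor += line_size
        blocks.append(tuple(lines))
    return PathwayStructure(blocks=tuple(blocks), n_universe=n_universe)


def boolean_sensitivity(profile: Iterable[int] | np.ndarray, pathway: PathwayStructure) -> int:
    """Ground-truth 0/1 sensitivity of an inhibition profile.

    1 iff the inhibited targets include at least one target from every
    line of some block -- cutting all parallel paths of one serial stage
    kills the tumor; anything less leaves an open path.
    """
    profile = np.asarray(profile)
    if profile.ndim != 1 or len(profile) < pathway.n_universe:
        raise ValueError("profile must cover the pathway universe")
    hit = {int(j) for j in np.flatnonzero(profile)}
    for block in pathway.blocks:
        if all(any(t in hit for t in line) for line in block):
            return 1
    return 0


def true_minimal_terms(pathway: PathwayStructure) -> frozenset[frozenset[int]]:
    """Minimal effective combinations: one target per line of one block."""
    terms: set[frozenset[int]] = set()
    for block in pathway.blocks:
        for pick in itertools.product(*block):
            terms.add(frozenset(pick))
    return frozenset(
        t for t in terms if not any(s < t for s in terms)
    )


def generate_library(
    pathway: PathwayStructure,
    n_drugs: int = 1000,
    seed: int | np.random.Generator | None = None,
    config: PathwayConfig = PathwayConfig(),
) -> np.ndarray:
    """Random drug library: (n_drugs x n_universe) binary profile matrix.

    Each drug inhibits a Poisson(lambda)-many (minimum 1) distinct
    targets drawn uniformly from the whole universe.
    """
    rng = _rng(seed)
    n = pathway.n_universe
    counts = np.maximum(1, rng.poisson(config.poisson_lambda, size=n_drugs))
    counts = np.minimum(counts, n)
    lib = np.zeros((n_drugs, n), dtype=np.uint8)
    for i, k in enumerate(counts):
        lib[i, rng.choice(n, size=int(k), replace=False)] = 1
    return lib


def screen_from_library(
    library: np.ndarray,
    pathway: PathwayStructure,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    prefix: str = "D",
) -> list[BinarizedDrug]:
    """Attach ground-truth sensitivities (optionally noisy) to profiles.

    Scores are the Boolean pathway sensitivities plus, when
    ``noise_sigma`` > 0, Gaussian measurement noise clipped to [0, 1].
    """
    rng = _rng(seed)
    drugs = []
    for i, profile in enumerate(library):
        y = float(boolean_sensitivity(profile, pathway))
        if noise_sigma > 0:
            y = float(np.clip(y + rng.normal(0.0, noise_sigma), 0.0, 1.0))
        drugs.append(
            BinarizedDrug(
                drug_id=f"{prefix}{i:04d}",
                dtip=profile.astype(np.uint8),
                score=y,
                excluded=not profile.any(),
            )
        )
    return drugs


def run_benchmark(
    n_active_values: Sequence[int] = (6, 7, 8, 9, 10),
    reps: int = 40,
    n_train: int = 60,
    n_test: int = 40,
    library_size: int = 1000,
    seed: int | None = 0,
    config: PathwayConfig = PathwayConfig(),
    *,
    max_size: int = 20,
    discount: float = 1.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Train/test benchmark over replicate random pathways.

    For each replicate: draw a pathway, a drug library, and disjoint
    training/test panels; run selection + TIM on the training panel's
    Boolean sensitivities; threshold test predictions at ``threshold``.
    Returns one row per n_active with the mean number of correctly
    predicted test drugs, the accuracy percentage, and the accuracy of a
    coin-flip baseline on the same panels.
    """
    rng = _rng(seed)
    records = []
    for n_active in n_active_values:
        correct_counts = []
        baseline_counts = []
        for _ in range(reps):
            pathway = generate_pathway(n_active, rng, config)
            library = generate_library(pathway, library_size, rng, config)
            panel = rng.choice(library_size, size=n_train + n_test, replace=False)
            train = screen_from_library(library[panel[:n_train]], pathway, prefix="TR")
            test_profiles = library[panel[n_train:]]
            truth = np.array(
                [boolean_sensitivity(p, pathway) for p in test_profiles]
            )
            tset = sffs_select(train, max_size=max_size)
            tim = build_tim(train, tset, discount=discount)
            test = screen_from_library(test_profiles, pathway, prefix="TE")
            pred = np.array(
                [1 if tim.predict_drug(d) >= threshold else 0 for d in test]
            )
            correct_counts.append(int((pred == truth).sum()))
            baseline_counts.append(int(((rng.random(n_test) < 0.5) == truth).sum()))
        records.append(
            {
                "Targets": n_active,
                "Correct prediction": float(np.mean(correct_counts)),
                "Accuracy percentage": 100.0 * np.mean(correct_counts) / n_test,
                "Baseline percentage": 100.0 * np.mean(baseline_counts) / n_test,
            }
        )
    return pd.DataFrame.from_records(records)
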