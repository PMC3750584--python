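from __future__ import annotations

import numpy as np
import pytest

from timkit import BinarizedDrug


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_drugs(dtips, scores, prefix="d") -> list[BinarizedDrug]:
    """Binary-profile drugs straight from explicit bit rows and scores."""
    out = []
    for i, (bits, y) in enumerate(zip(dtips, scores)):
        arr = np.asarray(bits, dtype=np.uint8)
        out.append(
            BinarizedDrug(
                drug_id=f"{prefix}{i}", dtip=arr, score=float(y), excluded=not arr.any()
            )
        )
    return out


def random_screen(rng, n_drugs, n_targets, p_hit=0.35, discrete=False):
    """Seeded random binarized screen with scores in [0, 1]."""
    dtips = (rng.random((n_drugs, n_targets)) < p_hit).astype(np.uint8)
    # avoid all-zero rows so every drug is usable
    for row in dtips:
        if not row.any():
            row[rng.integers(n_targets)] = 1
    scores = (
        rng.integers(0, 2, n_drugs).astype(float)
        if discrete
        else np.round(rng.random(n_drugs), 3)
    )
    return make_drugs(dtips, scores)
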