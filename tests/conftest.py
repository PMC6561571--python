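"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rnaswitch.energy import EnsembleModel
from rnaswitch.ensemble import Constraints, enumerate_all_structures, structure_satisfies


@pytest.fixture(scope="session")
def model() -> EnsembleModel:
    return EnsembleModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def oracle_ensemble(seq: str, c: Constraints, m: EnsembleModel):
    """(Z, {pair: prob}, min energy) by exhaustive enumeration — the
    independent ground truth for every DP operation."""
    admissible = [
        (s, e)
        for s, e in enumerate_all_structures(seq, m)
        if structure_satisfies(s, c)
    ]
    if not admissible:
        return 0.0, {}, math.inf
    weights = [math.exp(-e / m.rt) for _, e in admissible]
    z = sum(weights)
    probs: dict = {}
    for (s, _), w in zip(admissible, weights):
        for p in s.pairs:
            probs[p] = probs.get(p, 0.0) + w / z
    return z, probs, min(e for _, e in admissible)
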