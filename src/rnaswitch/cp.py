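"""Conditional-probability prediction of the alternative structure.

The method, for a single sequence:

1. Predict the stable structure S1* as the unconstrained MFE structure at
   37 °C.
2. Build the excluded set E(τ): every index pair within
   base-pair-to-structure distance τ of S1* (E(0) is exactly the pair set
   of S1*). Membership is positional — it does not consult the sequence —
   since excluding an already-impossible pair is a no-op.
3. Compute base-pair probabilities conditional on the absence of every
   pair of E, at the configured temperature.
4. Select a seed: by default the longest bulge-tolerant stem whose every
   pair individually has conditional probability strictly above 0.5.
5. Predict the alternative structure S2* as the minimum-energy structure
   containing the seed. The exclusion set constrains only the probability
   computation, never this final fold, so S2* may incidentally re-use
   excluded pairs; but the seed itself always lies outside S1*, hence
   S2* ≠ S1* whenever the seed is non-empty.

Iterating the procedure (iteration i > 2) re-runs steps 2–5 with E taken
as the union of the τ-neighborhoods of all previously predicted
structures, yielding S3*, S4*, ….

The normalized seed length, ``#L* / log10(sequence length)``, serves as a
riboswitch classification score: switch-like sequences tend to retain a
long high-probability stem after the MFE neighborhood is excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

from .energy import EnsembleModel, normalize_sequence
from .ensemble import BasePairProbMatrix, Constraints, basepair_probabilities, constrained_mfe
from .structures import (
    MIN_HAIRPIN_UNPAIRED,
    BasePair,
    Structure,
    write_dotbracket,
)

__all__ = [
    "ExclusionSet",
    "Seed",
    "SeedKind",
    "CPConfig",
    "CPResult",
    "build_excluded_set",
    "select_seed",
    "predict_alternative",
    "normalized_seed_length",
]

SeedKind = Literal["stem", "single-bp", "all-above-threshold"]

#: Allowed steps between consecutive pairs of a bulge-tolerant stem:
#: perfect stack, single 5' bulge, single 3' bulge. 1×1 internal loops are
#: deliberately not steps — a stem tolerates single *bulges* only.
_STEM_STEPS = ((1, 1), (2, 1), (1, 2))


@dataclass(frozen=True)
class ExclusionSet:
    """The set E(τ) of index pairs within δbs ≤ τ of a reference structure."""

    tau: int
    pairs: frozenset[BasePair]

    def __contains__(self, pair) -> bool:
        return BasePair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Seed:
    """An ordered chain of base pairs around which the alternative
    structure is folded."""

    chain: tuple[BasePair, ...]
    kind: SeedKind

    def __len__(self) -> int:
        return len(self.chain)

    @property
    def pairs(self) -> frozenset[BasePair]:
        return frozenset(self.chain)

    @property
    def empty(self) -> bool:
        return not self.chain


def build_excluded_set(
    s_ref: Structure,
    tau: int,
    n: int | None = None,
    *,
    min_hairpin_unpaired: int = MIN_HAIRPIN_UNPAIRED,
) -> ExclusionSet:
    """All index pairs ``[i·j]`` (i < j, min-loop respected) whose
    base-pair-to-structure distance to ``s_ref`` is ≤ τ.

    E(0) is exactly the pair set of ``s_ref``; an empty reference yields an
    empty set for every τ (empty-minimum convention). τ-monotone:
    τ1 ≤ τ2 implies E(τ1) ⊆ E(τ2).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    n = s_ref.length if n is None else n
    if s_ref.length != n:
        raise ValueError(f"reference length {s_ref.length} != n {n}")
    out: set[BasePair] = set()
    for p in s_ref.pairs:
        for i in range(max(1, p.i - tau), min(n, p.i + tau) + 1):
            for j in range(max(i + 1, p.j - tau), min(n, p.j + tau) + 1):
                if j - i - 1 >= min_hairpin_unpaired:
                    out.add(BasePair(i, j))
    return ExclusionSet(tau, frozenset(out))


def _longest_stem(cands: dict[BasePair, float]) -> tuple[BasePair, ...]:
    """Longest bulge-tolerant chain among candidate pairs.

    Ties are broken by larger total probability along the chain, then by
    the smaller first pair, then by step preference (stack before bulges).
    """
    # chains run outside-in; a successor has strictly smaller span, so
    # processing candidates by increasing span makes the DP well-ordered
    order = sorted(cands, key=lambda p: (p.j - p.i, p.i))
    best: dict[BasePair, tuple[int, float, BasePair | None]] = {}
    for p in order:
        top = (1, cands[p], None)
        for di, dj in _STEM_STEPS:
            nxt = BasePair(p.i + di, p.j - dj)
            if nxt in best:
                length, prob, _ = best[nxt]
                cand = (length + 1, cands[p] + prob, nxt)
                if (cand[0], cand[1]) > (top[0], top[1]):
                    top = cand
        best[p] = top
    if not best:
        return ()
    start = max(best, key=lambda p: (best[p][0], best[p][1], (-p.i, -p.j)))
    chain = [start]
    while best[chain[-1]][2] is not None:
        chain.append(best[chain[-1]][2])
    return tuple(chain)


def select_seed(
    p: BasePairProbMatrix,
    kind: SeedKind = "stem",
    threshold: float = 0.5,
) -> Seed:
    """Select a seed from a (conditional) base-pair probability matrix.

    ``stem``: longest bulge-tolerant chain of pairs each with probability
    strictly above the threshold. ``single-bp``: the single highest-
    probability pair (if above threshold). ``all-above-threshold``: every
    pair above the threshold. An empty seed is a valid outcome.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    above = p.pairs_above(threshold)
    if kind == "stem":
        chain = _longest_stem(dict(above))
        return Seed(chain, kind)
    if kind == "single-bp":
        if not above:
            return Seed((), kind)
        bp, _ = max(above, key=lambda t: (t[1], (-t[0].i, -t[0].j)))
        return Seed((bp,), kind)
    if kind == "all-above-threshold":
        return Seed(tuple(bp for bp, _ in above), kind)
    raise ValueError(f"unknown seed kind {kind!r}")


@dataclass(frozen=True)
class CPConfig:
    """Adjustable parameters of the conditional-probability prediction."""

    tau: int = 5
    temperature: float = 37.0
    seed_kind: SeedKind = "stem"
    threshold: float = 0.5
    iteration: int = 2

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.iteration < 2:
            raise ValueError("iteration must be ≥ 2")


@dataclass(frozen=True)
class CPResult:
    """Outcome of one conditional-probability prediction run."""

    sequence: str
    s1: Structure
    s_alt: Structure | None
    seed: Seed
    exclusion: ExclusionSet
    cond_probs: BasePairProbMatrix
    energy_s1: float
    energy_alt: float | None
    normalized_seed_length: float
    iteration: int
    temperature: float
    empty_seed_reason: str | None = None
    intermediate: tuple[Structure, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "s1": write_dotbracket(self.s1),
            "s_alt": write_dotbracket(self.s_alt) if self.s_alt else None,
            "seed": [list(p) for p in self.seed.chain],
            "seed_kind": self.seed.kind,
            "seed_length": len(self.seed),
            "normalized_seed_length": self.normalized_seed_length,
            "tau": self.exclusion.tau,
            "excluded_count": len(self.exclusion),
            "energy_s1": self.energy_s1,
            "energy_alt": self.energy_alt,
            "iteration": self.iteration,
            "temperature": self.temperature,
            "empty_seed_reason": self.empty_seed_reason,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def normalized_seed_length(seed_len: int, seq_len: int) -> float:
    """Seed length in base pairs divided by log10 of sequence length."""
    if seq_len < 2:
        raise ValueError("sequence length must be ≥ 2")
    return seed_len / math.log10(seq_len)


def predict_alternative(
    seq: str, config: CPConfig = CPConfig(), m: EnsembleModel = EnsembleModel()
) -> CPResult:
    """Run the full conditional-probability pipeline on one sequence.

    The stable structure S1* is always predicted at 37 °C; the conditional
    probabilities (and hence the seed) use ``config.temperature``. An empty
    seed is reported, not raised.
    """
    seq = normalize_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    m37 = m.at_temperature(37.0)
    s1, e1 = constrained_mfe(seq, Constraints(), m37)
    predictions: list[Structure] = [s1]
    h = m.min_hairpin_unpaired

    seed = Seed((), config.seed_kind)
    cond = None
    exclusion = ExclusionSet(config.tau, frozenset())
    s_alt: Structure | None = None
    e_alt: float | None = None
    reason: str | None = None

    for _ in range(2, config.iteration + 1):
        union: set[BasePair] = set()
        for prev in predictions:
            union |= build_excluded_set(
                prev, config.tau, n, min_hairpin_unpaired=h
            ).pairs
        exclusion = ExclusionSet(config.tau, frozenset(union))
        cond = basepair_probabilities(
            seq,
            Constraints(excluded=exclusion.pairs),
            m.at_temperature(config.temperature),
        )
        seed = select_seed(cond, config.seed_kind, config.threshold)
        if seed.empty:
            s_alt, e_alt = None, None
            reason = (
                "no base pair exceeded the conditional-probability threshold "
                f"{config.threshold} outside the excluded neighborhood"
            )
            break
        s_alt, e_alt = constrained_mfe(seq, Constraints(forced=seed.pairs), m37)
        predictions.append(s_alt)
        reason = None

    if cond is None:  # iteration loop never ran (cannot happen: iteration ≥ 2)
        raise AssertionError("iteration < 2 slipped past config validation")

    return CPResult(
        sequence=seq,
        s1=s1,
        s_alt=s_alt,
        seed=seed,
        exclusion=exclusion,
        cond_probs=cond,
        energy_s1=e1,
        energy_alt=e_alt,
        normalized_seed_length=normalized_seed_length(len(seed), n),
        iteration=config.iteration,
        temperature=config.temperature,
        empty_seed_reason=reason,
        intermediate=tuple(predictions),
    )
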