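"""Boltzmann-ensemble dynamic programming over secondary structures.

The engine computes, for a single RNA sequence under the additive reference
energy model and an optional set of hard constraints (excluded base pairs
that must not occur; forced base pairs that must occur):

* the partition function ``Z = Σ_S exp(−E(S)/RT)`` over admissible
  structures (McCaskill-style inside recursion over closed intervals);
* exact base-pair probabilities ``P_ij`` — unconditional, or conditional on
  an excluded set E, i.e. the probability that ``[i·j]`` occurs in the
  ensemble restricted to structures containing no pair of E (inside–outside
  recursion);
* the constrained minimum-free-energy structure (same decomposition with
  min/+ instead of Σ/×, deterministic traceback);
* independent Boltzmann samples by stochastic traceback over the inside
  tables;
* an exhaustive enumeration oracle for short sequences, used as ground
  truth for every one of the above.

Because the energy model is strictly additive over pairs and stacks, the
interval decomposition is exact: ``Qb(i,j)``, the weight of structures on
``[i..j]`` closed by ``[i·j]``, satisfies

    Qb(i,j) = w_pair(i,j) · [ Q(i+1,j−1) + (w_stack − 1) · Qb(i+1,j−1) ]

(the correction term upgrades interior structures whose outermost pair is
``[i+1·j−1]`` to stacked weight), and

    Q(i,j) = Q(i,j−1) + Σ_k Q(i,k−1) · Qb(k,j).

Hard constraints enter as zeros: an excluded pair zeroes only its own
``Qb``; a forced pair ``[a·b]`` zeroes every decomposition in which *a* or
*b* is unpaired or paired otherwise. Tables are rescaled per nucleotide
when the ordinary double range would overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .energy import EnsembleModel, is_canonical, structure_energy
from .structures import BasePair, Structure, _as_pair, _crossing

__all__ = [
    "Constraints",
    "ConstraintError",
    "InfeasibleError",
    "BasePairProbMatrix",
    "PartitionResult",
    "partition_function",
    "basepair_probabilities",
    "constrained_mfe",
    "sample_structures",
    "enumerate_all_structures",
    "enumerate_admissible",
    "structure_satisfies",
    "MAX_ENUMERATION_LENGTH",
]

#: Hard guard on the exhaustive oracle, which scales exponentially.
MAX_ENUMERATION_LENGTH = 22

_TIE_EPS = 1e-9


class ConstraintError(ValueError):
    """Contradictory constraints (forced pair excluded / non-canonical /
    loop-violating, crossing forced pairs, ...)."""


class InfeasibleError(ValueError):
    """No structure satisfies the constraints."""


@dataclass(frozen=True)
class Constraints:
    """Hard constraints on the ensemble.

    ``excluded`` pairs must not occur in any admissible structure;
    ``forced`` pairs must occur in every admissible structure. Forced pairs
    must be mutually non-crossing and position-disjoint.
    """

    excluded: frozenset[BasePair] = field(default_factory=frozenset)
    forced: frozenset[BasePair] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(
            self, "excluded", frozenset(_as_pair(p) for p in self.excluded)
        )
        object.__setattr__(
            self, "forced", frozenset(_as_pair(p) for p in self.forced)
        )
        overlap = self.excluded & self.forced
        if overlap:
            raise ConstraintError(f"pairs both forced and excluded: {sorted(overlap)}")
        seen: set[int] = set()
        for p in self.forced:
            if p.i in seen or p.j in seen:
                raise ConstraintError(f"forced pairs share position {p}")
            seen.update(p)
        forced = sorted(self.forced)
        for a, b in zip(forced, forced[1:]):
            if _crossing(a, b):
                raise ConstraintError(f"forced pairs cross: {a}, {b}")

    @property
    def empty(self) -> bool:
        return not self.excluded and not self.forced


@dataclass(frozen=True)
class PartitionResult:
    """Partition function with its inside tables (opaque internals)."""

    log_z: float
    _ctx: "_FoldContext"

    @property
    def Z(self) -> float:
        try:
            return math.exp(self.log_z)
        except OverflowError:
            return math.inf


@dataclass
class BasePairProbMatrix:
    """Symmetric-upper-triangular matrix of base-pair probabilities.

    ``p`` is an ``(n+1, n+1)`` array addressed 1-based with ``i < j``;
    ``conditioning`` records the constraint set the probabilities were
    computed under (its ``excluded`` set is the E of a conditional matrix).
    """

    n: int
    p: np.ndarray
    conditioning: Constraints

    def __getitem__(self, key) -> float:
        i, j = key
        if i > j:
            i, j = j, i
        return float(self.p[i, j])

    def expected_pairs(self) -> float:
        return float(np.triu(self.p[1:, 1:]).sum())

    def row_sum(self, i: int) -> float:
        """Total pairing probability of base i (≤ 1)."""
        return float(self.p[i, i:].sum() + self.p[1:i, i].sum())

    def pairs_above(self, threshold: float) -> list[tuple[BasePair, float]]:
        """All pairs with probability strictly above ``threshold``,
        sorted by (i, j)."""
        out = []
        for i in range(1, self.n + 1):
            for j in range(i + 1, self.n + 1):
                v = float(self.p[i, j])
                if v > threshold:
                    out.append((BasePair(i, j), v))
        return out

    def write_tsv(self, path, *, min_prob: float = 0.0) -> None:
        """Write ``i\tj\tprob`` rows for all pairs above ``min_prob``."""
        with open(path, "w") as fh:
            fh.write("i\tj\tprob\n")
            for bp, v in self.pairs_above(min_prob):
                fh.write(f"{bp.i}\t{bp.j}\t{v:.10g}\n")

    def write_matrix(self, path) -> None:
        """Write the full n×n square matrix, tab-separated."""
        full = self.p[1:, 1:] + self.p[1:, 1:].T
        np.savetxt(path, full, fmt="%.10g", delimiter="\t")


class _FoldContext:
    """Precomputed tables shared by Z / probabilities / sampling for one
    (sequence, constraints, model) triple."""

    def __init__(self, seq: str, c: Constraints, m: EnsembleModel):
        self.seq = seq
        self.c = c
        self.m = m
        self.n = n = len(seq)
        h = m.min_hairpin_unpaired
        self.h = h
        rt = m.rt
        self.ws = math.exp(-m.stack_bonus / rt)

        self._validate_constraints()

        partner = np.zeros(n + 2, dtype=np.int64)
        for p in c.forced:
            partner[p.i] = p.j
            partner[p.j] = p.i
        self.partner = partner
        self.unpaired_ok = partner == 0

        allowed = np.zeros((n + 2, n + 2), dtype=bool)
        wpair = np.zeros((n + 2, n + 2))
        excluded = c.excluded
        for i in range(1, n + 1):
            for j in range(i + h + 1, n + 1):
                if not is_canonical(seq, i, j):
                    continue
                if BasePair(i, j) in excluded:
                    continue
                if partner[i] and partner[i] != j:
                    continue
                if partner[j] and partner[j] != i:
                    continue
                allowed[i, j] = True
                wpair[i, j] = math.exp(-m.energy_of_pair(seq, i, j) / rt)
        self.allowed = allowed
        self.wpair = wpair

        # Per-nucleotide rescaling guard: keep table entries within double
        # range for long, heavily pairing sequences. sigma cancels in every
        # probability; log Z is reconstructed exactly.
        if np.any(allowed):
            lw_max = math.log(wpair[allowed].max() * max(self.ws, 1.0))
        else:
            lw_max = 0.0
        est = 0.5 * n * max(lw_max, 0.0)
        self.log_sigma = (est - 150.0) / n if est > 300.0 else 0.0
        self.sigma = math.exp(self.log_sigma)

        self._inside()
        self._probs: BasePairProbMatrix | None = None
        self._mfe_tables = None

    # -- validation ---------------------------------------------------------

    def _validate_constraints(self):
        for p in self.c.forced:
            if p.j > self.n:
                raise ConstraintError(f"forced pair {p} exceeds length {self.n}")
            if not is_canonical(self.seq, p.i, p.j):
                raise ConstraintError(f"forced pair {p} is non-canonical")
            if p.j - p.i - 1 < self.m.min_hairpin_unpaired:
                raise ConstraintError(f"forced pair {p} violates the minimum loop")

    # -- inside recursion ---------------------------------------------------

    def _inside(self):
        n, h, sigma = self.n, self.h, self.sigma
        ws = self.ws
        Q = np.zeros((n + 2, n + 2))
        Qb = np.zeros((n + 2, n + 2))
        # empty intervals (j < i) have partition function 1 (scaled: sigma^0)
        for i in range(n + 2):
            Q[i, : min(i, n + 2)] = 1.0
        for span in range(1, n + 1):
            for i in range(1, n - span + 2):
                j = i + span - 1
                if span >= h + 2 and self.allowed[i, j]:
                    interior = Q[i + 1, j - 1] if span > 2 else 1.0
                    Qb[i, j] = (self.wpair[i, j] / sigma**2) * (
                        interior + (ws - 1.0) * Qb[i + 1, j - 1]
                    )
                acc = Q[i, j - 1] / sigma if self.unpaired_ok[j] else 0.0
                for k in range(i, j - h):
                    if Qb[k, j] > 0.0:
                        acc += Q[i, k - 1] * Qb[k, j]
                Q[i, j] = acc
        self.Q = Q
        self.Qb = Qb
        if Q[1, n] <= 0.0:
            raise InfeasibleError("no admissible structure under the constraints")
        self.log_z = math.log(Q[1, n]) + n * self.log_sigma

    # -- outside recursion → probabilities ----------------------------------

    def probabilities(self) -> BasePairProbMatrix:
        if self._probs is not None:
            return self._probs
        n, sigma, ws = self.n, self.sigma, self.ws
        Q, Qb = self.Q, self.Qb
        O = np.zeros((n + 2, n + 2))
        M = np.zeros((n + 2, n + 2))  # M[k,l] = (wpair/sigma^2) * O[k,l]
        P = np.zeros((n + 1, n + 1))
        zq = Q[1, n]
        for span in range(n, self.h + 1, -1):
            for i in range(1, n - span + 2):
                j = i + span - 1
                if not self.allowed[i, j]:
                    continue
                ext = Q[1, i - 1] * Q[j + 1, n]
                mid = 0.0
                if i > 1 and j < n:
                    # enclosing pair (k,l), k<i, l>j; loop decomposes into
                    # independent left/right segments around [i..j]
                    lv = Q[2 : i + 1, i - 1]          # Q[k+1, i-1], k=1..i-1
                    rv = Q[j + 1, j:n]                # Q[j+1, l-1], l=j+1..n
                    mid = float(lv @ M[1:i, j + 1 : n + 1] @ rv)
                    mid += (ws - 1.0) * M[i - 1, j + 1]
                O[i, j] = ext + mid
                M[i, j] = (self.wpair[i, j] / sigma**2) * O[i, j]
                P[i, j] = Qb[i, j] * O[i, j] / zq
        np.clip(P, 0.0, 1.0, out=P)
        self._probs = BasePairProbMatrix(n, P, self.c)
        return self._probs

    # -- MFE ----------------------------------------------------------------

    def _mfe(self):
        if self._mfe_tables is not None:
            return self._mfe_tables
        n, h = self.n, self.h
        inf = math.inf
        Mfull = np.full((n + 2, n + 2), 0.0)
        Mnp = np.full((n + 2, n + 2), 0.0)
        Mb = np.full((n + 2, n + 2), inf)
        with np.errstate(divide="ignore"):
            epair = np.where(self.wpair > 0, -self.m.rt * np.log(np.maximum(self.wpair, 1e-300)), inf)
        stack = self.m.stack_bonus
        for span in range(1, n + 1):
            for i in range(1, n - span + 2):
                j = i + span - 1
                if span >= h + 2 and self.allowed[i, j]:
                    interior_np = Mnp[i + 1, j - 1] if span > 2 else 0.0
                    best_in = interior_np
                    if Mb[i + 1, j - 1] < inf:
                        best_in = min(best_in, Mb[i + 1, j - 1] + stack)
                    Mb[i, j] = epair[i, j] + best_in
                best = Mfull[i, j - 1] if self.unpaired_ok[j] else inf
                best_np = best
                for k in range(i, j - h):
                    if Mb[k, j] < inf:
                        cand = Mfull[i, k - 1] + Mb[k, j]
                        best = min(best, cand)
                        if k > i:
                            best_np = min(best_np, cand)
                Mfull[i, j] = best
                Mnp[i, j] = best_np
        self._mfe_tables = (Mfull, Mnp, Mb)
        return self._mfe_tables

    def mfe_structure(self) -> tuple[Structure, float]:
        Mfull, Mnp, Mb = self._mfe()
        n, h = self.n, self.h
        if not math.isfinite(Mfull[1, n]):
            raise InfeasibleError("no admissible structure under the constraints")
        pairs: set[BasePair] = set()
        stack_iv: list[tuple[int, int, bool]] = [(1, n, False)]
        while stack_iv:
            i, j, forbid_ij = stack_iv.pop()
            if j <= i:
                continue
            target = Mnp[i, j] if forbid_ij else Mfull[i, j]
            # tie-break: prefer pairing (smallest k first), then leaving j
            # unpaired — deterministic output among equal-energy structures
            chosen = False
            for k in range(i, j - h):
                if forbid_ij and k == i:
                    continue
                if Mb[k, j] < math.inf and (
                    Mfull[i, k - 1] + Mb[k, j] <= target + _TIE_EPS
                ):
                    pairs.add(BasePair(k, j))
                    self._trace_pair(k, j, pairs, stack_iv, Mnp, Mb)
                    stack_iv.append((i, k - 1, False))
                    chosen = True
                    break
            if not chosen:
                stack_iv.append((i, j - 1, False))
        s = Structure(self.n, frozenset(pairs))
        return s, float(Mfull[1, n])

    def _trace_pair(self, i, j, pairs, stack_iv, Mnp, Mb):
        """Descend into the interior of chosen pair (i, j)."""
        target = Mb[i, j] - (-self.m.rt * math.log(self.wpair[i, j]))
        stack = self.m.stack_bonus
        if (
            Mb[i + 1, j - 1] < math.inf
            and Mb[i + 1, j - 1] + stack <= target + _TIE_EPS
        ):
            pairs.add(BasePair(i + 1, j - 1))
            self._trace_pair(i + 1, j - 1, pairs, stack_iv, Mnp, Mb)
        else:
            stack_iv.append((i + 1, j - 1, True))

    # -- stochastic traceback ------------------------------------------------

    def sample(self, rng: np.random.Generator) -> Structure:
        pairs: set[BasePair] = set()
        self._sample_interval(1, self.n, False, pairs, rng)
        return Structure(self.n, frozenset(pairs))

    def _sample_interval(self, i, j, forbid_ij, pairs, rng):
        Q, Qb, h, sigma = self.Q, self.Qb, self.h, self.sigma
        while j > i - 1:
            if j < i:
                return
            total = Q[i, j] - (Qb[i, j] if forbid_ij else 0.0)
            if total <= 0.0:
                return
            u = rng.random() * total
            w_unpaired = Q[i, j - 1] / sigma if self.unpaired_ok[j] else 0.0
            if u < w_unpaired:
                j -= 1
                forbid_ij = False
                continue
            u -= w_unpaired
            for k in range(i, j - h):
                if forbid_ij and k == i:
                    continue
                w = Q[i, k - 1] * Qb[k, j]
                if u < w:
                    pairs.add(BasePair(k, j))
                    self._sample_pair_interior(k, j, pairs, rng)
                    j = k - 1
                    forbid_ij = False
                    break
                u -= w
            else:  # numerical slack: fall back to the last viable branch
                for k in range(j - h - 1, i - 1, -1):
                    if (forbid_ij and k == i) or Qb[k, j] <= 0.0:
                        continue
                    pairs.add(BasePair(k, j))
                    self._sample_pair_interior(k, j, pairs, rng)
                    j = k - 1
                    forbid_ij = False
                    break
                else:
                    return

    def _sample_pair_interior(self, i, j, pairs, rng):
        """Interior of a chosen pair (i, j): stacked inner pair or not."""
        Q, Qb = self.Q, self.Qb
        ii, jj = i + 1, j - 1
        if jj - ii < self.h + 1:
            return
        w_stacked = self.ws * Qb[ii, jj]
        w_rest = max(Q[ii, jj] - Qb[ii, jj], 0.0)
        tot = w_stacked + w_rest
        if tot <= 0.0:
            return
        if rng.random() * tot < w_stacked:
            pairs.add(BasePair(ii, jj))
            self._sample_pair_interior(ii, jj, pairs, rng)
        else:
            self._sample_interval(ii, jj, True, pairs, rng)


# ---------------------------------------------------------------------------
# Public API


def partition_function(seq: str, c: Constraints, m: EnsembleModel) -> PartitionResult:
    """Partition function Z over all structures satisfying the constraints.

    Z equals the sum of Boltzmann weights of admissible structures; Z = 1
    exactly when the open chain is the only admissible structure.
    """
    ctx = _FoldContext(seq, c, m)
    return PartitionResult(ctx.log_z, ctx)


def basepair_probabilities(
    seq: str, c: Constraints, m: EnsembleModel
) -> BasePairProbMatrix:
    """Exact base-pair probabilities under the constraints.

    With empty constraints this is the unconditional ``P_ij``; with
    ``c.excluded = E`` it is the conditional probability that ``[i·j]``
    occurs given that no pair of E occurs.
    """
    return _FoldContext(seq, c, m).probabilities()


def constrained_mfe(
    seq: str, c: Constraints, m: EnsembleModel
) -> tuple[Structure, float]:
    """Minimum-free-energy structure among those satisfying the constraints.

    Ties are broken deterministically: the traceback prefers pairing over
    not pairing, then the 5'-most pairing partner.
    """
    return _FoldContext(seq, c, m).mfe_structure()


def sample_structures(
    seq: str, count: int, c: Constraints, m: EnsembleModel, seed
) -> list[Structure]:
    """Independent draws from the Boltzmann distribution restricted to
    admissible structures, by stochastic traceback. Reproducible given the
    seed (an int or a ``numpy.random.Generator``)."""
    if count < 1:
        raise ValueError("count must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctx = _FoldContext(seq, c, m)
    return [ctx.sample(rng) for _ in range(count)]


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle


def enumerate_all_structures(
    seq: str, m: EnsembleModel
) -> list[tuple[Structure, float]]:
    """Every valid secondary structure of ``seq`` exactly once, with its
    energy. Ground truth for the DP engine; refuses sequences longer than
    :data:`MAX_ENUMERATION_LENGTH`."""
    n = len(seq)
    if n > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"sequence of length {n} exceeds enumeration guard "
            f"({MAX_ENUMERATION_LENGTH})"
        )
    h = m.min_hairpin_unpaired
    memo: dict[tuple[int, int], list[frozenset[BasePair]]] = {}

    def gen(i: int, j: int) -> list[frozenset[BasePair]]:
        if j - i < h + 1:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(gen(i, j - 1))
        for k in range(i, j - h):
            if is_canonical(seq, k, j):
                for left in gen(i, k - 1):
                    for inner in gen(k + 1, j - 1):
                        out.append(left | inner | {BasePair(k, j)})
        memo[key] = out
        return out

    results = []
    for pairs in gen(1, n):
        s = Structure(n, pairs)
        results.append((s, structure_energy(seq, s, m)))
    return results


def structure_satisfies(s: Structure, c: Constraints) -> bool:
    """Whether a structure satisfies a constraint set (oracle-side check)."""
    return c.forced <= s.pairs and not (c.excluded & s.pairs)


def enumerate_admissible(
    seq: str, c: Constraints, m: EnsembleModel
) -> Iterator[tuple[Structure, float]]:
    """Enumerated structures filtered by the constraints."""
    for s, e in enumerate_all_structures(seq, m):
        if structure_satisfies(s, c):
            yield s, e
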