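"""Reference thermodynamic model: free energies, Boltzmann weights,
temperature handling, and an operational melting-temperature estimate.

The model is a deliberately simple additive one: each canonical base pair
(GC/CG, AU/UA, GU/UG) contributes a class energy, and each pair of directly
stacked adjacent pairs (``[i·j]`` with ``[i+1·j−1]``) contributes a stacking
bonus. Loop-size, dangle, and multiloop terms are omitted; the only steric
rule is the minimum hairpin size. This keeps the dynamic-programming engine
and the exhaustive-enumeration oracle additive and exactly consistent, while
preserving the qualitative GC > AU > GU stability ordering and stacking
cooperativity that alternative-structure prediction relies on. Any backend
mapping ``(sequence, structure, temperature) → kcal/mol`` with the same
additive decomposition can be plugged in through :class:`EnsembleModel`.

Temperature enters only through ``RT`` (no enthalpy/entropy split), so the
"melting temperature" here is an ensemble notion: the lowest temperature at
which the expected number of base pairs drops to half its 37 °C value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .structures import Structure

__all__ = [
    "CANONICAL_PAIRS",
    "GAS_CONSTANT_KCAL",
    "EnsembleModel",
    "NonCanonicalPairError",
    "pair_class",
    "is_canonical",
    "structure_energy",
    "boltzmann_weight",
    "estimate_melting_temperature",
    "load_params",
    "normalize_sequence",
]

#: Universal gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.98717e-3

#: Canonical (Watson-Crick + wobble) pair classes, keyed by unordered letters.
CANONICAL_PAIRS = {
    frozenset("GC"): "GC",
    frozenset("AU"): "AU",
    frozenset("GU"): "GU",
}


class NonCanonicalPairError(ValueError):
    """A structure pairs two bases that cannot form a canonical pair."""


def normalize_sequence(seq: str, *, warn: bool = True) -> str:
    """Uppercase a sequence and transliterate DNA T to U (with a warning)."""
    up = seq.upper()
    if "T" in up and warn:
        warnings.warn("DNA input: transliterating T to U", stacklevel=2)
    up = up.replace("T", "U")
    bad = set(up) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return up


def pair_class(a: str, b: str) -> str | None:
    """Canonical pair class of two bases, or None if they cannot pair."""
    return CANONICAL_PAIRS.get(frozenset((a, b)))


def is_canonical(seq: str, i: int, j: int) -> bool:
    """Whether 1-based positions i, j of seq can form a canonical pair."""
    return pair_class(seq[i - 1], seq[j - 1]) is not None


@dataclass(frozen=True)
class EnsembleModel:
    """Energy parameters plus the thermodynamic environment.

    Attributes
    ----------
    pair_energy:
        kcal/mol per canonical pair class; all ≤ 0.
    stack_bonus:
        kcal/mol per stacked adjacent pair ``([i·j], [i+1·j−1])``; ≤ 0.
    temperature:
        Folding temperature in °C, within [0, 100].
    gas_constant:
        kcal/(mol·K).
    min_hairpin_unpaired:
        Minimum unpaired bases enclosed by any pair.
    """

    pair_energy: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stack_bonus: float = -1.0
    temperature: float = 37.0
    gas_constant: float = GAS_CONSTANT_KCAL
    min_hairpin_unpaired: int = 3

    def __post_init__(self):
        if any(e > 0 for e in self.pair_energy.values()):
            raise ValueError("pair energies must be ≤ 0")
        if self.stack_bonus > 0:
            raise ValueError("stack bonus must be ≤ 0")
        if not 0.0 <= self.temperature <= 100.0:
            raise ValueError(f"temperature {self.temperature} outside [0, 100] °C")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")

    @property
    def rt(self) -> float:
        """``R·T`` in kcal/mol, with T in kelvin."""
        return self.gas_constant * (self.temperature + 273.15)

    def at_temperature(self, celsius: float) -> "EnsembleModel":
        return replace(self, temperature=celsius)

    def energy_of_pair(self, seq: str, i: int, j: int) -> float:
        cls = pair_class(seq[i - 1], seq[j - 1])
        if cls is None:
            raise NonCanonicalPairError(
                f"non-canonical pair [{i}·{j}] ({seq[i - 1]}-{seq[j - 1]})"
            )
        return self.pair_energy[cls]


def structure_energy(seq: str, s: Structure, m: EnsembleModel) -> float:
    """Free energy E(S) in kcal/mol: sum of pair-class energies plus the
    stacking bonus for every directly stacked adjacent pair."""
    if s.length != len(seq):
        raise ValueError(f"structure length {s.length} != sequence {len(seq)}")
    e = 0.0
    for p in s.pairs:
        e += m.energy_of_pair(seq, p.i, p.j)
        if (p.i + 1, p.j - 1) in s.pairs:
            e += m.stack_bonus
    return e


def boltzmann_weight(seq: str, s: Structure, m: EnsembleModel) -> float:
    """Boltzmann factor ``exp(−E(S)/RT)``; exactly 1 for the open chain."""
    return math.exp(-structure_energy(seq, s, m) / m.rt)


def estimate_melting_temperature(
    seq: str,
    m: EnsembleModel,
    *,
    t_start: float = 37.0,
    t_stop: float = 100.0,
    t_step: float = 1.0,
) -> float:
    """Operational melting temperature: the smallest T in a 1 °C scan over
    [37, 100] at which the ensemble's expected base-pair count falls to
    ≤ 50% of its value at ``t_start``. Returns ``t_stop`` if never reached,
    and ``t_start`` for sequences that cannot pair at all.
    """
    from .ensemble import Constraints, basepair_probabilities

    none = Constraints()

    def expected_pairs(t: float) -> float:
        return basepair_probabilities(seq, none, m.at_temperature(t)).expected_pairs()

    base = expected_pairs(t_start)
    if base <= 0.0:
        return t_start
    t = t_start
    while t <= t_stop + 1e-9:
        if expected_pairs(t) <= 0.5 * base:
            return t
        t += t_step
    return t_stop


def load_params(path) -> EnsembleModel:
    """Load model parameters from a flat ``key = value`` file.

    Recognized keys: ``GC``, ``AU``, ``GU`` (pair energies), ``stack_bonus``,
    ``temperature``, ``gas_constant``, ``min_hairpin_unpaired``.
    """
    kwargs: dict = {}
    pair_energy = dict(EnsembleModel().pair_energy)
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {raw!r}")
            key, val = (tok.strip() for tok in line.split("=", 1))
            if key in pair_energy:
                pair_energy[key] = float(val)
            elif key == "min_hairpin_unpaired":
                kwargs[key] = int(val)
            elif key in {"stack_bonus", "temperature", "gas_constant"}:
                kwargs[key] = float(val)
            else:
                raise ValueError(f"unknown parameter {key!r}")
    return EnsembleModel(pair_energy=pair_energy, **kwargs)
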