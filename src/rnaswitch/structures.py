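"""Secondary-structure data model and structure-space distances.

A secondary structure is a set of base pairs ``[i·j]`` (1-based, ``i < j``)
over a sequence of length *n*, subject to the usual constraints: each
position pairs at most once, pairs are non-crossing (no pseudoknots), and
every hairpin loop encloses at least :data:`MIN_HAIRPIN_UNPAIRED` unpaired
bases. Dot-bracket strings are the interchange format.

Two distances on this space drive alternative-structure prediction:

* the base-pair distance ``δbb([i·j], [i'·j']) = max(|i−i'|, |j−j'|)``, and
* the base-pair-to-structure distance ``δbs([i·j], S) = min over pairs of S``,

together with the base-pair Hamming distance between whole structures (the
size of the symmetric difference of their pair sets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "MIN_HAIRPIN_UNPAIRED",
    "BasePair",
    "Structure",
    "StructureError",
    "DotBracketError",
    "parse_dotbracket",
    "write_dotbracket",
    "hamming_distance",
    "basepair_distance",
    "basepair_to_structure_distance",
    "read_vienna",
    "write_vienna",
    "read_ct",
]

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN_UNPAIRED = 3


class StructureError(ValueError):
    """Raised for invalid structures (bounds, base triples, pseudoknots)."""


class DotBracketError(StructureError):
    """Raised for malformed dot-bracket strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class BasePair(NamedTuple):
    """A base pair between 1-based sequence positions ``i < j``."""

    i: int
    j: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.i}·{self.j}]"


def _as_pair(p) -> BasePair:
    bp = BasePair(*p)
    if not (0 < bp.i < bp.j):
        raise StructureError(f"invalid base pair {bp}: need 0 < i < j")
    return bp


def _crossing(p: BasePair, q: BasePair) -> bool:
    a, b = (p, q) if p.i <= q.i else (q, p)
    return a.i < b.i <= a.j < b.j


@dataclass(frozen=True)
class Structure:
    """An RNA secondary structure: a length and a set of base pairs.

    Parameters
    ----------
    length:
        Sequence length in nucleotides.
    pairs:
        Iterable of ``(i, j)`` index pairs, 1-based with ``i < j``.

    Raises
    ------
    StructureError
        If a pair is out of bounds, a position occurs in two pairs, or two
        pairs cross. Hairpin loops smaller than :data:`MIN_HAIRPIN_UNPAIRED`
        only trigger a warning, so experimentally determined reference
        structures still load.
    """

    length: int
    pairs: frozenset[BasePair] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.length < 0:
            raise StructureError(f"negative length {self.length}")
        pairs = frozenset(_as_pair(p) for p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for p in pairs:
            if p.j > self.length:
                raise StructureError(f"pair {p} exceeds length {self.length}")
            if p.i in seen or p.j in seen:
                raise StructureError(f"position reused by pair {p} (base triple)")
            seen.update(p)
        ordered = sorted(pairs)
        for a, b in zip(ordered, ordered[1:]):
            if _crossing(a, b):
                raise StructureError(f"crossing pairs {a} and {b} (pseudoknot)")
        for p in pairs:
            if p.j - p.i - 1 < MIN_HAIRPIN_UNPAIRED and not any(
                q.i > p.i and q.j < p.j for q in pairs
            ):
                warnings.warn(
                    f"hairpin loop of pair {p} has fewer than "
                    f"{MIN_HAIRPIN_UNPAIRED} unpaired bases",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return self.length

    def __contains__(self, pair) -> bool:
        return _as_pair(pair) in self.pairs

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def dotbracket(self) -> str:
        return write_dotbracket(self)


def parse_dotbracket(text: str) -> Structure:
    """Parse a dot-bracket string (``.`` unpaired, ``()`` paired) into a
    :class:`Structure`.

    Raises :class:`DotBracketError` on unbalanced brackets or foreign
    characters, naming the 1-based offending position.
    """
    stack: list[int] = []
    pairs: set[BasePair] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketError("unmatched ')'", pos)
            pairs.add(BasePair(stack.pop(), pos))
        elif ch != ".":
            raise DotBracketError(f"illegal character {ch!r}", pos)
    if stack:
        raise DotBracketError("unmatched '('", stack[0])
    return Structure(len(text), frozenset(pairs))


def write_dotbracket(s: Structure) -> str:
    """Render a :class:`Structure` as a dot-bracket string; exact inverse of
    :func:`parse_dotbracket` on valid structures."""
    chars = ["."] * s.length
    for p in s.pairs:
        chars[p.i - 1] = "("
        chars[p.j - 1] = ")"
    return "".join(chars)


def hamming_distance(a: Structure, b: Structure) -> int:
    """Base-pair Hamming distance: the number of base pairs present in
    exactly one of the two structures."""
    if a.length != b.length:
        raise StructureError(
            f"length mismatch: {a.length} vs {b.length}"
        )
    return len(a.pairs ^ b.pairs)


def basepair_distance(p, q) -> int:
    """Base-pair distance ``δbb = max(|i−i'|, |j−j'|)``; a metric on index
    pairs."""
    p, q = _as_pair(p), _as_pair(q)
    return max(abs(p.i - q.i), abs(p.j - q.j))


def basepair_to_structure_distance(p, s: Structure) -> float:
    """Base-pair-to-structure distance ``δbs(p, S) = min_{q∈S} δbb(p, q)``.

    Returns ``math.inf`` for an empty structure (the empty-minimum
    convention), so the exclusion neighborhood of a pair-free structure is
    empty for every threshold.
    """
    p = _as_pair(p)
    if not s.pairs:
        return math.inf
    return min(basepair_distance(p, q) for q in s.pairs)


# ---------------------------------------------------------------------------
# File formats: Vienna (">name / SEQUENCE / STRUCTURE") and 6-column CT.

def _drop_crossing(pairs: Iterable[BasePair]) -> frozenset[BasePair]:
    """Greedily drop crossing pairs, keeping the 5'-most of each clash."""
    kept: list[BasePair] = []
    for p in sorted(pairs):
        if any(_crossing(p, q) for q in kept):
            warnings.warn(f"dropping crossing pair {p} from reference structure")
            continue
        kept.append(p)
    return frozenset(kept)


def read_vienna(path) -> list[tuple[str, str, Structure]]:
    """Read a Vienna-style file of ``>name``, sequence, dot-bracket triples."""
    records = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    idx = 0
    while idx < len(lines):
        if not lines[idx].startswith(">"):
            raise ValueError(f"expected '>' header at line {idx + 1} of {path}")
        if idx + 2 >= len(lines):
            raise ValueError(f"truncated record {lines[idx]!r} in {path}")
        name = lines[idx][1:].strip()
        seq = lines[idx + 1].upper().replace("T", "U")
        struct = parse_dotbracket(lines[idx + 2])
        if struct.length != len(seq):
            raise ValueError(f"sequence/structure length mismatch for {name!r}")
        records.append((name, seq, struct))
        idx += 3
    return records


def write_vienna(path, records: Iterable[tuple[str, str, Structure]]) -> None:
    with open(path, "w") as fh:
        for name, seq, struct in records:
            fh.write(f">{name}\n{seq}\n{write_dotbracket(struct)}\n")


def read_ct(path) -> tuple[str, str, Structure]:
    """Read a standard 6-column CT file; returns (name, sequence, structure).

    Pseudoknotted reference pairs are dropped greedily (5'-most kept), with a
    warning, because the thermodynamic model is pseudoknot-free.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    name = " ".join(header[1:]) if len(header) > 1 else ""
    seq_chars: list[str] = []
    pairs: set[BasePair] = set()
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        idx, base, partner = int(cols[0]), cols[1], int(cols[4])
        seq_chars.append(base.upper().replace("T", "U"))
        if partner > idx:
            pairs.add(BasePair(idx, partner))
    return name, "".join(seq_chars), Structure(n, _drop_crossing(pairs))
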