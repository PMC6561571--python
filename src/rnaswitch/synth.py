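"""Synthetic sequences with known two-state or one-state ground truth.

A bistable design emulates the toggle at the heart of a riboswitch
(terminator/anti-terminator style): a central core segment *b* flanked by
two arms *a* and *c*, each the reverse complement of the core, separated
by unpairable adenosine linkers:

    sequence = a · l1 · b · l2 · c

Helix A pairs arm *a* with the core; helix B pairs the core with arm *c*.
The two helices share the core positions, so they are mutually exclusive —
exactly one can form at a time.

Composition is engineered so the designed helices are the *only* pairing
opportunities: the core is a guanosine run, the arms are cytosine runs,
and the linkers are adenosine runs. No segment can pair internally, the
arms cannot pair each other (pyrimidine with pyrimidine), and the linkers
are inert because the molecule contains no uridine at all. Although the
segments are homopolymeric, the *full* helix register is unique: the only
non-crossing antiparallel matching that uses every core G and every arm C
pairs them in order reversal, so each ground-truth helix is a single
well-defined structure and partial, shifted registers are strictly
weaker.

The bias mutation makes helix B strictly weaker by inserting one inert
adenosine *bulge* into arm *c*: helix B keeps all its Watson–Crick pairs
but loses exactly one stacking interaction (1 kcal/mol under the reference
model). The small gap keeps the alternative basin visible to Boltzmann
sampling while leaving helix A as the unique MFE state, and the designed
alternative helix is precisely a bulge-tolerant stem — the object the seed
search is defined on.

These designs are idealized: real riboswitches have multi-helix aptamers,
ligand-binding energetics, and far less clean-cut mutually exclusive
states. Passing tests on them demonstrates that the pipeline recovers a
designed alternative helix under the reference energy model, not that it
reproduces accuracy on biological data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnsembleModel, structure_energy
from .structures import BasePair, Structure, write_dotbracket

__all__ = [
    "BistableDesign",
    "generate_bistable",
    "generate_monostable",
    "design_energies",
    "write_fixture",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class BistableDesign:
    """A designed two-state sequence with its ground-truth helices."""

    sequence: str
    helix_a: frozenset[BasePair]
    helix_b: frozenset[BasePair]
    core_len: int
    linker_len: int
    biased: bool
    seed: int

    @property
    def structure_a(self) -> Structure:
        return Structure(len(self.sequence), self.helix_a)

    @property
    def structure_b(self) -> Structure:
        return Structure(len(self.sequence), self.helix_b)

    @property
    def stable_helix(self) -> frozenset[BasePair]:
        """The designed stable (lower-energy) helix: helix A when biased."""
        return self.helix_a

    @property
    def alternative_helix(self) -> frozenset[BasePair]:
        """The designed alternative (weaker) helix: helix B when biased."""
        return self.helix_b


def generate_bistable(
    core_len: int = 6,
    linker_len: int = 6,
    bias: bool = True,
    seed: int = 0,
    *,
    core: str | None = None,
) -> BistableDesign:
    """Generate a bistable sequence ``a·l1·b·l2·c`` with two mutually
    exclusive ground-truth helices.

    The default linker length (6) keeps the alternative helix outside the
    default τ = 5 exclusion neighborhood of the stable helix: every pair
    of helix B is at base-pair-to-structure distance ≥ linker_len + 1 from
    helix A. With ``bias`` (the default), one adenosine bulge is inserted
    into arm *c*, costing helix B one stacking interaction, so helix A is
    strictly more stable and helix B is the designed alternative state.
    An explicit ``core`` overrides the seeded G/C core (bias then inserts
    the bulge mid-arm).
    """
    if core_len < 4:
        raise ValueError("core_len must be ≥ 4")
    if linker_len < 3:
        raise ValueError("linker_len must be ≥ 3")
    rng = np.random.default_rng(seed)
    m, ell = core_len, linker_len
    if core is None:
        b = "G" * m
    else:
        if len(core) != core_len:
            raise ValueError("explicit core must match core_len")
        b = core
    t = int(rng.integers(1, m))  # seeded interior bulge position
    arm = _revcomp(b)

    helix_a = frozenset(BasePair(i, 2 * m + ell + 1 - i) for i in range(1, m + 1))

    c_start = 2 * (m + ell)  # 0-based offset of arm c
    if bias:
        c_arm = arm[:t] + "A" + arm[t:]
        # original arm-local k maps to k (k ≤ t) or k+1 (k > t) after insert
        helix_b = frozenset(
            BasePair(2 * m + ell + 1 - k, c_start + (k if k <= t else k + 1))
            for k in range(1, m + 1)
        )
    else:
        c_arm = arm
        helix_b = frozenset(
            BasePair(2 * m + ell + 1 - k, c_start + k) for k in range(1, m + 1)
        )

    seq = arm + "A" * ell + b + "A" * ell + c_arm
    return BistableDesign(
        sequence=seq,
        helix_a=helix_a,
        helix_b=helix_b,
        core_len=core_len,
        linker_len=linker_len,
        biased=bias,
        seed=seed,
    )


def generate_monostable(
    stem_len: int = 6, loop_len: int = 4, seed: int = 0
) -> tuple[str, Structure]:
    """A single strong hairpin with no designed alternative helix: the
    negative class for riboswitch classification tests. Same composition
    rules as the bistable designs (G/C stem, inert A loop)."""
    if stem_len < 3:
        raise ValueError("stem_len must be ≥ 3")
    if loop_len < 3:
        raise ValueError("loop_len must be ≥ 3")
    core = "G" * stem_len
    seq = core + "A" * loop_len + _revcomp(core)
    n = 2 * stem_len + loop_len
    hairpin = Structure(
        n, frozenset(BasePair(i, n + 1 - i) for i in range(1, stem_len + 1))
    )
    return seq, hairpin


def design_energies(design: BistableDesign, m: EnsembleModel) -> tuple[float, float]:
    """Energies of the two pure-helix structures (helix A, helix B)."""
    return (
        structure_energy(design.sequence, design.structure_a, m),
        structure_energy(design.sequence, design.structure_b, m),
    )


def write_fixture(path_fasta, path_vienna, designs: list[BistableDesign]) -> None:
    """Emit FASTA plus ground-truth dot-bracket files for a design cohort."""
    with open(path_fasta, "w") as fa, open(path_vienna, "w") as vn:
        for k, d in enumerate(designs):
            name = f"bistable_{k}_seed{d.seed}"
            fa.write(f">{name}\n{d.sequence}\n")
            vn.write(f">{name}|stable\n{d.sequence}\n")
            vn.write(write_dotbracket(d.structure_a) + "\n")
            vn.write(f">{name}|alternative\n{d.sequence}\n")
            vn.write(write_dotbracket(d.structure_b) + "\n")
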