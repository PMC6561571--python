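"""The DP engine against the exhaustive-enumeration oracle."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

from rnaswitch.ensemble import (
    MAX_ENUMERATION_LENGTH,
    BasePair,
    ConstraintError,
    Constraints,
    basepair_probabilities,
    constrained_mfe,
    enumerate_all_structures,
    partition_function,
    sample_structures,
    structure_satisfies,
)
from rnaswitch.structures import write_dotbracket

from .conftest import oracle_ensemble, random_sequence


def random_excluded(rng, n, k=3):
    cand = [BasePair(i, j) for i in range(1, n + 1) for j in range(i + 5, n + 1)]
    if not cand:
        return frozenset()
    idx = rng.choice(len(cand), size=min(k, len(cand)), replace=False)
    return frozenset(cand[int(t)] for t in idx)


def random_forced(rng, seq, m):
    """A feasible forced set: pairs taken from a random enumerated structure."""
    structs = [s for s, _ in enumerate_all_structures(seq, m) if s.pairs]
    if not structs:
        return frozenset()
    s = structs[int(rng.integers(len(structs)))]
    return frozenset(list(s.pairs)[:2])


class TestClosedFormExamples:
    def test_unpairable_sequence_has_unit_partition_function(self, model):
        assert partition_function("AAAAAA", Constraints(), model).Z == 1.0

    def test_two_state_hairpin_closed_form(self, model):
        w = math.exp(3.0 / model.rt)
        z = partition_function("GAAAC", Constraints(), model).Z
        assert z == pytest.approx(1 + w, rel=1e-12)
        p = basepair_probabilities("GAAAC", Constraints(), model)
        assert p[1, 5] == pytest.approx(w / (1 + w), rel=1e-12)

    def test_excluding_the_only_pair_leaves_open_chain(self, model):
        c = Constraints(excluded={(1, 5)})
        assert partition_function("GAAAC", c, model).Z == 1.0
        p = basepair_probabilities("GAAAC", c, model)
        assert p[1, 5] == 0.0

    def test_forced_pair_has_probability_one(self, model):
        p = basepair_probabilities("GAAAC", Constraints(forced={(1, 5)}), model)
        assert p[1, 5] == pytest.approx(1.0, abs=1e-12)


class TestOracleEquivalence:
    """The DP engine must reproduce exhaustive enumeration exactly, for
    unconstrained, excluded-pair, and forced-pair ensembles."""

    @pytest.mark.parametrize("trial", range(25))
    def test_z_probabilities_and_mfe_match_enumeration(self, trial, model):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 19))
        seq = random_sequence(rng, n)
        constraint_sets = [
            Constraints(),
            Constraints(excluded=random_excluded(rng, n)),
            Constraints(forced=random_forced(rng, seq, model)),
        ]
        for c in constraint_sets:
            z_o, probs_o, e_o = oracle_ensemble(seq, c, model)
            assert partition_function(seq, c, model).Z == pytest.approx(
                z_o, rel=1e-9
            )
            pm = basepair_probabilities(seq, c, model)
            for i in range(1, n + 1):
                for j in range(i + 1, n + 1):
                    assert pm[i, j] == pytest.approx(
                        probs_o.get(BasePair(i, j), 0.0), abs=1e-9
                    )
            s_mfe, e_mfe = constrained_mfe(seq, c, model)
            assert e_mfe == pytest.approx(e_o, abs=1e-9)
            assert structure_satisfies(s_mfe, c)

    def test_single_occupancy_row_sums(self, model):
        rng = np.random.default_rng(77)
        for _ in range(10):
            seq = random_sequence(rng, 16)
            pm = basepair_probabilities(seq, Constraints(), model)
            for i in range(1, 17):
                assert pm.row_sum(i) <= 1.0 + 1e-9


class TestConstraints:
    def test_forced_and_excluded_overlap_rejected(self):
        with pytest.raises(ConstraintError):
            Constraints(excluded={(1, 8)}, forced={(1, 8)})

    def test_crossing_forced_pairs_rejected(self):
        with pytest.raises(ConstraintError):
            Constraints(forced={(1, 8), (4, 12)})

    def test_position_sharing_forced_pairs_rejected(self):
        with pytest.raises(ConstraintError):
            Constraints(forced={(1, 8), (8, 12)})

    def test_non_canonical_forced_pair_rejected(self, model):
        with pytest.raises(ConstraintError, match="non-canonical"):
            partition_function("AAAAC", Constraints(forced={(1, 5)}), model)

    def test_loop_violating_forced_pair_rejected(self, model):
        with pytest.raises(ConstraintError, match="loop"):
            partition_function("GAAC", Constraints(forced={(1, 4)}), model)


class TestConstrainedMFE:
    def test_empty_sequence_of_as_gives_open_chain(self, model):
        s, e = constrained_mfe("AAAA", Constraints(), model)
        assert s.pairs == frozenset() and e == 0.0

    def test_forced_inclusion(self, model):
        s, e = constrained_mfe("GAAAC", Constraints(forced={(1, 5)}), model)
        assert write_dotbracket(s) == "(...)"
        assert e == -3.0

    def test_deterministic_tiebreak(self, model):
        seq = "GGAAAACCAAAAGGAAAACC"
        results = {write_dotbracket(constrained_mfe(seq, Constraints(), model)[0]) for _ in range(5)}
        assert len(results) == 1


class TestSampling:
    def test_unpairable_sequence_samples_open_chain(self, model):
        for s in sample_structures("AAAAAA", 20, Constraints(), model, 1):
            assert s.pairs == frozenset()

    def test_two_state_frequency_within_binomial_error(self, model):
        w = math.exp(3.0 / model.rt)
        p = w / (1 + w)
        draws = sample_structures("GAAAC", 10_000, Constraints(), model, 5)
        freq = sum(1 for s in draws if (1, 5) in s.pairs) / 10_000
        sd = math.sqrt(p * (1 - p) / 10_000)
        assert abs(freq - p) <= 3 * sd

    def test_equal_seeds_give_identical_samples(self, model):
        a = sample_structures("GGGCAAAAGCCC", 100, Constraints(), model, 11)
        b = sample_structures("GGGCAAAAGCCC", 100, Constraints(), model, 11)
        assert a == b

    def test_sampled_frequencies_match_oracle_distribution(self, model):
        """Chi-square goodness of fit of 10,000 seeded samples against the
        enumerated Boltzmann distribution, alpha = 0.001."""
        seq = "GGGCAAAAGCCC"
        z, _, _ = oracle_ensemble(seq, Constraints(), model)
        structs = enumerate_all_structures(seq, model)
        probs = {
            write_dotbracket(s): math.exp(-e / model.rt) / z for s, e in structs
        }
        counts = Counter(
            write_dotbracket(s)
            for s in sample_structures(seq, 10_000, Constraints(), model, 123)
        )
        keys = list(probs)
        expected = np.array([probs[k] * 10_000 for k in keys])
        observed = np.array([counts.get(k, 0) for k in keys], dtype=float)
        big = expected >= 5  # pool sparse bins for chi-square validity
        observed = np.append(observed[big], observed[~big].sum())
        expected = np.append(expected[big], expected[~big].sum())
        _, p_value = chisquare(observed, expected)
        assert p_value > 0.001

    def test_sampling_respects_constraints(self, model):
        c = Constraints(excluded={(1, 12)}, forced={(2, 11)})
        for s in sample_structures("GGGCAAAAGCCC", 200, c, model, 3):
            assert structure_satisfies(s, c)


class TestEnumeration:
    def test_counts_for_tiny_sequences(self, model):
        assert len(enumerate_all_structures("GAAAC", model)) == 2
        assert len(enumerate_all_structures("AAAA", model)) == 1

    def test_length_guard(self, model):
        with pytest.raises(ValueError, match="guard"):
            enumerate_all_structures("A" * (MAX_ENUMERATION_LENGTH + 1), model)

    def test_enumeration_sums_to_partition_function(self, model):
        rng = np.random.default_rng(5)
        for _ in range(5):
            seq = random_sequence(rng, 14)
            z = sum(
                math.exp(-e / model.rt)
                for _, e in enumerate_all_structures(seq, model)
            )
            assert partition_function(seq, Constraints(), model).Z == pytest.approx(
                z, rel=1e-9
            )

    def test_structures_are_unique(self, model):
        structs = [s for s, _ in enumerate_all_structures("GGCAAAAGCC", model)]
        assert len(structs) == len({s.pairs for s in structs})


class TestNumericalStability:
    def test_long_gc_rich_sequence_stays_finite(self, model):
        """A strongly pairing 100-mer overflows unscaled doubles; the
        rescaled tables must still give finite log Z and probabilities in
        [0, 1] with row sums ≤ 1."""
        seq = "GC" * 24 + "AAAA" + "GC" * 24
        pr = partition_function(seq, Constraints(), model)
        assert math.isfinite(pr.log_z) and pr.log_z > 0
        pm = basepair_probabilities(seq, Constraints(), model)
        assert np.all(pm.p >= 0.0) and np.all(pm.p <= 1.0)
        for i in range(1, len(seq) + 1):
            assert pm.row_sum(i) <= 1.0 + 1e-9

    def test_z_at_least_one_without_forced_pairs(self, model):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_sequence(rng, 12)
            c = Constraints(excluded=random_excluded(rng, 12))
            assert partition_function(seq, c, model).Z >= 1.0
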