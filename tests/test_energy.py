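"""Thermodynamics backend vs the exhaustive enumeration oracle."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from openrds.energy import (
    NearestNeighborBackend,
    ViennaRNABackend,
    Window,
    duplex_energy_nn,
)
from openrds.enumeration import (
    ensemble_free_energy_oracle,
    enumerate_structures,
    opening_energy_oracle,
    structure_energy,
)
from openrds.errors import LengthError, WindowError
from openrds.nnparams import DUPLEX_INIT, MIN_HAIRPIN, STACK, pair_type
from openrds.sequence import reverse_complement

rna_strings = st.text(alphabet="ACGU", min_size=1, max_size=20)


def _independent_structure_count(rna: str) -> int:
    """Nussinov-style recursive enumeration, written independently of the
    package's interval recursion: assign each position left-to-right as
    unpaired or paired with a compatible later partner, then filter."""
    n = len(rna)
    results = []

    def rec(pos, open_stack, pairs):
        if pos == n:
            if not open_stack:
                results.append(tuple(pairs))
            return
        # option 1: unpaired
        rec(pos + 1, open_stack, pairs)
        # option 2: close with the innermost open partner
        if open_stack and pos - open_stack[-1] - 1 >= MIN_HAIRPIN:
            i = open_stack[-1]
            if pair_type(rna[i], rna[pos]) >= 0:
                rec(pos + 1, open_stack[:-1], pairs + [(i, pos)])
        # option 3: open a new pair
        rec(pos + 1, open_stack + [pos], pairs)

    rec(0, [], [])
    def ok(st_):
        ps = set(st_)
        return all((i + 1, j - 1) in ps or (i - 1, j + 1) in ps for i, j in ps)
    return len({s for s in results if ok(s)})


class TestEnumeration:
    def test_polya_has_only_open_chain(self):
        assert enumerate_structures("AAAA") == [()]

    def test_open_chain_energy_zero(self):
        assert structure_energy("GGGAAAACCC", ()) == 0.0

    @pytest.mark.parametrize("rna", ["GGGAAAACCC", "GCGCAAAGCGC", "AUGGCUAAUAA"])
    def test_count_matches_independent_enumeration(self, rna):
        assert len(enumerate_structures(rna)) == _independent_structure_count(rna)

    def test_oracle_opening_energy_of_polya_is_zero(self):
        assert opening_energy_oracle("A" * 15, (3, 5)) == pytest.approx(0.0)

    def test_length_guard(self):
        with pytest.raises(LengthError):
            enumerate_structures("A" * 26)


class TestBackendOracleEquivalence:
    def test_random_sequences_match_oracle(self, backend):
        rng = random.Random(42)
        for _ in range(40):
            n = rng.randint(5, 20)
            s = "".join(rng.choice("ACGU") for _ in range(n))
            assert backend.ensemble_free_energy(s) == pytest.approx(
                ensemble_free_energy_oracle(s), abs=1e-6
            )
            start = rng.randint(0, n - 1)
            length = rng.randint(1, n - start)
            w = Window(start, length)
            assert backend.opening_energy(s, w) == pytest.approx(
                opening_energy_oracle(s, (start, length)), abs=1e-6
            )

    def test_designed_hairpin_with_constraint_matches_oracle(self, backend):
        s = "GGGGGAAAACCCCCAAAAAA"  # 14-nt hairpin + 6-nt tail
        w = Window(0, 5)  # constrain the 5' stem arm
        assert backend.ensemble_free_energy(s, w) == pytest.approx(
            ensemble_free_energy_oracle(s, unpaired=list(range(5))), abs=1e-6
        )
        assert backend.opening_energy(s, w) > 1.0

    def test_polya_ensemble_energy_zero(self, backend):
        assert backend.ensemble_free_energy("A" * 40) == 0.0


class TestBackendProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(rna_strings, st.integers(0, 19), st.integers(1, 6))
    def test_opening_energy_nonnegative(self, rna, start, length):
        backend = NearestNeighborBackend()
        if start + length > len(rna):
            return
        assert backend.opening_energy(rna, Window(start, length)) >= 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(rna_strings, st.integers(0, 19), st.integers(1, 6))
    def test_constraint_never_decreases_free_energy(self, rna, start, length):
        backend = NearestNeighborBackend()
        if start + length > len(rna):
            return
        w = Window(start, length)
        assert (
            backend.ensemble_free_energy(rna, w)
            >= backend.ensemble_free_energy(rna) - 1e-12
        )

    def test_determinism_bit_identical(self, backend):
        s = "GGCGCAAAGCGCCAUAGCA"
        fresh = NearestNeighborBackend()
        assert backend.ensemble_free_energy(s) == fresh.ensemble_free_energy(s)
        w = Window(2, 6)
        assert backend.opening_energy(s, w) == fresh.opening_energy(s, w)

    def test_stem_ladder_monotone(self, backend):
        """Lengthening a stem complementary to the window never decreases
        the cost of opening the window."""
        arm = "GCGGCUGC"
        previous = -1.0
        for s in range(2, 7):
            a = arm[:s]
            seq = a + "AAAA" + reverse_complement(a) + "AAAAAA"
            value = backend.opening_energy(seq, Window(0, s))
            assert value >= previous - 1e-12
            previous = value

    def test_window_out_of_bounds(self, backend):
        with pytest.raises(WindowError):
            backend.opening_energy("ACGUACGU", Window(5, 10))

    def test_overlong_sequence_rejected(self, backend):
        with pytest.raises(LengthError):
            backend.ensemble_free_energy("A" * 300)


def _best_ungapped_register(a: str, b: str):
    """Independent duplex oracle: contiguous-helix alignments only."""
    best = None
    br = b[::-1]
    for off in range(-(len(br) - 1), len(a)):
        for start in range(max(0, off), min(len(a), off + len(br))):
            run = []
            k = start
            while k < len(a) and 0 <= k - off < len(br):
                if pair_type(a[k], br[k - off]) < 0:
                    break
                run.append(k)
                k += 1
                e = DUPLEX_INIT
                for x, y in zip(run, run[1:]):
                    e += STACK[
                        pair_type(a[x], br[x - off]), pair_type(a[y], br[y - off])
                    ]
                if best is None or e < best:
                    best = e
    return best


class TestDuplex:
    def test_no_canonical_pair_gives_sentinel(self):
        assert duplex_energy_nn("AAAA", "AAAA") is None
        assert duplex_energy_nn("CCCC", "CCCC") is None

    def test_complementary_runs_are_stable(self):
        e = duplex_energy_nn("GGGGG", "CCCCC")
        assert e is not None and e < 0
        assert e == pytest.approx(_best_ungapped_register("GGGGG", "CCCCC"), abs=1e-9)

    def test_dp_at_least_as_good_as_any_register(self):
        rng = random.Random(5)
        for _ in range(25):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(3, 12)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(3, 12)))
            dp = duplex_energy_nn(a, b)
            reg = _best_ungapped_register(a, b)
            if reg is None:
                assert dp is None
            else:
                assert dp is not None and dp <= reg + 1e-9

    def test_sd_anti_sd_binds(self):
        e = duplex_energy_nn("AGGAGG", "ACCUCCUUA")
        assert e is not None and e < 0
        assert e <= _best_ungapped_register("AGGAGG", "ACCUCCUUA") + 1e-9

    def test_length_guard(self):
        with pytest.raises(LengthError):
            duplex_energy_nn("A" * 61, "CCC")


class TestViennaCrossCheck:
    """Loose qualitative agreement with the full Turner model."""

    def test_ladder_monotone_under_reference_engine(self):
        be = ViennaRNABackend()
        arm = "GCGGCUGC"
        values = []
        for s in (2, 4, 6):
            a = arm[:s]
            seq = a + "AAAA" + reverse_complement(a) + "AAAAAA"
            values.append(be.opening_energy(seq, Window(0, s)))
        assert values[0] < values[1] < values[2]

    def test_duplex_sign_agreement(self):
        be = ViennaRNABackend()
        e = be.duplex_energy("GGGGG", "CCCCC")
        assert e is not None and e < 0
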