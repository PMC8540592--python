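"""The delta model: closed forms, profiles, ranking."""

import math

import numpy as np
import pytest

from openrds.errors import EmptyInputError, UnsupportedStartCodonError, WindowError
from openrds.fixtures import hairpin_construct, stem_ladder, unstructured_construct
from openrds.score import (
    OpeningProfile,
    ScoreParameters,
    delta_from_energies,
    delta_score,
    locate_minimum,
    open_energy_profile,
    rank_constructs,
)
from openrds.sequence import CodingSequence, Construct


class TestDeltaClosedForm:
    def test_zero_energy_gives_one(self, params):
        assert delta_from_energies(0.0, params) == 1.0

    def test_minus_rt_gives_e(self, params):
        assert delta_from_energies(-params.rt, params) == pytest.approx(math.e)

    def test_plus_rt_gives_inverse_e(self, params):
        assert delta_from_energies(params.rt, params) == pytest.approx(1 / math.e)

    def test_strictly_decreasing_in_each_component(self, params):
        grid = np.linspace(-2.0, 2.0, 10)
        for de_sd in grid:
            for de_trna in grid:
                values = [
                    delta_from_energies(de_sd + de_trna + de_open, params)
                    for de_open in grid
                ]
                assert all(a > b for a, b in zip(values, values[1:]))

    def test_positive_everywhere(self, params):
        for e in np.linspace(-10, 10, 25):
            assert delta_from_energies(e, params) > 0


class TestDeltaScore:
    def test_aug_start_uses_minus_1_19(self, backend, params):
        score = delta_score(unstructured_construct(), params, backend)
        assert score.dE_tRNA == -1.19

    def test_gug_start_uses_minus_0_075(self, backend, params):
        c = unstructured_construct()
        gug = Construct(
            "gug", c.utr5, CodingSequence("GUG" + c.cds.rna[3:]), c.sd_sequence, c.sd_offset
        )
        assert delta_score(gug, params, backend).dE_tRNA == -0.075

    def test_delta_consistent_with_components(self, backend, params):
        s = delta_score(hairpin_construct(), params, backend)
        expected = math.exp(-(s.dE_SD + s.dE_tRNA + s.dE_open) / params.rt)
        assert s.delta == pytest.approx(expected, rel=1e-12)
        assert s.delta > 0

    def test_unknown_start_codon_rejected(self, backend):
        p = ScoreParameters(dE_tRNA_table={"AUG": -1.19})
        c = unstructured_construct()
        gug = Construct(
            "gug", c.utr5, CodingSequence("GUG" + c.cds.rna[3:]), c.sd_sequence, c.sd_offset
        )
        with pytest.raises(UnsupportedStartCodonError):
            delta_score(gug, p, backend)


class TestProfiles:
    def test_unstructured_profile_identically_zero(self, backend, params):
        prof = open_energy_profile(unstructured_construct(), p=params, backend=backend)
        assert prof.offsets == tuple(range(-13, -4))
        assert all(v == 0.0 for v in prof.values)

    def test_hairpin_profile_peaks_at_engineered_offset(self, backend, params):
        prof = open_energy_profile(hairpin_construct(), p=params, backend=backend)
        peak = prof.offsets[prof.values.index(max(prof.values))]
        assert peak == -11

    def test_window_error_names_offset(self, backend, params):
        c = unstructured_construct()
        with pytest.raises(WindowError, match="i=-21"):
            open_energy_profile(c, -21, -5, params, backend)

    def test_full_transcript_context_used(self, backend, params):
        """Padding the UTR upstream of every scanned window with inert
        nucleotides leaves the profile unchanged."""
        c = hairpin_construct()
        padded = Construct(
            c.name + "-padded", "A" * 30 + c.utr5, c.cds, c.sd_sequence, c.sd_offset
        )
        a = open_energy_profile(c, p=params, backend=backend)
        b = open_energy_profile(padded, p=params, backend=backend)
        assert a.values == pytest.approx(b.values, abs=1e-9)


class TestLocateMinimum:
    def test_flat_profile_breaks_tie_at_canonical(self, params):
        prof = OpeningProfile("flat", tuple(range(-13, -4)), (1.0,) * 9)
        assert locate_minimum(prof, params) == (-11, 1.0)

    def test_simple_minimum(self, params):
        prof = OpeningProfile("p", (-12, -11, -10), (5.0, 1.0, 4.0))
        assert locate_minimum(prof, params) == (-11, 1.0)

    def test_single_point(self, params):
        prof = OpeningProfile("p", (-7,), (2.5,))
        assert locate_minimum(prof, params) == (-7, 2.5)

    def test_tie_away_from_canonical_prefers_upstream(self, params):
        prof = OpeningProfile("p", (-13, -9), (1.0, 1.0))
        assert locate_minimum(prof, params)[0] == -13

    def test_empty_profile_rejected(self, params):
        with pytest.raises(EmptyInputError):
            locate_minimum(OpeningProfile("e", (), ()), params)


class TestRanking:
    def test_identical_constructs_tie_in_input_order(self, backend, params):
        a = unstructured_construct(name="first")
        b = unstructured_construct(name="second")
        entries = rank_constructs([a, b], params, backend)
        assert [e.name for e in entries] == ["first", "second"]
        assert entries[0].score.delta == entries[1].score.delta

    def test_unstructured_outranks_hairpin(self, backend, params):
        h = hairpin_construct()
        u = Construct("u", h.utr5[:11] + "A" * 11, unstructured_construct().cds,
                      sd_sequence="AAAAAA", sd_offset=-11)
        entries = rank_constructs([h, u], params, backend)
        assert entries[0].name == "u"

    def test_stem_ladder_order(self, backend, params):
        ladder = stem_ladder((0, 4, 8))
        entries = rank_constructs(list(reversed(ladder)), params, backend)
        assert [e.name for e in entries] == ["stem-0", "stem-4", "stem-8"]
        deltas = [e.score.delta for e in entries]
        assert deltas[0] > deltas[1] > deltas[2]

    def test_failed_construct_annotated_and_last(self, backend, params):
        good = unstructured_construct()
        # transcript too short for the 30-nt RDS window: scoring fails
        bad = Construct(
            "bad", "AGGAGG", CodingSequence("AUG" + "AAA" * 3), "AGGAGG", -6
        )
        entries = rank_constructs([bad, good], params, backend)
        assert entries[-1].name == "bad"
        assert entries[-1].error is not None
        assert entries[0].score is not None

    def test_ranking_invariant_under_monotone_transform(self, backend, params):
        ladder = stem_ladder((0, 4, 8))
        entries = rank_constructs(list(ladder), params, backend)
        deltas = [e.score.delta for e in entries]
        logs = [math.log(d) for d in deltas]
        assert sorted(logs, reverse=True) == logs
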