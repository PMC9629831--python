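"""SEG low-complexity detection, IDRs, composition and property statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from moltmap.errors import InputError
from moltmap.sequence_properties import (
    adjust_plaac,
    build_property_table,
    call_idrs,
    mean_composition,
    pct_lcr,
    property_enrichment,
    seg_low_complexity,
    trim_signal_peptide,
    weighted_property_profile,
    window_entropy,
)
from moltmap.synthetic_data import AMINO_ACIDS, ProteinRecord
from oracles import brute_force_seg, random_biased_sequence, shannon_bits

# 12-mer cycle of distinct residues: every window is maximally complex
HIGH = "ACDEFGHIKLMN"


class TestWindowEntropy:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ("AAAAAAAAAAAA", 0.0),
            ("AAAAAAVVVVVV", 1.0),
            ("ACDEFGHIKLMN", np.log2(12)),
        ],
    )
    def test_closed_forms(self, window, expected):
        assert window_entropy(window) == pytest.approx(expected, abs=1e-12)

    def test_non_canonical_letter_is_an_input_error(self):
        with pytest.raises(InputError):
            window_entropy("AAAAAAAAAAAX")

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30))
    def test_bounded_and_matches_counter_oracle(self, window):
        k2 = window_entropy(window)
        assert 0.0 <= k2 <= np.log2(min(20, len(window))) + 1e-12
        assert k2 == pytest.approx(shannon_bits(window), abs=1e-12)


class TestSegLowComplexity:
    def test_homopolymer_spans_whole_sequence(self):
        segs = seg_low_complexity("A" * 15)
        assert [(s.start, s.end) for s in segs] == [(0, 15)]
        assert segs[0].trigger_entropy == 0.0

    def test_embedded_polyq_is_found(self):
        flank = HIGH * 3
        seq = flank + "Q" * 30 + flank
        segs = seg_low_complexity(seq)
        assert len(segs) == 1
        s = segs[0]
        assert s.start <= len(flank) and s.end >= len(flank) + 30

    def test_uniform_random_sequence_is_barely_masked(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=1000))
        segs = seg_low_complexity(seq)
        assert sum(len(s) for s in segs) / 1000 < 0.02

    def test_short_sequence_returns_nothing_with_warning(self, caplog):
        assert seg_low_complexity("AAAA") == []
        assert any("no segments" in r.message for r in caplog.records)

    def test_non_canonical_default_error_and_skip_mode(self):
        seq = "A" * 10 + "X" + "A" * 10
        with pytest.raises(InputError):
            seg_low_complexity(seq)
        segs = seg_low_complexity(seq, on_noncanonical="skip")
        # the X never appears inside a reported segment
        assert all(not (s.start <= 10 < s.end) for s in segs)

    def test_segments_are_disjoint_and_sorted(self):
        seq = "Q" * 20 + HIGH * 4 + "S" * 25 + HIGH * 2
        segs = seg_low_complexity(seq)
        assert len(segs) == 2
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start

    def test_matches_exhaustive_oracle_on_small_sequences(self):
        rng = np.random.default_rng(2024)
        n_with_segments = 0
        for _ in range(60):
            seq = random_biased_sequence(rng, max_len=40)
            got = [(s.start, s.end) for s in seg_low_complexity(seq)]
            expected = brute_force_seg(seq)
            assert got == expected, seq
            n_with_segments += bool(expected)
        assert n_with_segments >= 20  # the sample actually exercises stage 2

    def test_appending_complex_suffix_keeps_the_segment(self):
        core = HIGH * 2 + "N" * 18 + HIGH * 2
        before = seg_low_complexity(core)
        after = seg_low_complexity(core + HIGH * 4)
        tract = (len(HIGH) * 2, len(HIGH) * 2 + 18)
        def overlaps(segs):
            return any(s.start < tract[1] and s.end > tract[0] for s in segs)
        assert overlaps(before) and overlaps(after)


class TestPctLcrAndIdr:
    def test_pct_lcr_arithmetic(self):
        from moltmap.sequence_properties import LcrSegment

        protein = "A" * 100
        assert pct_lcr(protein, []) == 0.0
        assert pct_lcr(protein, [LcrSegment(0, 100, 0.0)]) == 100.0
        assert pct_lcr(protein, [LcrSegment(10, 35, 1.0)]) == 25.0

    @pytest.mark.parametrize(
        "track, n_idrs, pct",
        [
            (np.r_[np.full(29, 0.9), np.full(71, 0.1)], 0, 0.0),
            (np.r_[np.full(30, 0.9), np.full(70, 0.1)], 1, 30.0),
            (np.full(50, 0.9), 1, 100.0),
        ],
    )
    def test_thirty_residue_rule(self, track, n_idrs, pct):
        intervals, got_pct = call_idrs(track)
        assert len(intervals) == n_idrs
        assert got_pct == pytest.approx(pct)

    def test_threshold_is_inclusive(self):
        intervals, _ = call_idrs(np.full(30, 0.5))
        assert intervals == [(0, 30)]

    def test_empty_track_is_an_input_error(self):
        with pytest.raises(InputError):
            call_idrs(np.array([]))


class TestMeanComposition:
    def test_single_protein(self):
        comp = mean_composition(["AAVV"])
        assert comp["A"] == pytest.approx(50.0)
        assert comp["V"] == pytest.approx(50.0)
        assert comp.drop(["A", "V"]).eq(0).all()

    def test_per_protein_averaging_not_pooled(self):
        comp = mean_composition(["AA", "VVVV"])
        assert comp["A"] == pytest.approx(50.0)
        assert comp["V"] == pytest.approx(50.0)
        pooled = mean_composition(["AA", "VVVV"], weighted=True)
        assert pooled["A"] == pytest.approx(100 * 2 / 6)

    @given(
        st.lists(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=20),
                 min_size=1, max_size=8)
    )
    def test_rows_sum_to_one_hundred(self, seqs):
        assert mean_composition(seqs).sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_set_is_an_input_error(self):
        with pytest.raises(InputError):
            mean_composition([])


class TestAdjustPlaac:
    @pytest.mark.parametrize("raw, adjusted", [(-60, 0), (0, 60), (12.5, 72.5)])
    def test_offset(self, raw, adjusted):
        assert adjust_plaac(raw) == pytest.approx(adjusted)

    def test_below_floor_is_an_input_error(self):
        with pytest.raises(InputError):
            adjust_plaac(-60.001)


class TestTrimSignalPeptide:
    def test_removes_first_twenty(self):
        seq = "M" * 20 + "QQQQQ"
        assert trim_signal_peptide(seq) == "QQQQQ"

    def test_too_short_is_an_input_error(self):
        with pytest.raises(InputError):
            trim_signal_peptide("A" * 20)


class TestPropertyEnrichment:
    def test_closed_form_t(self):
        values = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})
        out = property_enrichment({"grp": ["a", "b", "c"]}, values, global_mean=10.0)
        row = out.set_index("group").loc["grp"]
        assert row["mean"] == pytest.approx(20.0)
        assert row["p"] == pytest.approx(2 * stats.t.sf(np.sqrt(3), df=2), abs=1e-6)

    def test_small_group_gets_p_one_with_warning(self, caplog):
        out = property_enrichment({"grp": ["a"]}, pd.Series({"a": 1.0, "b": 2.0}))
        assert out.loc[0, "p"] == 1.0
        assert any("<2" in r.message for r in caplog.records)

    def test_planted_shift_is_detected(self, rng):
        background = {f"b{i}": rng.normal(10, 5) for i in range(400)}
        shifted = {f"s{i}": rng.normal(40, 5) for i in range(100)}
        values = pd.Series({**background, **shifted})
        out = property_enrichment({"shifted": list(shifted)}, values)
        assert out.loc[0, "p"] < 1e-10


class TestWeightedPropertyProfile:
    def test_single_gene_product(self):
        prof = weighted_property_profile(
            {"g": 10.0}, {"g": 20.0}, {"g": 3}
        )
        assert prof.loc[3] == pytest.approx(200.0)

    def test_zero_transcripts_give_zero(self):
        prof = weighted_property_profile(
            {"a": 0.0, "b": 0.0}, {"a": 5.0, "b": 9.0}, {"a": 1, "b": 2}
        )
        assert prof.dropna().eq(0).all()

    def test_bin_average_of_products(self):
        prof = weighted_property_profile(
            {"a": 10.0, "b": 10.0}, {"a": 20.0, "b": 10.0}, {"a": 4, "b": 4}
        )
        assert prof.loc[4] == pytest.approx(150.0)

    def test_linearity_in_transcripts(self, rng):
        genes = [f"g{i}" for i in range(40)]
        expr = pd.Series({g: float(rng.uniform(0, 50)) for g in genes})
        prop = pd.Series({g: float(rng.uniform(0, 100)) for g in genes})
        hours = pd.Series({g: int(rng.integers(1, 9)) for g in genes})
        one = weighted_property_profile(expr, prop, hours)
        two = weighted_property_profile(2 * expr, prop, hours)
        assert np.allclose(two.dropna(), 2 * one.dropna())

    def test_missing_property_excluded_with_warning(self, caplog):
        prof = weighted_property_profile(
            {"a": 10.0, "b": 5.0}, {"a": 2.0}, {"a": 1, "b": 1}
        )
        assert prof.loc[1] == pytest.approx(20.0)
        assert any("lack" in r.message for r in caplog.records)


class TestBuildPropertyTable:
    def test_percentages_and_external_scores(self):
        proteins = [
            ProteinRecord("p1", "Q" * 30 + HIGH * 3, np.r_[np.full(30, 0.9), np.full(36, 0.1)]),
            ProteinRecord("p2", HIGH * 5, np.full(60, 0.1)),
        ]
        ext = pd.DataFrame({"plaac_score": [-10.0, 5.0]}, index=["p1", "p2"])
        table = build_property_table(proteins, ext)
        assert table.loc["p1", "pct_lcr"] > 0
        assert table.loc["p2", "pct_lcr"] == 0.0
        assert table.loc["p1", "pct_idr"] == pytest.approx(100 * 30 / 66)
        assert table.loc["p1", "plaac_score_adjusted"] == pytest.approx(50.0)
        assert (table["pct_lcr"].between(0, 100)).all()

    def test_missing_track_marked_unavailable(self, caplog):
        table = build_property_table([ProteinRecord("p", HIGH * 2)])
        assert np.isnan(table.loc["p", "pct_idr"])
        assert any("lack disorder tracks" in r.message for r in caplog.records)
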