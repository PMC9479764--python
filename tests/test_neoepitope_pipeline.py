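"""Mutant context construction, 9-mer enumeration, ranking, selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neocorr.errors import ParameterError
from neocorr.neoepitope_pipeline import (
    NeoepitopeCandidate,
    ProteinConsequence,
    ProteinContext,
    SyntheticBindingPredictor,
    TableBindingPredictor,
    build_mutant_context,
    count_predicted,
    enumerate_9mers,
    rank_candidates,
    select_candidates,
)
from neocorr.variant_consensus import VariantKey

WT20 = "ACDEFGHIKLMNPQRSTVWY"  # 20-aa toy protein, all residues distinct
KEY = VariantKey("chr1", 1, "A", "T")


def missense(pos, alt, wt=WT20):
    return ProteinConsequence("missense", pos, ref_aa=wt[pos - 1], alt_aa=alt)


def windows_oracle(wt, mutant, altered):
    """Exhaustive enumeration of novel altered-overlapping 9-mer windows."""
    wt9 = {wt[i : i + 9] for i in range(len(wt) - 8)}
    out, seen = [], set()
    for s in range(1, len(mutant) - 7):
        pep = mutant[s - 1 : s + 8]
        if any(s <= q <= s + 8 for q in altered) and pep not in wt9 and pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


class TestBuildMutantContext:
    def test_missense_differs_at_exactly_one_position(self):
        ctx = build_mutant_context(WT20, missense(5, "V"), gene="G")
        diffs = [i + 1 for i, (a, b) in enumerate(zip(WT20, ctx.mutant_sequence)) if a != b]
        assert diffs == [5]
        assert ctx.altered_positions == frozenset({5})

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            build_mutant_context(WT20, ProteinConsequence("missense", 5, "A", "V"))

    def test_synonymous_rejected_as_not_nonsilent(self):
        with pytest.raises(ParameterError):
            build_mutant_context(WT20, ProteinConsequence("synonymous", 5, "F", "F"))
        with pytest.raises(ParameterError):
            build_mutant_context(WT20, ProteinConsequence("missense", 5, "F", "F"))

    def test_frameshift_translates_to_first_stop(self):
        # shift at codon 10 with 16 novel residues before the new stop:
        # mutant is 25 aa long and positions 10..25 are altered
        tail = "VVVVVVVVVVVVVVVV*AAAA"
        ctx = build_mutant_context(WT20, ProteinConsequence("frameshift", 10, tail=tail))
        assert len(ctx.mutant_sequence) == 25
        assert ctx.altered_positions == frozenset(range(10, 26))

    def test_immediate_stop_is_empty_context(self):
        ctx = build_mutant_context(WT20, ProteinConsequence("stop_gained", 3, ref_aa="D"))
        assert ctx.is_empty
        assert enumerate_9mers(ctx) == []

    def test_inframe_insertion_marks_inserted_plus_junction(self):
        ctx = build_mutant_context(WT20, ProteinConsequence("inframe_ins", 5, inserted="WW"))
        assert len(ctx.mutant_sequence) == 22
        assert {6, 7} <= set(ctx.altered_positions)


class TestEnumerate9mers:
    def test_interior_missense_yields_exactly_nine(self):
        ctx = build_mutant_context(WT20, missense(10, "A"))
        peps = enumerate_9mers(ctx)
        assert len(peps) == 9
        assert all(len(p) == 9 for p in peps)

    def test_edge_missense_p3_yields_three(self):
        ctx = build_mutant_context(WT20, missense(3, "W"))
        assert len(enumerate_9mers(ctx)) == 3  # windows starting at 1..3

    def test_every_peptide_contains_altered_residue(self):
        ctx = build_mutant_context(WT20, missense(7, "Y"))
        for pep in enumerate_9mers(ctx):
            assert "Y" in pep

    def test_wildtype_identical_windows_filtered(self):
        # a context whose mutant equals the wild type: novelty filter removes all
        ctx = ProteinContext("G", WT20, WT20, frozenset({5}))
        assert enumerate_9mers(ctx) == []

    def test_short_mutant_yields_nothing(self):
        ctx = ProteinContext("G", "ACDEFGHI", "ACDEFGHV", frozenset({8}))
        assert enumerate_9mers(ctx) == []

    @given(st.data())
    def test_matches_window_oracle_on_random_proteins(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        L = int(rng.integers(9, 60))
        wt = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
        p = int(rng.integers(1, L + 1))
        alt = str(rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != wt[p - 1]]))
        ctx = build_mutant_context(wt, ProteinConsequence("missense", p, wt[p - 1], alt))
        assert enumerate_9mers(ctx) == windows_oracle(wt, ctx.mutant_sequence, {p})


def cand(pep="AAAAAAAAA", tpm=10.0, vaf=0.5, ic50=100.0, pre=True):
    return NeoepitopeCandidate(pep, KEY, "G", "HLA-A*02:01", ic50, tpm, vaf, pre)


class TestRanking:
    def test_score_is_log_expression_times_vaf(self):
        ranked = rank_candidates([cand(tpm=15.0, vaf=0.5)])
        assert ranked[0].rank_score == pytest.approx(2.0)  # log2(16) * 0.5

    def test_monotone_in_vaf_and_tpm(self):
        hi_vaf, lo_vaf = cand(pep="A" * 9, vaf=0.5, tpm=3), cand(pep="C" * 9, vaf=0.25, tpm=3)
        assert rank_candidates([lo_vaf, hi_vaf])[0].peptide == "A" * 9
        hi_tpm, lo_tpm = cand(pep="D" * 9, tpm=31), cand(pep="E" * 9, tpm=3)
        assert rank_candidates([lo_tpm, hi_tpm])[0].peptide == "D" * 9

    def test_ties_broken_by_ascending_ic50(self):
        strong = cand(pep="H" * 9, ic50=40.0)
        weak = cand(pep="G" * 9, ic50=150.0)
        assert rank_candidates([weak, strong])[0].ic50_nm == 40.0


class TestSelection:
    def test_three_criteria_boundaries(self):
        ranked = rank_candidates([
            cand(pep="A" * 9, ic50=201.0),          # fails affinity (201 > 200)
            cand(pep="C" * 9, ic50=200.0, tpm=4.0),  # inclusive on both cutoffs
            cand(pep="D" * 9, tpm=3.9),             # fails expression
            cand(pep="E" * 9, pre=False),           # absent pretreatment
        ])
        kept = select_candidates(ranked)
        assert [c.peptide for c in kept] == ["C" * 9]
        assert all(c.selected for c in kept)

    def test_truncation_by_rank(self):
        ranked = rank_candidates([cand(pep=a * 9, tpm=10 + i) for i, a in enumerate("ACDEFG")])
        kept = select_candidates(ranked, max_per_patient=2)
        assert len(kept) == 2
        assert kept[0].rank_score >= kept[1].rank_score

    def test_selection_is_pure_order_preserving_filter(self):
        ranked = rank_candidates([cand(pep=a * 9, tpm=5 + i) for i, a in enumerate("ACDEF")])
        kept = select_candidates(ranked)
        peptides = [c.peptide for c in ranked]
        assert [c.peptide for c in kept] == [p for p in peptides if p in {c.peptide for c in kept}]

    def test_log_scale_expression_flag(self):
        ranked = rank_candidates([cand(tpm=16.0)])
        assert select_candidates(ranked, tpm_on_log_scale=True)  # log2(17) > 4
        ranked_low = rank_candidates([cand(tpm=10.0)])
        assert not select_candidates(ranked_low, tpm_on_log_scale=True)  # log2(11) < 4


class TestPredictors:
    def test_synthetic_predictor_deterministic_and_seed_dependent(self):
        p1 = SyntheticBindingPredictor(seed=1)
        p2 = SyntheticBindingPredictor(seed=1)
        p3 = SyntheticBindingPredictor(seed=2)
        v = p1("ACDEFGHIK", "HLA-A*02:01")
        assert v == p2("ACDEFGHIK", "HLA-A*02:01")
        assert v != p3("ACDEFGHIK", "HLA-A*02:01")

    def test_synthetic_strong_fraction_controls_binder_rate(self):
        pred = SyntheticBindingPredictor(seed=0, strong_fraction=0.25)
        rng = np.random.default_rng(0)
        peps = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9)) for _ in range(2000)]
        frac = np.mean([pred(p, "HLA-A*02:01") <= 200 for p in peps])
        assert frac == pytest.approx(0.25, abs=0.03)

    def test_table_predictor_round_trip(self, tmp_path):
        from neocorr.io import write_ic50_tsv

        rows = [("ACDEFGHIK", "HLA-A*02:01", 55.5), ("KIHGFEDCA", "HLA-B*07:02", 1200.0)]
        path = tmp_path / "ic50.tsv"
        write_ic50_tsv(path, rows)
        pred = TableBindingPredictor.from_tsv(path)
        assert pred("ACDEFGHIK", "HLA-A*02:01") == 55.5
        with pytest.raises(KeyError):
            pred("WWWWWWWWW", "HLA-A*02:01")

    def test_count_predicted_uses_500nm_threshold(self):
        cands = [cand(pep="A" * 9, ic50=499.0), cand(pep="C" * 9, ic50=501.0),
                 cand(pep="A" * 9, ic50=499.0)]
        assert count_predicted(cands) == 1
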