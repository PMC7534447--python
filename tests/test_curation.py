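"""Three-rule contamination filter, GC computation and renaming."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vespagen import (
    ContigEvidence,
    CurationParams,
    SequenceSet,
    apply_curation,
    apply_naming,
    assign_names,
    classify_contigs,
    gc_fraction,
)


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGCC", 1.0),
            ("ATNNAT", 0.0),
            ("ACGTacgt", 0.5),
            ("ACGRYT", 0.5),  # ambiguity codes excluded both sides
        ],
    )
    def test_hand_counts(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_undefined_without_unambiguous_bases(self):
        assert gc_fraction("NNNN") is None
        assert gc_fraction("") is None

    @given(st.text(alphabet="ACGTacgtNn", min_size=1, max_size=200))
    def test_case_invariance(self, seq):
        assert gc_fraction(seq) == gc_fraction(seq.upper())


def _assembly(ids):
    return SequenceSet([(cid, "ACGT") for cid in ids])


def _ev(cid, descs=(), rescued=0, gc=0.5):
    return ContigEvidence(
        contig_id=cid,
        taxonomy_descriptions=list(descs),
        rescued_gene_count=rescued,
        gc_fraction=gc,
    )


class TestClassifyContigs:
    def test_keyword_keeps_contig(self):
        asm = _assembly(["c1"])
        ev = {"c1": _ev("c1", ["Vespula vulgaris venom allergen"])}
        report = classify_contigs(asm, ev)
        assert report.decisions["c1"] == ("keep", "taxonomy_keyword")

    def test_keyword_match_is_case_insensitive_substring(self):
        asm = _assembly(["c1", "c2"])
        ev = {
            "c1": _ev("c1", ["PREDICTED: polistes dominula protein"]),
            "c2": _ev("c2", ["some wasp-like sequence"]),
        }
        report = classify_contigs(asm, ev)
        assert report.decisions["c1"][0] == "keep"
        assert report.decisions["c2"][0] == "keep"

    def test_mismatching_hit_discards_without_gc_evaluation(self):
        """A contig with hits but no keyword never reaches the GC band."""
        asm = _assembly(["good", "bad"])
        ev = {
            "good": _ev("good", ["Vespula protein"], gc=0.30),
            # GC identical to the keeper: would pass rule 3, but rule 1 fires
            "bad": _ev("bad", ["Escherichia coli genome"], gc=0.30),
        }
        report = classify_contigs(asm, ev)
        assert report.decisions["bad"] == ("discard", "taxonomy_mismatch")

    def test_orthogroup_rescue_for_hitless_contig(self):
        asm = _assembly(["k", "r"])
        ev = {
            "k": _ev("k", ["Vespula protein"]),
            "r": _ev("r", rescued=2),
        }
        report = classify_contigs(asm, ev)
        assert report.decisions["r"] == ("keep", "orthogroup_rescue")

    def test_rescue_not_consulted_when_hits_exist(self):
        """Rule precedence is strict: taxonomy hits outrank rescue genes."""
        asm = _assembly(["k", "x"])
        ev = {
            "k": _ev("k", ["Vespula protein"]),
            "x": _ev("x", ["Bacillus phage"], rescued=5),
        }
        report = classify_contigs(asm, ev)
        assert report.decisions["x"] == ("discard", "taxonomy_mismatch")

    def test_gc_band_from_hand_computed_mean_and_sd(self):
        """10 keepers with GC {0.30 x5, 0.32 x5}: mean 0.31, sample SD
        ~0.01054; a 0.55 candidate is far outside the 2-SD band, a 0.315
        candidate is inside."""
        ids = [f"k{i}" for i in range(10)] + ["far", "near"]
        asm = _assembly(ids)
        ev = {}
        for i in range(10):
            gc = 0.30 if i < 5 else 0.32
            ev[f"k{i}"] = _ev(f"k{i}", ["Vespula protein"], gc=gc)
        ev["far"] = _ev("far", gc=0.55)
        ev["near"] = _ev("near", gc=0.315)
        report = classify_contigs(asm, ev)
        assert report.gc_mean == pytest.approx(0.31)
        assert report.gc_sd == pytest.approx(np.std([0.30] * 5 + [0.32] * 5, ddof=1))
        assert report.decisions["far"] == ("discard", "gc_outside_band")
        assert report.decisions["near"] == ("keep", "gc_within_band")

    def test_band_bounds_inclusive(self):
        asm = _assembly(["a", "b", "edge"])
        ev = {
            "a": _ev("a", ["wasp"], gc=0.30),
            "b": _ev("b", ["wasp"], gc=0.32),
            "edge": _ev("edge", gc=0.31 + 2 * np.std([0.30, 0.32], ddof=1)),
        }
        report = classify_contigs(asm, ev)
        assert report.decisions["edge"][0] == "keep"

    def test_no_band_contig_is_error_with_guidance(self):
        asm = _assembly(["x"])
        ev = {"x": _ev("x")}
        with pytest.raises(ValueError, match="relax"):
            classify_contigs(asm, ev)

    def test_undefined_gc_at_rule3_discarded_with_warning(self):
        asm = _assembly(["k", "u"])
        ev = {
            "k": _ev("k", ["Vespula protein"], gc=0.3),
            "u": _ev("u", gc=None),
        }
        with pytest.warns(UserWarning, match="undefined GC"):
            report = classify_contigs(asm, ev)
        assert report.decisions["u"] == ("discard", "gc_outside_band")

    def test_missing_evidence_is_error(self):
        with pytest.raises(KeyError):
            classify_contigs(_assembly(["a"]), {})

    def test_determinism_under_evidence_dict_order(self):
        asm = _assembly(["a", "b", "c"])
        ev = {
            "a": _ev("a", ["Vespula protein"], gc=0.3),
            "b": _ev("b", rescued=1, gc=0.31),
            "c": _ev("c", gc=0.305),
        }
        rev = dict(reversed(list(ev.items())))
        r1 = classify_contigs(asm, ev)
        r2 = classify_contigs(asm, rev)
        assert r1.decisions == r2.decisions
        assert list(r1.decisions) == list(r2.decisions) == ["a", "b", "c"]

    def test_whole_word_option(self):
        asm = _assembly(["c"])
        ev = {"c": _ev("c", ["waspish protein"]), }
        loose = classify_contigs(asm, ev)
        assert loose.decisions["c"][0] == "keep"
        asm2 = _assembly(["c", "k"])
        ev2 = {
            "c": _ev("c", ["waspish protein"]),
            "k": _ev("k", ["true wasp protein"]),
        }
        strict = classify_contigs(
            asm2, ev2, CurationParams(whole_word=True)
        )
        assert strict.decisions["c"] == ("discard", "taxonomy_mismatch")
        assert strict.decisions["k"][0] == "keep"


class TestApplyCuration:
    def test_all_keep_is_identity(self):
        asm = SequenceSet([("a", "ACgt"), ("b", "GG")])
        ev = {
            "a": _ev("a", ["Vespula protein"]),
            "b": _ev("b", ["wasp protein"]),
        }
        report = classify_contigs(asm, ev)
        assert apply_curation(asm, report).records == asm.records

    def test_all_discard_is_error(self):
        asm = _assembly(["a"])
        ev = {"a": _ev("a", ["Staphylococcus plasmid"])}
        report = classify_contigs(asm, ev)
        with pytest.raises(ValueError, match="empty assembly"):
            apply_curation(asm, report)

    def test_kept_set_equals_keep_verdicts(self):
        asm = _assembly(["a", "b", "c"])
        ev = {
            "a": _ev("a", ["Vespula protein"], gc=0.3),
            "b": _ev("b", ["Yersinia phage"], gc=0.3),
            "c": _ev("c", rescued=1, gc=0.3),
        }
        report = classify_contigs(asm, ev)
        kept = apply_curation(asm, report)
        assert set(kept.ids) == {
            cid for cid, (v, _) in report.decisions.items() if v == "keep"
        }


class TestAssignNames:
    def test_chromosomes_then_four_digit_scaffolds(self):
        recs = [(f"s{i}", "A" * (100 - i)) for i in range(27)]
        naming = assign_names(SequenceSet(recs), n_chromosomes=25)
        assert naming["s0"] == "Chr1"
        assert naming["s24"] == "Chr25"
        assert naming["s25"] == "Scaffold0001"
        assert naming["s26"] == "Scaffold0002"

    def test_ties_broken_by_input_order(self):
        recs = [("first", "AAAA"), ("second", "AAAA")]
        naming = assign_names(SequenceSet(recs), n_chromosomes=2)
        assert naming["first"] == "Chr1"
        assert naming["second"] == "Chr2"

    def test_rank_order_matches_sort_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            lengths = rng.integers(1, 500, size=n).tolist()
            recs = [(f"c{i}", "A" * l) for i, l in enumerate(lengths)]
            naming = assign_names(SequenceSet(recs), n_chromosomes=0)
            oracle = sorted(range(n), key=lambda i: (-lengths[i], i))
            expected = {
                f"c{idx}": f"Scaffold{rank:04d}"
                for rank, idx in enumerate(oracle, start=1)
            }
            assert naming.mapping == expected

    def test_fewer_records_than_chromosomes_warns(self):
        with pytest.warns(UserWarning, match="fewer"):
            naming = assign_names(_assembly(["a"]), n_chromosomes=25)
        assert naming["a"] == "Chr1"

    def test_apply_naming_reorders_by_rank(self):
        recs = [("small", "AA"), ("big", "AAAA")]
        asm = SequenceSet(recs)
        naming = assign_names(asm, n_chromosomes=1)
        renamed = apply_naming(asm, naming)
        assert renamed.ids == ["Chr1", "Scaffold0001"]
        assert renamed["Chr1"] == "AAAA"
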