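"""Consensus intersection, dinucleotide collapsing, classification,
burden and recurrence, each against independent brute-force oracles."""

import numpy as np
import pytest

from uvsig.sbs import BASES, COMPLEMENT, PYRIMIDINES, revcomp
from uvsig.variants import (
    ConfigurationError,
    MutationEvent,
    VariantCall,
    build_consensus,
    burden_per_mb,
    classify_snv,
    collapse_dinucleotide_events,
    gene_recurrence,
)


def _call(sample, pos, ref="C", alt="T", chrom="chr1"):
    return VariantCall(sample, chrom, pos, ref, alt)


class TestConsensus:
    def test_variant_in_all_callers_is_retained(self):
        v = _call("s1", 100)
        out = build_consensus([[v], [v], [v]])
        assert out == [v]

    def test_variant_in_two_of_three_callers_is_dropped(self):
        v = _call("s1", 100)
        assert build_consensus([[v], [v], []]) == []

    def test_excluded_known_variant_is_removed(self):
        v = _call("s1", 100)
        assert build_consensus([[v]] * 3, {("s1", "chr1", 100, "C", "T")}) == []
        # site-level (sample-less) exclusion keys also match
        assert build_consensus([[v]] * 3, {("chr1", 100, "C", "T")}) == []

    def test_random_callsets_match_set_algebra_oracle(self, rng):
        def random_calls(n):
            out = {}
            for _ in range(n):
                pos = int(rng.integers(1, 2000))
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                v = VariantCall(f"s{rng.integers(3)}", "chr1", pos, ref, alt)
                out[v.key] = v
            return out

        sets = [random_calls(500) for _ in range(3)]
        exclusion = set(
            list(sets[0])[:50] + [("sX", "chr1", 5, "A", "C")]
        )
        out = build_consensus([list(s.values()) for s in sets], exclusion)
        expected = (set(sets[0]) & set(sets[1]) & set(sets[2])) - exclusion
        assert {v.key for v in out} == expected
        # consensus output is a subset of every input call set
        for s in sets:
            assert {v.key for v in out} <= set(s)

    def test_empty_callset_list_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_consensus([])

    def test_malformed_exclusion_key_reports_identity(self):
        with pytest.raises(ValueError, match="malformed"):
            build_consensus([[_call("s1", 1)]], [("chr1", 1)])


class TestCollapsing:
    def test_adjacent_pair_becomes_one_dinucleotide_event(self):
        ev = collapse_dinucleotide_events(
            [_call("s1", 100), _call("s1", 101)]
        )
        assert len(ev) == 1
        assert ev[0].event_kind == "dinucleotide"
        assert (ev[0].ref_allele, ev[0].alt_allele) == ("CC", "TT")

    def test_non_adjacent_snvs_stay_separate(self):
        ev = collapse_dinucleotide_events([_call("s1", 100), _call("s1", 103)])
        assert [e.event_kind for e in ev] == ["snv", "snv"]

    def test_different_samples_never_merge(self):
        ev = collapse_dinucleotide_events([_call("s1", 100), _call("s2", 101)])
        assert len(ev) == 2

    def test_triple_run_merges_greedily_left_to_right(self):
        ev = collapse_dinucleotide_events(
            [_call("s1", 100), _call("s1", 101), _call("s1", 102)]
        )
        assert [e.event_kind for e in ev] == ["dinucleotide", "snv"]
        assert ev[0].start == 100 and ev[1].start == 102

    def test_planted_pairs_match_linear_scan_oracle(self, rng):
        # 950 isolated SNVs + 25 adjacent pairs = 1000 SNVs, 975 events
        positions = rng.choice(np.arange(10, 200_000, 4), 975, replace=False)
        calls = []
        for i, p in enumerate(sorted(positions)):
            calls.append(_call("s1", int(p)))
            if i < 25:
                calls.append(_call("s1", int(p) + 1))
        events = collapse_dinucleotide_events(calls)
        assert len(events) == 975
        n_di = sum(1 for e in events if e.event_kind == "dinucleotide")
        # independent scan oracle over sorted positions
        pos = sorted(c.pos for c in calls)
        oracle = sum(
            1 for a, b in zip(pos, pos[1:]) if b == a + 1
        )
        assert n_di == oracle == 25

    def test_collapsing_is_idempotent(self, small_cohort):
        events = small_cohort["events"]
        starts = {(e.sample_id, e.start, e.event_kind) for e in events}
        # re-collapsing the snv portion of a collapsed stream changes nothing
        snv_calls = [
            VariantCall(e.sample_id, e.chrom, e.start, e.ref_allele, e.alt_allele)
            for e in events
            if e.event_kind == "snv"
        ]
        again = collapse_dinucleotide_events(snv_calls)
        assert all(e.event_kind == "snv" for e in again)
        assert {(e.sample_id, e.start, e.event_kind) for e in again} <= starts

    def test_position_beyond_reference_is_a_bounds_error(self):
        with pytest.raises(IndexError):
            collapse_dinucleotide_events(
                [_call("s1", 50)], {"chr1": "ACGT" * 10}
            )


class TestClassification:
    def _classify(self, trinuc, alt, pos=5):
        ref = {"chr1": "AAAA" + trinuc + "AAAA"}
        e = MutationEvent("s1", "chr1", pos + 1, trinuc[1], alt, "snv")
        return classify_snv(e, ref)

    def test_purine_snv_maps_through_reverse_complement(self):
        e = self._classify("AGA", "A")  # G>A in AGA -> C>T in TCT
        assert e.snv_class == "C>T"
        assert e.context == "TCT"
        assert not e.at_cpg

    def test_cpg_flag_set_when_c_followed_by_g(self):
        e = self._classify("ACG", "T")
        assert e.snv_class == "C>T"
        assert e.context == "ACG"
        assert e.at_cpg

    def test_all_192_strand_specific_substitutions_fold_to_96_channels(self):
        """Exhaustive enumeration: every (trinucleotide, alt) substitution
        and its reverse complement land on the same channel, 2-to-1."""
        from collections import Counter

        seen = Counter()
        for f5 in BASES:
            for mid in BASES:
                for f3 in BASES:
                    for alt in BASES:
                        if alt == mid:
                            continue
                        tri = f5 + mid + f3
                        e = self._classify(tri, alt)
                        # oracle: complement representation classifies equally
                        tri_rc = revcomp(tri)
                        e_rc = self._classify(tri_rc, COMPLEMENT[alt])
                        assert (e.snv_class, e.context) == (
                            e_rc.snv_class,
                            e_rc.context,
                        )
                        assert e.context[1] in PYRIMIDINES
                        seen[(e.snv_class, e.context)] += 1
        assert len(seen) == 96
        assert set(seen.values()) == {2}  # each channel has 2 orientations

    def test_ambiguous_context_is_excluded(self):
        ref = {"chr1": "AANCA"}
        e = MutationEvent("s1", "chr1", 4, "C", "T", "snv")
        assert classify_snv(e, ref) is None

    def test_reference_mismatch_raises(self):
        ref = {"chr1": "AAACA"}
        e = MutationEvent("s1", "chr1", 4, "G", "T", "snv")
        with pytest.raises(ValueError, match="mismatch"):
            classify_snv(e, ref)

    def test_class_counts_sum_to_snv_event_count(self, small_cohort):
        events = small_cohort["events"]
        snvs = [e for e in events if e.event_kind == "snv"]
        assert all(e.snv_class is not None for e in snvs)
        per_class = {}
        for e in snvs:
            per_class[e.snv_class] = per_class.get(e.snv_class, 0) + 1
        assert sum(per_class.values()) == len(snvs)


class TestBurden:
    def test_events_per_mb_simple_ratio(self):
        events = [
            MutationEvent("s1", "chr1", i, "C", "T", "snv") for i in range(1, 51)
        ]
        burden = burden_per_mb(events, 50_000_000)
        assert burden["s1"] == pytest.approx(1.0)

    def test_zero_events_zero_burden(self):
        events = [MutationEvent("s1", "chr1", 5, "C", "T", "indel")]
        assert burden_per_mb(events, 1_000_000, kind_filter="snv")["s1"] == 0.0

    def test_collapsed_catalog_hand_computation(self):
        # 1000 SNVs with 10 adjacent pairs -> 990 events over 49.6 Mb
        calls = []
        p = 10
        for i in range(990):
            calls.append(_call("s1", p))
            if i < 10:
                calls.append(_call("s1", p + 1))
            p += 5
        events = collapse_dinucleotide_events(calls)
        burden = burden_per_mb(events, 49_600_000)
        assert burden["s1"] == pytest.approx(990 * 1e6 / 49.6e6)

    def test_nonpositive_capture_size_rejected(self):
        with pytest.raises(ConfigurationError):
            burden_per_mb([], 0)


class TestRecurrence:
    def _event(self, sample, gene):
        return MutationEvent(
            sample, "chr1", 100, "C", "T", "snv", gene=gene
        )

    def test_gene_at_threshold_retained_with_frequency(self):
        events = [self._event(f"s{i}", "Flna") for i in range(3)]
        table = gene_recurrence(events, cohort_size=36, min_samples=3)
        summary = table.summary
        assert list(summary["gene"]) == ["Flna"]
        assert summary["frequency"].iloc[0] == pytest.approx(3 / 36)

    def test_gene_below_threshold_excluded(self):
        events = [self._event("s1", "Ttn"), self._event("s2", "Ttn")]
        assert gene_recurrence(events, 10).summary.empty

    def test_multiple_hits_in_one_sample_count_once(self):
        events = [self._event("s1", "Map3k1")] * 5 + [
            self._event("s2", "Map3k1")
        ]
        assert gene_recurrence(events, 10).summary.empty

    def test_random_table_matches_tally_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        events = [
            self._event(f"s{rng.integers(12)}", genes[rng.integers(20)])
            for _ in range(400)
        ]
        table = gene_recurrence(events, cohort_size=12, min_samples=3)
        oracle = {}
        for e in events:
            oracle.setdefault(e.gene, set()).add(e.sample_id)
        expected = {g for g, s in oracle.items() if len(s) >= 3}
        assert set(table.summary["gene"]) == expected

    def test_cohort_smaller_than_observed_samples_rejected(self):
        events = [self._event(f"s{i}", "g") for i in range(5)]
        with pytest.raises(ConfigurationError):
            gene_recurrence(events, cohort_size=3)
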