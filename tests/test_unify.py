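"""Chunking, combination enumeration, haplotype splicing and matching."""

from __future__ import annotations

import itertools

import pytest

from varunify.model import CandidateSite, Region, ThresholdConfig, UnifiedRecord, Variant
from varunify.unify import (
    CandidateCombination,
    Chunk,
    HaplotypePair,
    apply_combination,
    best_match,
    candidate_pair,
    chunk_sites,
    enumerate_candidate_combinations_bruteforce,
    enumerate_truth_combinations,
    equivalent,
    generate_supported_combinations,
    match_to_records,
    merge_outputs,
    rescue_weak,
    splice,
    truth_pair,
)

from conftest import make_read, make_random_chunk


def var(pos, ref, alt, gt=(0, 1), phased=True):
    return Variant("chr1", pos, ref, (alt,), gt, phased=phased)


def cand(pos, ref, alt, alt_count=10, depth=20):
    return CandidateSite("chr1", pos, ref, alt, depth, alt_count)


# ---------------------------------------------------------------------------
# chunking


class TestChunkSites:
    def test_sites_within_gap_share_a_chunk(self):
        vs = [var(100, "A", "G"), var(150, "C", "T")]
        specs = chunk_sites(vs, [], gap_bp=100, flank_bp=16)
        assert len(specs) == 1
        region, truths, cands = specs[0]
        assert truths == vs and cands == []
        assert region.start == 100 - 1 - 16 and region.end == 150 + 16

    def test_sites_at_gap_distance_split(self):
        vs = [var(100, "A", "G"), var(201, "C", "T")]  # gap exactly 100
        specs = chunk_sites(vs, [], gap_bp=100)
        assert len(specs) == 2

    def test_candidates_join_the_nearest_truth_cluster(self):
        vs = [var(100, "A", "G")]
        cs = [cand(130, "T", "C"), cand(600, "G", "A")]
        specs = chunk_sites(vs, cs, gap_bp=100)
        assert len(specs) == 1  # the lone far candidate group is dropped
        _, truths, cands = specs[0]
        assert truths == vs and cands == [cs[0]]

    def test_oversized_group_splits_at_widest_gap(self):
        vs = [var(p, "A", "G") for p in (100, 110, 180, 190)]
        specs = chunk_sites(vs, [], gap_bp=100, max_n=2)
        assert len(specs) == 2
        assert [t.pos for t in specs[0][1]] == [100, 110]
        assert [t.pos for t in specs[1][1]] == [180, 190]

    def test_flank_clipped_at_contig_bounds(self):
        specs = chunk_sites([var(5, "A", "G")], [], contig_lengths={"chr1": 12})
        region = specs[0][0]
        assert region.start == 0 and region.end == 12

    def test_chunks_cover_all_truths_exactly_once(self):
        vs = [var(p, "A", "G") for p in (10, 40, 500, 520, 2000)]
        cs = [cand(30, "T", "C"), cand(510, "G", "A")]
        specs = chunk_sites(vs, cs, max_n=12)
        got = [t.pos for _, truths, _ in specs for t in truths]
        assert sorted(got) == [10, 40, 500, 520, 2000]


# ---------------------------------------------------------------------------
# enumeration


WINDOW = "ACGTACGTACGTACGTACGT"


def chunk_of(truths, cands, reads=()):
    return Chunk(
        region=Region("chr1", 0, len(WINDOW)),
        window_seq=WINDOW,
        truth_variants=list(truths),
        candidates=list(cands),
        reads=list(reads),
    )


class TestEnumerateTruthCombinations:
    def test_phased_truths_give_two_to_the_n(self):
        c = chunk_of([var(4, "T", "A"), var(9, "A", "G", gt=(1, 0))], [])
        combos = enumerate_truth_combinations(c)
        assert len(combos) == 4
        assert combos[0].states == (None, None)
        assert combos[-1].positive_count == 2
        # phased orientation respected: (0,1) -> (ref, alt); (1,0) -> (alt, ref)
        full = combos[-1].states
        assert full[0] == ("T", "A") and full[1] == ("G", "A")

    def test_unphased_het_contributes_both_orientations(self):
        c = chunk_of([var(4, "T", "A", phased=False)], [])
        combos = enumerate_truth_combinations(c)
        states = [cb.states[0] for cb in combos]
        assert states == [None, ("T", "A"), ("A", "T")]

    def test_hom_contributes_single_form(self):
        c = chunk_of([var(4, "T", "A", gt=(1, 1))], [])
        combos = enumerate_truth_combinations(c)
        assert [cb.states[0] for cb in combos] == [None, ("A", "A")]

    def test_max_n_guard(self):
        c = chunk_of([var(p, WINDOW[p - 1], "A" if WINDOW[p - 1] != "A" else "C")
                      for p in range(1, 14)], [])
        with pytest.raises(ValueError, match="split"):
            enumerate_truth_combinations(c, max_n=12)


class TestBruteforceCandidates:
    def test_four_to_the_m_states(self):
        c = chunk_of([], [cand(4, "T", "A"), cand(9, "A", "G")])
        combos = enumerate_candidate_combinations_bruteforce(c)
        assert len(combos) == 16
        assert len({cb.states for cb in combos}) == 16


# ---------------------------------------------------------------------------
# splicing


class TestSplice:
    def test_reference_only(self):
        assert splice(WINDOW, 0, []) == WINDOW
        assert splice(WINDOW, 0, [(4, "T", "T")]) == WINDOW

    def test_snp_insertion_deletion(self):
        assert splice(WINDOW, 0, [(4, "T", "A")]) == "ACGAACGTACGTACGTACGT"
        assert splice(WINDOW, 0, [(4, "T", "TGG")]) == "ACGTGGACGTACGTACGTACGT"
        assert splice(WINDOW, 0, [(4, "TAC", "T")]) == "ACGTGTACGTACGTACGT"

    def test_nonzero_window_start(self):
        assert splice(WINDOW[4:12], 4, [(9, "A", "T")]) == "ACGTTCGT"

    def test_overlapping_entries_return_none(self):
        assert splice(WINDOW, 0, [(4, "TAC", "T"), (5, "A", "G")]) is None

    def test_entry_outside_window_returns_none(self):
        assert splice(WINDOW[:8], 0, [(8, "TA", "T")]) is None

    def test_apply_combination_builds_both_haplotypes(self):
        pair = apply_combination(WINDOW, 0, [(4, "T")], [("T", "A")])
        assert pair == HaplotypePair(WINDOW, "ACGAACGTACGTACGTACGT")


class TestEquivalent:
    def test_order_insensitive(self):
        a = HaplotypePair("AAA", "CCC")
        assert equivalent(a, HaplotypePair("CCC", "AAA"))
        assert equivalent(a, a)
        assert not equivalent(a, HaplotypePair("AAA", "CCG"))


# ---------------------------------------------------------------------------
# matching worked examples


def reads_expressing(haps, n_per_hap=10, start=0):
    """Error-free full-window reads drawn alternately from two haplotype
    sequences (tagged 1/2)."""
    out = []
    for h, seq in enumerate(haps, start=1):
        for i in range(n_per_hap):
            out.append(
                make_read(f"h{h}_{i}", "chr1", start, [("M", len(seq))], seq, hap=h)
            )
    return out


class TestBestMatchExamples:
    def test_mnp_truth_matches_two_snp_candidates(self):
        """Truth 'TA'>'AG' at 4 == candidates T>A at 4 and A>G at 5 in cis."""
        truth = [Variant("chr1", 4, "TA", ("AG",), (0, 1), phased=True)]
        cands = [cand(4, "T", "A"), cand(5, "A", "G")]
        hap1 = WINDOW
        hap2 = "ACGAGCGTACGTACGTACGT"  # TA>AG applied at 0-based 3
        chunk = chunk_of(truth, cands, reads_expressing([hap1, hap2]))
        m = best_match(chunk)
        assert m is not None
        assert m.candidate_combination.states == ("het01", "het01")
        assert m.missing_truths == []
        assert m.read_support == 20

    def test_shifted_deletion_representation(self):
        """A left-aligned truth deletion matches a right-shifted candidate
        deletion of the same repeat unit (identical haplotype sequence)."""
        # WINDOW is (ACGT)x5: deleting ACGT at 4..8 == deleting it at 8..12
        truth = [Variant("chr1", 4, "TACGT", ("T",), (0, 1), phased=True)]
        cands = [cand(8, "TACGT", "T")]  # reads express the shifted form
        hap1 = [make_read(f"h1_{i}", "chr1", 0, [("M", 20)], WINDOW, hap=1)
                for i in range(10)]
        seq2 = WINDOW[:8] + WINDOW[12:]
        hap2 = [make_read(f"h2_{i}", "chr1", 0,
                          [("M", 8), ("D", 4), ("M", 8)], seq2, hap=2)
                for i in range(10)]
        chunk = chunk_of(truth, cands, hap1 + hap2)
        m = best_match(chunk)
        assert m is not None and m.missing_truths == []
        assert m.candidate_combination.states == ("het01",)
        assert m.read_support == 20

    def test_unphased_truth_matches_either_orientation(self):
        truth = [var(4, "T", "A", phased=False)]
        cands = [cand(4, "T", "A")]
        hap1 = "ACGAACGTACGTACGTACGT"  # alt on hap1
        hap2 = WINDOW
        chunk = chunk_of(truth, cands, reads_expressing([hap1, hap2]))
        m = best_match(chunk)
        assert m is not None
        assert m.candidate_combination.states == ("het10",)

    def test_no_reads_yields_no_match(self):
        chunk = chunk_of([var(4, "T", "A")], [cand(4, "T", "A")], reads=[])
        assert best_match(chunk) is None

    def test_hom_truth(self):
        truth = [var(4, "T", "A", gt=(1, 1))]
        cands = [cand(4, "T", "A")]
        alt = "ACGAACGTACGTACGTACGT"
        chunk = chunk_of(truth, cands, reads_expressing([alt, alt]))
        m = best_match(chunk)
        assert m.candidate_combination.states == ("hom",)

    def test_prefers_more_positive_truths_then_read_support(self):
        """Lexicographic objective: a match keeping both truths wins over one
        dropping a truth variant even if the latter has more read support."""
        truth = [var(4, "T", "A"), var(9, "A", "G")]
        cands = [cand(4, "T", "A"), cand(9, "A", "G")]
        hap2 = splice(WINDOW, 0, [(4, "T", "A"), (9, "A", "G")])
        # 3 reads express both alts; 17 express reference only
        reads = reads_expressing([WINDOW, hap2], n_per_hap=3)
        reads += reads_expressing([WINDOW, WINDOW], n_per_hap=7)
        chunk = chunk_of(truth, cands, reads)
        m = best_match(chunk)
        assert m is not None
        assert m.truth_combination.positive_count == 2
        assert m.candidate_combination.states == ("het01", "het01")


# ---------------------------------------------------------------------------
# oracles on random chunks


def collect_chunks(n_target, coverage=20, max_m=5):
    chunks = []
    seed = 0
    while len(chunks) < n_target and seed < n_target * 30:
        c = make_random_chunk(seed, coverage=coverage)
        seed += 1
        if c is not None and c.m <= max_m:
            chunks.append(c)
    return chunks


class TestSupportedCombinationsOracle:
    def test_equals_bruteforce_filtered_to_both_haplotype_support(self):
        """With full-span error-free reads, the constructed set equals the
        4^m brute force filtered to support > 0 on BOTH haplotypes, with
        identical scores (a pattern pair needs a fully consistent read on
        each side, and a fully covering consistent read implies an exactly
        matching pattern)."""
        chunks = collect_chunks(40)
        assert len(chunks) >= 30
        for chunk in chunks:
            supported = generate_supported_combinations(chunk)
            brute = enumerate_candidate_combinations_bruteforce(chunk)
            expected = {
                b.states: b
                for b in brute
                if b.support[0] > 0 and b.support[1] > 0 and b.p_a > 0
            }
            assert {s.states for s in supported} == set(expected)
            for s in supported:
                b = expected[s.states]
                assert s.support == b.support
                assert s.p_a == b.p_a

    def test_pruned_count_never_exceeds_four_to_the_m(self):
        for chunk in collect_chunks(25):
            supported = generate_supported_combinations(chunk)
            assert len(supported) <= 4 ** chunk.m
            assert len({c.states for c in supported}) == len(supported)


class TestBestMatchOracle:
    def _exhaustive_best(self, chunk):
        """Literal 2^n x 4^m search with the same lexicographic objective,
        restricted to combinations with read evidence on both haplotypes."""
        brute = [
            c for c in enumerate_candidate_combinations_bruteforce(chunk)
            if c.support[0] > 0 and c.support[1] > 0 and c.p_a > 0
        ]
        best_key, best = (-1, -1), None
        for tc in enumerate_truth_combinations(chunk):
            tp = truth_pair(chunk, tc)
            if tp is None:
                continue
            for cc in brute:
                cp = candidate_pair(chunk, cc)
                if cp is None or not equivalent(tp, cp):
                    continue
                key = (tc.positive_count, cc.read_support)
                if key > best_key:
                    best_key, best = key, (tc, cc)
        return best_key, best

    def test_matches_exhaustive_on_random_chunks(self):
        """Pruned best_match finds a match exactly when the exhaustive
        search does, with identical (positive_count, read_support)."""
        chunks = collect_chunks(30)
        assert len(chunks) >= 25
        n_matched = 0
        for chunk in chunks:
            got = best_match(chunk)
            key, exp = self._exhaustive_best(chunk)
            if exp is None:
                assert got is None
                continue
            n_matched += 1
            assert got is not None
            assert (got.truth_combination.positive_count, got.read_support) == key
            # spliced pairs must be equivalent between the two solutions
            gp = candidate_pair(chunk, got.candidate_combination)
            ep = candidate_pair(chunk, exp[1])
            assert equivalent(gp, ep)
        assert n_matched >= 15


# ---------------------------------------------------------------------------
# rescue / merge / records


class TestRescueWeak:
    def test_single_supporting_read_rescues(self):
        v = var(4, "T", "A")
        alt_read = make_read("a", "chr1", 0, [("M", 20)], "ACGAACGTACGTACGTACGT")
        ref_read = make_read("b", "chr1", 0, [("M", 20)], WINDOW)
        rescued, missing = rescue_weak([v], [alt_read, ref_read], ThresholdConfig())
        assert [x.pos for x in rescued] == [4] and missing == []
        assert rescued[0].allele_frequency == 0.5

    def test_no_support_reports_missing(self):
        v = var(4, "T", "A")
        ref_read = make_read("b", "chr1", 0, [("M", 20)], WINDOW)
        rescued, missing = rescue_weak([v], [ref_read], ThresholdConfig())
        assert rescued == [] and missing == [v]


class TestMergeOutputs:
    def test_sorted_concatenation(self):
        rel = [Variant("chr1", 30, "A", ("G",), (0, 1), allele_frequency=0.5)]
        uni = [UnifiedRecord("chr1", 10, "C", "T", (0, 1), True, "unified")]
        res = [Variant("chr1", 20, "G", ("GA",), (0, 1), allele_frequency=0.1)]
        merged = merge_outputs(rel, uni, res)
        assert [(r.pos, r.category) for r in merged] == [
            (10, "unified"), (20, "rescued"), (30, "reliable_match")
        ]

    def test_duplicate_site_across_categories_errors(self):
        rel = [Variant("chr1", 10, "C", ("T",), (0, 1))]
        uni = [UnifiedRecord("chr1", 10, "C", "T", (0, 1), True, "unified")]
        with pytest.raises(ValueError, match="categories"):
            merge_outputs(rel, uni, [])


class TestMatchToRecords:
    def test_states_map_to_genotypes(self):
        cands = [cand(4, "T", "A"), cand(9, "A", "G"), cand(15, "C", "T")]
        chunk = chunk_of([], cands)
        combo = CandidateCombination(states=("R", "het10", "hom"), index=0)
        truth_combo = enumerate_truth_combinations(chunk_of([], []))[0]
        from varunify.unify import MatchResult

        m = MatchResult(truth_combo, combo, [], 5)
        recs = match_to_records(chunk, m, phase_set=7)
        assert [(r.pos, r.genotype, r.phase_set) for r in recs] == [
            (9, (1, 0), 7), (15, (1, 1), None)
        ]
        assert all(r.category == "unified" for r in recs)


# ---------------------------------------------------------------------------
# complexity


class TestComplexityBound:
    def test_supported_count_bounded_by_coverage_not_four_to_the_m(self):
        """On seeded chunks the number of generated combinations stays at or
        below ~2x coverage (pattern pairs are limited by distinct reads) and
        far below 4^m once m >= 4."""
        for coverage in (10, 20, 40):
            chunks = [c for c in collect_chunks(10, coverage=coverage) if c.m >= 2]
            for chunk in chunks:
                supported = generate_supported_combinations(chunk)
                assert len(supported) <= max(4, 2 * coverage)
                if chunk.m >= 4:
                    assert len(supported) < 4 ** chunk.m
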