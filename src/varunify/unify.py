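"""Haplotype-equivalence unification core.

For every chunk of clustered sites, truth variants are expanded into the
Cartesian set of present/absent forms (2^n for fully phased truths) and
pileup candidates into per-site states {hom-ref, het 0|1, het 1|0, hom-alt}.
Instead of enumerating all 4^m candidate combinations, supported
combinations are constructed directly from per-haplotype read allele
patterns, so only combinations with nonzero read evidence are compared.
Truth and candidate combinations are spliced into haplotype sequence pairs
over the chunk window and matched up to haplotype-order swap; the accepted
pair maximises (fewest missing truth variants, most supporting reads).

Truth variants with no accepted match fall through to a rescue pass that
keeps any variant whose exact alternate allele is expressed by at least one
read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    CATEGORY_RELIABLE,
    CATEGORY_RESCUED,
    CATEGORY_UNIFIED,
    UNTAGGED,
    CandidateSite,
    ReadObservation,
    Region,
    ThresholdConfig,
    UnifiedRecord,
    Variant,
)

CANDIDATE_STATES = ("R", "het01", "het10", "hom")


@dataclass
class Chunk:
    """A window of clustered truth variants and candidates plus the reads
    overlapping it; ``region`` includes the flanks."""

    region: Region
    window_seq: str
    truth_variants: List[Variant]
    candidates: List[CandidateSite]
    reads: List[ReadObservation] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.truth_variants)

    @property
    def m(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class HaplotypePair:
    hap1: str
    hap2: str


@dataclass
class TruthCombination:
    """One element of the truth Cartesian set: per-variant either absent
    (None) or a present form as (hap1 allele, hap2 allele)."""

    states: Tuple[Optional[Tuple[str, str]], ...]
    index: int

    @property
    def positive_count(self) -> int:
        return sum(s is not None for s in self.states)


@dataclass
class CandidateCombination:
    """One element of the candidate Cartesian set with read support.

    ``support`` counts reads fully consistent with the haplotype-1 and
    haplotype-2 allele patterns; ``p_a`` is the fraction of chunk-overlapping
    reads consistent with either haplotype."""

    states: Tuple[str, ...]
    index: int
    support: Tuple[int, int] = (0, 0)
    p_a: float = 0.0

    @property
    def read_support(self) -> int:
        return self.support[0] + self.support[1]


@dataclass
class MatchResult:
    truth_combination: TruthCombination
    candidate_combination: CandidateCombination
    missing_truths: List[Variant]
    read_support: int
    equivalent: bool = True


# ---------------------------------------------------------------------------
# chunking


def chunk_sites(
    variants: Sequence[Variant],
    candidates: Sequence[CandidateSite],
    gap_bp: int = 100,
    flank_bp: int = 16,
    max_n: int = 12,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> List[Tuple[Region, List[Variant], List[CandidateSite]]]:
    """Greedy clustering of truth/candidate sites into chunk windows.

    Consecutive sites (of either kind) whose REF spans are closer than
    ``gap_bp`` join one chunk; groups with more than ``max_n`` truth
    variants are split at the largest internal gap.  Groups without a truth
    variant are dropped (there is nothing to unify in them).
    """
    items: List[Tuple[str, int, int, str, object]] = []
    for v in variants:
        items.append((v.chrom, v.pos - 1, v.end, "T", v))
    for c in candidates:
        items.append((c.chrom, c.pos - 1, c.end, "C", c))
    items.sort(key=lambda t: (t[0], t[1], t[2]))

    groups: List[List[Tuple[str, int, int, str, object]]] = []
    for item in items:
        if (
            groups
            and groups[-1][0][0] == item[0]
            and item[1] - max(e for _, _, e, _, _ in groups[-1]) < gap_bp
        ):
            groups[-1].append(item)
        else:
            groups.append([item])

    def split_group(group):
        truths = [it for it in group if it[3] == "T"]
        if len(truths) <= max_n:
            return [group]
        # split between the two consecutive truth variants with the widest gap
        gaps = [
            (truths[i + 1][1] - truths[i][2], i) for i in range(len(truths) - 1)
        ]
        _, i = max(gaps, key=lambda g: (g[0], -g[1]))
        cut = (truths[i][2] + truths[i + 1][1]) / 2
        left = [it for it in group if it[1] < cut]
        right = [it for it in group if it[1] >= cut]
        return split_group(left) + split_group(right)

    out: List[Tuple[Region, List[Variant], List[CandidateSite]]] = []
    for group in groups:
        for g in split_group(group):
            truths = [it[4] for it in g if it[3] == "T"]
            if not truths:
                continue
            cands = [it[4] for it in g if it[3] == "C"]
            chrom = g[0][0]
            start = max(0, min(it[1] for it in g) - flank_bp)
            end = max(it[2] for it in g) + flank_bp
            if contig_lengths is not None:
                end = min(end, contig_lengths[chrom])
            out.append((Region(chrom, start, end), truths, cands))
    return out


# ---------------------------------------------------------------------------
# combination enumeration


def _truth_forms(v: Variant) -> List[Tuple[str, str]]:
    """Present forms of a truth variant as (hap1 allele, hap2 allele).

    Phased hets contribute their one orientation; unphased hets contribute
    both; homs contribute alt/alt."""
    if not v.is_het:
        return [(v.alt, v.alt)]
    if v.phased:
        return [(v.ref, v.alt)] if v.genotype == (0, 1) else [(v.alt, v.ref)]
    return [(v.ref, v.alt), (v.alt, v.ref)]


def enumerate_truth_combinations(chunk: Chunk, max_n: int = 12) -> List[TruthCombination]:
    """All present/absent assignments over the chunk's truth variants —
    exactly 2^n when every variant is phased or homozygous."""
    if chunk.n > max_n:
        raise ValueError(f"chunk has {chunk.n} truth variants (max_n={max_n}); split it")
    options = [[None] + _truth_forms(v) for v in chunk.truth_variants]
    return [
        TruthCombination(states=states, index=i)
        for i, states in enumerate(itertools.product(*options))
    ]


def _state_alleles(c: CandidateSite, state: str) -> Tuple[str, str]:
    return {
        "R": (c.ref, c.ref),
        "het01": (c.ref, c.alt),
        "het10": (c.alt, c.ref),
        "hom": (c.alt, c.alt),
    }[state]


def enumerate_candidate_combinations_bruteforce(
    chunk: Chunk, max_m: int = 8
) -> List[CandidateCombination]:
    """The full 4^m candidate Cartesian set (oracle use only)."""
    if chunk.m > max_m:
        raise ValueError(f"chunk has {chunk.m} candidates; brute force capped at {max_m}")
    combos = [
        CandidateCombination(states=states, index=i)
        for i, states in enumerate(itertools.product(CANDIDATE_STATES, repeat=chunk.m))
    ]
    patterns = [(_read_pattern(r, chunk.candidates), r.hap_tag) for r in chunk.reads]
    for combo in combos:
        _score_combination(combo, chunk, patterns)
    return combos


def _read_pattern(
    read: ReadObservation, candidates: Sequence[CandidateSite]
) -> Tuple[Optional[int], ...]:
    """Per-candidate allele code: 0=ref, 1=alt, None=site not covered,
    -1=an allele matching neither (read cannot describe this candidate set)."""
    pat: List[Optional[int]] = []
    for c in candidates:
        allele = read.local_allele(c.pos, c.ref)
        if allele is None:
            pat.append(None)
        elif allele == c.ref:
            pat.append(0)
        elif allele == c.alt:
            pat.append(1)
        else:
            pat.append(-1)
    return tuple(pat)


def _consistent(pattern: Tuple[Optional[int], ...], hap_pattern: Tuple[int, ...]) -> bool:
    """A read is consistent with a haplotype pattern if it matches on every
    candidate site it covers (partial reads allowed, -1 never matches)."""
    return all(p is None or p == h for p, h in zip(pattern, hap_pattern))


def _combo_hap_patterns(
    combo: CandidateCombination,
) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
    h1 = tuple(1 if s in ("het10", "hom") else 0 for s in combo.states)
    h2 = tuple(1 if s in ("het01", "hom") else 0 for s in combo.states)
    return h1, h2


def _score_combination(
    combo: CandidateCombination,
    chunk: Chunk,
    patterns: Optional[List[Tuple[Tuple[Optional[int], ...], int]]] = None,
) -> None:
    if patterns is None:
        patterns = [(_read_pattern(r, chunk.candidates), r.hap_tag) for r in chunk.reads]
    h1, h2 = _combo_hap_patterns(combo)
    x1 = x2 = consistent_reads = 0
    y = len(patterns)
    for pat, tag in patterns:
        c1 = tag in (1, UNTAGGED) and _consistent(pat, h1)
        c2 = tag in (2, UNTAGGED) and _consistent(pat, h2)
        x1 += c1
        x2 += c2
        consistent_reads += c1 or c2
    combo.support = (x1, x2)
    combo.p_a = consistent_reads / y if y else 0.0


def generate_supported_combinations(chunk: Chunk) -> List[CandidateCombination]:
    """Construct candidate combinations directly from read evidence.

    For each haplotype the distinct full allele patterns over the chunk's
    candidates observed among reads eligible for that haplotype (tagged with
    it, or untagged) are collected; every (pattern_h1, pattern_h2) pair
    defines one combination.  Reads that do not span every candidate site,
    or that carry an allele outside {ref, alt} at a covered site, contribute
    to support counting but not to pattern formation.  With no overlapping
    reads the result is empty and the chunk falls through to rescue.
    """
    if not chunk.reads:
        return []
    patterns = [(_read_pattern(r, chunk.candidates), r.hap_tag) for r in chunk.reads]
    full: Dict[int, List[Tuple[int, ...]]] = {1: [], 2: []}
    for pat, tag in patterns:
        if any(p is None or p == -1 for p in pat):
            continue
        for h in (1, 2):
            if tag in (h, UNTAGGED) and pat not in full[h]:
                full[h].append(pat)  # first-seen order keeps determinism

    combos: List[CandidateCombination] = []
    seen: set[Tuple[str, ...]] = set()
    for p1 in full[1]:
        for p2 in full[2]:
            states = tuple(
                ("R", "het01", "het10", "hom")[(a1 << 1) | a2]
                for a1, a2 in zip(p1, p2)
            )
            if states in seen:
                continue
            seen.add(states)
            combos.append(CandidateCombination(states=states, index=len(combos)))
    for combo in combos:
        _score_combination(combo, chunk, patterns)
    return [c for c in combos if c.p_a > 0]


# ---------------------------------------------------------------------------
# haplotype splicing and matching


def splice(
    window_seq: str,
    window_start: int,
    entries: Sequence[Tuple[int, str, str]],
) -> Optional[str]:
    """Apply (pos, ref, allele) entries to the window (pos is 1-based).

    Entries where allele == ref contribute reference.  Returns None when two
    applied non-reference entries have overlapping REF spans (inconsistent
    combination)."""
    out: List[str] = []
    cursor = window_start
    for pos, ref, allele in sorted(entries):
        p0 = pos - 1
        if allele == ref:
            continue
        if p0 < cursor:
            return None
        if p0 < window_start or p0 + len(ref) > window_start + len(window_seq):
            return None
        out.append(window_seq[cursor - window_start : p0 - window_start])
        out.append(allele)
        cursor = p0 + len(ref)
    out.append(window_seq[cursor - window_start :])
    return "".join(out)


def apply_combination(
    window_seq: str,
    window_start: int,
    sites: Sequence[Tuple[int, str]],
    hap_alleles: Sequence[Tuple[str, str]],
) -> Optional[HaplotypePair]:
    """Splice per-haplotype alleles into the reference window; None when a
    haplotype has overlapping applied REF spans."""
    entries1 = [(pos, ref, a1) for (pos, ref), (a1, _) in zip(sites, hap_alleles)]
    entries2 = [(pos, ref, a2) for (pos, ref), (_, a2) in zip(sites, hap_alleles)]
    h1 = splice(window_seq, window_start, entries1)
    h2 = splice(window_seq, window_start, entries2)
    if h1 is None or h2 is None:
        return None
    return HaplotypePair(h1, h2)


def truth_pair(chunk: Chunk, combo: TruthCombination) -> Optional[HaplotypePair]:
    sites = [(v.pos, v.ref) for v in chunk.truth_variants]
    alleles = [
        s if s is not None else (v.ref, v.ref)
        for v, s in zip(chunk.truth_variants, combo.states)
    ]
    return apply_combination(chunk.window_seq, chunk.region.start, sites, alleles)


def candidate_pair(chunk: Chunk, combo: CandidateCombination) -> Optional[HaplotypePair]:
    sites = [(c.pos, c.ref) for c in chunk.candidates]
    alleles = [
        _state_alleles(c, s) for c, s in zip(chunk.candidates, combo.states)
    ]
    return apply_combination(chunk.window_seq, chunk.region.start, sites, alleles)


def equivalent(pair_a: HaplotypePair, pair_b: HaplotypePair) -> bool:
    """Haplotype-order-insensitive sequence equality."""
    return (pair_a.hap1 == pair_b.hap1 and pair_a.hap2 == pair_b.hap2) or (
        pair_a.hap1 == pair_b.hap2 and pair_a.hap2 == pair_b.hap1
    )


def best_match(
    chunk: Chunk,
    candidate_combinations: Optional[List[CandidateCombination]] = None,
    max_n: int = 12,
) -> Optional[MatchResult]:
    """Select, over all equivalent (truth, candidate) combination pairs, the
    one with (1) the most present truth variants, (2) the most supporting
    reads, (3) the lowest enumeration index — fully deterministic."""
    if candidate_combinations is None:
        candidate_combinations = generate_supported_combinations(chunk)
    truth_combos = enumerate_truth_combinations(chunk, max_n=max_n)
    cand_pairs = [
        (combo, candidate_pair(chunk, combo)) for combo in candidate_combinations
    ]
    best: Optional[MatchResult] = None
    best_key: Tuple[int, int] = (-1, -1)
    for tc in truth_combos:
        tp = truth_pair(chunk, tc)
        if tp is None:
            continue
        for cc, cp in cand_pairs:
            if cp is None or not equivalent(tp, cp):
                continue
            key = (tc.positive_count, cc.read_support)
            if key > best_key:
                best_key = key
                missing = [
                    v
                    for v, s in zip(chunk.truth_variants, tc.states)
                    if s is None
                ]
                best = MatchResult(
                    truth_combination=tc,
                    candidate_combination=cc,
                    missing_truths=missing,
                    read_support=cc.read_support,
                )
    return best


# ---------------------------------------------------------------------------
# rescue and merge


def rescue_weak(
    unmatched_truths: Sequence[Variant],
    reads: Sequence[ReadObservation],
    config: ThresholdConfig,
) -> Tuple[List[Variant], List[Variant]]:
    """Rescue truths whose exact alternate allele is expressed by at least
    one read (no AF or coverage threshold); returns (rescued, missing).
    Rescued variants carry their observed allele frequency."""
    rescued: List[Variant] = []
    missing: List[Variant] = []
    for v in unmatched_truths:
        supporting = depth = 0
        for r in reads:
            if r.chrom != v.chrom or not r.covers(v.pos, v.ref):
                continue
            depth += 1
            if r.local_allele(v.pos, v.ref) == v.alt:
                supporting += 1
        if supporting >= 1:
            rescued.append(replace(v, allele_frequency=supporting / depth))
        else:
            missing.append(v)
    return rescued, missing


def merge_outputs(
    reliable: Sequence[Variant],
    unified: Sequence[UnifiedRecord],
    rescued: Sequence[Variant],
) -> List[UnifiedRecord]:
    """Concatenate the three output categories into one sorted record list;
    a site appearing in two categories violates the partition and errors."""
    records: List[UnifiedRecord] = []
    for v in reliable:
        records.append(_variant_record(v, CATEGORY_RELIABLE))
    records.extend(unified)
    for v in rescued:
        records.append(_variant_record(v, CATEGORY_RESCUED))
    seen: Dict[Tuple[str, int, str, str], str] = {}
    for r in records:
        key = (r.chrom, r.pos, r.ref, r.alt)
        if key in seen:
            raise ValueError(
                f"site {key} appears in categories {seen[key]} and {r.category}"
            )
        seen[key] = r.category
    records.sort(key=UnifiedRecord.sort_key)
    return records


def _variant_record(v: Variant, category: str) -> UnifiedRecord:
    return UnifiedRecord(
        chrom=v.chrom,
        pos=v.pos,
        ref=v.ref,
        alt=v.alt,
        genotype=v.genotype,
        phased=v.phased,
        category=category,
        allele_frequency=v.allele_frequency,
        phase_set=v.phase_set,
    )


def match_to_records(
    chunk: Chunk,
    match: MatchResult,
    phase_set: Optional[int] = None,
) -> List[UnifiedRecord]:
    """Adopted candidates of an accepted match as unified output records."""
    out: List[UnifiedRecord] = []
    for c, state in zip(chunk.candidates, match.candidate_combination.states):
        if state == "R":
            continue
        gt = {"het01": (0, 1), "het10": (1, 0), "hom": (1, 1)}[state]
        out.append(
            UnifiedRecord(
                chrom=c.chrom,
                pos=c.pos,
                ref=c.ref,
                alt=c.alt,
                genotype=gt,
                phased=True,
                category=CATEGORY_UNIFIED,
                allele_frequency=c.af,
                phase_set=phase_set if state != "hom" else None,
            )
        )
    return out
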