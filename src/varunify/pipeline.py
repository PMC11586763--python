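"""Pipeline orchestration: phase -> haplotag -> discover -> mask -> chunk ->
unify -> rescue -> merge, with optional multiprocess fan-out over chunks.

The output is deterministic for fixed inputs regardless of the worker
count: chunks are processed independently and merged in coordinate order.
"""

from __future__ import annotations

import bisect
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import alnio, vcfio
from .discovery import discover_candidates, mask_reliable_matches, pileup_counts
from .model import (
    Region,
    ReadObservation,
    ThresholdConfig,
    UnifiedRecord,
    Variant,
    split_multiallelic,
)
from .phasing import PhasingResult, apply_phasing, haplotag_reads, phase_variants
from .unify import (
    Chunk,
    best_match,
    chunk_sites,
    match_to_records,
    merge_outputs,
    rescue_weak,
)


@dataclass
class RunConfig:
    vcf: str
    alignments: str
    reference: str
    output: Optional[str] = None
    bed: Optional[str] = None
    platform: str = "pacbio"
    thresholds: Optional[ThresholdConfig] = None
    gap_bp: int = 100
    flank_bp: int = 16
    max_n: int = 12
    disable_phasing: bool = False
    allow_genotype_switch: bool = False
    processes: int = 1
    seed: int = 0

    def resolved_thresholds(self) -> ThresholdConfig:
        if self.thresholds is not None:
            return self.thresholds
        return ThresholdConfig.for_platform(self.platform)


@dataclass
class PipelineSummary:
    """Per-category truth accounting (mirrors the unified-result analysis):
    reliable + unified + rescued + insufficient == total truths."""

    total_candidates: int = 0
    total_truths: int = 0
    reliable: int = 0
    truths_to_unify: int = 0
    unified: int = 0
    rescued: int = 0
    insufficient: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


class ReadIndex:
    """Per-contig coordinate index over reads for interval queries."""

    def __init__(self, reads: Sequence[ReadObservation]):
        self._by_chrom: Dict[str, Tuple[List[int], List[ReadObservation], int]] = {}
        tmp: Dict[str, List[ReadObservation]] = {}
        for r in reads:
            tmp.setdefault(r.chrom, []).append(r)
        for chrom, rs in tmp.items():
            rs.sort(key=lambda r: (r.start, r.read_id))
            starts = [r.start for r in rs]
            max_len = max((r.end - r.start) for r in rs)
            self._by_chrom[chrom] = (starts, rs, max_len)

    def overlapping(self, region: Region) -> List[ReadObservation]:
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return []
        starts, rs, max_len = entry
        lo = bisect.bisect_left(starts, region.start - max_len)
        hi = bisect.bisect_right(starts, region.end)
        return [r for r in rs[lo:hi] if r.start < region.end and r.end > region.start]


def _process_chunk(args) -> Tuple[Region, List[UnifiedRecord], List[Variant], int]:
    """Unify one chunk; returns (region, unified records, unmatched truths,
    truths adopted)."""
    chunk, max_n = args
    match = best_match(chunk, max_n=max_n)
    if match is None:
        return (chunk.region, [], list(chunk.truth_variants), 0)
    phase_set = None
    for v in chunk.truth_variants:
        if v.phase_set is not None:
            phase_set = v.phase_set
            break
    if phase_set is None:
        phase_set = chunk.region.start + 1
    records = match_to_records(chunk, match, phase_set=phase_set)
    adopted = match.truth_combination.positive_count
    return (chunk.region, records, match.missing_truths, adopted)


def run_pipeline(
    config: RunConfig,
) -> Tuple[List[UnifiedRecord], PipelineSummary]:
    """Run the full unification pipeline; writes the output VCF when
    ``config.output`` is set and returns (records, summary)."""
    thresholds = config.resolved_thresholds()
    reference = vcfio.read_fasta(config.reference)
    regions = vcfio.read_bed(config.bed) if config.bed else None
    variants = vcfio.read_vcf(config.vcf, region_filter=regions)
    reads = alnio.read_alignments(config.alignments)

    for v in variants:
        if v.chrom not in reference:
            raise ValueError(f"VCF contig {v.chrom!r} absent from reference")
    for r in reads:
        if r.chrom not in reference:
            raise ValueError(f"alignment contig {r.chrom!r} absent from reference")

    variants = split_multiallelic(variants)
    total_truths = len(variants)

    # Step 1: phasing and haplotagging
    hets = [v for v in variants if v.is_het and len(v.alts) == 1]
    if config.disable_phasing:
        phasing = None
        reads = [ReadObservation(r.read_id, r.chrom, r.start, r.cigar, r.sequence) for r in reads]
    elif hets and all(v.phased for v in hets):
        # pre-phased input: adopt its phase, skip the phasing stage
        phasing = PhasingResult()
        for v in hets:
            phasing.orientations[v.site_key()] = 0 if v.genotype == (0, 1) else 1
            phasing.phase_sets[v.site_key()] = (
                v.phase_set if v.phase_set is not None else 1
            )
        reads = haplotag_reads(phasing, hets, reads, reference)
    else:
        phasing = phase_variants(
            hets,
            reads,
            allow_genotype_switch=config.allow_genotype_switch,
            reference=reference,
        )
        reads = haplotag_reads(phasing, hets, reads, reference)
        variants = apply_phasing(variants, phasing)
        total_truths = len(variants)

    # candidate discovery over each contig touched by reads
    candidates = []
    read_index = ReadIndex(reads)
    for chrom in sorted({r.chrom for r in reads}):
        region = Region(chrom, 0, len(reference[chrom]))
        counts = pileup_counts([r for r in reads if r.chrom == chrom], region, reference)
        candidates.extend(discover_candidates(counts, thresholds))
    if regions is not None:
        candidates = [
            c for c in candidates if any(r.contains(c.chrom, c.pos - 1) for r in regions)
        ]

    # Step 2: masking and chunked unification
    reliable, remaining_v, remaining_c = mask_reliable_matches(
        variants, candidates, thresholds.epsilon
    )
    contig_lengths = {name: len(seq) for name, seq in reference.items()}
    chunk_specs = chunk_sites(
        remaining_v,
        remaining_c,
        gap_bp=config.gap_bp,
        flank_bp=config.flank_bp,
        max_n=config.max_n,
        contig_lengths=contig_lengths,
    )
    chunks = [
        Chunk(
            region=region,
            window_seq=reference[region.chrom][region.start : region.end],
            truth_variants=truths,
            candidates=cands,
            reads=read_index.overlapping(region),
        )
        for region, truths, cands in chunk_specs
    ]

    tasks = [(chunk, config.max_n) for chunk in chunks]
    if config.processes > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=config.processes) as pool:
            results = list(pool.map(_process_chunk, tasks, chunksize=8))
    else:
        results = [_process_chunk(t) for t in tasks]
    results.sort(key=lambda r: (r[0].chrom, r[0].start))

    unified_records: List[UnifiedRecord] = []
    unmatched: List[Variant] = []
    truths_adopted = 0
    for _, records, missing, adopted in results:
        unified_records.extend(records)
        unmatched.extend(missing)
        truths_adopted += adopted

    # Step 3: rescue and merge
    rescued, missing = [], []
    for v in unmatched:
        r, m = rescue_weak([v], read_index.overlapping(Region(v.chrom, max(0, v.pos - 1), v.end)), thresholds)
        rescued.extend(r)
        missing.extend(m)

    records = merge_outputs(reliable, unified_records, rescued)
    summary = PipelineSummary(
        total_candidates=len(candidates),
        total_truths=total_truths,
        reliable=len(reliable),
        truths_to_unify=len(remaining_v),
        unified=truths_adopted,
        rescued=len(rescued),
        insufficient=len(missing),
    )
    if config.output:
        vcfio.write_vcf(
            records,
            config.output,
            contigs=contig_lengths,
            low_qual_af=thresholds.low_qual_af,
        )
    return records, summary
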