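"""Shared fixtures: tiny synthetic genomes, reads, and random chunks."""

from __future__ import annotations

import numpy as np
import pytest

from varunify import (
    Chunk,
    Region,
    SimConfig,
    ThresholdConfig,
    discover_candidates,
    haplotag_reads,
    mask_reliable_matches,
    phase_variants,
    pileup_counts,
    rerepresent_vcf,
    simulate_reads,
    simulate_truth,
)
from varunify.model import ReadObservation, Variant
from varunify.unify import chunk_sites


def make_read(
    read_id: str,
    chrom: str,
    start: int,
    cigar,
    sequence: str,
    hap: int = 0,
) -> ReadObservation:
    return ReadObservation(
        read_id=read_id,
        chrom=chrom,
        start=start,
        cigar=tuple(cigar),
        sequence=sequence,
        hap_tag=hap,
    )


@pytest.fixture(scope="session")
def small_sim():
    """20 kb clean diploid simulation shared across tests."""
    cfg = SimConfig(genome_length=20_000, seed=11, coverage=30, read_length=1_000)
    truth = simulate_truth(cfg)
    reads = simulate_reads(truth, cfg)
    return cfg, truth, reads


def make_random_chunk(seed: int, coverage: int = 20, error_rate: float = 0.0):
    """A small realistic chunk: clustered truth variants on a short genome,
    full-span reads, pileup-derived candidates, phased and haplotagged.

    Returns None when the draw yields no usable cluster (caller skips the
    seed), otherwise a Chunk with n<=5 truths and m<=5 candidates whose
    truth set is the *re-represented* VCF (so truth and candidate
    representations genuinely differ).
    """
    cfg = SimConfig(
        genome_length=400,
        snp_rate=8e-3,
        indel_rate=4e-3,
        cluster_fraction=1.0,
        coverage=coverage,
        read_length=400,
        error_rate=error_rate,
        seed=seed,
    )
    truth = simulate_truth(cfg)
    if not truth.variants:
        return None
    reads = simulate_reads(truth, cfg)
    rerep = rerepresent_vcf(truth.variants, truth.reference, seed=seed)

    hets = [v for v in rerep if v.is_het]
    phasing = phase_variants(hets, reads)
    tagged = haplotag_reads(phasing, hets, reads)
    from varunify.phasing import apply_phasing

    variants = apply_phasing(rerep, phasing)

    chrom = truth.chrom
    region = Region(chrom, 0, cfg.genome_length)
    counts = pileup_counts(tagged, region, truth.reference)
    candidates = discover_candidates(counts, ThresholdConfig())
    _, remaining_v, remaining_c = mask_reliable_matches(variants, candidates)
    specs = chunk_sites(
        remaining_v, remaining_c, contig_lengths={chrom: cfg.genome_length}
    )
    for reg, truths, cands in specs:
        if 1 <= len(truths) <= 5 and len(cands) <= 5:
            return Chunk(
                region=reg,
                window_seq=truth.reference[chrom][reg.start : reg.end],
                truth_variants=truths,
                candidates=cands,
                reads=[r for r in tagged if r.start < reg.end and r.end > reg.start],
            )
    return None
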