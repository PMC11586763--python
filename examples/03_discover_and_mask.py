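"""Discover candidate alleles from the read pileup, then mask the truth
variants whose representation the alignments already agree with (the
"reliable matches") — only the remainder needs combinatorial unification."""

from varunify import (
    Region,
    SimConfig,
    ThresholdConfig,
    discover_candidates,
    mask_reliable_matches,
    pileup_counts,
    rerepresent_vcf,
    simulate_reads,
    simulate_truth,
)

cfg = SimConfig(genome_length=30_000, seed=3)
truth = simulate_truth(cfg)
reads = simulate_reads(truth, cfg)
query = rerepresent_vcf(truth.variants, truth.reference, seed=3)

region = Region(truth.chrom, 0, cfg.genome_length)
counts = pileup_counts(reads, region, truth.reference)

thresholds = ThresholdConfig.for_platform("pacbio")  # SNP AF >= 0.08 etc.
candidates = discover_candidates(counts, thresholds)
print(f"{len(candidates)} candidate alleles pass AF/coverage thresholds")

reliable, remaining_v, remaining_c = mask_reliable_matches(
    query, candidates, epsilon=thresholds.epsilon
)
print(f"{len(reliable)} query variants are reliable matches "
      f"(identical representation, AF inside the epsilon window)")
print(f"{len(remaining_v)} variants and {len(remaining_c)} candidates "
      f"continue to chunked unification")
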