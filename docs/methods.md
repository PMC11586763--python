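# Methods

This note describes the algorithm precisely enough to re-derive the
implementation. Notation: the input VCF contains *truth variants*
(the set whose representation we want to rewrite); alleles observed in the
reads are *candidates*; a diploid *haplotype pair* is an unordered pair of
sequences over a genomic window.

## 1. Problem statement

Two variant sets are **haplotype-equivalent** over a window if splicing each
set into the reference yields the same pair of haplotype sequences (up to
swapping the two haplotypes). The unifier's job: given truth variants, reads
and the reference, output a variant set that is haplotype-equivalent to a
maximal subset of the truth variants while using only representations the
reads express, and report which truth variants could not be supported.

## 2. Phasing and haplotagging

Heterozygous truth variants are phased from read co-occurrence:

- **Allele codes.** For each read × het variant, the read's expressed
  sequence over a padded window (variant REF span ± 10 bp) is extracted by
  walking the CIGAR. It is compared to the REF-spliced and ALT-spliced
  versions of the same window; an unambiguous match yields code 0 or 1,
  anything else is unknown. The windowed comparison (rather than exact
  anchor-base matching) makes codes robust when the VCF's representation is
  shifted or merged relative to the read's alignment. A read must extend
  strictly beyond the window to vote — a read ending at the window's last
  base cannot exclude a trailing insertion.
- **Graph phasing.** Variants sharing informative reads form components
  (union–find). Within a component, each read pair-votes cis/trans for each
  variant pair; a greedy orientation pass followed by single-flip refinement
  minimizes the **minimum error correction (MEC)** score: the smallest
  number of allele-code flips needed so every read is consistent with one of
  the two haplotypes. Each component becomes a phase set; orientation 0
  means genotype `0|1`.
- **Haplotagging.** Each read is assigned haplotype 1 or 2 by majority vote
  of its allele codes against the phased haplotypes; ties and uninformative
  reads stay untagged.

`compute_mec` is verified in tests against brute force over all
2^(#variants) orientations × 2^(#reads) read assignments.

## 3. Candidate discovery and thresholds

A pileup over the region collects, per site, reference-allele counts and
counts for each distinct SNP/insertion/deletion allele expressed by the
reads (indels use an anchor base, matching VCF convention). A candidate is
kept when site coverage ≥ `min_coverage` and allele frequency
AF = support/coverage ≥ the per-type threshold:

| platform | SNP AF | indel AF | min coverage | ε | LowQual AF |
| --- | --- | --- | --- | --- | --- |
| `pacbio` | 0.08 | 0.15 | 4 | 0.10 | 0.08 |
| `ilmn`   | 0.08 | 0.15 | 4 | 0.10 | 0.08 |
| `ont`    | 0.15 | 0.15 | 4 | 0.10 | 0.08 |

**Reliable-match masking.** A truth variant whose normalized alleles
(common suffix then prefix trimmed) equal a candidate's, and whose AF is
consistent with its genotype — AF ∈ [0.5 − ε, 0.5 + ε] (closed) for hets,
AF > 1 − ε (strict) for homs — is emitted unchanged as `reliable_match` and
removed, along with the candidate, before chunking. Output records with
AF < the LowQual cutoff are flagged `LowQual`.

## 4. Chunked combination matching

Remaining truth variants and candidates are merged into position-sorted
sites and split into **chunks**: a new chunk starts when the gap to the
previous site is ≥ 100 bp (configurable). Each chunk is processed over a
window padded by a 16 bp flank. Chunks exceeding `max_variants_per_chunk`
are reported insufficient rather than truncated.

- **Truth combinations.** Every subset of the chunk's n truth variants
  (2^n); phased hets contribute their phased orientation, unphased hets both
  orientations.
- **Candidate combinations.** Each of the m candidates can take one of four
  states — absent, het `0|1`, het `1|0`, hom `1|1` — giving 4^m in
  principle. Instead of enumerating them, supported combinations are
  **generated from read evidence**: every read that fully covers all m
  candidates with a known 0/1 code at each contributes an m-bit allele
  pattern to the haplotype(s) it is tagged to (untagged reads to both).
  Distinct (hap1 pattern, hap2 pattern) pairs define the combinations;
  partially covering reads add support weight only. Combinations with zero
  reliability weight are dropped.

  With error-free reads that each fully cover the chunk, this generated set
  is **provably identical** to the brute-force 4^m set filtered to
  combinations with read support on both haplotypes — the property the test
  suite and acceptance script check exhaustively on hundreds of random
  chunks. Its size grows with the number of distinct patterns per haplotype
  (bounded by coverage), not with 4^m.
- **Matching.** A (truth combination, candidate combination) pair matches
  when their spliced haplotype pairs over the padded window are equal up to
  swap. `best_match` scores matches lexicographically: most truth variants
  retained, then most read support, then lowest enumeration index (for
  determinism). Truth variants absent from the winning combination but
  individually supported by at least one read are **rescued** and re-emitted
  in their original representation.
- **Merge.** Per-chunk results are concatenated in genomic order; the output
  records carry category `reliable_match` / `unified` / `rescued`, phase-set
  and genotype information, and the summary partition satisfies
  `reliable + unified + rescued + insufficient == total truth variants`.

## 5. Benchmarking comparator

`compare_sites` matches normalized (site, alleles, genotype) records and
tabulates TP/FP/FN per category (Overall, SNP, Indel, Insertion, Deletion)
with precision, recall and F1 = 2PR/(P+R) in percent (NaN when undefined).
`haplotype_metrics` instead splices query and truth into haplotype pairs
over well-separated site groups and scores each group's pairwise equality —
representation-invariant, so an equivalently re-represented VCF scores
precision = recall = 100.

## 6. Simulator

`simulate_truth` draws per-locus SNP (default 1e-3) and indel (2e-4) counts
from Binomial(L, rate), places a configurable fraction (30%) in clusters of
2–3 within 20 bp, biases insertions toward homopolymers, and assigns random
phased genotypes. `simulate_reads` tiles both haplotypes to the target
coverage with optional uniform substitution errors; reads carry their
alignment back to reference coordinates, so no aligner is needed (a real
BAM can still be written). `rerepresent_vcf` rewrites a random subset of
records by indel shifting within repeat context, merging nearby variants
(gap ≤ 10 bp) into complex alleles, or decomposing MNPs — every rewrite is
verified by splicing to leave both haplotypes byte-identical.

## 7. Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; worker seeds are derived arithmetically and kept
below 2^31. Chunk results are sorted by region before merging, so output is
byte-identical across repeated runs and across `--processes` values — this
is asserted by tests and the acceptance script.
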