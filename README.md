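# varunify

Haplotype-aware unification of small-variant representations against
sequencing alignments.

The same underlying mutation can be written in a VCF in many equivalent
ways — an indel left-shifted to a different anchor, two adjacent SNPs merged
into one MNP record, a complex allele decomposed into pieces. When the
variants in a VCF and the variants expressed by a sample's alignments encode
the same haplotype sequences but in different representations, naive
site-level comparison and downstream tools report spurious mismatches.

`varunify` rewrites each variant in an input VCF into **the representation
the alignments actually express**, without running a variant caller. It:

1. **Phases** heterozygous variants from read co-occurrence (minimum error
   correction) and **haplotags** each read.
2. **Discovers** candidate alleles directly from the read pileup, with
   platform-specific allele-frequency and coverage thresholds.
3. **Masks reliable matches** — input variants whose normalized
   representation is already present among the candidates with a consistent
   allele frequency — so only the disagreeing remainder is processed further.
4. Splits the remainder into **chunks** of nearby variants and, per chunk,
   enumerates truth combinations (present/absent per variant) against
   candidate combinations (absent / het `0|1` / het `1|0` / hom per
   candidate). Candidate combinations are **generated from read evidence**
   rather than by brute force, so the search stays near-linear in coverage
   instead of exponential in candidate count.
5. Declares a match when the **spliced haplotype-pair sequences are
   identical** (up to haplotype swap), preferring matches that keep the most
   variants and have the most read support, and **rescues** weakly supported
   variants that no candidate explains.
6. Emits a unified VCF whose records are tagged `reliable_match`,
   `unified`, or `rescued`, with `LowQual` filters for low-frequency sites,
   plus summary counts.

It also ships a site- and haplotype-level **benchmarking comparator** and a
**synthetic diploid simulator** that produces a reference, a truth VCF, an
equivalent re-represented VCF, and reads — everything needed to exercise the
pipeline end to end.

## Quickstart (CLI)

```bash
# 1. make a synthetic fixture: 100 kb reference, truth VCF, a VCF of the
#    same haplotypes in shifted/merged/decomposed representations, and reads
varunify simulate --outdir fixture --seed 7

# 2. rewrite the re-represented VCF into what the reads express
varunify unify \
    --vcf fixture/rerepresented.vcf \
    --alignments fixture/reads.aln.tsv \
    --reference fixture/reference.fa \
    --output fixture/unified.vcf

# 3. compare: before unification the representations disagree at many
#    sites; after unification they match the truth exactly
varunify get-overall-metrics --query fixture/unified.vcf --truth fixture/truth.vcf
```

`--alignments` accepts a BAM/CRAM (via pysam) or the package's plain-text
alignment fixture format; `varunify simulate --bam` writes a real BAM too.
Thresholds default to the PacBio profile (`--platform ont|pacbio|ilmn`) and
every cutoff can be overridden individually.

## Quickstart (library)

```python
from varunify import SimConfig, rerepresent_vcf, simulate_reads, simulate_truth
from varunify.metrics import haplotype_metrics

cfg = SimConfig(genome_length=50_000, seed=9)
truth = simulate_truth(cfg)
reads = simulate_reads(truth, cfg)
query = rerepresent_vcf(truth.variants, truth.reference, seed=9)

# the query encodes the same haplotypes, so the haplotype-level comparator
# already scores it perfectly even though site representations differ
precision, recall = haplotype_metrics(query, truth.variants, truth.reference)
assert precision == recall == 100.0
```

The full pipeline is one call:

```python
from varunify.pipeline import RunConfig, run_pipeline

records, summary = run_pipeline(RunConfig(
    vcf="fixture/rerepresented.vcf",
    alignments="fixture/reads.aln.tsv",
    reference="fixture/reference.fa",
    output="fixture/unified.vcf",
))
print(summary.as_dict())   # reliable / unified / rescued / insufficient counts
```

Lower-level building blocks (`phase_variants`, `haplotag_reads`,
`pileup_counts`, `discover_candidates`, `mask_reliable_matches`,
`chunk_sites`, `generate_supported_combinations`, `best_match`, …) are all
importable; see `examples/` for a short narrative script per capability:

| script | shows |
| --- | --- |
| `examples/01_simulate_fixture.py` | simulator + splice self-check |
| `examples/02_phase_and_haplotag.py` | phasing, MEC, haplotagging |
| `examples/03_discover_and_mask.py` | pileup discovery and reliable-match masking |
| `examples/04_unify_pipeline.py` | full file-to-file pipeline |
| `examples/05_benchmark_metrics.py` | site-level vs haplotype-level comparison |

## Algorithm notes

See [`docs/methods.md`](docs/methods.md) for a precise description of the
matching objective, the read-evidence pruning and its exactness conditions,
the threshold tables, and determinism guarantees.

## Testing

```bash
pytest -q                                   # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch (pruned-vs-exhaustive agreement, simulator round-trip
precision/recall, MEC correctness, pruning growth envelope, metric worked
examples, determinism) and writes them as JSON.

## License

MIT
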