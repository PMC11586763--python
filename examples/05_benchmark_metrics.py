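"""Benchmark a query VCF against a truth VCF.

Two comparators: the strict site-level table (right after unification, when
representations agree) and the haplotype-level comparison (robust to
representation differences — it splices both sets into haplotype sequences
and compares those)."""

from varunify import SimConfig, rerepresent_vcf, simulate_truth
from varunify.metrics import (
    compare_sites,
    f1_score,
    haplotype_metrics,
    metrics_table,
)

cfg = SimConfig(genome_length=50_000, seed=9)
truth = simulate_truth(cfg)
query = rerepresent_vcf(truth.variants, truth.reference, seed=9)

# site-level: representation differences read as FP+FN
counts = compare_sites(query, truth.variants)
print(metrics_table(counts))

# haplotype-level: the same query is perfect, because it encodes the same
# haplotype sequences
precision, recall = haplotype_metrics(query, truth.variants, truth.reference)
print(f"haplotype-level precision={precision} recall={recall} "
      f"F1={f1_score(precision, recall)}")
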