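"""Run the full unification pipeline on files, end to end:
phase -> haplotag -> discover -> mask -> chunked matching -> rescue.

The output VCF rewrites each input variant into the representation the
alignments express, tagged reliable_match / unified / rescued."""

import os
import tempfile

from varunify import SimConfig, rerepresent_vcf, simulate_reads, simulate_truth
from varunify import alnio, vcfio
from varunify.pipeline import RunConfig, run_pipeline

cfg = SimConfig(seed=5)  # 100 kb, 30x error-free reads
truth = simulate_truth(cfg)
reads = simulate_reads(truth, cfg)
query = rerepresent_vcf(truth.variants, truth.reference, seed=5)

workdir = tempfile.mkdtemp()
paths = {name: os.path.join(workdir, name) for name in
         ("query.vcf", "reads.tsv", "ref.fa", "unified.vcf")}
vcfio.write_variants_vcf(query, paths["query.vcf"], {truth.chrom: cfg.genome_length})
alnio.write_fixture(reads, paths["reads.tsv"])
vcfio.write_fasta(truth.reference, paths["ref.fa"])

records, summary = run_pipeline(RunConfig(
    vcf=paths["query.vcf"],
    alignments=paths["reads.tsv"],
    reference=paths["ref.fa"],
    output=paths["unified.vcf"],
))

for key, value in summary.as_dict().items():
    print(f"{key}\t{value}")
print(f"unified VCF written to {paths['unified.vcf']}")

# equivalent CLI invocation:
#   varunify unify --vcf query.vcf --alignments reads.tsv \
#       --reference ref.fa --output unified.vcf
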