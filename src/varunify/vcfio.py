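"""VCF, FASTA and BED input/output.

VCF is read and written through :mod:`pysam`; output records carry
``FILTER`` (PASS/LowQual), an ``INFO/CATEGORY`` key naming how the variant
was resolved (reliable_match / unified / rescued), ``INFO/AF`` and a phased
``GT`` (+ ``PS``) where phase is known.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import pysam
from pyfaidx import Fasta

from .model import Region, UnifiedRecord, Variant


class VcfParseError(ValueError):
    """Raised when a VCF body record cannot be parsed; names the record."""


def read_vcf(path: str, region_filter: Optional[Sequence[Region]] = None) -> list[Variant]:
    """Read a VCF into :class:`Variant` records, sorted by (chrom, pos).

    Multiallelic records are preserved; phase (``|`` vs ``/``) and the PS tag
    are preserved.  ``region_filter`` keeps only records whose POS falls in
    one of the given 0-based half-open regions.
    """
    variants: list[Variant] = []
    with pysam.VariantFile(path) as vf:
        sample = vf.header.samples[0] if list(vf.header.samples) else None
        for i, rec in enumerate(vf.fetch() if vf.index is not None else vf):
            try:
                variants.append(_record_to_variant(rec, sample))
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise VcfParseError(
                    f"{path}: malformed VCF body record {i + 1} "
                    f"(~{rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    if region_filter is not None:
        variants = [
            v
            for v in variants
            if any(r.contains(v.chrom, v.pos - 1) for r in region_filter)
        ]
    variants.sort(key=Variant.sort_key)
    return variants


def _record_to_variant(rec, sample: Optional[str]) -> Variant:
    if rec.alts is None:
        raise ValueError("record has no ALT allele")
    if sample is None:
        raise ValueError("VCF has no sample column")
    call = rec.samples[sample]
    gt = call.get("GT")
    if gt is None or len(gt) != 2 or any(g is None for g in gt):
        raise ValueError(f"missing or non-diploid GT {gt!r}")
    phase_set = call.get("PS")
    af = rec.info.get("AF")
    if isinstance(af, tuple):
        af = af[0]
    return Variant(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref.upper(),
        alts=tuple(a.upper() for a in rec.alts),
        genotype=(gt[0], gt[1]),
        phased=bool(call.phased),
        phase_set=phase_set,
        allele_frequency=float(af) if af is not None else None,
    )


def _build_header(contigs: Mapping[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.filters.add("LowQual", None, None, "Allele frequency below the low-quality cutoff")
    header.info.add("CATEGORY", 1, "String", "Resolution category: reliable_match, unified or rescued")
    header.info.add("AF", "A", "Float", "Alternate allele frequency observed in the alignment")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.add_sample(sample)
    return header


def write_vcf(
    records: Sequence[UnifiedRecord],
    path: str,
    contigs: Mapping[str, int],
    sample: str = "SAMPLE",
    low_qual_af: float = 0.08,
) -> None:
    """Write unified records to a VCF; requires coordinate-sorted input."""
    keys = [r.sort_key() for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be coordinate-sorted")
    header = _build_header(contigs, sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref, r.alt),
                filter=r.filter_status(low_qual_af),
            )
            rec.info["CATEGORY"] = r.category
            if r.allele_frequency is not None:
                rec.info["AF"] = (round(r.allele_frequency, 4),)
            rec.samples[sample]["GT"] = r.genotype
            rec.samples[sample].phased = r.phased
            if r.phase_set is not None:
                rec.samples[sample]["PS"] = r.phase_set
            out.write(rec)


def read_unified_vcf(path: str) -> list[UnifiedRecord]:
    """Read back a VCF written by :func:`write_vcf` (field-level round trip)."""
    out: list[UnifiedRecord] = []
    with pysam.VariantFile(path) as vf:
        sample = vf.header.samples[0]
        for rec in vf:
            call = rec.samples[sample]
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            out.append(
                UnifiedRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alt=rec.alts[0].upper(),
                    genotype=tuple(call["GT"]),
                    phased=bool(call.phased),
                    category=rec.info["CATEGORY"],
                    allele_frequency=float(af) if af is not None else None,
                    phase_set=call.get("PS"),
                )
            )
    return out


def write_variants_vcf(
    variants: Sequence[Variant],
    path: str,
    contigs: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write plain :class:`Variant` records (e.g. a simulated truth set)."""
    header = _build_header(contigs, sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=Variant.sort_key):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref,) + v.alts, filter="PASS"
            )
            if v.allele_frequency is not None:
                rec.info["AF"] = (round(v.allele_frequency, 4),)
            rec.samples[sample]["GT"] = v.genotype
            rec.samples[sample].phased = v.phased
            if v.phase_set is not None:
                rec.samples[sample]["PS"] = v.phase_set
            out.write(rec)


# ---------------------------------------------------------------------------
# BED and FASTA helpers


def read_bed(path: str) -> list[Region]:
    """3-column BED (0-based half-open) into regions."""
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(Region(chrom, int(start), int(end)))
    return regions


def write_bed(regions: Sequence[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_fasta(path: str) -> dict[str, str]:
    """Whole contigs into memory (intended for small references)."""
    with Fasta(path) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    # a .fai-style index lets pyfaidx/pysam fetch by region
    try:
        pysam.faidx(path)
    except pysam.SamtoolsError:
        pass
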