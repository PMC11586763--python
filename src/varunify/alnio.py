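"""Alignment input/output.

Two dialects map onto the same :class:`~varunify.model.ReadObservation`
contract:

* standard BAM/CRAM through :mod:`pysam`, with the haplotype taken from the
  ``HP`` integer tag (1 or 2; absent = untagged);
* a plain-text tab-separated fixture dialect so the test suite runs without
  binary files::

      # read_id  chrom  pos(1-based)  CIGAR  sequence  [hap]

  ``hap`` is 0 (untagged, default), 1 or 2.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .model import UNTAGGED, ReadObservation, Region

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# pysam numeric op codes -> characters
_PYSAM_OPS = "MIDNSHP=XB"


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    for op, _ in ops:
        if op in ("N", "P", "B"):
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return tuple(ops)


def format_cigar(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def read_alignments(
    path: str,
    region: Optional[Region] = None,
    phased_only: bool = False,
) -> list[ReadObservation]:
    """Read BAM/CRAM (by extension) or the text fixture dialect.

    ``region`` keeps reads overlapping the interval; ``phased_only`` drops
    untagged reads.
    """
    if path.endswith((".bam", ".cram")):
        reads = _read_bam(path, region)
    else:
        reads = _read_fixture(path, region)
    if phased_only:
        reads = [r for r in reads if r.hap_tag != UNTAGGED]
    return reads


def _overlaps(read: ReadObservation, region: Optional[Region]) -> bool:
    if region is None:
        return True
    return (
        read.chrom == region.chrom
        and read.start < region.end
        and read.end > region.start
    )


def _read_fixture(path: str, region: Optional[Region]) -> list[ReadObservation]:
    reads: list[ReadObservation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 6):
                raise ValueError(f"{path}:{ln}: expected 5 or 6 tab-separated fields")
            read_id, chrom, pos, cigar, seq = fields[:5]
            hap = int(fields[5]) if len(fields) == 6 else UNTAGGED
            obs = ReadObservation(
                read_id=read_id,
                chrom=chrom,
                start=int(pos) - 1,
                cigar=parse_cigar(cigar),
                sequence=seq.upper(),
                hap_tag=hap,
            )
            if _overlaps(obs, region):
                reads.append(obs)
    return reads


def _read_bam(path: str, region: Optional[Region]) -> list[ReadObservation]:
    reads: list[ReadObservation] = []
    with pysam.AlignmentFile(path) as bam:
        if region is not None:
            if not bam.has_index():
                raise FileNotFoundError(f"{path}: region queries require an index")
            it = bam.fetch(region.chrom, region.start, region.end)
        else:
            it = bam.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cigar = tuple(
                (_PYSAM_OPS[op], n) for op, n in (aln.cigartuples or ())
            )
            hp = aln.get_tag("HP") if aln.has_tag("HP") else UNTAGGED
            reads.append(
                ReadObservation(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    cigar=parse_cigar_ops(cigar),
                    sequence=(aln.query_sequence or "").upper(),
                    hap_tag=int(hp),
                )
            )
    return reads


def parse_cigar_ops(ops: tuple[tuple[str, int], ...]) -> tuple[tuple[str, int], ...]:
    for op, _ in ops:
        if op in ("N", "P", "B"):
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return ops


def write_fixture(reads: Iterable[ReadObservation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tchrom\tpos\tcigar\tsequence\thap\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.start + 1}\t"
                f"{format_cigar(r.cigar)}\t{r.sequence}\t{r.hap_tag}\n"
            )


def write_bam(
    reads: Sequence[ReadObservation],
    path: str,
    contigs: Mapping[str, int],
) -> None:
    """Optional hook: emit a real, sorted, indexed BAM from observations."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    order = {name: i for i, name in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (order[r.chrom], r.start))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = format_cigar(r.cigar)
            a.flag = 0
            if r.hap_tag != UNTAGGED:
                a.set_tag("HP", r.hap_tag, value_type="i")
            bam.write(a)
    pysam.index(path)
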