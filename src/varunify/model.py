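"""Core data model: variants, read observations, candidate sites, thresholds.

Coordinate conventions
----------------------
VCF records (and :class:`Variant.pos`) are 1-based; every internal interval
(:class:`Region`, read spans) is 0-based half-open.  Indel alleles follow the
VCF anchor-base convention: REF and ALT share their first base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

_DNA_RE = re.compile(r"^[ACGTN]+$")

UNTAGGED = 0  # hap_tag value for reads not assigned to a haplotype


@dataclass(frozen=True)
class Region:
    """Half-open 0-based interval on a contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class Variant:
    """One (possibly multiallelic) VCF record with genotype and optional phase."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]
    phased: bool = False
    phase_set: Optional[int] = None
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not _DNA_RE.match(self.ref):
            raise ValueError(f"bad REF allele {self.ref!r}")
        for alt in self.alts:
            if not _DNA_RE.match(alt):
                raise ValueError(f"bad ALT allele {alt!r}")
            # pure insertions/deletions must carry the VCF anchor base;
            # complex substitutions (both alleles multi-base) are exempt
            if min(len(self.ref), len(alt)) == 1 and len(self.ref) != len(alt):
                if self.ref[0] != alt[0]:
                    raise ValueError(
                        f"indel alleles must share an anchor base: {self.ref}>{alt}"
                    )
        n_alleles = 1 + len(self.alts)
        for g in self.genotype:
            if not 0 <= g < n_alleles:
                raise ValueError(f"genotype index {g} out of range")

    # -- convenience -------------------------------------------------------
    @property
    def alt(self) -> str:
        """The single ALT allele of a biallelic record."""
        if len(self.alts) != 1:
            raise ValueError("record is not biallelic")
        return self.alts[0]

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype[0] == self.genotype[1] != 0

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def end(self) -> int:
        """0-based exclusive end of the REF span."""
        return self.pos - 1 + len(self.ref)

    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def sort_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, ",".join(self.alts))


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious representation: trim the shared suffix, then the shared
    prefix (keeping at least one base of each allele); the position advances
    past trimmed prefix bases.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def split_multiallelic(variants: Iterable[Variant]) -> list[Variant]:
    """Split multiallelic records into biallelic units sharing the site,
    remapping genotype indices (non-carried alleles become REF calls).
    """
    out: list[Variant] = []
    for v in variants:
        if len(v.alts) == 1:
            out.append(v)
            continue
        for k, alt in enumerate(v.alts, start=1):
            gt = tuple(1 if g == k else 0 for g in v.genotype)
            if gt == (0, 0):
                continue  # allele not carried by this sample
            npos, nref, nalt = normalize_alleles(v.pos, v.ref, alt)
            out.append(
                replace(v, pos=npos, ref=nref, alts=(nalt,), genotype=gt)  # type: ignore[arg-type]
            )
    out.sort(key=Variant.sort_key)
    return out


@dataclass
class ReadObservation:
    """A single aligned read, stored compactly as (start, CIGAR, sequence).

    ``allele_at`` / :meth:`local_allele` derive the allele the read expresses
    over any reference window by walking the CIGAR; 'N' bases never support a
    non-reference allele.
    """

    read_id: str
    chrom: str
    start: int  # 0-based reference start
    cigar: tuple[tuple[str, int], ...]  # ops in {M,X,=,I,D,S,H}
    sequence: str
    hap_tag: int = UNTAGGED

    def __post_init__(self) -> None:
        if self.hap_tag not in (UNTAGGED, 1, 2):
            raise ValueError(f"hap_tag must be 0/1/2, got {self.hap_tag}")

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + sum(n for op, n in self.cigar if op in "MX=D")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def local_allele(self, pos: int, ref: str) -> Optional[str]:
        """Allele the read expresses over the site (1-based ``pos``, REF
        string ``ref``), or None when the read does not fully cover the
        window or carries an N there.

        The expressed allele is the read content aligned to the REF window
        plus any insertion immediately following each window base (so an
        anchor-base insertion at a length-1 window yields anchor+inserted).
        """
        p0 = pos - 1
        w_end = p0 + len(ref)
        # the read must extend strictly beyond the window: a read ending at
        # the window's last base cannot exclude an insertion following it
        if p0 < self.start or w_end >= self.end:
            return None
        out: list[str] = []
        rpos = self.start  # reference cursor
        qpos = 0  # query cursor
        for op, n in self.cigar:
            if op in ("S", "H"):
                if op == "S":
                    qpos += n
                continue
            if op == "I":
                # insertion sits after reference base rpos-1
                if p0 <= rpos - 1 < w_end:
                    out.append(self.sequence[qpos : qpos + n])
                qpos += n
                continue
            # M/X/=/D consume reference
            if op == "D":
                rpos += n
                continue
            # match block
            lo = max(rpos, p0)
            hi = min(rpos + n, w_end)
            if lo < hi:
                off = qpos + (lo - rpos)
                out.append(self.sequence[off : off + (hi - lo)])
            qpos += n
            rpos += n
        allele = "".join(out)
        if "N" in allele:
            return None
        return allele

    def covers(self, pos: int, ref: str) -> bool:
        """True when the read can report an allele at the site (spans the
        REF window with at least one aligned base beyond it)."""
        p0 = pos - 1
        return self.start <= p0 and p0 + len(ref) < self.end


@dataclass
class CandidateSite:
    """A pileup-derived non-reference allele with per-haplotype read counts."""

    chrom: str
    pos: int  # 1-based anchor
    ref: str
    alt: str
    depth: int
    alt_count: int
    hap_counts: dict[int, int] = field(default_factory=dict)  # keyed 0/1/2

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt_count must lie in [0, depth]")
        if self.hap_counts and sum(self.hap_counts.values()) != self.alt_count:
            raise ValueError("hap_counts must sum to alt_count")

    @property
    def af(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        return self.pos - 1 + len(self.ref)

    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ThresholdConfig:
    """Candidate-discovery and masking thresholds.

    Defaults are platform presets: minimum SNP allele frequency 0.08
    (PacBio/Illumina) or 0.15 (ONT), minimum indel allele frequency 0.15,
    minimum coverage 4, reliable-match tolerance epsilon 0.1, and the
    low-quality AF cutoff 0.08.
    """

    min_af_snp: float = 0.08
    min_af_indel: float = 0.15
    min_coverage: int = 4
    epsilon: float = 0.1
    low_qual_af: float = 0.08

    def __post_init__(self) -> None:
        for name in ("min_af_snp", "min_af_indel", "epsilon", "low_qual_af"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")

    @classmethod
    def for_platform(cls, platform: str, **overrides) -> "ThresholdConfig":
        platform = platform.lower()
        if platform == "ont":
            base = dict(min_af_snp=0.15)
        elif platform in ("pacbio", "ilmn", "illumina"):
            base = dict(min_af_snp=0.08)
        else:
            raise ValueError(f"unknown platform {platform!r}")
        base.update(overrides)
        return cls(**base)


CATEGORY_RELIABLE = "reliable_match"
CATEGORY_UNIFIED = "unified"
CATEGORY_RESCUED = "rescued"


@dataclass
class UnifiedRecord:
    """One output VCF record: a variant in its alignment-consistent
    representation, tagged with how it was resolved."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, int]
    phased: bool
    category: str  # reliable_match | unified | rescued
    allele_frequency: Optional[float] = None
    phase_set: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in (CATEGORY_RELIABLE, CATEGORY_UNIFIED, CATEGORY_RESCUED):
            raise ValueError(f"unknown category {self.category!r}")

    def filter_status(self, low_qual_af: float = 0.08) -> str:
        if self.allele_frequency is not None and self.allele_frequency < low_qual_af:
            return "LowQual"
        return "PASS"

    def sort_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def to_variant(self) -> Variant:
        return Variant(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alts=(self.alt,),
            genotype=self.genotype,
            phased=self.phased,
            phase_set=self.phase_set,
            allele_frequency=self.allele_frequency,
        )
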