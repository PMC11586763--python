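"""Pileup-based candidate discovery and reliable-match masking.

A *candidate* is a non-reference allele observed in the alignment pileup,
keyed at its VCF anchor base, that clears the platform's minimum allele
frequency and a minimum coverage.  A truth variant whose representation-
identical candidate has an allele frequency inside the epsilon window for
its genotype is a *reliable match* and is excluded from combinatorial
unification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .model import (
    CandidateSite,
    Region,
    ThresholdConfig,
    Variant,
    normalize_alleles,
)


@dataclass
class PileupCounts:
    """Per-site allele counts over a region (anchor positions are 1-based)."""

    region: Region
    depth: np.ndarray  # len == region length; reads spanning each position
    # (pos, ref, alt) -> per-hap_tag alt counts {0: n, 1: n, 2: n}
    alt_counts: Dict[Tuple[int, str, str], Dict[int, int]] = field(default_factory=dict)

    def depth_at(self, pos: int) -> int:
        """Read depth at 1-based position ``pos``."""
        i = pos - 1 - self.region.start
        if not 0 <= i < len(self.depth):
            return 0
        return int(self.depth[i])


def pileup_counts(
    reads: Sequence,
    region: Region,
    reference: Mapping[str, str],
) -> PileupCounts:
    """Single pass over the reads collecting coverage and every
    non-reference local allele (mismatch, insertion or deletion merged at
    its anchor base).  'N' bases never support an alternative allele."""
    ref_seq = reference[region.chrom]
    length = region.end - region.start
    cover = np.zeros(length + 1, dtype=np.int32)
    counts = PileupCounts(region=region, depth=np.zeros(length, dtype=np.int32))

    for read in reads:
        if read.chrom != region.chrom:
            continue
        s = max(read.start, region.start)
        e = min(read.end, region.end)
        if s >= e:
            continue
        cover[s - region.start] += 1
        cover[e - region.start] -= 1

        # per-anchor events: anchor -> [base, ins_seq, del_len]
        events: Dict[int, list] = {}

        def ev(anchor: int) -> list:
            return events.setdefault(anchor, ["", "", 0])

        rpos, qpos = read.start, 0
        for op, n in read.cigar:
            if op in ("S", "H"):
                if op == "S":
                    qpos += n
            elif op == "I":
                if rpos - 1 >= read.start:
                    ev(rpos - 1)[1] = read.sequence[qpos : qpos + n]
                qpos += n
            elif op == "D":
                if rpos - 1 >= read.start:
                    ev(rpos - 1)[2] = n
                rpos += n
            else:  # M / X / =
                seg = read.sequence[qpos : qpos + n]
                ref_seg = ref_seq[rpos : rpos + n]
                if seg != ref_seg:
                    a = np.frombuffer(seg.encode(), dtype=np.uint8)
                    b = np.frombuffer(ref_seg.encode(), dtype=np.uint8)
                    for off in np.nonzero(a != b)[0]:
                        ev(rpos + int(off))[0] = seg[int(off)]
                qpos += n
                rpos += n

        for anchor, (base, ins, dlen) in sorted(events.items()):
            if not region.start <= anchor < region.end:
                continue
            anchor_base = base or ref_seq[anchor]
            allele = anchor_base + ins
            site_ref = ref_seq[anchor : anchor + 1 + dlen]
            if allele == site_ref or "N" in allele or "N" in site_ref:
                continue
            key = (anchor + 1, site_ref, allele)
            hap = counts.alt_counts.setdefault(key, {0: 0, 1: 0, 2: 0})
            hap[read.hap_tag] = hap.get(read.hap_tag, 0) + 1

    counts.depth = np.cumsum(cover[:-1], dtype=np.int32)
    return counts


def discover_candidates(
    counts: PileupCounts, config: ThresholdConfig
) -> List[CandidateSite]:
    """Keep sites with depth >= min_coverage and allele frequency above the
    class threshold (SNP vs indel)."""
    out: List[CandidateSite] = []
    for (pos, ref, alt), hap_counts in sorted(counts.alt_counts.items()):
        depth = counts.depth_at(pos)
        alt_count = sum(hap_counts.values())
        if depth < config.min_coverage or depth == 0:
            continue
        af = alt_count / depth
        min_af = config.min_af_snp if (len(ref) == len(alt) == 1) else config.min_af_indel
        if af < min_af:
            continue
        out.append(
            CandidateSite(
                chrom=counts.region.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                depth=depth,
                alt_count=min(alt_count, depth),
                hap_counts=dict(hap_counts)
                if alt_count <= depth
                else _rescale(hap_counts, depth),
            )
        )
    return out


def _rescale(hap_counts: Dict[int, int], depth: int) -> Dict[int, int]:
    # pathological fixture where alt observations exceed span depth; clamp
    total = sum(hap_counts.values())
    out = {k: v * depth // total for k, v in hap_counts.items()}
    k0 = min(out)
    out[k0] += depth - sum(out.values())
    return out


def mask_reliable_matches(
    variants: Sequence[Variant],
    candidates: Sequence[CandidateSite],
    epsilon: float = 0.1,
) -> Tuple[List[Variant], List[Variant], List[CandidateSite]]:
    """Site-to-site verification.

    A variant is reliable iff a candidate with identical (chrom, pos, ref,
    alt) after anchor-base normalization exists and the candidate allele
    frequency lies in [0.5-eps, 0.5+eps] for a het genotype or above 1-eps
    (strict) for a hom genotype.  Returns (reliable, remaining_variants,
    remaining_candidates); reliable pairs are removed from both sets.
    """
    by_key: Dict[Tuple[str, int, str, str], CandidateSite] = {}
    for c in candidates:
        npos, nref, nalt = normalize_alleles(c.pos, c.ref, c.alt)
        by_key[(c.chrom, npos, nref, nalt)] = c

    reliable: List[Variant] = []
    remaining_v: List[Variant] = []
    used_candidates: set[Tuple[str, int, str, str]] = set()

    for v in variants:
        matched = False
        if len(v.alts) == 1 and v.genotype != (0, 0):
            npos, nref, nalt = normalize_alleles(v.pos, v.ref, v.alt)
            cand = by_key.get((v.chrom, npos, nref, nalt))
            if cand is not None:
                af = cand.af
                if v.is_het:
                    matched = 0.5 - epsilon <= af <= 0.5 + epsilon
                else:
                    matched = af > 1 - epsilon
                if matched:
                    reliable.append(replace(v, allele_frequency=af))
                    used_candidates.add(cand.site_key())
        if not matched:
            remaining_v.append(v)

    remaining_c = [c for c in candidates if c.site_key() not in used_candidates]
    return reliable, remaining_v, remaining_c
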