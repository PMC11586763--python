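"""Read-backed phasing of heterozygous variants and read haplotagging.

The phaser is a deterministic heuristic that minimises the minimum error
correction (MEC) cost: the fewest read-allele corrections needed to make
every read consistent with one of the two haplotypes implied by an
orientation assignment.  It is intentionally simple — the unifier only needs
*a* consistent phasing, and a pre-phased input VCF can bypass this stage.

Orientation encoding: for a heterozygous variant, orientation ``0`` means
``0|1`` (haplotype 1 carries REF, haplotype 2 carries ALT) and ``1`` means
``1|0``.  Ties break toward ``0`` and components are traversed in coordinate
order, so results are deterministic given input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .model import UNTAGGED, ReadObservation, Variant

SiteKey = Tuple[str, int, str, str]


@dataclass
class PhasingResult:
    """Orientation per phased het variant, phase-set membership, MEC score."""

    orientations: Dict[SiteKey, int] = field(default_factory=dict)
    phase_sets: Dict[SiteKey, int] = field(default_factory=dict)
    mec_score: int = 0
    # het variants re-genotyped to hom (key -> new genotype)
    switched: Dict[SiteKey, Tuple[int, int]] = field(default_factory=dict)

    def hap_code(self, key: SiteKey, hap: int) -> int:
        """Allele code (0=REF, 1=ALT) carried by haplotype ``hap`` (1 or 2)."""
        o = self.orientations[key]
        return o if hap == 1 else 1 - o


def _read_codes(
    read: ReadObservation,
    het_variants: Sequence[Variant],
    reference: Optional[Mapping[str, str]] = None,
    pad: int = 10,
) -> Dict[SiteKey, int]:
    """Allele codes (0=REF, 1=ALT) a read expresses at het sites it covers;
    alleles matching neither are uninformative and omitted.

    With a ``reference``, the comparison runs over a window padded by
    ``pad`` bases: the read's expressed sequence is matched against the
    REF-spliced and ALT-spliced window, so reads aligned under an
    equivalent shifted/merged representation of the variant still produce
    the right code (exact anchor comparison would miscall them as REF)."""
    codes: Dict[SiteKey, int] = {}
    for v in het_variants:
        if v.chrom != read.chrom:
            continue
        if reference is None:
            if not read.covers(v.pos, v.ref):
                continue
            allele = read.local_allele(v.pos, v.ref)
            if allele == v.ref:
                codes[v.site_key()] = 0
            elif allele == v.alt:
                codes[v.site_key()] = 1
            continue
        ref_seq = reference[v.chrom]
        w_start = max(0, v.pos - 1 - pad)
        w_end = min(len(ref_seq), v.end + pad)
        window_ref = ref_seq[w_start:w_end]
        expressed = read.local_allele(w_start + 1, window_ref)
        if expressed is None:
            continue
        ref_version = window_ref
        alt_version = (
            window_ref[: v.pos - 1 - w_start]
            + v.alt
            + window_ref[v.end - w_start :]
        )
        if expressed == ref_version and expressed != alt_version:
            codes[v.site_key()] = 0
        elif expressed == alt_version and expressed != ref_version:
            codes[v.site_key()] = 1
    return codes


def compute_mec(
    assignment: PhasingResult,
    reads: Sequence[ReadObservation],
    het_variants: Sequence[Variant],
    reference: Optional[Mapping[str, str]] = None,
) -> int:
    """MEC cost of an orientation assignment: each read is placed on its
    best-fitting haplotype and its conflicting sites are counted."""
    for v in het_variants:
        key = v.site_key()
        if key not in assignment.orientations and key not in assignment.switched:
            raise ValueError(f"assignment does not cover het variant {key}")
    phased = [v for v in het_variants if v.site_key() in assignment.orientations]
    total = 0
    for read in reads:
        codes = _read_codes(read, phased, reference)
        if not codes:
            continue
        cost = [0, 0]
        for key, code in codes.items():
            for h in (1, 2):
                if code != assignment.hap_code(key, h):
                    cost[h - 1] += 1
        total += min(cost)
    return total


def phase_variants(
    het_variants: Sequence[Variant],
    reads: Sequence[ReadObservation],
    allow_genotype_switch: bool = False,
    switch_threshold: float = 0.8,
    max_refine_rounds: int = 10,
    reference: Optional[Mapping[str, str]] = None,
) -> PhasingResult:
    """Phase het variants from read co-occurrence.

    Builds connected components of variants linked by reads, orients each
    component greedily in coordinate order, then refines by alternating
    read-to-haplotype assignment and per-variant orientation flips until the
    MEC stops improving.  With ``allow_genotype_switch``, a variant where
    more than ``switch_threshold`` of informative reads carry one allele is
    re-genotyped to homozygous and removed from the phase graph.
    """
    het_variants = sorted(het_variants, key=Variant.sort_key)
    result = PhasingResult()

    read_codes = [_read_codes(r, het_variants, reference) for r in reads]

    if allow_genotype_switch:
        support: Dict[SiteKey, List[int]] = {}
        for codes in read_codes:
            for key, code in codes.items():
                support.setdefault(key, [0, 0])[code] += 1
        kept = []
        for v in het_variants:
            cnt = support.get(v.site_key(), [0, 0])
            n = cnt[0] + cnt[1]
            if n > 0 and max(cnt) / n > switch_threshold:
                new_gt = (1, 1) if cnt[1] > cnt[0] else (0, 0)
                result.switched[v.site_key()] = new_gt
            else:
                kept.append(v)
        het_variants = kept
        read_codes = [
            {k: c for k, c in codes.items() if k not in result.switched}
            for codes in read_codes
        ]

    if not het_variants:
        return result

    keys = [v.site_key() for v in het_variants]
    index = {k: i for i, k in enumerate(keys)}

    # union-find over variants linked by a shared read
    parent = list(range(len(keys)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    pair_votes: Dict[Tuple[int, int], List[int]] = {}
    for codes in read_codes:
        idxs = sorted(index[k] for k in codes)
        for a, b in zip(idxs, idxs[1:]):
            union(a, b)
        for ii, a in enumerate(idxs):
            for b in idxs[ii + 1 :]:
                same = codes[keys[a]] == codes[keys[b]]
                pair_votes.setdefault((a, b), [0, 0])[0 if same else 1] += 1

    # greedy orientation in coordinate order: relative to oriented neighbours
    orient = [0] * len(keys)
    oriented: set[int] = set()
    for i in range(len(keys)):
        votes = [0, 0]  # votes for orient[i] = 0 / 1
        for j in oriented:
            if find(j) != find(i):
                continue
            a, b = min(i, j), max(i, j)
            v = pair_votes.get((a, b))
            if v is None:
                continue
            same_votes, diff_votes = v
            # cis (same codes on one hap) => same orientation parity
            votes[orient[j]] += same_votes
            votes[1 - orient[j]] += diff_votes
        orient[i] = 0 if votes[0] >= votes[1] else 1
        oriented.add(i)

    # local refinement: alternate read placement and orientation flips
    def read_cost(codes: Dict[SiteKey, int]) -> int:
        cost = [0, 0]
        for key, code in codes.items():
            i = index[key]
            for h, hap_code in ((1, orient[i]), (2, 1 - orient[i])):
                if code != hap_code:
                    cost[h - 1] += 1
        return min(cost)

    def total_mec() -> int:
        return sum(read_cost(codes) for codes in read_codes if codes)

    best = total_mec()
    for _ in range(max_refine_rounds):
        improved = False
        for i in range(len(keys)):
            orient[i] ^= 1
            cand = total_mec()
            if cand < best:
                best = cand
                improved = True
            else:
                orient[i] ^= 1
        if not improved:
            break

    result.orientations = {k: orient[i] for i, k in enumerate(index)}
    comp_min_pos: Dict[int, int] = {}
    for i, v in enumerate(het_variants):
        root = find(i)
        comp_min_pos[root] = min(comp_min_pos.get(root, v.pos), v.pos)
    result.phase_sets = {
        keys[i]: comp_min_pos[find(i)] for i in range(len(keys))
    }
    result.mec_score = best
    return result


def haplotag_reads(
    phasing: PhasingResult,
    het_variants: Sequence[Variant],
    reads: Sequence[ReadObservation],
    reference: Optional[Mapping[str, str]] = None,
) -> list[ReadObservation]:
    """Tag each read 1 or 2 by majority vote of its alleles at phased sites;
    ties or zero informative sites leave the read untagged."""
    phased = [v for v in het_variants if v.site_key() in phasing.orientations]
    tagged: list[ReadObservation] = []
    for read in reads:
        codes = _read_codes(read, phased, reference)
        votes = [0, 0]
        for key, code in codes.items():
            for h in (1, 2):
                if code == phasing.hap_code(key, h):
                    votes[h - 1] += 1
        if votes[0] > votes[1]:
            tag = 1
        elif votes[1] > votes[0]:
            tag = 2
        else:
            tag = UNTAGGED
        tagged.append(replace(read, hap_tag=tag))
    return tagged


def apply_phasing(variants: Sequence[Variant], phasing: PhasingResult) -> list[Variant]:
    """Return variants with phased genotypes (and PS) where the phaser
    resolved them; genotype-switched variants are re-genotyped."""
    out: list[Variant] = []
    for v in variants:
        key = v.site_key() if len(v.alts) == 1 else None
        if key in phasing.switched:
            new_gt = phasing.switched[key]
            if new_gt == (0, 0):
                continue  # re-genotyped to hom-ref: variant dropped
            out.append(replace(v, genotype=new_gt, phased=True, phase_set=None))
        elif key in phasing.orientations:
            o = phasing.orientations[key]
            gt = (0, 1) if o == 0 else (1, 0)
            out.append(
                replace(v, genotype=gt, phased=True, phase_set=phasing.phase_sets[key])
            )
        else:
            out.append(v)
    return out
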