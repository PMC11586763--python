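"""Synthetic diploid fixtures: reference genomes, truth VCFs,
haplotype-preserving alternative representations, and pre-aligned reads.

The generator emulates the scenario the unifier targets: a diploid sample
whose variants partly cluster within ~20 bp windows (where alternative
representations of the same haplotype arise), sequenced at configurable
coverage and per-base substitution error.  Reads are emitted pre-aligned
against the reference with correct CIGARs — there is no realignment step —
and read names encode the source haplotype for oracle checks.

Every re-representation rewrite is verified by a splice oracle: applying
the rewritten VCF must reproduce the input haplotype sequences exactly.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ReadObservation, Variant
from .unify import splice

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults are the small-genome regime used throughout the test suite:
    100 kb diploid genome, 1e-3 SNPs/bp and 2e-4 indels/bp, 30% of variants
    placed in <=20 bp clusters, 60% heterozygous, 30x coverage of 1 kb
    error-free reads.
    """

    genome_length: int = 100_000
    snp_rate: float = 1e-3
    indel_rate: float = 2e-4
    cluster_fraction: float = 0.3
    het_fraction: float = 0.6
    max_indel_len: int = 6
    homopolymer_bias: float = 0.5  # fraction of indels made shift-ambiguous
    coverage: int = 30
    read_length: int = 1_000
    error_rate: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0,1]")
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")


@dataclass
class SimTruth:
    reference: Dict[str, str]
    variants: List[Variant]  # phased truth set
    hap1: str
    hap2: str
    chrom: str


def _hap_entries(variants: Sequence[Variant], hap: int) -> List[Tuple[str, str, str]]:
    entries = []
    for v in variants:
        allele = v.alt if v.genotype[hap - 1] == 1 else v.ref
        entries.append((v.pos, v.ref, allele))
    return entries


def apply_variants(reference: str, variants: Sequence[Variant], hap: int) -> str:
    """Splice one haplotype (1 or 2) of a phased variant set into the
    reference; raises on overlapping REF spans."""
    seq = splice(reference, 0, _hap_entries(variants, hap))
    if seq is None:
        raise ValueError("variants have overlapping REF spans")
    return seq


def simulate_truth(config: SimConfig) -> SimTruth:
    """Random reference plus a phased truth set and its two haplotypes."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    ref = "".join(rng.choice(list(BASES), size=L))

    n_snp = int(rng.binomial(L, config.snp_rate))
    n_indel = int(rng.binomial(L, config.indel_rate))
    total = n_snp + n_indel
    kinds = ["snp"] * n_snp + ["indel"] * n_indel
    rng.shuffle(kinds)

    n_clustered = int(round(config.cluster_fraction * total))
    used: List[Tuple[int, int]] = []  # occupied [start, end) ref spans (0-based)

    def free(start: int, end: int) -> bool:
        return all(end + 2 <= s or e + 2 <= start for s, e in used)

    def draw_variant(kind: str, p0: int, rng) -> Optional[Variant]:
        """A variant anchored at 0-based p0, or None if it does not fit."""
        if kind == "snp":
            if p0 >= L:
                return None
            r = ref[p0]
            a = BASES[(BASES.index(r) + int(rng.integers(1, 4))) % 4]
            v_ref, v_alt = r, a
        else:
            length = int(rng.integers(1, config.max_indel_len + 1))
            insert = bool(rng.integers(0, 2))
            if insert:
                if p0 >= L:
                    return None
                if rng.random() < config.homopolymer_bias and p0 + 1 < L:
                    ins = ref[p0 + 1] * length  # duplicates the next base run
                else:
                    ins = "".join(rng.choice(list(BASES), size=length))
                v_ref, v_alt = ref[p0], ref[p0] + ins
            else:
                if p0 + 1 + length > L:
                    return None
                v_ref, v_alt = ref[p0 : p0 + 1 + length], ref[p0]
        span = (p0, p0 + len(v_ref))
        if not free(*span):
            return None
        if rng.random() < config.het_fraction:
            gt = (0, 1) if rng.random() < 0.5 else (1, 0)
        else:
            gt = (1, 1)
        used.append(span)
        return Variant(
            chrom=config.chrom,
            pos=p0 + 1,
            ref=v_ref,
            alts=(v_alt,),
            genotype=gt,
            phased=True,
            phase_set=1,
        )

    variants: List[Variant] = []
    # clustered variants: groups of 2-3 inside a 20 bp window
    placed_clustered = 0
    attempts = 0
    while placed_clustered < n_clustered and attempts < 50 * max(1, n_clustered):
        attempts += 1
        k = int(rng.integers(2, 4))
        anchor = int(rng.integers(10, L - 40))
        offsets = sorted(rng.choice(np.arange(20), size=k, replace=False))
        group: List[Variant] = []
        ok = True
        for off in offsets:
            kind = kinds[min(placed_clustered + len(group), total - 1)]
            v = draw_variant(kind, anchor + int(off), rng)
            if v is None:
                ok = False
                break
            group.append(v)
        if ok:
            variants.extend(group)
            placed_clustered += len(group)
        else:
            for v in group:  # roll back the partial group
                used.remove((v.pos - 1, v.end))

    # isolated variants fill the remainder
    placed_isolated = 0
    n_isolated = max(0, total - placed_clustered)
    attempts = 0
    while placed_isolated < n_isolated and attempts < 50 * max(1, n_isolated):
        attempts += 1
        p0 = int(rng.integers(10, L - 20))
        kind = kinds[min(placed_clustered + placed_isolated, total - 1)]
        # keep isolated variants away from existing sites so they stay
        # representation-unambiguous
        if not free(p0 - 25, p0 + 25):
            continue
        v = draw_variant(kind, p0, rng)
        if v is not None:
            variants.append(v)
            placed_isolated += 1

    variants.sort(key=Variant.sort_key)
    hap1 = apply_variants(ref, variants, 1)
    hap2 = apply_variants(ref, variants, 2)
    return SimTruth(
        reference={config.chrom: ref},
        variants=variants,
        hap1=hap1,
        hap2=hap2,
        chrom=config.chrom,
    )


# ---------------------------------------------------------------------------
# haplotype-preserving re-representation


def _window_equal(
    reference: str,
    old: Sequence[Variant],
    new: Sequence[Variant],
    pad: int = 30,
) -> bool:
    """Splice oracle: both variant groups encode the same two haplotypes
    over a padded window (haplotype order preserved)."""
    sites = list(old) + list(new)
    start = max(0, min(v.pos - 1 for v in sites) - pad)
    end = min(len(reference), max(v.end for v in sites) + pad)
    window = reference[start:end]
    for hap in (1, 2):
        a = splice(window, start, [(v.pos, v.ref, v.alt if v.genotype[hap - 1] else v.ref) for v in old])
        b = splice(window, start, [(v.pos, v.ref, v.alt if v.genotype[hap - 1] else v.ref) for v in new])
        if a is None or b is None or a != b:
            return False
    return True


def _shift_indel(v: Variant, reference: str, rng) -> Optional[List[Variant]]:
    """Move a pure insertion/deletion to an equivalent anchor within its
    repeat tract (verified by the splice oracle)."""
    if len(v.ref) == len(v.alt):
        return None
    shifts = [s for s in (-3, -2, -1, 1, 2, 3)]
    rng.shuffle(shifts)
    is_del = len(v.ref) > len(v.alt)
    for s in shifts:
        p0 = v.pos - 1 + s
        if p0 < 0:
            continue
        if is_del:
            d = len(v.ref) - 1
            if p0 + 1 + d > len(reference):
                continue
            cand = replace(
                v, pos=p0 + 1, ref=reference[p0 : p0 + 1 + d], alts=(reference[p0],)
            )
        else:
            ins_len = len(v.alt) - 1
            if p0 >= len(reference):
                continue
            # rotate the inserted sequence through the reference tract
            old_p0 = v.pos - 1
            ins = v.alt[1:]
            if s > 0:
                tract = reference[old_p0 + 1 : old_p0 + 1 + s]
                if len(tract) < s or ins[:s] != tract:
                    continue
                new_ins = ins[s:] + tract
            else:
                tract = reference[p0 + 1 : p0 + 1 + (-s)]
                if len(tract) < -s or ins[s:] != tract:
                    continue
                new_ins = tract + ins[:s]
            cand = replace(
                v, pos=p0 + 1, ref=reference[p0], alts=(reference[p0] + new_ins,)
            )
        try:
            if _window_equal(reference, [v], [cand]):
                return [cand]
        except ValueError:
            continue
    return None


def _decompose(v: Variant, reference: str) -> Optional[List[Variant]]:
    """Split a multi-base record into minimal SNP/indel pieces via a
    sequence alignment of REF and ALT (MNP -> SNPs; complex -> indel+SNPs)."""
    ref, alt = v.ref, v.alt
    if len(ref) == 1 and len(alt) == 1:
        return None
    pieces: List[Variant] = []
    if len(ref) == len(alt):
        # substitution block: one SNP per differing offset
        for k, (a, b) in enumerate(zip(ref, alt)):
            if a != b:
                pieces.append(replace(v, pos=v.pos + k, ref=a, alts=(b,)))
        if len(pieces) < 2:
            return None
        if _window_equal(reference, [v], pieces):
            return pieces
        return None
    sm = difflib.SequenceMatcher(a=ref, b=alt, autojunk=False)
    for tag, i1, i2, j1, j2 in sm.get_opcodes():
        if tag == "equal":
            continue
        if tag == "replace" and (i2 - i1) == (j2 - j1):
            for k in range(i2 - i1):
                pieces.append(
                    replace(
                        v,
                        pos=v.pos + i1 + k,
                        ref=ref[i1 + k],
                        alts=(alt[j1 + k],),
                    )
                )
        elif tag == "delete" and i1 > 0:
            pieces.append(
                replace(
                    v,
                    pos=v.pos + i1 - 1,
                    ref=ref[i1 - 1 : i2],
                    alts=(ref[i1 - 1],),
                )
            )
        elif tag == "insert" and i1 > 0:
            pieces.append(
                replace(
                    v,
                    pos=v.pos + i1 - 1,
                    ref=ref[i1 - 1],
                    alts=(ref[i1 - 1] + alt[j1:j2],),
                )
            )
        else:
            return None  # unanchored edit; keep the original record
    if len(pieces) < 2:
        return None
    try:
        if _window_equal(reference, [v], pieces):
            return pieces
    except ValueError:
        pass
    return None


def _merge_group(group: Sequence[Variant], reference: str) -> Optional[List[Variant]]:
    """Merge adjacent variants with identical genotype into one complex
    record spanning them (the 'platform merged' representation)."""
    if len(group) < 2:
        return None
    gt = group[0].genotype
    if any(v.genotype != gt or v.phased != group[0].phased for v in group[1:]):
        return None
    start = group[0].pos - 1
    end = max(v.end for v in group)
    ref = reference[start:end]
    merged_alts = []
    for hap in (1, 2):
        entries = [
            (v.pos, v.ref, v.alt if v.genotype[hap - 1] else v.ref) for v in group
        ]
        alt = splice(ref, start, entries)
        if alt is None:
            return None
        merged_alts.append(alt)
    alt = merged_alts[0] if gt[0] == 1 else merged_alts[1]
    if alt == ref:
        return None
    merged = replace(group[0], pos=start + 1, ref=ref, alts=(alt,))
    if _window_equal(reference, list(group), [merged]):
        return [merged]
    return None


DEFAULT_MODES = ("shift", "merge", "decompose")


def rerepresent_vcf(
    variants: Sequence[Variant],
    reference: Dict[str, str],
    modes: Sequence[str] = DEFAULT_MODES,
    seed: int = 0,
) -> List[Variant]:
    """Rewrite a phased truth set into alternative representations of the
    same haplotypes.  Hard invariant (asserted): applying the output
    reproduces the input haplotype sequences byte for byte."""
    rng = np.random.default_rng(seed)
    by_chrom: Dict[str, List[Variant]] = {}
    for v in sorted(variants, key=Variant.sort_key):
        by_chrom.setdefault(v.chrom, []).append(v)

    out: List[Variant] = []
    for chrom, vs in by_chrom.items():
        ref = reference[chrom]
        # group nearby variants (candidates for merging into one complex
        # record; intervening reference bases are carried in REF/ALT)
        groups: List[List[Variant]] = []
        for v in vs:
            if groups and v.pos - 1 - groups[-1][-1].end <= 10:
                groups[-1].append(v)
            else:
                groups.append([v])
        new_vs: List[Variant] = []
        for group in groups:
            rewritten: Optional[List[Variant]] = None
            if len(group) >= 2 and "merge" in modes and rng.random() < 0.7:
                rewritten = _merge_group(group, ref)
            if rewritten is None:
                rewritten = []
                for v in group:
                    one: Optional[List[Variant]] = None
                    choices = [m for m in modes if m != "merge"]
                    rng.shuffle(choices)
                    for mode in choices:
                        if mode == "shift":
                            one = _shift_indel(v, ref, rng)
                        elif mode == "decompose":
                            one = _decompose(v, ref)
                        if one is not None:
                            break
                    rewritten.extend(one if one is not None else [v])
            new_vs.extend(rewritten)
        new_vs.sort(key=Variant.sort_key)
        # shifted indels may now collide with a neighbour; back out collisions
        new_vs = _resolve_overlaps(vs, new_vs)
        for hap in (1, 2):
            old_seq = apply_variants(ref, vs, hap)
            new_seq = apply_variants(ref, new_vs, hap)
            assert old_seq == new_seq, "re-representation changed a haplotype"
        out.extend(new_vs)
    out.sort(key=Variant.sort_key)
    return out


def _resolve_overlaps(
    original: List[Variant], rewritten: List[Variant]
) -> List[Variant]:
    """If rewrites produced overlapping REF spans on a haplotype, fall back
    to the original records (rare; keeps the splice oracle satisfiable)."""
    for hap in (1, 2):
        cursor = -1
        for v in rewritten:
            a = v.alt if v.genotype[hap - 1] else v.ref
            if a == v.ref:
                continue
            if v.pos - 1 <= cursor:
                return list(original)
            cursor = v.end - 1
    return rewritten


# ---------------------------------------------------------------------------
# read simulation


def _alignment_blocks(
    variants: Sequence[Variant], hap: int, ref_len: int
) -> List[Tuple[str, int, int]]:
    """(op, ref_len, hap_len) blocks aligning one haplotype to the
    reference, assuming anchored SNP/ins/del truth records."""
    blocks: List[Tuple[str, int, int]] = []
    ref_cursor = 0
    for v in sorted(variants, key=Variant.sort_key):
        allele = v.alt if v.genotype[hap - 1] == 1 else v.ref
        if allele == v.ref:
            continue
        p0 = v.pos - 1
        if p0 > ref_cursor:
            blocks.append(("M", p0 - ref_cursor, p0 - ref_cursor))
        lr, la = len(v.ref), len(allele)
        if lr == la:
            blocks.append(("M", lr, la))
        elif la > lr:  # insertion (anchored)
            blocks.append(("M", lr, lr))
            blocks.append(("I", 0, la - lr))
        else:  # deletion
            blocks.append(("M", la, la))
            blocks.append(("D", lr - la, 0))
        ref_cursor = p0 + lr
    if ref_cursor < ref_len:
        blocks.append(("M", ref_len - ref_cursor, ref_len - ref_cursor))
    return blocks


def _read_alignment(
    blocks: Sequence[Tuple[str, int, int]], hap_start: int, hap_end: int
) -> Tuple[int, List[Tuple[str, int]]]:
    """CIGAR and reference start of the haplotype interval [hap_start,
    hap_end), with boundary deletions stripped and boundary insertions
    soft-clipped."""
    ops: List[Tuple[str, int]] = []
    ref_pos = 0
    hap_pos = 0
    ref_start = None
    for op, rlen, hlen in blocks:
        if hap_pos >= hap_end and op != "D":
            break
        if op == "D":
            if hap_start < hap_pos < hap_end:
                ops.append(("D", rlen))
            ref_pos += rlen
            continue
        lo = max(hap_pos, hap_start)
        hi = min(hap_pos + hlen, hap_end)
        if lo < hi:
            if op == "M":
                if ref_start is None:
                    ref_start = ref_pos + (lo - hap_pos)
                ops.append(("M", hi - lo))
            else:  # I
                ops.append(("I", hi - lo))
        ref_pos += rlen
        hap_pos += hlen
    # strip leading/trailing D; convert boundary I to soft clips
    while ops and ops[0][0] == "D":
        ops.pop(0)
    while ops and ops[-1][0] == "D":
        ops.pop()
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    # merge adjacent same ops
    merged: List[Tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    assert ref_start is not None
    return ref_start, merged


def simulate_reads(truth: SimTruth, config: SimConfig) -> List[ReadObservation]:
    """Uniform reads from each haplotype at coverage/2, pre-aligned against
    the reference; substitution errors at ``error_rate``.  Read names encode
    the source haplotype (``h1_…``/``h2_…``); reads are emitted untagged."""
    if config.read_length > config.genome_length:
        raise ValueError("read_length exceeds genome_length")
    rng = np.random.default_rng(config.seed + 1)
    ref_len = len(truth.reference[truth.chrom])
    reads: List[ReadObservation] = []
    for hap, seq in ((1, truth.hap1), (2, truth.hap2)):
        blocks = _alignment_blocks(truth.variants, hap, ref_len)
        n_reads = int(np.ceil(config.coverage / 2 * len(seq) / config.read_length))
        hi = max(1, len(seq) - config.read_length + 1)
        starts = np.sort(rng.integers(0, hi, size=n_reads))
        for i, s in enumerate(starts):
            s = int(s)
            e = s + config.read_length
            ref_start, cigar = _read_alignment(blocks, s, e)
            bases = list(seq[s:e])
            if config.error_rate > 0:
                errs = np.nonzero(rng.random(len(bases)) < config.error_rate)[0]
                for k in errs:
                    k = int(k)
                    bases[k] = BASES[
                        (BASES.index(bases[k]) + int(rng.integers(1, 4))) % 4
                    ]
            reads.append(
                ReadObservation(
                    read_id=f"h{hap}_{i:05d}",
                    chrom=truth.chrom,
                    start=ref_start,
                    cigar=tuple(cigar),
                    sequence="".join(bases),
                )
            )
    reads.sort(key=lambda r: (r.start, r.read_id))
    return reads
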