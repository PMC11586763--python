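"""Site-level benchmarking of a query VCF against a truth VCF.

This comparator requires identical (normalized) site, alleles and genotype
for a true positive, which is the right notion *after* representations have
been unified; it is not a haplotype-aware matcher for divergent
representations (use :func:`haplotype_metrics` for that).  Precision,
recall and F1 are reported per category (Overall / SNP / Indel / Insertion /
Deletion) as percentages rounded to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import Region, Variant, normalize_alleles
from .unify import HaplotypePair, apply_combination, equivalent

CATEGORIES = ("Overall", "SNP", "Indel", "Insertion", "Deletion")


@dataclass
class MetricsCounts:
    query_tp: int = 0
    query_fp: int = 0
    truth_tp: int = 0
    truth_fn: int = 0

    def __iadd__(self, other: "MetricsCounts") -> "MetricsCounts":
        self.query_tp += other.query_tp
        self.query_fp += other.query_fp
        self.truth_tp += other.truth_tp
        self.truth_fn += other.truth_fn
        return self


def variant_categories(ref: str, alt: str) -> Tuple[str, ...]:
    """Categories a record contributes to (always includes Overall).
    Equal-length alleles count as SNP (substitutions); length changes as
    Insertion or Deletion, both also rolled up into Indel."""
    if len(ref) == len(alt):
        return ("Overall", "SNP")
    if len(alt) > len(ref):
        return ("Overall", "Indel", "Insertion")
    return ("Overall", "Indel", "Deletion")


def _norm_key(v: Variant) -> Tuple[str, int, str, str, Tuple[int, int]]:
    pos, ref, alt = normalize_alleles(v.pos, v.ref, v.alt)
    gt = tuple(sorted(v.genotype))
    return (v.chrom, pos, ref, alt, gt)  # type: ignore[return-value]


def _in_regions(v: Variant, regions: Optional[Sequence[Region]]) -> bool:
    if regions is None:
        return True
    return any(r.contains(v.chrom, v.pos - 1) for r in regions)


def compare_sites(
    query: Sequence[Variant],
    truth: Sequence[Variant],
    regions: Optional[Sequence[Region]] = None,
) -> Dict[str, MetricsCounts]:
    """TP = same normalized site, alleles and (unordered) genotype; query
    records that fail are FP; unmatched truth records are FN.  Restricted to
    the given high-confidence regions when provided."""
    query = [v for v in query if _in_regions(v, regions)]
    truth = [v for v in truth if _in_regions(v, regions)]
    truth_keys = {_norm_key(v): v for v in truth}
    counts = {cat: MetricsCounts() for cat in CATEGORIES}

    matched: set = set()
    for q in query:
        key = _norm_key(q)
        cats = variant_categories(key[2], key[3])
        if key in truth_keys and key not in matched:
            matched.add(key)
            for cat in cats:
                counts[cat].query_tp += 1
                counts[cat].truth_tp += 1
        else:
            for cat in cats:
                counts[cat].query_fp += 1
    for t in truth:
        key = _norm_key(t)
        if key not in matched:
            for cat in variant_categories(key[2], key[3]):
                counts[cat].truth_fn += 1
    return counts


def overall_metrics(
    counts: MetricsCounts,
) -> Tuple[float, float, float]:
    """(precision, recall, F1) as percentages rounded to two decimals.

    precision = QUERY.TP / (QUERY.TP + QUERY.FP)
    recall    = TRUTH.TP / (TRUTH.TP + TRUTH.FN)
    F1        = 2 P R / (P + R)

    Undefined metrics (zero denominator) are NaN, never 0.
    """
    p = r = f1 = math.nan
    if counts.query_tp + counts.query_fp > 0:
        p = 100.0 * counts.query_tp / (counts.query_tp + counts.query_fp)
    if counts.truth_tp + counts.truth_fn > 0:
        r = 100.0 * counts.truth_tp / (counts.truth_tp + counts.truth_fn)
    if not (math.isnan(p) or math.isnan(r)) and (p + r) > 0:
        f1 = 2.0 * p * r / (p + r)
    return (round(p, 2), round(r, 2), round(f1, 2))


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """F1 (percent, two decimals) from printed precision/recall percents."""
    if precision_pct + recall_pct == 0:
        return math.nan
    return round(2.0 * precision_pct * recall_pct / (precision_pct + recall_pct), 2)


def metrics_table(counts: Dict[str, MetricsCounts]) -> str:
    """Per-category TSV table of counts and metrics."""
    lines = ["Category\tQUERY.TP\tQUERY.FP\tTRUTH.TP\tTRUTH.FN\tPrecision\tRecall\tF1"]
    for cat in CATEGORIES:
        c = counts[cat]
        p, r, f1 = overall_metrics(c)
        lines.append(
            f"{cat}\t{c.query_tp}\t{c.query_fp}\t{c.truth_tp}\t{c.truth_fn}"
            f"\t{p:.2f}\t{r:.2f}\t{f1:.2f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# haplotype-level comparison (for divergent representations)


def haplotype_metrics(
    query: Sequence[Variant],
    truth: Sequence[Variant],
    reference: Dict[str, str],
    gap_bp: int = 100,
    flank_bp: int = 16,
    max_flips: int = 12,
) -> Tuple[float, float]:
    """(precision, recall) percentages at the haplotype-sequence level.

    Query and truth records are chunked jointly; within each chunk both sets
    are spliced into haplotype sequence pairs and compared up to
    haplotype-order swap, trying orientation flips per query phase set (and
    per unphased het) up to ``2**max_flips`` assignments.  When a chunk's
    haplotypes agree, every record in it is a TP; otherwise all its query
    records are FP and truth records FN.
    """
    items = sorted(
        [("T", v) for v in truth] + [("Q", v) for v in query],
        key=lambda t: (t[1].chrom, t[1].pos),
    )
    groups: List[List[Tuple[str, Variant]]] = []
    for kind, v in items:
        if (
            groups
            and groups[-1][-1][1].chrom == v.chrom
            and v.pos - 1 - max(x.end for _, x in groups[-1]) < gap_bp
        ):
            groups[-1].append((kind, v))
        else:
            groups.append([(kind, v)])

    tp_q = fp_q = tp_t = fn_t = 0
    for group in groups:
        t_vars = [v for k, v in group if k == "T"]
        q_vars = [v for k, v in group if k == "Q"]
        chrom = group[0][1].chrom
        start = max(0, min(v.pos - 1 for _, v in group) - flank_bp)
        end = min(len(reference[chrom]), max(v.end for _, v in group) + flank_bp)
        window = reference[chrom][start:end]
        ok = _group_haplotypes_match(t_vars, q_vars, window, start, max_flips)
        if ok:
            tp_q += len(q_vars)
            tp_t += len(t_vars)
        else:
            fp_q += len(q_vars)
            fn_t += len(t_vars)
    p = 100.0 * tp_q / (tp_q + fp_q) if (tp_q + fp_q) else math.nan
    r = 100.0 * tp_t / (tp_t + fn_t) if (tp_t + fn_t) else math.nan
    return (round(p, 2), round(r, 2))


def _pairs_for(
    variants: Sequence[Variant], window: str, start: int, max_flips: int
) -> List[HaplotypePair]:
    """All haplotype pairs a variant group can encode, flipping each phase
    set (and each unphased het) independently."""
    sites = [(v.pos, v.ref) for v in variants]
    flip_units: List[List[int]] = []
    ps_unit: Dict[Tuple[str, Optional[int]], List[int]] = {}
    for i, v in enumerate(variants):
        if not v.is_het:
            continue
        if v.phased and v.phase_set is not None:
            ps_unit.setdefault((v.chrom, v.phase_set), []).append(i)
        else:
            flip_units.append([i])
    flip_units.extend(ps_unit.values())
    if len(flip_units) > max_flips:
        flip_units = flip_units[:max_flips]
    base = []
    for v in variants:
        if not v.is_het:
            base.append((v.alt, v.alt))
        elif v.genotype == (1, 0):
            base.append((v.alt, v.ref))
        else:
            base.append((v.ref, v.alt))
    out: List[HaplotypePair] = []
    for mask in range(1 << len(flip_units)):
        alleles = list(base)
        for b, unit in enumerate(flip_units):
            if mask >> b & 1:
                for i in unit:
                    a1, a2 = alleles[i]
                    alleles[i] = (a2, a1)
        pair = apply_combination(window, start, sites, alleles)
        if pair is not None:
            out.append(pair)
    return out


def _group_haplotypes_match(
    t_vars: Sequence[Variant],
    q_vars: Sequence[Variant],
    window: str,
    start: int,
    max_flips: int,
) -> bool:
    t_pairs = _pairs_for(t_vars, window, start, max_flips)
    q_pairs = _pairs_for(q_vars, window, start, max_flips)
    return any(equivalent(tp, qp) for tp in t_pairs for qp in q_pairs)
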