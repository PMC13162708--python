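"""Genomic-context labels, nearest-gene assignment, and per-element score
aggregation.

Two labelling schemes share one TSS window (default 2 kb either side):

* three-way: TSS_PROXIMAL > GENIC > INTERGENIC
* four-way:  PROMOTER > EXONIC > INTRONIC > INTERGENIC_FEATURE

"Within <= 2 kb of the TSS" is read as >=1 bp overlap with the closed window
[tss - window, tss + window]; the half-open equivalent is
[tss - window, tss + window + 1). A midpoint or containment trigger is
available via ``tss_rule``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .classify import ConstraintCategory
from .intervals import GeneModel, GenomicInterval, ScoreTrack


class LocationLabel(str, Enum):
    TSS_PROXIMAL = "TSS_PROXIMAL"
    GENIC = "GENIC"
    INTERGENIC = "INTERGENIC"


class FeatureLabel(str, Enum):
    PROMOTER = "PROMOTER"
    EXONIC = "EXONIC"
    INTRONIC = "INTRONIC"
    INTERGENIC_FEATURE = "INTERGENIC_FEATURE"


def tss_window_interval(gene: GeneModel, window: int) -> GenomicInterval:
    """Closed window [tss - window, tss + window] as a half-open interval,
    clipped at 0."""
    tss = gene.tss
    return GenomicInterval(gene.interval.seq_id, max(0, tss - window), tss + window + 1)


def _hits_window(re: GenomicInterval, win: GenomicInterval, rule: str) -> bool:
    if rule == "overlap":
        return re.overlaps(win)
    if rule == "midpoint":
        mid = (re.start + re.end) // 2
        return re.seq_id == win.seq_id and win.start <= mid < win.end
    if rule == "containment":
        return re.seq_id == win.seq_id and win.start <= re.start and re.end <= win.end
    raise ValueError(f"unknown tss_rule {rule!r}")


def classify_location(re: GenomicInterval, genes: Sequence[GeneModel],
                      window: int = 2000, tss_rule: str = "overlap") -> LocationLabel:
    """Three-way label with precedence TSS_PROXIMAL > GENIC > INTERGENIC."""
    genic = False
    for g in genes:
        if _hits_window(re, tss_window_interval(g, window), tss_rule):
            return LocationLabel.TSS_PROXIMAL
        if re.overlaps(g.interval):
            genic = True
    return LocationLabel.GENIC if genic else LocationLabel.INTERGENIC


def classify_feature(re: GenomicInterval, genes: Sequence[GeneModel],
                     window: int = 2000, tss_rule: str = "overlap") -> FeatureLabel:
    """Four-way label with precedence PROMOTER > EXONIC > INTRONIC > intergenic."""
    exonic = genic = False
    for g in genes:
        if _hits_window(re, tss_window_interval(g, window), tss_rule):
            return FeatureLabel.PROMOTER
        if re.overlaps(g.interval):
            genic = True
            if any(re.overlaps(ex) for ex in g.exons):
                exonic = True
    if exonic:
        return FeatureLabel.EXONIC
    if genic:
        return FeatureLabel.INTRONIC
    return FeatureLabel.INTERGENIC_FEATURE


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Minimal base gap between two intervals on one sequence (0 if overlapping)."""
    if a.seq_id != b.seq_id:
        raise ValueError("intervals on different sequences")
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def nearest_gene(re: GenomicInterval, genes: Sequence[GeneModel]) -> tuple[str, int] | None:
    """Closest gene on the RE's sequence by interval-to-interval gap.

    Ties break to the lexicographically smaller gene_id. None if the RE's
    sequence carries no gene.
    """
    best: tuple[int, str] | None = None
    for g in genes:
        if g.interval.seq_id != re.seq_id:
            continue
        cand = (interval_gap(re, g.interval), g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[1], best[0]


@dataclass
class ScoreSummary:
    re_name: str
    mean_score: float | None   # None when no base is scored
    n_bases_scored: int


@dataclass
class CategoryScoreStats:
    category: ConstraintCategory
    n_res: int          # REs with a defined mean
    mean: float | None
    sd: float | None    # population SD (n denominator)


def score_interval(re: GenomicInterval, track: ScoreTrack) -> tuple[float, int]:
    """(sum of per-base scores, number of scored bases) over the interval."""
    total = 0.0
    n = 0
    for start, end, score in track.records(re.seq_id):
        lo, hi = max(start, re.start), min(end, re.end)
        if lo < hi:
            total += score * (hi - lo)
            n += hi - lo
    return total, n


def aggregate_scores(res: Sequence[GenomicInterval], track: ScoreTrack,
                     categories: Mapping[str, ConstraintCategory] | None = None
                     ) -> tuple[list[ScoreSummary], list[CategoryScoreStats]]:
    """Per-RE mean over scored bases, then per-category mean +/- population SD
    of the per-RE means. REs with no scored base are flagged (mean None) and
    excluded from category aggregates."""
    summaries: list[ScoreSummary] = []
    for iv in res:
        name = iv.name if iv.name else f"{iv.seq_id}:{iv.start}-{iv.end}"
        total, n = score_interval(iv, track)
        summaries.append(ScoreSummary(name, total / n if n else None, n))

    stats: list[CategoryScoreStats] = []
    if categories is not None:
        by_cat: dict[ConstraintCategory, list[float]] = {}
        for s in summaries:
            cat = categories.get(s.re_name)
            if cat is None or s.mean_score is None:
                continue
            by_cat.setdefault(ConstraintCategory(cat), []).append(s.mean_score)
        for cat in sorted(by_cat, key=lambda c: c.value):
            vals = by_cat[cat]
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
            stats.append(CategoryScoreStats(cat, len(vals), mean, sd))
    return summaries, stats


def label_proportions(labels: Iterable[Enum]) -> dict[str, float]:
    counts: dict[str, int] = {}
    total = 0
    for lab in labels:
        counts[lab.value] = counts.get(lab.value, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no labels")
    return {k: v / total for k, v in sorted(counts.items())}
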