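"""TE coverage and class composition, motif presence, and QTL intersection
per constraint category.

TE intervals are merged (union) per sequence before coverage so nested or
overlapping repeat calls are not double-counted. When TEs of different
classes overlap, the shared bases are attributed to the longer element
(tie -> lexicographically smaller class) so class contributions are disjoint
and sum exactly to total TE coverage. Every overlap is >=1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import CATEGORY_ORDER, ConstraintCategory
from .intervals import GenomicInterval, TEInterval

KNOWN_TE_CLASSES = ("DNA", "LINE", "LTR", "SINE", "Satellite", "Simple_repeat")
OTHER_CLASS = "OTHER"

OVERALL = "ALL"  # pseudo-category key for whole-set statistics


def merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans, sorted and disjoint."""
    if not spans:
        return []
    ordered = sorted(spans)
    out = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo > out[-1][1]:
            out.append([lo, hi])
        else:
            out[-1][1] = max(out[-1][1], hi)
    return [(lo, hi) for lo, hi in out]


def merge_intervals(ivs: Sequence[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    return {seq: merge_spans(spans) for seq, spans in by_seq.items()}


def _overlap_bases(iv: GenomicInterval, merged: dict[str, list[tuple[int, int]]]) -> int:
    total = 0
    for lo, hi in merged.get(iv.seq_id, []):
        total += max(0, min(hi, iv.end) - max(lo, iv.start))
    return total


def _touches(iv: GenomicInterval, merged: dict[str, list[tuple[int, int]]]) -> bool:
    return any(lo < iv.end and iv.start < hi for lo, hi in merged.get(iv.seq_id, []))


def _re_name(iv: GenomicInterval) -> str:
    return iv.name if iv.name else f"{iv.seq_id}:{iv.start}-{iv.end}"


def _category_of(iv: GenomicInterval, categories: Mapping[str, ConstraintCategory] | None):
    if categories is None:
        return ConstraintCategory.UNCLASSIFIED
    return ConstraintCategory(categories.get(_re_name(iv), ConstraintCategory.UNCLASSIFIED))


@dataclass
class CategoryCoverage:
    total_re_bases: int = 0
    te_covered_bases: int = 0
    class_covered_bases: dict[str, int] = field(default_factory=dict)

    @property
    def coverage_fraction(self) -> float:
        return self.te_covered_bases / self.total_re_bases if self.total_re_bases else 0.0

    def class_fraction(self, te_class: str) -> float:
        if not self.total_re_bases:
            return 0.0
        return self.class_covered_bases.get(te_class, 0) / self.total_re_bases


@dataclass
class CoverageReport:
    per_category: dict[str, CategoryCoverage]  # keys: category values + OVERALL


def te_coverage(res: Sequence[GenomicInterval], tes: Sequence[GenomicInterval],
                categories: Mapping[str, ConstraintCategory] | None = None) -> CoverageReport:
    """Fraction of RE bases covered by the merged TE track, per category and
    overall."""
    if not res:
        raise ValueError("no REs")
    merged = merge_intervals(tes)
    per: dict[str, CategoryCoverage] = {
        key: CategoryCoverage() for key in [c.value for c in CATEGORY_ORDER] + [OVERALL]
    }
    for iv in res:
        covered = _overlap_bases(iv, merged)
        for key in (_category_of(iv, categories).value, OVERALL):
            cc = per[key]
            cc.total_re_bases += iv.length
            cc.te_covered_bases += covered
    return CoverageReport(per)


def attribute_te_classes(tes: Sequence[TEInterval]) -> dict[str, list[tuple[int, int, str]]]:
    """Disjoint per-sequence spans labelled by TE class.

    Longer elements claim shared bases first; ties go to the
    lexicographically smaller class label. Unknown classes map to OTHER.
    """
    by_seq: dict[str, list[TEInterval]] = {}
    for te in tes:
        by_seq.setdefault(te.seq_id, []).append(te)
    out: dict[str, list[tuple[int, int, str]]] = {}
    for seq, items in by_seq.items():
        items = sorted(items, key=lambda t: (-(t.length), t.te_class, t.start))
        claimed: list[tuple[int, int]] = []
        pieces: list[tuple[int, int, str]] = []
        for te in items:
            cls = te.te_class if te.te_class in KNOWN_TE_CLASSES else OTHER_CLASS
            for lo, hi in _subtract_spans(te.start, te.end, claimed):
                pieces.append((lo, hi, cls))
                claimed.append((lo, hi))
            claimed.sort()
        pieces.sort()
        out[seq] = pieces
    return out


def _subtract_spans(lo: int, hi: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    cur = lo
    for s, e in sorted(claimed):
        if e <= cur:
            continue
        if s >= hi:
            break
        if s > cur:
            out.append((cur, min(s, hi)))
        cur = max(cur, e)
        if cur >= hi:
            break
    if cur < hi:
        out.append((cur, hi))
    return out


def te_class_composition(res: Sequence[GenomicInterval], tes: Sequence[TEInterval],
                         categories: Mapping[str, ConstraintCategory] | None = None) -> CoverageReport:
    """te_coverage plus per-class covered bases under disjoint attribution;
    class contributions sum exactly to total TE coverage."""
    report = te_coverage(res, tes, categories)
    attributed = attribute_te_classes(tes)
    for iv in res:
        pieces = attributed.get(iv.seq_id, [])
        for key in (_category_of(iv, categories).value, OVERALL):
            cc = report.per_category[key]
            for lo, hi, cls in pieces:
                ov = max(0, min(hi, iv.end) - max(lo, iv.start))
                if ov:
                    cc.class_covered_bases[cls] = cc.class_covered_bases.get(cls, 0) + ov
    return report


@dataclass
class CategoryMotifStats:
    n_res: int = 0
    n_res_with_motif: int = 0

    @property
    def proportion(self) -> float | None:
        return self.n_res_with_motif / self.n_res if self.n_res else None


@dataclass
class MotifReport:
    per_category: dict[str, CategoryMotifStats]
    n_motif_hits_total: int
    n_motif_hits_in_res: int
    n_motif_hits_overlapping_te: int          # among in-RE hits
    n_all_hits_overlapping_te: int            # among all hits

    @property
    def overlap_proportion_in_res(self) -> float | None:
        """Fraction of in-RE motif hits that touch a TE (Fig-3D style)."""
        if not self.n_motif_hits_in_res:
            return None
        return self.n_motif_hits_overlapping_te / self.n_motif_hits_in_res

    @property
    def overlap_proportion_all(self) -> float | None:
        if not self.n_motif_hits_total:
            return None
        return self.n_all_hits_overlapping_te / self.n_motif_hits_total


def motif_reports(res: Sequence[GenomicInterval], motif_hits: Sequence[GenomicInterval],
                  tes: Sequence[GenomicInterval],
                  categories: Mapping[str, ConstraintCategory] | None = None) -> MotifReport:
    """An RE "has a motif" iff >=1 hit overlaps it by >=1 bp; each hit counts
    once globally in the TE-overlap numerator/denominator even if it spans
    several REs. Both denominators (in-RE hits, all hits) are reported."""
    merged_res = merge_intervals(res)
    merged_tes = merge_intervals(tes)
    per: dict[str, CategoryMotifStats] = {
        c.value: CategoryMotifStats() for c in CATEGORY_ORDER
    }
    per[OVERALL] = CategoryMotifStats()

    motif_merged = merge_intervals(motif_hits)
    for iv in res:
        has = _touches(iv, motif_merged)
        for key in (_category_of(iv, categories).value, OVERALL):
            per[key].n_res += 1
            if has:
                per[key].n_res_with_motif += 1

    in_re = in_re_and_te = all_te = 0
    for hit in motif_hits:
        touches_te = _touches(hit, merged_tes)
        if touches_te:
            all_te += 1
        if _touches(hit, merged_res):
            in_re += 1
            if touches_te:
                in_re_and_te += 1
    return MotifReport(per, len(motif_hits), in_re, in_re_and_te, all_te)


def qtl_overlap(res: Sequence[GenomicInterval], qtls: Sequence[GenomicInterval],
                max_qtl_len: int = 1_000_000) -> list[tuple[str, str]]:
    """(re_name, qtl_name) pairs with >=1 bp overlap, after removing QTLs
    strictly longer than ``max_qtl_len`` (length == max is kept)."""
    kept = [q for q in qtls if q.length <= max_qtl_len]
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for iv in res:
        for q in kept:
            if iv.overlaps(q):
                key = (_re_name(iv), _re_name(q))
                if key not in seen:
                    seen.add(key)
                    pairs.append(key)
    return pairs
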