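"""N1/N2 computation and hierarchical constraint classification.

N1 counts target genomes in which >=90% of an element's bases are alignable;
N2 counts genomes with <=10% alignable. Classification is strict:

* CROSS_SPECIES_CONSTRAINED — fraction >= hi in every target genome;
* CLADE_SPECIFIC — >= hi in every clade member and <= lo in every outgroup;
* REFERENCE_SPECIES_SPECIFIC — <= lo in every target genome;
* UNCLASSIFIED — everything else.

Threshold comparisons are rational-exact (Fraction) so boundary cases like
27/30 vs 0.9 never depend on float rounding. Printed percentages are
floor-truncated, not rounded: 22,123/135,254 = 16.3567% prints as 16.35.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Sequence

from .chains import ConservationMatrix


class ConstraintCategory(str, Enum):
    CROSS_SPECIES_CONSTRAINED = "CROSS_SPECIES_CONSTRAINED"
    CLADE_SPECIFIC = "CLADE_SPECIFIC"
    REFERENCE_SPECIES_SPECIFIC = "REFERENCE_SPECIES_SPECIFIC"
    UNCLASSIFIED = "UNCLASSIFIED"


CATEGORY_ORDER = (
    ConstraintCategory.CROSS_SPECIES_CONSTRAINED,
    ConstraintCategory.CLADE_SPECIFIC,
    ConstraintCategory.REFERENCE_SPECIES_SPECIFIC,
    ConstraintCategory.UNCLASSIFIED,
)


def _as_fraction(x) -> Fraction:
    """Exact rational view of a threshold or fraction.

    Floats go through their shortest decimal repr so a literal 0.9 means
    9/10, not the binary double below it.
    """
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(repr(x))
    return Fraction(x)


@dataclass
class ConstraintProfile:
    re_name: str
    fractions: dict[str, Fraction]
    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("n1/n2 must be >= 0")
        if self.n1 + self.n2 > len(self.fractions):
            raise ValueError("n1 + n2 exceeds genome count")


@dataclass(frozen=True)
class GenomeGrouping:
    """Partition of the target genomes into clade members and outgroup."""

    clade_members: frozenset[str]
    outgroup_members: frozenset[str]

    def __post_init__(self):
        overlap = self.clade_members & self.outgroup_members
        if overlap:
            raise ValueError(f"genomes in both clade and outgroup: {sorted(overlap)}")
        if not self.clade_members or not self.outgroup_members:
            raise ValueError("both clade and outgroup must be non-empty")

    @property
    def all_genomes(self) -> frozenset[str]:
        return self.clade_members | self.outgroup_members


def compute_n1_n2(fractions: Mapping[str, object], hi=0.9, lo=0.1) -> tuple[int, int]:
    """Count genomes with fraction >= hi (N1) and <= lo (N2), boundaries inclusive."""
    hi_f, lo_f = _as_fraction(hi), _as_fraction(lo)
    if not lo_f < hi_f:
        raise ValueError(f"need lo < hi, got lo={lo} hi={hi}")
    n1 = n2 = 0
    for genome, f in fractions.items():
        fr = _as_fraction(f)
        if not (0 <= fr <= 1):
            raise ValueError(f"genome {genome}: fraction {f} outside [0, 1]")
        if fr >= hi_f:
            n1 += 1
        if fr <= lo_f:
            n2 += 1
    return n1, n2


def build_profile(re_name: str, fractions: Mapping[str, object], hi=0.9, lo=0.1) -> ConstraintProfile:
    n1, n2 = compute_n1_n2(fractions, hi, lo)
    return ConstraintProfile(re_name, {g: _as_fraction(f) for g, f in fractions.items()}, n1, n2)


def classify_re(profile: ConstraintProfile, grouping: GenomeGrouping,
                hi=0.9, lo=0.1, lenient_outgroup: bool = False) -> ConstraintCategory:
    """Assign one category per the strict hierarchy (see module docstring).

    ``lenient_outgroup`` relaxes the clade-specific outgroup condition from
    "fraction <= lo" to "fraction < hi".
    """
    hi_f, lo_f = _as_fraction(hi), _as_fraction(lo)
    missing = grouping.all_genomes - set(profile.fractions)
    if missing:
        raise ValueError(f"profile {profile.re_name} missing genomes: {sorted(missing)}")
    f = {g: _as_fraction(v) for g, v in profile.fractions.items()}
    genomes = grouping.all_genomes
    if all(f[g] >= hi_f for g in genomes):
        return ConstraintCategory.CROSS_SPECIES_CONSTRAINED
    if all(f[g] <= lo_f for g in genomes):
        return ConstraintCategory.REFERENCE_SPECIES_SPECIFIC
    out_ok = (
        all(f[g] < hi_f for g in grouping.outgroup_members)
        if lenient_outgroup
        else all(f[g] <= lo_f for g in grouping.outgroup_members)
    )
    if out_ok and all(f[g] >= hi_f for g in grouping.clade_members):
        return ConstraintCategory.CLADE_SPECIFIC
    return ConstraintCategory.UNCLASSIFIED


def classify_matrix(matrix: ConservationMatrix, grouping: GenomeGrouping,
                    hi=0.9, lo=0.1, lenient_outgroup: bool = False
                    ) -> list[tuple[str, ConstraintProfile, ConstraintCategory]]:
    """Classify every matrix row; matrix columns must cover the grouping."""
    missing = grouping.all_genomes - set(matrix.genome_names)
    if missing:
        raise ValueError(f"matrix lacks genomes required by grouping: {sorted(missing)}")
    out = []
    for i, name in enumerate(matrix.re_names):
        fracs = {g: f for g, f in matrix.row(i).items() if g in grouping.all_genomes}
        profile = build_profile(name, fracs, hi, lo)
        out.append((name, profile, classify_re(profile, grouping, hi, lo, lenient_outgroup)))
    return out


def truncate_percent(count: int, total: int, decimals: int) -> str:
    """Floor-truncated percentage string, e.g. (22123, 135254, 2) -> '16.35'."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError(f"count {count} outside [0, {total}]")
    scaled = count * 100 * 10 ** decimals // total
    if decimals == 0:
        return str(scaled)
    s = str(scaled).rjust(decimals + 1, "0")
    return s[:-decimals] + "." + s[-decimals:]


@dataclass
class SummaryReport:
    total: int
    counts: dict[ConstraintCategory, int]
    percentages: dict[ConstraintCategory, str] = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts do not sum to total")
        if not self.percentages:
            self.percentages = {
                cat: truncate_percent(self.counts.get(cat, 0), self.total, 2)
                for cat in CATEGORY_ORDER
            }

    def as_table(self) -> str:
        lines = ["category\tcount\tpercent"]
        for cat in CATEGORY_ORDER:
            lines.append(f"{cat.value}\t{self.counts.get(cat, 0)}\t{self.percentages[cat]}")
        lines.append(f"TOTAL\t{self.total}\t100.00")
        return "\n".join(lines)


def summarize_classification(categories: Iterable[tuple[str, ConstraintCategory]]) -> SummaryReport:
    """Per-category counts and floor-truncated percentages (2 decimal places)."""
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    total = 0
    for _, cat in categories:
        counts[ConstraintCategory(cat)] += 1
        total += 1
    if total == 0:
        raise ValueError("no REs to summarize")
    return SummaryReport(total, counts)


@dataclass
class IntraspecificSummary:
    total: int
    k: int
    count_all: int
    count_at_least_k: int
    percent_all: str
    percent_at_least_k: str


def intraspecific_summary(matrix: ConservationMatrix, hi=0.9, k: int = 30) -> IntraspecificSummary:
    """Count REs mapped (fraction >= hi) in every genome and in >= k genomes.

    Percentages are floor-truncated to 1 decimal place. Bulk comparison uses
    floats: matrix fractions are ratios of genomic-scale integers, for which
    the nearest-double comparison against the threshold is exact.
    """
    n_res, n_genomes = matrix.shape
    if n_res == 0 or n_genomes == 0:
        raise ValueError("empty conservation matrix")
    if not (1 <= k <= n_genomes):
        raise ValueError(f"k={k} outside [1, {n_genomes}]")
    vals = matrix.values()
    ok = vals >= float(_as_fraction(hi))
    per_row = ok.sum(axis=1)
    count_all = int((per_row == n_genomes).sum())
    count_k = int((per_row >= k).sum())
    return IntraspecificSummary(
        total=n_res, k=k, count_all=count_all, count_at_least_k=count_k,
        percent_all=truncate_percent(count_all, n_res, 1),
        percent_at_least_k=truncate_percent(count_k, n_res, 1),
    )


def write_classes_tsv(rows: Sequence[tuple[str, ConstraintProfile, ConstraintCategory]], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("re_name\tn1\tn2\tcategory\n")
        for name, profile, cat in rows:
            fh.write(f"{name}\t{profile.n1}\t{profile.n2}\t{cat.value}\n")


def read_classes_tsv(path) -> list[tuple[str, ConstraintCategory]]:
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "re_name" not in header or "category" not in header:
            raise ValueError(f"{path}: expected columns re_name and category")
        i_name, i_cat = header.index("re_name"), header.index("category")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            out.append((cols[i_name], ConstraintCategory(cols[i_cat])))
    return out
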