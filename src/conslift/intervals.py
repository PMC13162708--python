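"""Coordinate data model and readers/writers for the external text formats.

Every reader emits 0-based half-open intervals regardless of the source
dialect: BED is native, GFF3 and RepeatMasker ``.out`` are 1-based inclusive
and converted at the boundary. All readers accept plain or gzip-compressed
files (detected by the ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in an input file; carries file path and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.seq_id, self.start + offset, self.end + offset, self.strand, self.name
        )


@dataclass(frozen=True)
class TEInterval(GenomicInterval):
    """Transposable-element interval carrying RepeatMasker class/family labels."""

    te_class: str = ""
    te_family: str = ""


@dataclass
class GeneModel:
    """Gene with TSS derived from strand and optional exon structure."""

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = ordered

    @property
    def tss(self) -> int:
        """TSS offset: interval start on '+', last base (end-1) on '-'."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class ScoreTrack:
    """Per-sequence sorted, non-overlapping scored intervals (per-base scores)."""

    def __init__(self, records: Sequence[tuple[GenomicInterval, float]] = ()):
        by_seq: dict[str, list[tuple[int, int, float]]] = {}
        for iv, score in records:
            by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end, float(score)))
        self._by_seq = {}
        for seq, recs in by_seq.items():
            recs.sort()
            for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping score records on {seq}: [{s1},{e1}) and start {s2}"
                    )
            self._by_seq[seq] = recs

    def records(self, seq_id: str) -> list[tuple[int, int, float]]:
        return self._by_seq.get(seq_id, [])

    def sequences(self) -> list[str]:
        return sorted(self._by_seq)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_seq.values())


@dataclass
class DivergenceTable:
    """Rows of (taxon, divergence time in MYA, clade label)."""

    rows: list[tuple[str, float, str]]

    def __post_init__(self):
        names = [t for t, _, _ in self.rows]
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate taxon names: {dupes}")
        for taxon, mya, _ in self.rows:
            if not (mya >= 0 and mya == mya and mya != float("inf")):
                raise ValueError(f"taxon {taxon}: divergence_mya must be finite and >= 0")

    def mya(self, taxon: str) -> float:
        for t, m, _ in self.rows:
            if t == taxon:
                return m
        raise KeyError(taxon)

    def clade_of(self, taxon: str) -> str:
        for t, _, c in self.rows:
            if t == taxon:
                return c
        raise KeyError(taxon)

    def taxa(self) -> list[str]:
        return [t for t, _, _ in self.rows]


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _iter_lines(path) -> Iterator[tuple[int, str]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            yield lineno, raw.rstrip("\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (extra columns ignored); strand from column 6 when present."""
    out: list[GenomicInterval] = []
    seen_names: Counter = Counter()
    for lineno, line in _iter_lines(path):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(cols)}")
        seq_id = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {cols[1]!r}/{cols[2]!r}") from None
        name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
        strand = cols[5] if len(cols) > 5 else "."
        if strand not in VALID_STRANDS:
            raise ParseError(path, lineno, f"invalid strand {strand!r}")
        try:
            iv = GenomicInterval(seq_id, start, end, strand, name)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        if name is not None:
            seen_names[name] += 1
        out.append(iv)
    dupes = [n for n, c in seen_names.items() if c > 1]
    if dupes:
        logger.warning("%s: %d duplicate interval names (e.g. %s)", path, len(dupes), dupes[0])
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, extra_columns=None) -> None:
    """Write BED6 (or BED4 if no interval carries a strand).

    ``extra_columns`` optionally maps list index -> extra string appended
    after the strand column (used for truth-label columns).
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.seq_id, str(iv.start), str(iv.end), iv.name or ".", "0", iv.strand]
            if extra_columns is not None:
                fields.append(str(extra_columns[i]))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _gff_attributes(field: str, path, lineno) -> dict[str, str]:
    attrs = {}
    for part in field.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
        elif " " in part:  # GTF-ish key "value"
            key, _, value = part.partition(" ")
            value = value.strip().strip('"')
        else:
            continue
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff_genes(path, biotype_filter: str | None = "protein_coding") -> list[GeneModel]:
    """Parse gene + exon features from GFF3, keeping genes of ``biotype_filter``.

    Exons may point at the gene directly or via an intermediate transcript
    feature (Parent chain of depth 2). GFF3 1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    genes: dict[str, GeneModel] = {}
    transcript_parent: dict[str, str] = {}
    pending_exons: list[tuple[str, GenomicInterval]] = []

    for lineno, line in _iter_lines(path):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ParseError(path, lineno, f"expected 9 columns, got {len(cols)}")
        seq_id, _, ftype, start_s, end_s, _, strand, _, attr_s = cols[:9]
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        attrs = _gff_attributes(attr_s, path, lineno)
        if ftype == "gene":
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"gene with unknown strand {strand!r}")
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ParseError(path, lineno, "gene feature missing ID attribute")
            biotype = attrs.get("biotype") or attrs.get("gene_biotype") or ""
            genes[gene_id] = GeneModel(
                gene_id,
                GenomicInterval(seq_id, start1 - 1, end1, strand, gene_id),
                biotype=biotype,
            )
        elif ftype in ("mRNA", "transcript"):
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid and parent:
                transcript_parent[tid] = parent
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                continue
            pending_exons.append(
                (parent, GenomicInterval(seq_id, start1 - 1, end1, strand if strand in VALID_STRANDS else "."))
            )

    for parent, exon in pending_exons:
        gene_id = parent if parent in genes else transcript_parent.get(parent)
        if gene_id in genes:
            genes[gene_id].exons.append(exon)

    out = []
    for g in genes.values():
        if biotype_filter is not None and g.biotype != biotype_filter:
            continue
        # re-run exon validation/sorting now that exons are attached
        out.append(GeneModel(g.gene_id, g.interval, g.biotype, g.exons))
    out.sort(key=lambda g: (g.interval.seq_id, g.interval.start, g.gene_id))
    return out


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [iv.seq_id, "conslift", "gene", str(iv.start + 1), str(iv.end), ".",
                     iv.strand, ".", f"ID={g.gene_id};biotype={g.biotype}"]
                ) + "\n"
            )
            for k, ex in enumerate(g.exons, start=1):
                fh.write(
                    "\t".join(
                        [ex.seq_id, "conslift", "exon", str(ex.start + 1), str(ex.end), ".",
                         iv.strand, ".", f"ID={g.gene_id}.e{k};Parent={g.gene_id}"]
                    ) + "\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out

def read_repeatmasker_out(path) -> list[TEInterval]:
    """Parse RepeatMasker ``.out``: 3 header lines then whitespace columns.

    Query coordinates (cols 5-7) are 1-based inclusive; the repeat
    class/family (col 11) is split on "/" into class and family.
    """
    out: list[TEInterval] = []
    for lineno, line in _iter_lines(path):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("SW", "score")):  # header lines
            continue
        cols = stripped.split()
        if len(cols) < 11:
            raise ParseError(path, lineno, f"truncated line: {len(cols)} columns, expected >=11")
        try:
            begin1, end1 = int(cols[5]), int(cols[6])
        except ValueError:
            raise ParseError(path, lineno, "non-integer query coordinates") from None
        seq_id, repeat_name, cf = cols[4], cols[9], cols[10]
        te_class, _, te_family = cf.partition("/")
        try:
            out.append(
                TEInterval(seq_id, begin1 - 1, end1, ".", repeat_name,
                           te_class=te_class, te_family=te_family)
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def read_te_bed(path) -> list[TEInterval]:
    """BED with class (and optional family) labels in columns 7/8; falls back
    to column 4 name of the form class/family."""
    out: list[TEInterval] = []
    for lineno, line in _iter_lines(path):
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(path, lineno, "expected >=3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        name = cols[3] if len(cols) > 3 else None
        if len(cols) > 6:
            te_class, te_family = cols[6], cols[7] if len(cols) > 7 else ""
        elif name and "/" in name:
            te_class, _, te_family = name.partition("/")
        else:
            te_class, te_family = (name or ""), ""
        try:
            out.append(TEInterval(cols[0], start, end, ".", name, te_class=te_class, te_family=te_family))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def write_te_bed(tes: Sequence[TEInterval], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for te in tes:
            fh.write(
                "\t".join([te.seq_id, str(te.start), str(te.end), te.name or ".",
                           "0", ".", te.te_class, te.te_family]) + "\n"
            )


# ---------------------------------------------------------------------------
# Score tracks (bedGraph / fixed-step wig)

def read_score_track(path) -> ScoreTrack:
    """Read a bedGraph (4 columns) or fixed-step wig file into a ScoreTrack."""
    records: list[tuple[GenomicInterval, float]] = []
    wig_state: dict | None = None
    for lineno, line in _iter_lines(path):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        if stripped.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in stripped.split()[1:])
            try:
                wig_state = {
                    "chrom": fields["chrom"],
                    "pos": int(fields["start"]) - 1,  # wig is 1-based
                    "step": int(fields.get("step", 1)),
                    "span": int(fields.get("span", 1)),
                }
            except (KeyError, ValueError):
                raise ParseError(path, lineno, "malformed fixedStep declaration") from None
            continue
        if stripped.startswith("variableStep"):
            raise ParseError(path, lineno, "variableStep wig not supported")
        cols = stripped.split()
        if wig_state is not None and len(cols) == 1:
            try:
                score = float(cols[0])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric wig value {cols[0]!r}") from None
            p = wig_state["pos"]
            records.append(
                (GenomicInterval(wig_state["chrom"], p, p + wig_state["span"]), score)
            )
            wig_state["pos"] = p + wig_state["step"]
            continue
        if len(cols) < 4:
            raise ParseError(path, lineno, f"expected 4 bedGraph columns, got {len(cols)}")
        wig_state = None
        try:
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
            score = float(cols[3])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        records.append((iv, score))
    try:
        return ScoreTrack(records)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def write_bedgraph(track: ScoreTrack, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for seq in track.sequences():
            for start, end, score in track.records(seq):
                fh.write(f"{seq}\t{start}\t{end}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Divergence table

DIVERGENCE_HEADER = ("taxon", "divergence_mya", "clade")


def read_divergence_table(path) -> DivergenceTable:
    rows: list[tuple[str, float, str]] = []
    lines = list(_iter_lines(path))
    if not lines:
        raise ParseError(path, 0, "empty divergence table")
    header = tuple(lines[0][1].rstrip().split("\t"))
    if header != DIVERGENCE_HEADER:
        raise ParseError(path, 1, f"expected header {DIVERGENCE_HEADER}, got {header}")
    for lineno, line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(cols)}")
        try:
            mya = float(cols[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric divergence {cols[1]!r}") from None
        rows.append((cols[0], mya, cols[2]))
    try:
        return DivergenceTable(rows)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def write_divergence_table(table: DivergenceTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(DIVERGENCE_HEADER) + "\n")
        for taxon, mya, clade in table.rows:
            fh.write(f"{taxon}\t{mya:g}\t{clade}\n")
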