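"""UCSC chain parsing and interval projection.

A chain records a pairwise alignment as ungapped blocks separated by gaps on
the source (t) and target (q) sides. Projection walks a source interval
through the blocks of every overlapping chain: a source base counts as
aligned iff it falls inside an ungapped block of at least one chain
(``mode="any"``, the default) or of the best-scoring overlapping chain
(``mode="best"``).

Aligned fractions are kept as exact integer counts over interval lengths so
threshold tests at exactly 90%/10% are reproducible.
"""

from __future__ import annotations

import gzip
import io
from bisect import bisect_right
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval


class ChainIntegrityError(ValueError):
    """Chain whose block sums disagree with its header spans."""


@dataclass(frozen=True)
class ChainBlock:
    size: int   # aligned bases
    dt: int     # gap advance on source (t) after the block
    dq: int     # gap advance on target (q) after the block

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"block size must be >= 1, got {self.size}")
        if self.dt < 0 or self.dq < 0:
            raise ValueError("gap advances must be >= 0")


@dataclass
class ChainAlignment:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: list[ChainBlock] = field(default_factory=list)

    def validate(self) -> None:
        if self.t_strand != "+":
            raise ChainIntegrityError(f"chain {self.chain_id}: tStrand must be '+'")
        if self.q_strand not in ("+", "-"):
            raise ChainIntegrityError(f"chain {self.chain_id}: qStrand must be '+' or '-'")
        if not self.blocks:
            raise ChainIntegrityError(f"chain {self.chain_id}: no blocks")
        last = self.blocks[-1]
        if last.dt != 0 or last.dq != 0:
            raise ChainIntegrityError(f"chain {self.chain_id}: last block must have dt=dq=0")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainIntegrityError(
                f"chain {self.chain_id}: block t-span {t_span} != header span "
                f"{self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainIntegrityError(
                f"chain {self.chain_id}: block q-span {q_span} != header span "
                f"{self.q_end - self.q_start}"
            )
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ChainIntegrityError(f"chain {self.chain_id}: t range outside [0, tSize]")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ChainIntegrityError(f"chain {self.chain_id}: q range outside [0, qSize]")

    def block_coordinates(self) -> Iterable[tuple[int, int, int]]:
        """Yield (t_block_start, t_block_end, q_block_start) per ungapped block.

        q coordinates are on the chain's q_strand (reversed coordinates when
        q_strand == '-', per UCSC convention).
        """
        t, q = self.t_start, self.q_start
        for b in self.blocks:
            yield t, t + b.size, q
            t += b.size + b.dt
            q += b.size + b.dq


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_chain_file(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file, validating every chain eagerly on load."""
    chains: list[ChainAlignment] = []
    current: ChainAlignment | None = None
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if current is not None:
                    current.validate()
                    chains.append(current)
                fields = line.split()
                if len(fields) != 13:
                    raise ChainIntegrityError(
                        f"{path}:{lineno}: chain header has {len(fields)} fields, expected 13"
                    )
                current = ChainAlignment(
                    score=float(fields[1]),
                    t_name=fields[2], t_size=int(fields[3]), t_strand=fields[4],
                    t_start=int(fields[5]), t_end=int(fields[6]),
                    q_name=fields[7], q_size=int(fields[8]), q_strand=fields[9],
                    q_start=int(fields[10]), q_end=int(fields[11]),
                    chain_id=int(fields[12]),
                )
            else:
                if current is None:
                    raise ChainIntegrityError(f"{path}:{lineno}: block line before any chain header")
                parts = line.split()
                if len(parts) == 1:
                    current.blocks.append(ChainBlock(int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    current.blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ChainIntegrityError(f"{path}:{lineno}: malformed block line {line!r}")
    if current is not None:
        current.validate()
        chains.append(current)
    return chains


def write_chain_file(chains: Sequence[ChainAlignment], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} "
                f"{c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


@dataclass(frozen=True)
class _IndexedBlock:
    t_start: int
    t_end: int
    q_start: int          # q_strand coordinates at t_start
    q_strand: str
    q_name: str
    q_size: int
    score: float
    chain_id: int


class ChainIndex:
    """Per source sequence, blocks sorted by start with a running-max end,
    giving O(log n + k) overlap retrieval."""

    def __init__(self, chains: Sequence[ChainAlignment]):
        for c in chains:
            c.validate()
        by_seq: dict[str, list[_IndexedBlock]] = {}
        for c in chains:
            for t0, t1, q0 in c.block_coordinates():
                by_seq.setdefault(c.t_name, []).append(
                    _IndexedBlock(t0, t1, q0, c.q_strand, c.q_name, c.q_size, c.score, c.chain_id)
                )
        self._blocks: dict[str, list[_IndexedBlock]] = {}
        self._starts: dict[str, list[int]] = {}
        self._cummax_end: dict[str, list[int]] = {}
        for seq, blocks in by_seq.items():
            blocks.sort(key=lambda b: (b.t_start, b.t_end))
            self._blocks[seq] = blocks
            self._starts[seq] = [b.t_start for b in blocks]
            cm, m = [], 0
            for b in blocks:
                m = max(m, b.t_end)
                cm.append(m)
            self._cummax_end[seq] = cm

    def overlapping_blocks(self, seq_id: str, start: int, end: int) -> list[_IndexedBlock]:
        blocks = self._blocks.get(seq_id)
        if not blocks:
            return []
        hi = bisect_right(self._starts[seq_id], end - 1)
        # first index that can still overlap: cummax_end must exceed `start`
        lo = bisect_right(self._cummax_end[seq_id], start)
        return [b for b in blocks[lo:hi] if b.t_end > start]


@dataclass
class ProjectionResult:
    source: GenomicInterval
    mapped_segments: list[tuple[str, GenomicInterval, str]]
    aligned_bases: int

    @property
    def aligned_fraction(self) -> Fraction:
        return Fraction(self.aligned_bases, self.source.length)


def project_interval(iv: GenomicInterval, index: ChainIndex, mode: str = "any") -> ProjectionResult:
    """Project a source interval; see module docstring for the aligned-base rule.

    Overlapping chains that map one source base to several target positions
    contribute that base once to ``aligned_bases``; ``mapped_segments`` keep
    the highest-score chain's image of each base.
    """
    if mode not in ("any", "best"):
        raise ValueError(f"mode must be 'any' or 'best', got {mode!r}")
    hits = index.overlapping_blocks(iv.seq_id, iv.start, iv.end)
    if mode == "best" and hits:
        best = max(h.score for h in hits)
        best_ids = {h.chain_id for h in hits if h.score == best}
        # deterministic tie-break: keep the smallest chain id among top scores
        keep = min(best_ids)
        hits = [h for h in hits if h.chain_id == keep]

    # clip each block to the interval
    pieces = []
    for b in hits:
        lo, hi = max(b.t_start, iv.start), min(b.t_end, iv.end)
        if lo < hi:
            pieces.append((lo, hi, b))
    if not pieces:
        return ProjectionResult(iv, [], 0)

    # union size for aligned_bases
    spans = sorted((lo, hi) for lo, hi, _ in pieces)
    aligned = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            aligned += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    aligned += cur_hi - cur_lo

    # greedy attribution by descending score for mapped segments
    pieces.sort(key=lambda p: (-p[2].score, p[2].chain_id, p[0]))
    claimed: list[tuple[int, int]] = []  # disjoint, sorted lazily
    segments: list[tuple[str, GenomicInterval, str]] = []
    for lo, hi, b in pieces:
        remaining = _subtract(lo, hi, claimed)
        for s, e in remaining:
            claimed.append((s, e))
            off = s - b.t_start
            if b.q_strand == "+":
                q_lo = b.q_start + off
                q_hi = q_lo + (e - s)
            else:
                # q coords are on the reversed strand; convert to forward
                rev_lo = b.q_start + off
                rev_hi = rev_lo + (e - s)
                q_lo = b.q_size - rev_hi
                q_hi = b.q_size - rev_lo
            segments.append((b.q_name, GenomicInterval(b.q_name, q_lo, q_hi), b.q_strand))
        claimed.sort()
    segments.sort(key=lambda s: (s[0], s[1].start))
    return ProjectionResult(iv, segments, aligned)


def _subtract(lo: int, hi: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """[lo, hi) minus already-claimed disjoint spans."""
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


class ConservationMatrix:
    """REs x genomes matrix of aligned-base fractions in [0, 1].

    When built from projections the exact integer counts are retained so
    threshold comparisons are rational-exact; when read from TSV the printed
    decimals are parsed exactly via Fraction.
    """

    def __init__(self, re_names: Sequence[str], genome_names: Sequence[str],
                 fractions: Sequence[Sequence[Fraction]]):
        if len(set(genome_names)) != len(genome_names):
            raise ValueError("duplicate genome names")
        self.re_names = list(re_names)
        self.genome_names = list(genome_names)
        if isinstance(fractions, np.ndarray):
            self.exact = fractions.astype(float)
            if self.exact.shape != (len(self.re_names), len(self.genome_names)):
                raise ValueError("array shape mismatch")
            if self.exact.size and (self.exact.min() < 0 or self.exact.max() > 1):
                raise ValueError("fraction outside [0, 1]")
            return
        self.exact = [list(row) for row in fractions]
        if len(self.exact) != len(self.re_names):
            raise ValueError("row count mismatch")
        for row in self.exact:
            if len(row) != len(self.genome_names):
                raise ValueError("column count mismatch")
            for f in row:
                if not (0 <= f <= 1):
                    raise ValueError(f"fraction {f} outside [0, 1]")

    @classmethod
    def from_float_array(cls, re_names: Sequence[str], genome_names: Sequence[str],
                         array: np.ndarray) -> "ConservationMatrix":
        """Bulk float-backed construction (loses exact-rational cells)."""
        return cls(re_names, genome_names, np.asarray(array, dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.re_names), len(self.genome_names)

    def values(self) -> np.ndarray:
        if isinstance(self.exact, np.ndarray):
            return self.exact
        return np.array([[float(f) for f in row] for row in self.exact], dtype=float)

    def row(self, i: int) -> dict[str, Fraction]:
        if isinstance(self.exact, np.ndarray):
            return {g: Fraction(repr(v)) for g, v in zip(self.genome_names, self.exact[i])}
        return dict(zip(self.genome_names, self.exact[i]))

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("re_name\t" + "\t".join(self.genome_names) + "\n")
            for name, row in zip(self.re_names, self.exact):
                fh.write(name + "\t" + "\t".join(f"{float(f):.6f}" for f in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ConservationMatrix":
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "re_name":
                raise ValueError(f"{path}: expected header starting with 're_name'")
            genomes = header[1:]
            names, rows = [], []
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) != len(genomes) + 1:
                    raise ValueError(f"{path}: ragged row for {cols[0]!r}")
                names.append(cols[0])
                rows.append([Fraction(c) for c in cols[1:]])
        return cls(names, genomes, rows)


def conservation_matrix(res: Sequence[GenomicInterval],
                        indexes: Mapping[str, ChainIndex],
                        genome_order: Sequence[str] | None = None,
                        mode: str = "any") -> ConservationMatrix:
    """Project every RE through every genome's chain index.

    Row order follows the input REs; column order follows ``genome_order``
    (default: sorted genome names, recorded in the matrix).
    """
    if not res:
        raise ValueError("need at least one RE")
    if not indexes:
        raise ValueError("need at least one genome")
    order = list(genome_order) if genome_order is not None else sorted(indexes)
    if len(set(order)) != len(order):
        raise ValueError("duplicate genome names in order")
    missing = [g for g in order if g not in indexes]
    if missing:
        raise ValueError(f"genomes in order but without chains: {missing}")
    names = [iv.name if iv.name else f"{iv.seq_id}:{iv.start}-{iv.end}" for iv in res]
    rows = []
    for iv in res:
        rows.append([project_interval(iv, indexes[g], mode=mode).aligned_fraction for g in order])
    return ConservationMatrix(names, order, rows)
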