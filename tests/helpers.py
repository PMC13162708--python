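"""Independent brute-force oracles and random-fixture builders.

Everything here deliberately avoids the package's own fast paths: projection
walks every base through every chain, overlap statistics are quadratic
all-pairs scans, and percentages use Decimal floor division.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, Decimal

import numpy as np

from conslift.chains import ChainAlignment, ChainBlock
from conslift.intervals import GenomicInterval


# ---------------------------------------------------------------------------
# per-base chain walking

def chain_base_map(chain: ChainAlignment) -> list[tuple[int, int]]:
    """(source base, forward-strand target base) for every aligned base."""
    pairs = []
    t, q = chain.t_start, chain.q_start
    for b in chain.blocks:
        for k in range(b.size):
            q_pos = q + k
            if chain.q_strand == "-":
                q_pos = chain.q_size - q_pos - 1
            pairs.append((t + k, q_pos))
        t += b.size + b.dt
        q += b.size + b.dq
    return pairs


def brute_force_aligned_bases(iv: GenomicInterval, chains: list[ChainAlignment]) -> int:
    """Walk every base of the interval through every chain."""
    aligned = set()
    for c in chains:
        if c.t_name != iv.seq_id:
            continue
        for t, _ in chain_base_map(c):
            if iv.start <= t < iv.end:
                aligned.add(t)
    return len(aligned)


def invert_chain(chain: ChainAlignment, new_id: int = 1) -> ChainAlignment:
    """Exact inverse built from the per-base map (target becomes source)."""
    pairs = sorted((q, t) for t, q in chain_base_map(chain))
    # group into runs where both coordinates advance by +1 (q_strand '+')
    # or source +1 / old-source -1 (q_strand '-')
    sgn = 1 if chain.q_strand == "+" else -1
    runs: list[list[tuple[int, int]]] = [[pairs[0]]]
    for prev, cur in zip(pairs, pairs[1:]):
        if cur[0] == prev[0] + 1 and cur[1] == prev[1] + sgn:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    q_size = chain.t_size
    blocks = []
    t_starts, q_starts = [], []
    for run in runs:
        t0 = run[0][0]
        fwd0 = min(run[0][1], run[-1][1])
        q0 = fwd0 if sgn == 1 else q_size - (fwd0 + len(run))
        t_starts.append(t0)
        q_starts.append(q0)
        blocks.append(len(run))
    chain_blocks = []
    for i, size in enumerate(blocks):
        dt = t_starts[i + 1] - (t_starts[i] + size) if i + 1 < len(blocks) else 0
        dq = q_starts[i + 1] - (q_starts[i] + size) if i + 1 < len(blocks) else 0
        chain_blocks.append(ChainBlock(size, dt, dq))
    inv = ChainAlignment(
        score=chain.score,
        t_name=chain.q_name, t_size=chain.q_size, t_strand="+",
        t_start=t_starts[0], t_end=t_starts[-1] + blocks[-1],
        q_name=chain.t_name, q_size=q_size, q_strand=chain.q_strand,
        q_start=q_starts[0], q_end=q_starts[-1] + blocks[-1],
        chain_id=new_id, blocks=chain_blocks,
    )
    inv.validate()
    return inv


def random_chain(rng: np.random.Generator, t_name: str, t_size: int,
                 q_name: str = "target", chain_id: int = 1,
                 max_blocks: int = 6) -> ChainAlignment:
    """A structurally valid random chain over the source sequence."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    sizes = rng.integers(1, 40, size=n_blocks)
    dts = rng.integers(0, 30, size=n_blocks)
    dqs = rng.integers(0, 30, size=n_blocks)
    dts[-1] = dqs[-1] = 0
    t_span = int(sizes.sum() + dts[:-1].sum())
    q_span = int(sizes.sum() + dqs[:-1].sum())
    if t_span >= t_size:
        sizes = np.maximum(1, sizes // 4)
        dts = dts // 4
        dts[-1] = 0
        t_span = int(sizes.sum() + dts[:-1].sum())
        q_span = int(sizes.sum() + dqs[:-1].sum())
    t_start = int(rng.integers(0, max(1, t_size - t_span)))
    q_strand = "+" if rng.random() < 0.5 else "-"
    q_size = q_span + int(rng.integers(0, 50))
    q_start = int(rng.integers(0, q_size - q_span + 1))
    chain = ChainAlignment(
        score=float(rng.integers(1, 10_000)),
        t_name=t_name, t_size=t_size, t_strand="+",
        t_start=t_start, t_end=t_start + t_span,
        q_name=q_name, q_size=q_size, q_strand=q_strand,
        q_start=q_start, q_end=q_start + q_span,
        chain_id=chain_id,
        blocks=[ChainBlock(int(s), int(dt), int(dq))
                for s, dt, dq in zip(sizes, dts, dqs)],
    )
    chain.validate()
    return chain


# ---------------------------------------------------------------------------
# quadratic overlap oracles

def brute_covered_bases(iv: GenomicInterval, tracks: list[GenomicInterval]) -> int:
    bases = set()
    for t in tracks:
        if t.seq_id != iv.seq_id:
            continue
        lo, hi = max(t.start, iv.start), min(t.end, iv.end)
        bases.update(range(lo, hi))
    return len(bases)


def brute_overlap_pairs(res, others) -> set[tuple[str, str]]:
    pairs = set()
    for iv in res:
        for o in others:
            if iv.seq_id == o.seq_id and iv.start < o.end and o.start < iv.end:
                pairs.add((iv.name, o.name))
    return pairs


def floor_percent(count: int, total: int, decimals: int) -> str:
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_DOWN))


def random_intervals(rng: np.random.Generator, n: int, seq: str, seq_len: int,
                     min_len: int = 1, max_len: int = 120, prefix: str = "iv") -> list[GenomicInterval]:
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, seq_len - length))
        out.append(GenomicInterval(seq, start, start + length, ".", f"{prefix}{i}"))
    return out
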