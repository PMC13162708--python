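"""Coordinate-level genome-evolution simulator.

For each taxon the reference genome is tiled into retained segments and gaps
with geometric run lengths, calibrated so a neutral base survives with
probability exp(-lambda * divergence_mya). Truth-labelled RE loci override
the neutral process (forced retained or forced deleted in the designated
taxa, with an optional per-base noise flip), and retained runs are emitted
as UCSC chains with cumulative target offsets. TE placement is enriched
inside reference-species-specific REs; gene/motif/QTL tracks and the
divergence table complete the bundle.

No nucleotide sequences are generated: chains, not FASTA, are the contract,
which keeps a full dataset under a second of runtime.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .chains import ChainAlignment, ChainBlock, write_chain_file
from .classify import CATEGORY_ORDER, ConstraintCategory
from .intervals import (
    DivergenceTable,
    GeneModel,
    GenomicInterval,
    ScoreTrack,
    TEInterval,
    write_bedgraph,
    write_divergence_table,
    write_gff3,
    write_te_bed,
)

NEUTRAL = "NEUTRAL"  # unforced REs that follow the neutral retention process

TRUTH_LABELS = tuple(c.value for c in CATEGORY_ORDER) + (NEUTRAL,)

CLADE, OUTGROUP, CONSPECIFIC = "clade", "outgroup", "conspecific"

_TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Satellite", "Simple_repeat")
_TE_WEIGHTS = (0.3, 0.3, 0.15, 0.15, 0.05, 0.05)
_TE_WEIGHTS_SPECIFIC = (0.4, 0.1, 0.3, 0.05, 0.1, 0.05)  # LINE/LTR-heavy

_SCORE_BY_TRUTH = {
    ConstraintCategory.CROSS_SPECIES_CONSTRAINED.value: 2.0,
    ConstraintCategory.CLADE_SPECIFIC.value: 1.0,
    ConstraintCategory.REFERENCE_SPECIES_SPECIFIC.value: -0.5,
    ConstraintCategory.UNCLASSIFIED.value: 0.2,
    NEUTRAL: 0.2,
}


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    divergence_mya: float
    clade: str  # clade | outgroup | conspecific

    def __post_init__(self):
        if self.clade not in (CLADE, OUTGROUP, CONSPECIFIC):
            raise ValueError(f"taxon {self.name}: unknown clade label {self.clade!r}")
        if self.divergence_mya < 0:
            raise ValueError(f"taxon {self.name}: negative divergence")


def default_taxa() -> list[TaxonSpec]:
    """12 target taxa: 4 clade members, 8 outgroup, spanning 2-90 MYA."""
    clade_t = [2.0, 4.0, 6.0, 8.0]
    out_t = [20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0]
    taxa = [TaxonSpec(f"clade_{i+1}", t, CLADE) for i, t in enumerate(clade_t)]
    taxa += [TaxonSpec(f"outgroup_{i+1}", t, OUTGROUP) for i, t in enumerate(out_t)]
    return taxa


def conspecific_taxa(n: int = 8, mya: float = 0.5) -> list[TaxonSpec]:
    return [TaxonSpec(f"pig_{i+1}", mya, CONSPECIFIC) for i in range(n)]


def trend_config(seed: int, n_res: int = 800) -> "SimulationConfig":
    """Neutral-RE configuration for divergence-trend checks: 12 taxa evenly
    spaced in time, decay calibrated so high/low counts move across their
    thresholds over the sampled range."""
    myas = [5, 15, 25, 35, 45, 55, 65, 75, 85, 95, 105, 115]
    taxa = [TaxonSpec(f"taxon_{i+1}", float(m), OUTGROUP if i else CLADE)
            for i, m in enumerate(myas)]
    return SimulationConfig(
        seed=seed, taxa=taxa, n_res={NEUTRAL: n_res},
        deletion_rate=0.012, mean_segment=500, re_length=(80, 150),
        genome_length=1_500_000,
    )


@dataclass
class SimulationConfig:
    seed: int
    genome_length: int = 1_000_000
    n_sequences: int = 2
    taxa: list[TaxonSpec] = field(default_factory=default_taxa)
    n_res: dict[str, int] = field(default_factory=lambda: {
        ConstraintCategory.CROSS_SPECIES_CONSTRAINED.value: 150,
        ConstraintCategory.CLADE_SPECIFIC.value: 150,
        ConstraintCategory.REFERENCE_SPECIES_SPECIFIC.value: 100,
        ConstraintCategory.UNCLASSIFIED.value: 100,
    })
    re_length: tuple[int, int] = (150, 400)
    deletion_rate: float = 0.01       # lambda: per-base per-MYA loss rate
    mean_segment: int = 150           # mean retained-run length (bases)
    noise: float = 0.0                # per-base flip rate on forced RE bases
    te_density: float = 0.15
    te_enrichment_specific: float = 3.0
    te_length: tuple[int, int] = (80, 600)
    n_genes: int = 20
    gene_length: tuple[int, int] = (3000, 12000)
    n_motifs: int = 300
    motif_length: tuple[int, int] = (8, 15)
    n_qtls: int = 20
    qtl_length: tuple[int, int] = (2000, 20000)
    emit_scores: bool = True

    def validate(self) -> None:
        if self.genome_length < 1 or self.n_sequences < 1:
            raise ValueError("genome_length and n_sequences must be positive")
        if not self.taxa:
            raise ValueError("need at least one taxon")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names")
        unknown = set(self.n_res) - set(TRUTH_LABELS)
        if unknown:
            raise ValueError(f"unknown truth labels in n_res: {sorted(unknown)}")
        for rate in (self.deletion_rate, self.noise, self.te_density):
            if not (0 <= rate <= 1):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.re_length[0] > self.re_length[1] or self.re_length[0] < 1:
            raise ValueError("invalid re_length range")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    sequences: dict[str, int]                       # seq name -> length
    res: list[GenomicInterval]
    truth: dict[str, str]                           # re name -> truth label
    chains: dict[str, list[ChainAlignment]]         # taxon -> chains
    genes: list[GeneModel]
    tes: list[TEInterval]
    motifs: list[GenomicInterval]
    qtls: list[GenomicInterval]
    divergence: DivergenceTable
    scores: ScoreTrack | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "chains").mkdir(parents=True, exist_ok=True)
        for taxon, chains in self.chains.items():
            write_chain_file(chains, outdir / "chains" / f"{taxon}.chain")
        with open(outdir / "res.bed", "wt", encoding="utf-8") as fh:
            for iv in self.res:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                         f"{self.truth[iv.name]}\t{iv.strand}\n")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_te_bed(self.tes, outdir / "te.bed")
        with open(outdir / "motifs.bed", "wt", encoding="utf-8") as fh:
            for iv in self.motifs:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\n")
        with open(outdir / "qtl.bed", "wt", encoding="utf-8") as fh:
            for iv in self.qtls:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\n")
        write_divergence_table(self.divergence, outdir / "divergence.tsv")
        if self.scores is not None:
            write_bedgraph(self.scores, outdir / "scores.bedgraph")
        manifest = {
            "seed": self.config.seed,
            "genome_length": self.config.genome_length,
            "n_sequences": self.config.n_sequences,
            "taxa": [[t.name, t.divergence_mya, t.clade] for t in self.config.taxa],
            "n_res": dict(self.config.n_res),
            "noise": self.config.noise,
            "deletion_rate": self.config.deletion_rate,
            "te_density": self.config.te_density,
            "te_enrichment_specific": self.config.te_enrichment_specific,
        }
        with open(outdir / "manifest.yaml", "wt", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


def read_truth_bed(path) -> tuple[list[GenomicInterval], dict[str, str]]:
    """Read res.bed emitted by the simulator (column 5 carries the truth label)."""
    res, truth = [], {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]),
                                 cols[5] if len(cols) > 5 else ".", cols[3])
            res.append(iv)
            truth[cols[3]] = cols[4]
    return res, truth


# ---------------------------------------------------------------------------
# placement helpers

def _split_lengths(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    out[0] += total - base * parts
    return out


def _place_nonoverlapping(rng: np.random.Generator, seq_len: int,
                          lengths: Sequence[int], min_gap: int = 1) -> list[tuple[int, int]]:
    """Place intervals of the given lengths without overlap on [0, seq_len)."""
    n = len(lengths)
    if n == 0:
        return []
    occupied = sum(lengths) + (n - 1) * min_gap
    slack = seq_len - occupied
    if slack < 0:
        raise ValueError(
            f"infeasible placement: {n} intervals totalling {sum(lengths)} bases "
            f"do not fit in a sequence of {seq_len}"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    spans = []
    cursor = 0
    for i, length in enumerate(lengths):
        start = int(cuts[i]) + cursor
        spans.append((start, start + length))
        cursor += length + min_gap
    return spans


def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


# ---------------------------------------------------------------------------
# retention masks and chains

def _neutral_mask(rng: np.random.Generator, seq_len: int, p_keep: float,
                  mean_segment: int) -> np.ndarray:
    """Alternating retained/gap runs with geometric lengths; expected retained
    fraction ~= p_keep."""
    if p_keep >= 1.0:
        return np.ones(seq_len, dtype=bool)
    if p_keep <= 0.0:
        return np.zeros(seq_len, dtype=bool)
    mean_gap = max(1.0, mean_segment * (1.0 - p_keep) / p_keep)
    n_runs = int(2 * seq_len / (mean_segment + mean_gap)) + 16
    mask = np.zeros(seq_len, dtype=bool)
    pos = 0
    retained = rng.random() < p_keep
    while pos < seq_len:
        keep_lens = rng.geometric(1.0 / mean_segment, size=n_runs)
        gap_lens = rng.geometric(1.0 / mean_gap, size=n_runs)
        for k in range(n_runs):
            if pos >= seq_len:
                break
            run = int(keep_lens[k] if retained else gap_lens[k])
            end = min(seq_len, pos + run)
            if retained:
                mask[pos:end] = True
            pos = end
            retained = not retained
    return mask


def _force_re(mask: np.ndarray, start: int, end: int, keep: bool,
              noise: float, rng: np.random.Generator) -> None:
    mask[start:end] = keep
    if noise > 0:
        flips = rng.random(end - start) < noise
        mask[start:end] ^= flips


def _mask_to_chain(mask: np.ndarray, seq_name: str, seq_len: int,
                   taxon: str, chain_id: int) -> ChainAlignment | None:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    q_size = int(idx.size)
    blocks = []
    for i in range(len(run_starts)):
        size = int(run_ends[i] - run_starts[i])
        dt = int(run_starts[i + 1] - run_ends[i]) if i + 1 < len(run_starts) else 0
        blocks.append(ChainBlock(size, dt, 0))
    chain = ChainAlignment(
        score=float(q_size),
        t_name=seq_name, t_size=seq_len, t_strand="+",
        t_start=int(run_starts[0]), t_end=int(run_ends[-1]),
        q_name=f"{taxon}.{seq_name}", q_size=q_size, q_strand="+",
        q_start=0, q_end=q_size,
        chain_id=chain_id, blocks=blocks,
    )
    chain.validate()
    return chain


def _forced_state(label: str, taxon: TaxonSpec, clade_rank: int) -> bool | None:
    """True = forced retained, False = forced deleted, None = neutral."""
    if label == NEUTRAL:
        return None
    if label == ConstraintCategory.CROSS_SPECIES_CONSTRAINED.value:
        return True
    if label == ConstraintCategory.CLADE_SPECIFIC.value:
        return taxon.clade in (CLADE, CONSPECIFIC)
    if label == ConstraintCategory.REFERENCE_SPECIES_SPECIFIC.value:
        return taxon.clade == CONSPECIFIC
    if label == ConstraintCategory.UNCLASSIFIED.value:
        # split the clade members so neither the all->=hi nor the all-<=lo
        # rule can fire, whatever the noise level
        if taxon.clade == CLADE:
            return clade_rank % 2 == 0
        if taxon.clade == CONSPECIFIC:
            return True
        return False
    raise ValueError(f"unknown truth label {label!r}")


# ---------------------------------------------------------------------------
# main entry

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    config.validate()
    seq_lens = _split_lengths(config.genome_length, config.n_sequences)
    sequences = {f"chr{i+1}": seq_lens[i] for i in range(config.n_sequences)}
    seq_names = list(sequences)

    # --- REs with truth labels (stream 0) -------------------------------
    rng_place = _sub_rng(config.seed, 0)
    labels: list[str] = []
    for lab in TRUTH_LABELS:
        labels += [lab] * config.n_res.get(lab, 0)
    if not labels:
        raise ValueError("n_res specifies zero REs")
    order = rng_place.permutation(len(labels))
    labels = [labels[i] for i in order]
    lengths = rng_place.integers(config.re_length[0], config.re_length[1] + 1,
                                 size=len(labels))
    # round-robin REs across sequences, then place within each
    per_seq: dict[str, list[int]] = {s: [] for s in seq_names}
    for i in range(len(labels)):
        per_seq[seq_names[i % len(seq_names)]].append(i)
    res: list[GenomicInterval] = []
    truth: dict[str, str] = {}
    for seq in seq_names:
        idxs = per_seq[seq]
        spans = _place_nonoverlapping(rng_place, sequences[seq],
                                      [int(lengths[i]) for i in idxs], min_gap=20)
        for i, (s, e) in zip(idxs, spans):
            name = f"RE{i+1:05d}"
            res.append(GenomicInterval(seq, s, e, ".", name))
            truth[name] = labels[i]
    res.sort(key=lambda iv: (iv.seq_id, iv.start))

    # --- per-taxon retention masks and chains (streams 1..n_taxa) ------
    clade_ranks = {}
    rank = 0
    for t in config.taxa:
        if t.clade == CLADE:
            clade_ranks[t.name] = rank
            rank += 1
    chains: dict[str, list[ChainAlignment]] = {}
    for ti, taxon in enumerate(config.taxa):
        rng_t = _sub_rng(config.seed, 1 + ti)
        p_keep = float(np.exp(-config.deletion_rate * taxon.divergence_mya))
        taxon_chains: list[ChainAlignment] = []
        chain_id = 1
        for seq in seq_names:
            seq_len = sequences[seq]
            if taxon.divergence_mya == 0:
                mask = np.ones(seq_len, dtype=bool)  # zero divergence: identity
            else:
                mask = _neutral_mask(rng_t, seq_len, p_keep, config.mean_segment)
                for iv in res:
                    if iv.seq_id != seq:
                        continue
                    state = _forced_state(truth[iv.name], taxon,
                                          clade_ranks.get(taxon.name, 0))
                    if state is not None:
                        _force_re(mask, iv.start, iv.end, state, config.noise, rng_t)
            chain = _mask_to_chain(mask, seq, seq_len, taxon.name, chain_id)
            if chain is not None:
                taxon_chains.append(chain)
                chain_id += 1
        chains[taxon.name] = taxon_chains

    # --- TE track (stream 10001) ----------------------------------------
    rng_te = _sub_rng(config.seed, 10001)
    tes: list[TEInterval] = []
    mean_te = (config.te_length[0] + config.te_length[1]) / 2
    n_te = int(config.te_density * config.genome_length / mean_te)
    te_i = 0
    for _ in range(n_te):
        seq = seq_names[int(rng_te.integers(0, len(seq_names)))]
        length = int(rng_te.integers(config.te_length[0], config.te_length[1] + 1))
        length = min(length, sequences[seq] - 1)
        start = int(rng_te.integers(0, sequences[seq] - length))
        cls = str(rng_te.choice(_TE_CLASSES, p=_TE_WEIGHTS))
        te_i += 1
        tes.append(TEInterval(seq, start, start + length, ".", f"TE{te_i:05d}",
                              te_class=cls, te_family=f"{cls}_fam"))
    # enrichment inside reference-species-specific REs
    extra_per_base = config.te_density * max(0.0, config.te_enrichment_specific - 1.0)
    for iv in res:
        if truth[iv.name] != ConstraintCategory.REFERENCE_SPECIES_SPECIFIC.value:
            continue
        target = extra_per_base * iv.length
        placed = 0
        while placed < target:
            length = int(rng_te.integers(config.te_length[0], config.te_length[1] + 1))
            length = min(length, iv.length)
            start = iv.start + int(rng_te.integers(0, iv.length - length + 1))
            cls = str(rng_te.choice(_TE_CLASSES, p=_TE_WEIGHTS_SPECIFIC))
            te_i += 1
            tes.append(TEInterval(iv.seq_id, start, start + length, ".",
                                  f"TE{te_i:05d}", te_class=cls, te_family=f"{cls}_fam"))
            placed += length
    tes.sort(key=lambda t: (t.seq_id, t.start))

    # --- genes (stream 10002) -------------------------------------------
    rng_g = _sub_rng(config.seed, 10002)
    genes: list[GeneModel] = []
    per_seq_genes = _split_lengths(config.n_genes, len(seq_names)) if config.n_genes else []
    gi = 0
    for si, seq in enumerate(seq_names):
        n_here = per_seq_genes[si] if per_seq_genes else 0
        if n_here == 0:
            continue
        glens = [int(rng_g.integers(config.gene_length[0], config.gene_length[1] + 1))
                 for _ in range(n_here)]
        spans = _place_nonoverlapping(rng_g, sequences[seq], glens, min_gap=500)
        for s, e in spans:
            gi += 1
            strand = "+" if rng_g.random() < 0.5 else "-"
            biotype = "lncRNA" if gi % 7 == 0 else "protein_coding"
            n_ex = int(rng_g.integers(2, 5))
            bounds = np.sort(rng_g.choice(np.arange(s + 1, e - 1), size=2 * n_ex - 2,
                                          replace=False))
            edges = [s, *[int(b) for b in bounds], e]
            exons = []
            for k in range(0, len(edges), 2):
                lo, hi = edges[k], edges[k + 1]
                if hi > lo:
                    exons.append(GenomicInterval(seq, lo, hi, strand))
            genes.append(GeneModel(f"gene{gi:03d}",
                                   GenomicInterval(seq, s, e, strand, f"gene{gi:03d}"),
                                   biotype, exons))

    # --- motifs (stream 10003) ------------------------------------------
    rng_m = _sub_rng(config.seed, 10003)
    motifs: list[GenomicInterval] = []
    for mi in range(config.n_motifs):
        length = int(rng_m.integers(config.motif_length[0], config.motif_length[1] + 1))
        if res and rng_m.random() < 0.6:  # bias into REs
            host = res[int(rng_m.integers(0, len(res)))]
            if host.length > length:
                start = host.start + int(rng_m.integers(0, host.length - length))
                motifs.append(GenomicInterval(host.seq_id, start, start + length,
                                              ".", f"motif{mi+1:04d}"))
                continue
        seq = seq_names[int(rng_m.integers(0, len(seq_names)))]
        start = int(rng_m.integers(0, sequences[seq] - length))
        motifs.append(GenomicInterval(seq, start, start + length, ".", f"motif{mi+1:04d}"))
    motifs.sort(key=lambda iv: (iv.seq_id, iv.start))

    # --- QTLs (stream 10004) --------------------------------------------
    rng_q = _sub_rng(config.seed, 10004)
    qtls: list[GenomicInterval] = []
    for qi in range(config.n_qtls):
        seq = seq_names[int(rng_q.integers(0, len(seq_names)))]
        length = int(rng_q.integers(config.qtl_length[0], config.qtl_length[1] + 1))
        length = min(length, sequences[seq] - 1)
        start = int(rng_q.integers(0, sequences[seq] - length))
        qtls.append(GenomicInterval(seq, start, start + length, ".", f"QTL{qi+1:03d}"))
    qtls.sort(key=lambda iv: (iv.seq_id, iv.start))

    divergence = DivergenceTable([(t.name, t.divergence_mya, t.clade)
                                  for t in config.taxa])

    scores = None
    if config.emit_scores:
        scores = ScoreTrack([(iv, _SCORE_BY_TRUTH[truth[iv.name]]) for iv in res])

    return SyntheticDataset(config, sequences, res, truth, chains, genes, tes,
                            motifs, qtls, divergence, scores)


# ---------------------------------------------------------------------------
# recovery evaluation

@dataclass
class RecoveryResult:
    categories: tuple[str, ...]
    matrix: np.ndarray  # truth rows x predicted columns
    accuracy: float

    def count(self, truth_cat: str, predicted_cat: str) -> int:
        i = self.categories.index(truth_cat)
        j = self.categories.index(predicted_cat)
        return int(self.matrix[i, j])


def evaluate_recovery(truth: Mapping[str, object], predicted: Mapping[str, object]) -> RecoveryResult:
    """4x4 confusion matrix (truth rows x predicted columns) and accuracy."""
    if set(truth) != set(predicted):
        missing = set(truth) ^ set(predicted)
        raise ValueError(f"truth/predicted key sets differ (e.g. {sorted(missing)[:3]})")
    if not truth:
        raise ValueError("empty label maps")
    cats = tuple(c.value for c in CATEGORY_ORDER)
    mat = np.zeros((4, 4), dtype=int)
    for name, t in truth.items():
        t_val = ConstraintCategory(t).value
        p_val = ConstraintCategory(predicted[name]).value
        mat[cats.index(t_val), cats.index(p_val)] += 1
    return RecoveryResult(cats, mat, float(np.trace(mat)) / mat.sum())


def dataset_checksum(outdir) -> str:
    """SHA256 over all emitted files, for determinism checks."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
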