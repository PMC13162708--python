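"""End-to-end orchestration: project -> classify -> annotate -> overlaps ->
trends -> report, with a machine-readable manifest.

Every stage is a pure function of (inputs, config); the manifest records the
package version, a config hash and input checksums so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

from . import __version__
from .chains import ChainIndex, ConservationMatrix, conservation_matrix, read_chain_file
from .classify import (
    ConstraintCategory,
    GenomeGrouping,
    classify_matrix,
    intraspecific_summary,
    summarize_classification,
    write_classes_tsv,
)
from .context import aggregate_scores, classify_feature, classify_location, nearest_gene
from .intervals import (
    read_divergence_table,
    read_gff_genes,
    read_score_track,
    read_te_bed,
    read_bed,
)
from .overlaps import OVERALL, motif_reports, qtl_overlap, te_class_composition
from .simulate import CONSPECIFIC, CLADE, OUTGROUP, NEUTRAL, evaluate_recovery, read_truth_bed
from .trends import count_by_genome, fit_regression, run_pca, write_pca_tsv, write_trends_tsv

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    hi: float = 0.9
    lo: float = 0.1
    window: int = 2000
    max_qtl_len: int = 1_000_000
    k: int = 30
    chain_mode: str = "any"          # any | best
    lenient_outgroup: bool = False
    pca_components: int = 2
    percent_decimals: int = 2

    def __post_init__(self):
        if not (0 <= self.lo < self.hi <= 1):
            raise ValueError("need 0 <= lo < hi <= 1")
        if self.chain_mode not in ("any", "best"):
            raise ValueError(f"chain_mode must be any|best, got {self.chain_mode!r}")
        if self.window < 0 or self.max_qtl_len < 1 or self.k < 1:
            raise ValueError("window/max_qtl_len/k out of bounds")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_chain_indexes(chains_dir, mode_stage: str = "projection") -> dict[str, ChainIndex]:
    chains_dir = Path(chains_dir)
    if not chains_dir.is_dir():
        raise StageError(mode_stage, f"chain directory {chains_dir} does not exist")
    indexes = {}
    for path in sorted(chains_dir.glob("*.chain*")):
        taxon = path.name.removesuffix(".gz").removesuffix(".chain")
        indexes[taxon] = ChainIndex(read_chain_file(path))
    if not indexes:
        raise StageError(mode_stage, f"no .chain files in {chains_dir}")
    return indexes


def run_pipeline(input_dir, out_dir, config: RunConfig | None = None) -> dict[str, Any]:
    """Run every stage on a simulator-layout input directory; returns the
    report dict (also written to out/report.json)."""
    config = config or RunConfig()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": asdict(config), "version": __version__}

    # ---- load inputs ----------------------------------------------------
    stage = "load"
    try:
        res_path = input_dir / "res.bed"
        truth = None
        try:
            res, truth = read_truth_bed(res_path)
            if not all(t in {c.value for c in ConstraintCategory} | {NEUTRAL} for t in truth.values()):
                res, truth = read_bed(res_path), None
        except (IndexError, ValueError):
            res, truth = read_bed(res_path), None
        if not res:
            raise StageError(stage, "no REs in res.bed")
        divergence = read_divergence_table(input_dir / "divergence.tsv")
    except OSError as exc:
        raise StageError(stage, str(exc)) from exc
    logger.info("[%s] %d REs, %d taxa", stage, len(res), len(divergence.rows))

    # ---- projection -----------------------------------------------------
    stage = "projection"
    indexes = load_chain_indexes(input_dir / "chains", stage)
    inter_taxa = [t for t in divergence.taxa()
                  if divergence.clade_of(t) in (CLADE, OUTGROUP)]
    intra_taxa = [t for t in divergence.taxa() if divergence.clade_of(t) == CONSPECIFIC]
    missing = [t for t in inter_taxa + intra_taxa if t not in indexes]
    if missing:
        raise StageError(stage, f"no chain file for taxa: {missing}")
    matrix = conservation_matrix(res, indexes, genome_order=inter_taxa + intra_taxa,
                                 mode=config.chain_mode)
    matrix.to_tsv(out_dir / "matrix.tsv")
    logger.info("[%s] matrix %dx%d", stage, *matrix.shape)

    # ---- classification -------------------------------------------------
    stage = "classification"
    grouping = GenomeGrouping(
        frozenset(t for t in inter_taxa if divergence.clade_of(t) == CLADE),
        frozenset(t for t in inter_taxa if divergence.clade_of(t) == OUTGROUP),
    )
    inter_matrix = ConservationMatrix(
        matrix.re_names, inter_taxa,
        [[row[matrix.genome_names.index(t)] for t in inter_taxa] for row in matrix.exact],
    )
    classified = classify_matrix(inter_matrix, grouping, config.hi, config.lo,
                                 config.lenient_outgroup)
    write_classes_tsv(classified, out_dir / "classes.tsv")
    summary = summarize_classification([(n, c) for n, _, c in classified])
    report["classification"] = {
        "total": summary.total,
        "counts": {c.value: summary.counts[c] for c in summary.counts},
        "percentages": {c.value: summary.percentages[c] for c in summary.percentages},
    }
    categories = {n: c for n, _, c in classified}
    if truth is not None:
        comparable = {n: t for n, t in truth.items() if t != NEUTRAL}
        if comparable:
            rec = evaluate_recovery(comparable,
                                    {n: categories[n] for n in comparable})
            report["truth_recovery"] = {
                "accuracy": rec.accuracy,
                "confusion": rec.matrix.tolist(),
                "categories": list(rec.categories),
            }
    logger.info("[%s] %s", stage, report["classification"]["counts"])

    # ---- intraspecific --------------------------------------------------
    if intra_taxa:
        stage = "intraspecific"
        intra_matrix = ConservationMatrix(
            matrix.re_names, intra_taxa,
            [[row[matrix.genome_names.index(t)] for t in intra_taxa] for row in matrix.exact],
        )
        k = min(config.k, len(intra_taxa))
        intra = intraspecific_summary(intra_matrix, config.hi, k)
        report["intraspecific"] = {
            "total": intra.total, "k": intra.k,
            "count_all": intra.count_all, "count_at_least_k": intra.count_at_least_k,
            "percent_all": intra.percent_all, "percent_at_least_k": intra.percent_at_least_k,
        }

    # ---- annotation -----------------------------------------------------
    stage = "annotation"
    genes_path = input_dir / "genes.gff3"
    annot_rows = []
    if genes_path.exists():
        genes = read_gff_genes(genes_path, "protein_coding")
        scores_path = input_dir / "scores.bedgraph"
        track = read_score_track(scores_path) if scores_path.exists() else None
        summaries = {}
        if track is not None:
            per_re, per_cat = aggregate_scores(res, track, categories)
            summaries = {s.re_name: s for s in per_re}
            report["score_aggregates"] = [
                {"category": st.category.value, "n": st.n_res,
                 "mean": st.mean, "sd": st.sd} for st in per_cat
            ]
        for iv in res:
            three = classify_location(iv, genes, config.window)
            four = classify_feature(iv, genes, config.window)
            ng = nearest_gene(iv, genes)
            s = summaries.get(iv.name)
            annot_rows.append((iv.name, three.value, four.value,
                               ng[0] if ng else ".", ng[1] if ng else -1,
                               f"{s.mean_score:.4f}" if s and s.mean_score is not None else "NA"))
        with open(out_dir / "annot.tsv", "wt", encoding="utf-8") as fh:
            fh.write("re_name\tthree_way\tfour_way\tnearest_gene\tdistance\tmean_score\n")
            for row in annot_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        logger.info("[%s] %d REs annotated against %d genes", stage, len(res), len(genes))

    # ---- overlaps -------------------------------------------------------
    stage = "overlaps"
    te_path = input_dir / "te.bed"
    if te_path.exists():
        tes = read_te_bed(te_path)
        coverage = te_class_composition(res, tes, categories)
        report["te_coverage"] = {
            key: {"total_re_bases": cc.total_re_bases,
                  "te_covered_bases": cc.te_covered_bases,
                  "coverage_fraction": cc.coverage_fraction,
                  "class_fractions": {cls: cc.class_fraction(cls)
                                      for cls in sorted(cc.class_covered_bases)}}
            for key, cc in coverage.per_category.items()
        }
        motifs_path = input_dir / "motifs.bed"
        if motifs_path.exists():
            motifs = read_bed(motifs_path)
            mreport = motif_reports(res, motifs, tes, categories)
            report["motifs"] = {
                "per_category": {key: {"n_res": st.n_res,
                                       "n_res_with_motif": st.n_res_with_motif,
                                       "proportion": st.proportion}
                                 for key, st in mreport.per_category.items()},
                "n_hits_total": mreport.n_motif_hits_total,
                "n_hits_in_res": mreport.n_motif_hits_in_res,
                "overlap_proportion_in_res": mreport.overlap_proportion_in_res,
                "overlap_proportion_all": mreport.overlap_proportion_all,
            }
        qtl_path = input_dir / "qtl.bed"
        if qtl_path.exists():
            qtls = read_bed(qtl_path)
            pairs = qtl_overlap(res, qtls, config.max_qtl_len)
            with open(out_dir / "qtl_pairs.tsv", "wt", encoding="utf-8") as fh:
                fh.write("re_name\tqtl_name\n")
                for re_name, qtl_name in pairs:
                    fh.write(f"{re_name}\t{qtl_name}\n")
            report["qtl"] = {"n_pairs": len(pairs),
                             "n_qtls_kept": sum(1 for q in qtls if q.length <= config.max_qtl_len),
                             "n_qtls_total": len(qtls)}

    # ---- trends and PCA -------------------------------------------------
    stage = "trends"
    try:
        mya = [divergence.mya(t) for t in inter_taxa]
        high = count_by_genome(inter_matrix, "high", config.hi, config.lo)
        low = count_by_genome(inter_matrix, "low", config.hi, config.lo)
        if len(set(mya)) > 1 and len(mya) >= 3:
            fit_high = fit_regression(mya, [high[t] for t in inter_taxa])
            fit_low = fit_regression(mya, [low[t] for t in inter_taxa])
            write_trends_tsv(fit_high, fit_low, out_dir / "trends.tsv")
            report["trends"] = {
                "high": {"slope": fit_high.slope, "r_squared": fit_high.r_squared,
                         "p_value": fit_high.p_value},
                "low": {"slope": fit_low.slope, "r_squared": fit_low.r_squared,
                        "p_value": fit_low.p_value},
            }
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "pca"
    n_comp = min(config.pca_components, *matrix.shape)
    if min(matrix.shape) >= 2:
        pca = run_pca(matrix, n_comp)
        write_pca_tsv(matrix.re_names, pca, out_dir / "pca.tsv")
        report["pca"] = {"explained_variance_ratio": pca.explained_variance_ratio.tolist()}

    # ---- manifest -------------------------------------------------------
    config_blob = json.dumps(asdict(config), sort_keys=True).encode()
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(config_blob).hexdigest(),
        "inputs": {p.name: _sha256_file(p) for p in sorted(input_dir.glob("*")) if p.is_file()},
    }
    with open(out_dir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
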