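"""Integrated mining: DEG selection, Venn intersection, Fisher test, correlations.

This stage joins the two arms of the study — in vitro binding (candidate
promoters from selection) and in vivo phenotype (differential expression
between overproducer and disruptant strains) — and asks which promoter
features track expression: motif counts, motif coexistence, peak fold
enrichment and summit position.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .motifscan import MotifCountVector, count_motifs, kmer_enrichment
from .promannot import PromoterHit, assign_windows, build_upstream1000, candidate_genes
from .selex_sim import (
    AffinityModel,
    emit_reads,
    library_weights,
    relative_binding,
    run_selection,
)
from .synthetic_data import (
    EffectModel,
    ExpressionTable,
    build_library,
    generate_expression,
    generate_genome,
    plant_motifs,
    random_motif_plan,
)
from .tagproc import GenomeIndex, call_peaks, extract_windows, map_read_pairs, trim_adapters


@dataclass
class DEGSet:
    """Genes whose expression ratio strictly exceeds the fold threshold."""

    threshold: float
    genes: set[str]


@dataclass
class IntegrationRecord:
    """One row of the per-gene mining table."""

    gene_id: str
    ratio: float
    counts: MotifCountVector
    fold_enrichment: float | None = None
    summit_pos: int | None = None
    in_intersection: bool = False


@dataclass
class CorrelationResult:
    parameter: str
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n: int
    defined: bool = True


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def select_degs(expr: ExpressionTable, threshold: float = 5.0) -> DEGSet:
    """Differentially expressed genes: ratio strictly greater than threshold."""
    return DEGSet(threshold, {g for g, r in expr.ratios.items() if r > threshold})


def intersect_sets(
    candidates: Iterable[str], degs: DEGSet
) -> tuple[tuple[int, int, int], set[str]]:
    """Venn counts (candidates only, DEGs only, intersection) and the overlap."""
    cand = set(candidates)
    inter = cand & degs.genes
    return (len(cand - degs.genes), len(degs.genes - cand), len(inter)), inter


def fisher_motif_presence(records: list[IntegrationRecord]) -> FisherResult:
    """Two-sided Fisher exact test of canonical-motif presence.

    Rows: intersection vs non-intersection DEGs; columns: promoter carries
    at least one canonical hexamer (GGCTAA/GGCTGA/GGCTAG) vs none.
    """
    groups = {True: [0, 0], False: [0, 0]}
    for r in records:
        groups[r.in_intersection][0 if r.counts.n_total > 0 else 1] += 1
    a, b = groups[True]
    c, d = groups[False]
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("both intersection and non-intersection partitions required")
    return fisher_from_table(a, b, c, d)


def fisher_from_table(a: int, b: int, c: int, d: int) -> FisherResult:
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if (a == 0 or d == 0) and b * c == 0 else math.nan)
    else:
        odds = (a * d) / (b * c)
    # degenerate margins: one row or column empty -> only one table possible
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        p = 1.0
    return FisherResult(((a, b), (c, d)), odds, float(p))


#: Mining parameters: label -> accessor over an IntegrationRecord.
PARAMETERS: dict[str, callable] = {
    "GGCTGA": lambda r: r.counts.n_ga,
    "GGCTAA": lambda r: r.counts.n_aa,
    "GGCTAG": lambda r: r.counts.n_ag,
    "total": lambda r: r.counts.n_total,
    "CGGNTAAW": lambda r: r.counts.n_monomer,
    "TTAGSCTAA": lambda r: r.counts.n_dimer,
    "coex_GGCTGA_GGCTAA": lambda r: int(r.counts.coex_ga_aa),
    "coex_GGCTAA_GGCTAG": lambda r: int(r.counts.coex_aa_ag),
    "coex_GGCTGA_GGCTAG": lambda r: int(r.counts.coex_ga_ag),
    "fold_enrichment": lambda r: r.fold_enrichment,
    "summit_pos": lambda r: r.summit_pos,
}


def correlate_parameters(
    records: list[IntegrationRecord],
    expr_transform: str = "log",
    parameters: Mapping[str, callable] | None = None,
) -> list[CorrelationResult]:
    """Spearman and Pearson correlation of each parameter with expression.

    Spearman uses average ranks on ties (invariant to the expression
    scale); Pearson is computed on ``log(ratio)`` by default because the
    ratios are multiplicative. Records lacking a value (e.g. no peak in
    the promoter) are dropped pairwise per parameter; constant vectors
    yield an undefined, flagged result.
    """
    if expr_transform not in ("log", "linear"):
        raise ValueError("expr_transform must be 'log' or 'linear'")
    parameters = parameters or PARAMETERS
    results = []
    for name, get in parameters.items():
        xs, ys = [], []
        for r in records:
            v = get(r)
            if v is None:
                continue
            xs.append(float(v))
            ys.append(math.log(r.ratio) if expr_transform == "log" else r.ratio)
        n = len(xs)
        if n < 3 or len(set(xs)) < 2 or len(set(ys)) < 2:
            results.append(CorrelationResult(name, math.nan, math.nan, math.nan, math.nan, n, False))
            continue
        rho, sp = stats.spearmanr(xs, ys)
        pr, pp = stats.pearsonr(xs, ys)
        results.append(CorrelationResult(name, float(rho), float(sp), float(pr), float(pp), n))
    return results


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (NaN passed through)."""
    idx = [i for i, p in enumerate(pvals) if not math.isnan(p)]
    out = [math.nan] * len(pvals)
    m = len(idx)
    order = sorted(idx, key=lambda i: pvals[i])
    prev = 1.0
    for rank, i in reversed(list(enumerate(order, start=1))):
        prev = min(prev, pvals[i] * m / rank)
        out[i] = prev
    return out


def build_records(
    expr: ExpressionTable,
    counts: Mapping[str, MotifCountVector],
    hits: list[PromoterHit] | None = None,
    intersection: set[str] | None = None,
    genes: Iterable[str] | None = None,
) -> list[IntegrationRecord]:
    """Assemble the per-gene mining table.

    When several windows hit one promoter, the hit with the largest fold
    enrichment is kept (one FE and summit per gene).
    """
    best_hit: dict[str, PromoterHit] = {}
    for h in hits or []:
        if h.fold_enrichment is None:
            continue
        prev = best_hit.get(h.gene_id)
        if prev is None or h.fold_enrichment > prev.fold_enrichment:
            best_hit[h.gene_id] = h
    gene_ids = sorted(genes) if genes is not None else sorted(expr.ratios)
    records = []
    for gid in gene_ids:
        h = best_hit.get(gid)
        records.append(
            IntegrationRecord(
                gene_id=gid,
                ratio=expr.ratios[gid],
                counts=counts[gid],
                fold_enrichment=h.fold_enrichment if h else None,
                summit_pos=h.summit_pos if h else None,
                in_intersection=(gid in intersection) if intersection else False,
            )
        )
    return records


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Study-scale defaults for the synthetic end-to-end run."""

    n_genes: int = 20
    contig_length: int = 25_000
    promoter_spacing: int = 2000
    n_contigs: int = 2
    n_regulated: int = 5
    regulated_sites: tuple[tuple[str, int], ...] = (("GGCTAA", 2), ("GGCTGA", 1))
    background_rates: Mapping[str, float] = field(default_factory=dict)
    n_fragments: int = 50_000
    fragment_mean_len: int = 100
    fragment_sd_len: float = 15.0
    rounds: int = 3
    pool_size: int = 50_000
    n_read_pairs: int = 15_000
    read_len: int = 75
    substitution_rate: float = 0.001
    max_mismatches: int = 0
    peak_window: int = 50
    peak_step: int = 10
    peak_p_threshold: float = 1e-5
    merge_gap: int = 50
    flank_left: int = 24
    flank_right: int = 25
    assign_min_len: int = 30
    assign_min_identity: float = 0.9
    deg_threshold: float = 5.0
    expr_transform: str = "log"
    top_n_windows: int = 100
    kmer_k: int = 6
    effect: EffectModel = field(default_factory=EffectModel)
    affinity: AffinityModel = field(default_factory=AffinityModel)


@dataclass
class PipelineReport:
    venn: tuple[int, int, int]
    intersection: list[str]
    n_candidates: int
    n_degs: int
    n_peaks: int
    planted_genes: list[str]
    planted_recall: float
    top_kmers: list[tuple[str, float]]
    enrichment_curve: list[float]
    fisher: FisherResult | None
    correlations: list[CorrelationResult]

    def to_json(self) -> str:
        payload = {
            "venn": list(self.venn),
            "intersection": self.intersection,
            "n_candidates": self.n_candidates,
            "n_degs": self.n_degs,
            "n_peaks": self.n_peaks,
            "planted_genes": self.planted_genes,
            "planted_recall": round(self.planted_recall, 6),
            "top_kmers": [[k, round(s, 6)] for k, s in self.top_kmers],
            "enrichment_curve": [round(v, 6) for v in self.enrichment_curve],
            "fisher": None
            if self.fisher is None
            else {
                "table": [list(r) for r in self.fisher.table],
                "odds_ratio": None
                if not math.isfinite(self.fisher.odds_ratio)
                else round(self.fisher.odds_ratio, 6),
                "p_value": round(self.fisher.p_value, 8),
            },
            "correlations": [
                {
                    "parameter": c.parameter,
                    "spearman_rho": None if math.isnan(c.spearman_rho) else round(c.spearman_rho, 6),
                    "spearman_p": None if math.isnan(c.spearman_p) else round(c.spearman_p, 8),
                    "pearson_r": None if math.isnan(c.pearson_r) else round(c.pearson_r, 6),
                    "pearson_p": None if math.isnan(c.pearson_p) else round(c.pearson_p, 8),
                    "n": c.n,
                }
                for c in self.correlations
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0, out_dir=None) -> PipelineReport:
    """Simulate, select, sequence, call peaks, annotate, count, and mine.

    All artifacts are written under ``out_dir`` when given; the returned
    report summarizes the Venn intersection, Fisher test, correlation
    table, k-mer ranking and enrichment curve.
    """
    cfg = config or PipelineConfig()
    genome = generate_genome(
        cfg.n_genes, cfg.contig_length, cfg.promoter_spacing, seed, cfg.n_contigs
    )
    # plant strong sites into the regulated promoters, background rates elsewhere
    gene_ids = [g.gene_id for g in genome.genes]
    regulated = gene_ids[: cfg.n_regulated]
    rng_positions = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    plan: dict[str, list[tuple[str, int, str]]] = {}
    for gid in regulated:
        sites = []
        occupied: list[tuple[int, int]] = []
        for mid, n_sites in cfg.regulated_sites:
            for _ in range(n_sites):
                for _try in range(200):
                    pos = int(rng_positions.integers(1, 1000 - len(mid) + 2))
                    if all(not (pos < b and a < pos + len(mid)) for a, b in occupied):
                        occupied.append((pos, pos + len(mid)))
                        sites.append((mid, pos, "+" if rng_positions.random() < 0.5 else "-"))
                        break
        plan[gid] = sites
    if cfg.background_rates:
        bg_plan = random_motif_plan(
            genome, cfg.background_rates, seed, genes=set(gene_ids) - set(regulated)
        )
        plan.update(bg_plan)
    genome, truth = plant_motifs(genome, plan, seed)

    promoters = build_upstream1000(genome)
    counts = {p.gene_id: count_motifs(p) for p in promoters}
    expr = generate_expression(counts, cfg.effect, seed)

    library = build_library(
        genome, cfg.n_fragments, cfg.fragment_mean_len, cfg.fragment_sd_len, seed=seed
    )
    weights = library_weights(library, cfg.affinity)
    rounds = run_selection(
        library, cfg.affinity, cfg.rounds, cfg.pool_size, seed, weights=weights
    )
    curve = relative_binding(rounds, cfg.affinity, weights=weights)

    index = GenomeIndex(genome)
    tags = {}
    for idx in (0, cfg.rounds):
        r1, r2 = emit_reads(
            rounds[idx], library, cfg.read_len, cfg.n_read_pairs, cfg.substitution_rate, seed
        )
        t1 = trim_adapters(r1)
        t2 = trim_adapters(r2)
        tags[idx] = map_read_pairs(t1, t2, genome, cfg.max_mismatches, index=index)
    peaks = call_peaks(
        tags[cfg.rounds],
        tags[0],
        genome,
        cfg.peak_window,
        cfg.peak_step,
        cfg.peak_p_threshold,
        cfg.merge_gap,
    )
    windows = extract_windows(peaks, genome, cfg.flank_left, cfg.flank_right)

    if windows:
        hits = assign_windows(
            windows, promoters, peaks, cfg.assign_min_len, cfg.assign_min_identity
        )
        candidates = candidate_genes(hits)
    else:
        hits, candidates = [], set()

    degs = select_degs(expr, cfg.deg_threshold)
    venn, intersection = intersect_sets(candidates, degs)
    records = build_records(expr, counts, hits, intersection, genes=degs.genes)
    fisher = None
    in_part = [r for r in records if r.in_intersection]
    out_part = [r for r in records if not r.in_intersection]
    if in_part and out_part:
        fisher = fisher_motif_presence(records)
    correlations = correlate_parameters(records, cfg.expr_transform) if len(records) >= 3 else []

    top_windows = [w for w in windows if w.source_rank <= cfg.top_n_windows]
    if top_windows:
        bg = [f.insert for f in library.fragments[: min(len(library.fragments), 2000)]]
        ranking = kmer_enrichment(top_windows, bg, cfg.kmer_k)
        top_kmers = [(r.kmer, r.score) for r in ranking[:10]]
    else:
        top_kmers = []

    recall = (
        sum(1 for g in regulated if g in candidates) / len(regulated) if regulated else math.nan
    )
    report = PipelineReport(
        venn=venn,
        intersection=sorted(intersection),
        n_candidates=len(candidates),
        n_degs=len(degs.genes),
        n_peaks=len(peaks),
        planted_genes=sorted(regulated),
        planted_recall=recall,
        top_kmers=top_kmers,
        enrichment_curve=curve.values,
        fisher=fisher,
        correlations=correlations,
    )
    if out_dir is not None:
        _write_artifacts(out_dir, genome, truth, expr, library, rounds, curve, peaks, windows,
                         hits, records, report)
    return report


def _write_artifacts(out_dir, genome, truth, expr, library, rounds, curve, peaks, windows,
                     hits, records, report) -> None:
    from . import promannot, selex_sim, synthetic_data, tagproc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic_data.write_genome(genome, out)
    synthetic_data.write_truth(truth, out / "planted_truth.tsv")
    synthetic_data.write_expression(expr, out / "expression.tsv")
    synthetic_data.write_library(library, out / "library.fasta")
    selex_sim.write_rounds(rounds, out / "rounds.tsv")
    selex_sim.write_enrichment_curve(curve, out / "enrichment_curve.tsv")
    tagproc.write_peaks_bed(peaks, out / "peaks.bed")
    tagproc.write_peaks_tsv(peaks, out / "peaks.tsv")
    tagproc.write_windows_bed(windows, out / "windows.bed")
    tagproc.write_windows_fasta(windows, out / "windows.fasta")
    if hits:
        promannot.write_hits_tsv(hits, out / "promoter_hits.tsv")
    write_integration_tsv(records, out / "integration_table.tsv")
    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json() + "\n")


def write_integration_tsv(records: list[IntegrationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tratio\tn_GGCTAA\tn_GGCTGA\tn_GGCTAG\tn_total\tn_CGGNTAAW\t"
            "n_TTAGSCTAA\tcoex_GA_AA\tcoex_AA_AG\tcoex_GA_AG\tfold_enrichment\t"
            "summit_pos\tin_intersection\n"
        )
        for r in records:
            c = r.counts
            fe = "" if r.fold_enrichment is None else f"{r.fold_enrichment:.4g}"
            sp = "" if r.summit_pos is None else r.summit_pos
            fh.write(
                f"{r.gene_id}\t{r.ratio:.6g}\t{c.n_aa}\t{c.n_ga}\t{c.n_ag}\t{c.n_total}\t"
                f"{c.n_monomer}\t{c.n_dimer}\t{int(c.coex_ga_aa)}\t{int(c.coex_aa_ag)}\t"
                f"{int(c.coex_ga_ag)}\t{fe}\t{sp}\t{int(r.in_intersection)}\n"
            )


def write_correlations_tsv(results: list[CorrelationResult], path, with_bh: bool = True) -> None:
    bh_s = bh_adjust([c.spearman_p for c in results]) if with_bh else None
    with open(path, "w") as fh:
        header = "parameter\tspearman_rho\tspearman_p\tpearson_r\tpearson_p\tn"
        if with_bh:
            header += "\tspearman_p_bh"
        fh.write(header + "\n")
        for i, c in enumerate(results):
            row = (
                f"{c.parameter}\t{c.spearman_rho:.4g}\t{c.spearman_p:.4g}\t"
                f"{c.pearson_r:.4g}\t{c.pearson_p:.4g}\t{c.n}"
            )
            if with_bh:
                row += f"\t{bh_s[i]:.4g}"
            fh.write(row + "\n")


def expression_mining_run(
    n_genes: int = 72,
    seed: int = 0,
    rates: Mapping[str, float] | None = None,
    effect: EffectModel | None = None,
) -> list[CorrelationResult]:
    """Sequencing-free mining run: planted promoters -> expression -> correlations.

    Emulates the motif-count arm of the integrated analysis at the DEG-set
    scale (default 72 genes) without the selection/sequencing stages.
    Default plant rates put roughly one strong site per promoter so that
    both single-site and coexistence effects are observable.
    """
    rates = dict(rates or {"GGCTAA": 0.5, "GGCTGA": 0.5, "GGCTAG": 0.4})
    genome = generate_genome(n_genes, contig_length=2000 * ((n_genes + 1) // 2), seed=seed)
    plan = random_motif_plan(genome, rates, seed)
    genome, _ = plant_motifs(genome, plan, seed)
    promoters = build_upstream1000(genome)
    counts = {p.gene_id: count_motifs(p) for p in promoters}
    expr = generate_expression(counts, effect or EffectModel(), seed)
    records = build_records(expr, counts)
    params = {k: v for k, v in PARAMETERS.items() if k not in ("fold_enrichment", "summit_pos")}
    return correlate_parameters(records, parameters=params)
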