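"""Upstream-1000 promoter extraction and summit-window annotation.

A gene's promoter is the 1000 bp immediately 5' of its start codon, in
promoter-forward orientation (reading toward the codon); the base adjacent
to the start codon is promoter position 1000. Summit windows are assigned
to promoters by ungapped matching in both orientations — a permissive
stand-in for the local-alignment annotation step, with explicit length and
identity thresholds instead of an E-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, seq_to_array
from .synthetic_data import PROMOTER_LEN, GenomeModel, upstream_interval, write_fasta
from .tagproc import Peak, TagWindow


@dataclass
class Promoter:
    gene_id: str
    sequence: str  # promoter-forward orientation
    contig: str
    start: int
    end: int
    strand: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 < len(self.sequence) <= PROMOTER_LEN:
            raise ValueError("promoter length must be in 1..1000")


@dataclass
class PromoterHit:
    window: TagWindow
    gene_id: str
    match_len: int
    identity: float
    summit_pos: int | None  # promoter-forward, 1..1000; None if summit outside
    fold_enrichment: float | None = None


def build_upstream1000(genome: GenomeModel, length: int = PROMOTER_LEN) -> list[Promoter]:
    """The upstream-``length`` promoter set for every annotated gene."""
    promoters = []
    for g in genome.genes:
        contig = genome.contigs[g.contig]
        start, end, truncated = upstream_interval(g, len(contig), length)
        seq = contig[start:end]
        if not seq:
            continue
        if g.strand == "-":
            seq = revcomp(seq)
        promoters.append(Promoter(g.gene_id, seq, g.contig, start, end, g.strand, truncated))
    return promoters


def _best_ungapped(win: np.ndarray, prom: np.ndarray, min_len: int) -> tuple[int, float]:
    """Best full-overlap ungapped match (length, identity) over all shifts."""
    nw, npr = len(win), len(prom)
    best = (0, 0.0)
    for shift in range(-(nw - min_len), npr - min_len + 1):
        a, b = max(0, -shift), min(nw, npr - shift)
        if b - a < min_len:
            continue
        matches = int(np.count_nonzero(win[a:b] == prom[a + shift : b + shift]))
        ident = matches / (b - a)
        if (ident, b - a) > (best[1], best[0]):
            best = (b - a, ident)
    return best


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def assign_windows(
    windows: list[TagWindow],
    promoters: list[Promoter],
    peaks: list[Peak] | None = None,
    min_len: int = 30,
    min_identity: float = 0.9,
    seed_k: int = 12,
) -> list[PromoterHit]:
    """Assign summit windows to promoters by ungapped matching.

    Every promoter whose best ungapped match with the window (either
    orientation) reaches ``min_len`` and ``min_identity`` is reported, so a
    window upstream of divergent genes can hit two promoters. When
    ``peaks`` is given, each hit carries its source peak's fold enrichment
    and the summit's promoter-forward position.
    """
    if not windows or not promoters:
        raise ValueError("windows and promoters must be non-empty")
    peak_by_rank = {p.rank: p for p in peaks} if peaks else {}
    prom_arrays = [
        (pr, seq_to_array(pr.sequence), _kmer_set(pr.sequence, seed_k)) for pr in promoters
    ]
    hits = []
    for w in windows:
        for wseq in (w.sequence, revcomp(w.sequence)):
            warr = seq_to_array(wseq)
            wkmers = _kmer_set(wseq, seed_k)
            for pr, parr, pkmers in prom_arrays:
                if not (wkmers & pkmers):
                    continue  # exact seed prefilter; mismatched pairs skip the scan
                mlen, ident = _best_ungapped(warr, parr, min_len)
                if mlen >= min_len and ident >= min_identity:
                    peak = peak_by_rank.get(w.source_rank)
                    spos = None
                    fe = None
                    if peak is not None:
                        spos = summit_position(peak, pr)
                        fe = peak.fold_enrichment
                    hits.append(PromoterHit(w, pr.gene_id, mlen, ident, spos, fe))
    # a window can match a promoter in both orientations; keep the better hit
    return _dedup(hits)


def _dedup(hits: list[PromoterHit]) -> list[PromoterHit]:
    best: dict[tuple[int, str], PromoterHit] = {}
    for h in hits:
        key = (id(h.window), h.gene_id)
        prev = best.get(key)
        if prev is None or (h.identity, h.match_len) > (prev.identity, prev.match_len):
            best[key] = h
    return list(best.values())


def candidate_genes(hits: list[PromoterHit]) -> set[str]:
    """Distinct gene ids with at least one window hit."""
    return {h.gene_id for h in hits}


def summit_position(peak: Peak, promoter: Promoter) -> int | None:
    """Promoter-forward 1-based summit position (1000 = adjacent to start codon).

    Returns None when the summit lies outside the promoter's genomic
    interval (the hit is then flagged by the caller).
    """
    if peak.contig != promoter.contig or not promoter.start <= peak.summit < promoter.end:
        return None
    if promoter.strand == "+":
        return peak.summit - promoter.start + 1 + (PROMOTER_LEN - len(promoter.sequence))
    return promoter.end - peak.summit + (PROMOTER_LEN - len(promoter.sequence))


def promoter_position_to_genomic(promoter: Promoter, pos: int) -> int:
    """Inverse of summit_position: promoter-forward position -> genome coordinate."""
    offset = PROMOTER_LEN - len(promoter.sequence)
    if promoter.strand == "+":
        return promoter.start + (pos - offset) - 1
    return promoter.end - (pos - offset)


def write_promoters_fasta(promoters: list[Promoter], path) -> None:
    write_fasta(path, ((p.gene_id, p.sequence) for p in promoters))


def write_hits_tsv(hits: list[PromoterHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("window_rank\tgene_id\tmatch_len\tidentity\tsummit_pos\tfold_enrichment\n")
        for h in hits:
            spos = "" if h.summit_pos is None else h.summit_pos
            fe = "" if h.fold_enrichment is None else f"{h.fold_enrichment:.4g}"
            fh.write(
                f"{h.window.source_rank}\t{h.gene_id}\t{h.match_len}\t"
                f"{h.identity:.4g}\t{spos}\t{fe}\n"
            )
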