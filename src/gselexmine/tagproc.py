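"""From raw reads to ranked enrichment peaks and summit windows.

Stages: exact-overlap adapter trimming, exact/near-exact placement of the
trimmed reads on the synthetic genome (mate pairs merged to fragment
intervals), Poisson local-lambda peak calling against the round-0 control
pool, and extraction of fixed-width windows centred on each peak summit.

Coordinates are 0-based half-open throughout; BED output follows BED
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from ._seq import revcomp
from .synthetic_data import (
    DEFAULT_LINKER_5,
    READ2_ADAPTER,
    GenomeModel,
    write_fasta,
)

DEFAULT_ADAPTERS_5 = (DEFAULT_LINKER_5, READ2_ADAPTER)
DEFAULT_ADAPTERS_3 = (revcomp(DEFAULT_LINKER_5), revcomp(READ2_ADAPTER))


@dataclass(frozen=True)
class AlignedTag:
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("tag interval must be non-empty")


@dataclass
class Peak:
    contig: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    p_value: float
    rank: int = 0


@dataclass
class TagWindow:
    """Fixed-width sequence window centred on a peak summit."""

    sequence: str
    contig: str
    start: int
    end: int
    source_rank: int
    truncated: bool = False


def trim_adapters(
    reads: list[tuple[str, str]],
    adapters_5=DEFAULT_ADAPTERS_5,
    adapters_3=DEFAULT_ADAPTERS_3,
    min_overlap: int = 15,
    min_read_len: int = 20,
) -> list[tuple[str, str]]:
    """Strip linker sequence from read ends by exact overlap.

    A 5' adapter is removed when its suffix of >= ``min_overlap`` bases
    equals the read prefix (longest such overlap wins); 3' adapters
    symmetrically at the read end. Reads shorter than ``min_read_len``
    after trimming are discarded; reads without a match pass unchanged.
    """
    if not adapters_5 and not adapters_3:
        raise ValueError("at least one adapter required")
    out = []
    for name, seq in reads:
        cut5 = 0
        for ad in adapters_5:
            hi = min(len(ad), len(seq))
            for k in range(hi, min_overlap - 1, -1):
                if seq.startswith(ad[-k:]):
                    cut5 = max(cut5, k)
                    break
        seq = seq[cut5:]
        cut3 = 0
        for ad in adapters_3:
            hi = min(len(ad), len(seq))
            for k in range(hi, min_overlap - 1, -1):
                if seq.endswith(ad[:k]):
                    cut3 = max(cut3, k)
                    break
        if cut3:
            seq = seq[:-cut3]
        if len(seq) >= min_read_len:
            out.append((name, seq))
    return out


class GenomeIndex:
    """Seed-and-verify exact/near-exact read placement on small genomes.

    A fixed-length k-mer table maps every genomic seed to its positions;
    a read is placed by looking up mm+1 evenly spaced seeds (pigeonhole:
    at most ``max_mismatches`` substitutions leave one seed intact) and
    verifying each candidate by Hamming distance.
    """

    def __init__(self, genome: GenomeModel, seed_len: int = 20) -> None:
        self.genome = genome
        self.k = seed_len
        self.index: dict[str, list[tuple[str, int]]] = {}
        for cid in sorted(genome.contigs):
            seq = genome.contigs[cid]
            for i in range(len(seq) - seed_len + 1):
                self.index.setdefault(seq[i : i + seed_len], []).append((cid, i))

    def _candidates(self, read: str, mm: int) -> set[tuple[str, int]]:
        L = len(read)
        if L < self.k:
            return set()
        offsets = {round(i * (L - self.k) / max(mm, 1)) for i in range(mm + 1)} if mm else {0}
        cand = set()
        for off in offsets:
            for cid, pos in self.index.get(read[off : off + self.k], ()):
                start = pos - off
                if 0 <= start <= len(self.genome.contigs[cid]) - L:
                    cand.add((cid, start))
        return cand

    def place(self, read: str, mm: int = 0) -> AlignedTag | None:
        """Unique best placement of a read, or None (unmapped/ambiguous)."""
        L = len(read)
        best_d = mm + 1
        hits: list[AlignedTag] = []
        for seq, strand in ((read, "+"), (revcomp(read), "-")):
            for cid, start in self._candidates(seq, mm):
                ref = self.genome.contigs[cid][start : start + L]
                d = 0 if ref == seq else sum(a != b for a, b in zip(ref, seq))
                if d > mm:
                    continue
                if d < best_d:
                    best_d = d
                    hits = [AlignedTag(cid, start, start + L, strand)]
                elif d == best_d:
                    hits.append(AlignedTag(cid, start, start + L, strand))
        return hits[0] if len(hits) == 1 else None


def map_reads(
    reads: list[tuple[str, str]],
    genome: GenomeModel,
    max_mismatches: int = 0,
    index: GenomeIndex | None = None,
) -> list[AlignedTag]:
    """Place each read at its unique genomic hit; ambiguous reads dropped."""
    index = index or GenomeIndex(genome)
    tags = []
    for _, seq in reads:
        tag = index.place(seq, max_mismatches)
        if tag is not None:
            tags.append(tag)
    return tags


def map_read_pairs(
    reads1: list[tuple[str, str]],
    reads2: list[tuple[str, str]],
    genome: GenomeModel,
    max_mismatches: int = 0,
    max_fragment: int = 1000,
    index: GenomeIndex | None = None,
) -> list[AlignedTag]:
    """Map mates and merge concordant pairs into one fragment interval.

    Pairs whose mates map uniquely to opposite strands of the same contig
    within ``max_fragment`` bp become a single fragment tag; otherwise any
    uniquely mapped mate contributes its own tag.
    """
    index = index or GenomeIndex(genome)
    by_name2 = {name: seq for name, seq in reads2}
    seen = set()
    tags = []
    place_cache: dict[str, AlignedTag | None] = {}

    def _place(seq: str) -> AlignedTag | None:
        if seq not in place_cache:
            place_cache[seq] = index.place(seq, max_mismatches)
        return place_cache[seq]

    for name, seq1 in reads1:
        seen.add(name)
        t1 = _place(seq1)
        t2 = _place(by_name2[name]) if name in by_name2 else None
        if t1 and t2 and t1.contig == t2.contig and t1.strand != t2.strand:
            start, end = min(t1.start, t2.start), max(t1.end, t2.end)
            if end - start <= max_fragment:
                tags.append(AlignedTag(t1.contig, start, end, t1.strand))
                continue
        for t in (t1, t2):
            if t is not None:
                tags.append(t)
    for name, seq in reads2:
        if name not in seen:
            t = _place(seq)
            if t is not None:
                tags.append(t)
    return tags


def _coverage(tags: list[AlignedTag], length: int, cid: str) -> np.ndarray:
    delta = np.zeros(length + 1)
    for t in tags:
        if t.contig == cid:
            delta[t.start] += 1
            delta[t.end] -= 1
    return np.cumsum(delta[:-1])


def call_peaks(
    tags_selected: list[AlignedTag],
    tags_control: list[AlignedTag],
    genome: GenomeModel,
    window: int = 50,
    step: int = 10,
    p_threshold: float = 1e-5,
    merge_gap: int = 50,
    pseudocount: float = 0.5,
) -> list[Peak]:
    """Poisson local-lambda peak calling against the control pool.

    Per sliding window the selected-pool fragment count is tested against
    lambda = max(library-size-scaled control count, uniform expectation,
    pseudocount); significant windows within ``merge_gap`` merge into one
    peak. The summit is the leftmost position of maximal per-base selected
    coverage, and fold enrichment compares per-million-scaled coverage at
    the summit with a pseudocount in both numerator and denominator.
    """
    if not tags_selected or not tags_control:
        raise ValueError("both selected and control tag lists are required")
    n_sel, n_ctrl = len(tags_selected), len(tags_control)
    # significance is tested on distinct fragment intervals: selection and
    # resampling duplicate identical molecules, which would make window
    # counts overdispersed relative to the Poisson model (coverage, summit
    # and fold enrichment still use every tag)
    sel_unique = {cid: sorted({(t.start, t.end) for t in tags_selected if t.contig == cid})
                  for cid in genome.contigs}
    ctrl_unique = {cid: sorted({(t.start, t.end) for t in tags_control if t.contig == cid})
                   for cid in genome.contigs}
    n_sel_u = sum(len(v) for v in sel_unique.values())
    n_ctrl_u = sum(len(v) for v in ctrl_unique.values())
    scale = n_sel_u / n_ctrl_u
    genome_len = sum(len(s) for s in genome.contigs.values())
    mean_tag = float(np.mean([t.end - t.start for t in tags_selected]))
    uniform_lambda = n_sel_u * (window + mean_tag - 1) / genome_len
    peaks: list[Peak] = []
    for cid in sorted(genome.contigs):
        clen = len(genome.contigs[cid])
        sel = [t for t in tags_selected if t.contig == cid]
        ctrl = [t for t in tags_control if t.contig == cid]
        if not sel:
            continue
        sel_starts = np.sort([s for s, _ in sel_unique[cid]])
        sel_ends = np.sort([e for _, e in sel_unique[cid]])
        ctrl_starts = np.sort([s for s, _ in ctrl_unique[cid]])
        ctrl_ends = np.sort([e for _, e in ctrl_unique[cid]])
        wstarts = np.arange(0, max(1, clen - window + 1), step)
        wends = wstarts + window
        # tags overlapping [w, w+window): start < w+window and end > w
        k_sel = np.searchsorted(sel_starts, wends, "left") - np.searchsorted(
            sel_ends, wstarts, "right"
        )
        k_ctrl = np.searchsorted(ctrl_starts, wends, "left") - np.searchsorted(
            ctrl_ends, wstarts, "right"
        )
        lam = np.maximum(np.maximum(k_ctrl * scale, uniform_lambda), pseudocount)
        pvals = poisson.sf(k_sel - 1, lam)
        sig = np.nonzero(pvals < p_threshold)[0]
        if len(sig) == 0:
            continue
        sel_cov = _coverage(sel, clen, cid)
        ctrl_cov = _coverage(ctrl, clen, cid)
        # merge significant windows separated by <= merge_gap
        groups: list[list[int]] = [[sig[0]]]
        for i in sig[1:]:
            if wstarts[i] - wends[groups[-1][-1]] <= merge_gap:
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            start = int(wstarts[grp[0]])
            end = int(min(wends[grp[-1]], clen))
            summit = start + int(np.argmax(sel_cov[start:end]))
            fe = (sel_cov[summit] * 1e6 / n_sel + pseudocount) / (
                ctrl_cov[summit] * 1e6 / n_ctrl + pseudocount
            )
            peaks.append(Peak(cid, start, end, summit, float(fe), float(pvals[grp].min())))
    peaks.sort(key=lambda p: (-p.fold_enrichment, p.contig, p.start))
    for i, p in enumerate(peaks, start=1):
        p.rank = i
    return peaks


def extract_windows(
    peaks: list[Peak],
    genome: GenomeModel,
    flank_left: int = 24,
    flank_right: int = 25,
) -> list[TagWindow]:
    """Summit-centred windows [summit-flank_left, summit+flank_right+1).

    Defaults give 50-bp windows (24 left + summit + 25 right). Windows
    running off a contig end are clipped and flagged. Sequence is always
    reported from the + strand.
    """
    windows = []
    for p in peaks:
        clen = len(genome.contigs[p.contig])
        start = p.summit - flank_left
        end = p.summit + flank_right + 1
        cstart, cend = max(0, start), min(clen, end)
        windows.append(
            TagWindow(
                sequence=genome.contigs[p.contig][cstart:cend],
                contig=p.contig,
                start=cstart,
                end=cend,
                source_rank=p.rank,
                truncated=(cstart != start or cend != end),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# writers

def write_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(p.fold_enrichment * 100))
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\tpeak{p.rank}\t{score}\t.\n")


def write_peaks_tsv(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tsummit\tfold_enrichment\tp_value\trank\n")
        for p in peaks:
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.summit}\t"
                f"{p.fold_enrichment:.4g}\t{p.p_value:.4g}\t{p.rank}\n"
            )


def write_windows_bed(windows: list[TagWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\twindow{w.source_rank}\t0\t.\n")


def write_windows_fasta(windows: list[TagWindow], path) -> None:
    write_fasta(
        path,
        ((f"window{w.source_rank}|{w.contig}:{w.start}-{w.end}", w.sequence) for w in windows),
    )
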