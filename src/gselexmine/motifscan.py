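"""IUPAC motif scanning and k-mer over-representation analysis.

The registry holds the five binding sites relevant to the fungal
Zn(II)2Cys6 transcription factor studied here: the three canonical
hexamers ``GGCTAA``, ``GGCTGA`` and ``GGCTAG``, the degenerate
monomer site ``CGGNTAAW`` and the dimer site ``TTAGSCTAA``
(``N`` = any base, ``W`` = A/T, ``S`` = G/C).

Counting policy: occurrences are reported on both strands and
overlapping occurrences are all counted; both choices are configurable
because neither is uniquely dictated by convention.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from ._seq import revcomp

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "N": "[ACGT]",
    "W": "[AT]",
    "S": "[CG]",
}

#: The canonical hexamers counted in the motif-presence test.
CANONICAL_MOTIFS = ("GGCTAA", "GGCTGA", "GGCTAG")


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC motif."""

    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"unsupported IUPAC code(s) {sorted(bad)} in {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def regex(self) -> re.Pattern:
        return _compile_iupac(self.pattern)

    def regex_rc(self) -> re.Pattern:
        return _compile_iupac(revcomp(self.pattern))


@lru_cache(maxsize=256)
def _compile_iupac(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    return re.compile("(?=(" + "".join(IUPAC[c] for c in pattern) + "))")


def default_registry() -> dict[str, MotifDef]:
    """Registry of the five motifs used throughout the pipeline."""
    defs = [
        MotifDef("GGCTAA", "GGCTAA"),
        MotifDef("GGCTGA", "GGCTGA"),
        MotifDef("GGCTAG", "GGCTAG"),
        MotifDef("CGGNTAAW", "CGGNTAAW"),
        MotifDef("TTAGSCTAA", "TTAGSCTAA"),
    ]
    return {m.motif_id: m for m in defs}


REGISTRY = default_registry()


def scan_iupac(seq: str, motif: MotifDef | str, both_strands: bool = True) -> list[tuple[int, str]]:
    """All occurrences of ``motif`` in ``seq``.

    Returns ``(position, strand)`` pairs, positions 0-based on the given
    sequence. A ``-`` hit at position p means the reverse complement of
    the motif occurs at p on the forward sequence.
    """
    if isinstance(motif, str):
        motif = REGISTRY.get(motif, MotifDef(motif, motif))
    seq = seq.upper()
    hits = [(m.start(), "+") for m in motif.regex().finditer(seq)]
    if both_strands:
        hits += [(m.start(), "-") for m in motif.regex_rc().finditer(seq)]
    return sorted(hits)


@dataclass
class MotifCountVector:
    """Per-promoter motif counts, positions and coexistence flags."""

    gene_id: str | None = None
    counts: dict[str, int] = field(default_factory=dict)
    positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    @property
    def n_aa(self) -> int:
        return self.counts.get("GGCTAA", 0)

    @property
    def n_ga(self) -> int:
        return self.counts.get("GGCTGA", 0)

    @property
    def n_ag(self) -> int:
        return self.counts.get("GGCTAG", 0)

    @property
    def n_total(self) -> int:
        """Sum of the three canonical hexamer counts."""
        return self.n_aa + self.n_ga + self.n_ag

    @property
    def n_monomer(self) -> int:
        return self.counts.get("CGGNTAAW", 0)

    @property
    def n_dimer(self) -> int:
        return self.counts.get("TTAGSCTAA", 0)

    def coex(self, motif_x: str, motif_y: str) -> bool:
        """True when the promoter carries at least one site of each motif."""
        return self.counts.get(motif_x, 0) > 0 and self.counts.get(motif_y, 0) > 0

    @property
    def coex_ga_aa(self) -> bool:
        return self.coex("GGCTGA", "GGCTAA")

    @property
    def coex_aa_ag(self) -> bool:
        return self.coex("GGCTAA", "GGCTAG")

    @property
    def coex_ga_ag(self) -> bool:
        return self.coex("GGCTGA", "GGCTAG")


def count_motifs(
    promoter,
    registry: dict[str, MotifDef] | None = None,
    both_strands: bool = True,
) -> MotifCountVector:
    """Count every registered motif on a promoter (or raw sequence)."""
    seq = getattr(promoter, "sequence", promoter)
    gene_id = getattr(promoter, "gene_id", None)
    registry = registry or REGISTRY
    vec = MotifCountVector(gene_id=gene_id)
    for mid, mdef in registry.items():
        hits = scan_iupac(seq, mdef, both_strands=both_strands)
        vec.positions[mid] = hits
        vec.counts[mid] = len(hits)
    return vec


@dataclass
class KmerEnrichmentResult:
    """One canonical k-mer with its foreground/background log-odds score."""

    kmer: str
    fg_count: int
    bg_count: int
    bg_expectation: float
    score: float
    rank: int


def _canonical_kmer_counts(seqs, k: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    total = 0
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) - {"A", "C", "G", "T"}:
                continue
            counts[min(kmer, revcomp(kmer))] += 1
            total += 1
    return counts, total


def kmer_enrichment(
    foreground,
    background,
    k: int = 6,
    pseudocount: float = 0.5,
) -> list[KmerEnrichmentResult]:
    """Rank canonical k-mers by foreground-vs-background log2 odds.

    A defined, deterministic stand-in for de novo motif discovery: each
    k-mer is merged with its reverse complement into one canonical class
    and scored ``log2(p_fg) - log2(p_bg)`` with additive pseudocounts.
    Ties in score break lexicographically for reproducibility.
    """
    fg_seqs = [getattr(s, "sequence", s) for s in foreground]
    bg_seqs = [getattr(s, "sequence", s) for s in background]
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    if any(len(s) < k for s in fg_seqs):
        raise ValueError(f"k={k} exceeds the shortest foreground sequence")
    fg, fg_total = _canonical_kmer_counts(fg_seqs, k)
    bg, bg_total = _canonical_kmer_counts(bg_seqs, k)
    denom_fg = fg_total + pseudocount * 4**k
    denom_bg = bg_total + pseudocount * 4**k
    results = []
    for kmer in sorted(set(fg) | set(bg)):
        fgc, bgc = fg.get(kmer, 0), bg.get(kmer, 0)
        score = math.log2((fgc + pseudocount) / denom_fg) - math.log2(
            (bgc + pseudocount) / denom_bg
        )
        exp = bgc / bg_total * fg_total if bg_total else 0.0
        results.append(KmerEnrichmentResult(kmer, fgc, bgc, exp, score, rank=0))
    results.sort(key=lambda r: (-r.score, r.kmer))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results
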