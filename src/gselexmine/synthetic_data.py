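"""Synthetic study inputs: genome, promoters with planted sites, expression, library.

Everything downstream of this module (selection, sequencing, peak calling,
annotation, mining) is exercised on data generated here, so the generators
are first-class, deterministic, and carry explicit ground truth.

Background sequence is i.i.d. over ACGT (GC content configurable); gene
start codons are laid out so that every gene has a full 1000-bp upstream
promoter. Differential-expression ratios follow a log-linear model of the
promoter's motif content, with an extra boost when the two major sites
(GGCTAA and GGCTGA) co-occur — the qualitative structure the mining stage
is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import random_dna, revcomp, substream
from .motifscan import REGISTRY, MotifDef, MotifCountVector

PROMOTER_LEN = 1000

#: 5' linker ligated upstream of every insert (read-1 adapter).
DEFAULT_LINKER_5 = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
#: Read-2 adapter as sequenced; the 3' linker is its reverse complement.
READ2_ADAPTER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"
DEFAULT_LINKER_3 = revcomp(READ2_ADAPTER)


class SizingError(ValueError):
    """Requested gene layout does not fit on the contig."""


class PlantConflictError(ValueError):
    """Two planted motifs overlap at conflicting promoter positions."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int  # 0-based position of the start codon's first base


@dataclass
class GenomeModel:
    """A small multi-contig genome with annotated start codons."""

    contigs: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig}")
            if not 0 <= g.start < len(self.contigs[g.contig]):
                raise ValueError(f"{g.gene_id}: start codon outside contig")
        if any(len(s) == 0 for s in self.contigs.values()):
            raise ValueError("contig sequences must be non-empty")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def upstream_interval(
    gene: Gene, contig_len: int, length: int = PROMOTER_LEN
) -> tuple[int, int, bool]:
    """Genomic half-open interval of the upstream region; flag = truncated."""
    if gene.strand == "+":
        start, end = max(0, gene.start - length), gene.start
    else:
        start, end = gene.start + 1, min(contig_len, gene.start + 1 + length)
    return start, end, (end - start) < length


def promoter_forward_seq(genome: GenomeModel, gene: Gene, length: int = PROMOTER_LEN) -> str:
    """Upstream sequence in promoter-forward orientation (reads toward the start codon)."""
    contig = genome.contigs[gene.contig]
    start, end, _ = upstream_interval(gene, len(contig), length)
    seq = contig[start:end]
    return seq if gene.strand == "+" else revcomp(seq)


@dataclass
class PlantedSite:
    motif_id: str
    position: int  # 1-based promoter-forward position (1000 = adjacent to start codon... see docs)
    strand: str
    realization: str  # concrete ACGT sequence written, promoter-forward orientation


@dataclass
class PlantedTruth:
    """Ground truth of what was written into which promoter."""

    sites: dict[str, list[PlantedSite]] = field(default_factory=dict)

    def planted_counts(self, motif_id: str) -> dict[str, int]:
        return {
            g: sum(1 for s in sites if s.motif_id == motif_id) for g, sites in self.sites.items()
        }

    @property
    def genes(self) -> list[str]:
        return sorted(self.sites)


@dataclass
class EffectModel:
    """Log-linear model tying expression ratios to promoter motif content.

    ``ln r = b0 + b_aa*nAA + b_ga*nGA + b_ag*nAG + b_coex*[nAA>0 and nGA>0] + eps``
    with ``eps ~ Normal(0, sigma^2)``. Defaults are synthetic choices that
    make the coexistence indicator the strongest single correlate.
    """

    b0: float = 0.0
    b_aa: float = 0.3
    b_ga: float = 0.3
    b_ag: float = 0.1
    b_coex: float = 1.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class ExpressionTable:
    """Per-gene differential expression ratio (overproducer / disruptant)."""

    ratios: dict[str, float]

    def __post_init__(self) -> None:
        for g, r in self.ratios.items():
            if not (r > 0 and math.isfinite(r)):
                raise ValueError(f"{g}: ratio must be positive and finite, got {r}")

    def __getitem__(self, gene_id: str) -> float:
        return self.ratios[gene_id]

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class Fragment:
    insert: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class FragmentLibrary:
    """Linker-flanked genomic fragment pool (round 0 of the selection)."""

    fragments: list[Fragment]
    linker5: str = DEFAULT_LINKER_5
    linker3: str = DEFAULT_LINKER_3

    def __len__(self) -> int:
        return len(self.fragments)

    def full_sequence(self, i: int) -> str:
        return self.linker5 + self.fragments[i].insert + self.linker3


def generate_genome(
    n_genes: int,
    contig_length: int = 50_000,
    promoter_spacing: int = 2000,
    seed: int = 0,
    n_contigs: int = 2,
    gc: float = 0.5,
) -> GenomeModel:
    """Uniform-background genome with ``n_genes`` start codons.

    Genes are laid out in disjoint ``promoter_spacing`` blocks so every
    gene owns a full 1000-bp upstream region; strand is random per gene.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if promoter_spacing < PROMOTER_LEN + 10:
        raise SizingError(f"promoter_spacing must be >= {PROMOTER_LEN + 10}")
    n_contigs = min(n_contigs, n_genes)
    per_contig = -(-n_genes // n_contigs)  # ceil
    if per_contig * promoter_spacing > contig_length:
        raise SizingError(
            f"contig of {contig_length} bp cannot hold {per_contig} genes "
            f"spaced {promoter_spacing} bp"
        )
    rng = substream(seed, "genome")
    contigs = {f"chr{c + 1}": random_dna(rng, contig_length, gc) for c in range(n_contigs)}
    genes = []
    width = len(str(n_genes))
    for i in range(n_genes):
        contig = f"chr{(i % n_contigs) + 1}"
        block = (i // n_contigs) * promoter_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start = block + PROMOTER_LEN
        else:
            start = block + promoter_spacing - PROMOTER_LEN - 1
            if start <= block:  # spacing barely above minimum
                start = block + 1
        genes.append(Gene(f"g{i + 1:0{width}d}", contig, strand, start))
    return GenomeModel(contigs=contigs, genes=genes)


def _promoter_to_genomic(gene: Gene, pos: int, length: int) -> tuple[int, int]:
    """Genomic half-open interval of promoter-forward positions [pos, pos+length-1]."""
    if gene.strand == "+":
        start = gene.start - PROMOTER_LEN + pos - 1
        return start, start + length
    start = gene.start + PROMOTER_LEN + 2 - pos - length
    return start, start + length


def realize_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracies uniformly at random."""
    from .motifscan import IUPAC

    out = []
    for c in pattern:
        choices = IUPAC[c].strip("[]")
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices)
    return "".join(out)


def plant_motifs(
    genome: GenomeModel,
    plan: Mapping[str, Sequence[tuple[str, int, str]]],
    seed: int = 0,
    registry: Mapping[str, MotifDef] | None = None,
) -> tuple[GenomeModel, PlantedTruth]:
    """Write concrete motif realizations into promoters per ``plan``.

    ``plan`` maps gene-id to ``(motif_id, promoter position 1..1000, strand)``
    triples; position 1000 is the base adjacent to the start codon, so a
    motif at position p occupies promoter-forward bases p..p+len-1.
    """
    registry = dict(registry or REGISTRY)
    rng = substream(seed, "plant")
    buffers = {cid: bytearray(seq, "ascii") for cid, seq in genome.contigs.items()}
    truth = PlantedTruth()
    for gene_id in sorted(plan):
        gene = genome.gene(gene_id)
        occupied: list[tuple[int, int]] = []
        for motif_id, pos, strand in plan[gene_id]:
            mdef = registry.get(motif_id, MotifDef(motif_id, motif_id))
            L = len(mdef)
            if not 1 <= pos <= PROMOTER_LEN - L + 1:
                raise ValueError(
                    f"{gene_id}: position {pos} does not leave room for {motif_id}"
                )
            span = (pos, pos + L)
            for a, b in occupied:
                if span[0] < b and a < span[1]:
                    raise PlantConflictError(
                        f"{gene_id}: plant at {pos} overlaps an earlier plant"
                    )
            occupied.append(span)
            realized = realize_iupac(mdef.pattern, rng)
            written = realized if strand == "+" else revcomp(realized)
            gstart, gend = _promoter_to_genomic(gene, pos, L)
            # promoter-forward equals genomic forward only for + strand genes
            genomic = written if gene.strand == "+" else revcomp(written)
            buffers[gene.contig][gstart:gend] = genomic.encode("ascii")
            truth.sites.setdefault(gene_id, []).append(
                PlantedSite(motif_id, pos, strand, realized)
            )
    planted = GenomeModel(
        contigs={cid: buf.decode("ascii") for cid, buf in buffers.items()},
        genes=list(genome.genes),
    )
    return planted, truth


def random_motif_plan(
    genome: GenomeModel,
    rates: Mapping[str, float],
    seed: int = 0,
    genes: Iterable[str] | None = None,
    max_tries: int = 200,
) -> dict[str, list[tuple[str, int, str]]]:
    """Poisson-distributed per-promoter plant plan with non-overlapping sites."""
    rng = substream(seed, "plan")
    gene_ids = sorted(genes) if genes is not None else [g.gene_id for g in genome.genes]
    plan: dict[str, list[tuple[str, int, str]]] = {}
    for gid in gene_ids:
        sites: list[tuple[str, int, str]] = []
        occupied: list[tuple[int, int]] = []
        for mid in sorted(rates):
            L = len(REGISTRY.get(mid, MotifDef(mid, mid)))
            for _ in range(rng.poisson(rates[mid])):
                for _try in range(max_tries):
                    pos = int(rng.integers(1, PROMOTER_LEN - L + 2))
                    if all(not (pos < b and a < pos + L) for a, b in occupied):
                        occupied.append((pos, pos + L))
                        strand = "+" if rng.random() < 0.5 else "-"
                        sites.append((mid, pos, strand))
                        break
        if sites:
            plan[gid] = sites
    return plan


def generate_expression(
    counts: Mapping[str, MotifCountVector],
    model: EffectModel | None = None,
    seed: int = 0,
) -> ExpressionTable:
    """Draw expression ratios from the log-linear effect model.

    ``counts`` should come from scanning the planted promoters, so that the
    table reflects everything a scanner will later see (planted sites plus
    chance background occurrences).
    """
    model = model or EffectModel()
    rng = substream(seed, "expression")
    ratios = {}
    for gid in sorted(counts):
        v = counts[gid]
        ln_r = (
            model.b0
            + model.b_aa * v.n_aa
            + model.b_ga * v.n_ga
            + model.b_ag * v.n_ag
            + model.b_coex * (1 if (v.n_aa > 0 and v.n_ga > 0) else 0)
        )
        if model.sigma > 0:
            ln_r += rng.normal(0.0, model.sigma)
        ratios[gid] = math.exp(ln_r)
    return ExpressionTable(ratios=ratios)


def build_library(
    genome: GenomeModel,
    n_fragments: int,
    mean_len: int = 100,
    sd_len: float = 15.0,
    linkers: tuple[str, str] = (DEFAULT_LINKER_5, DEFAULT_LINKER_3),
    seed: int = 0,
) -> FragmentLibrary:
    """Sheared, size-fractionated (~``mean_len`` bp) linker-flanked library."""
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = substream(seed, "library")
    cids = sorted(genome.contigs)
    lens = np.array([len(genome.contigs[c]) for c in cids], dtype=float)
    if mean_len >= lens.min():
        raise ValueError("mean_len must be smaller than the shortest contig")
    p = lens / lens.sum()
    lengths = np.clip(
        np.rint(rng.normal(mean_len, sd_len, size=n_fragments)).astype(int), 30, 3 * mean_len
    )
    contig_idx = rng.choice(len(cids), size=n_fragments, p=p)
    strands = np.where(rng.random(n_fragments) < 0.5, "+", "-")
    fragments = []
    for i in range(n_fragments):
        cid = cids[contig_idx[i]]
        seq = genome.contigs[cid]
        L = min(int(lengths[i]), len(seq))
        start = int(rng.integers(0, len(seq) - L + 1))
        insert = seq[start : start + L]
        if strands[i] == "-":
            insert = revcomp(insert)
        fragments.append(Fragment(insert, cid, start, start + L, str(strands[i])))
    return FragmentLibrary(fragments=fragments, linker5=linkers[0], linker3=linkers[1])


# ---------------------------------------------------------------------------
# plain-text writers

def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome(genome: GenomeModel, out_dir) -> None:
    """Write genome FASTA plus a gene table TSV (0-based start codons)."""
    out = Path(out_dir)
    write_fasta(out / "genome.fasta", sorted(genome.contigs.items()))
    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene_id\tcontig\tstrand\tstart_codon\n")
        for g in genome.genes:
            fh.write(f"{g.gene_id}\t{g.contig}\t{g.strand}\t{g.start}\n")


def write_expression(expr: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tratio\n")
        for gid in sorted(expr.ratios):
            fh.write(f"{gid}\t{expr.ratios[gid]:.6g}\n")


def read_expression(path) -> ExpressionTable:
    ratios = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gid, r = line.split("\t")
            ratios[gid] = float(r)
    return ExpressionTable(ratios=ratios)


def write_truth(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmotif_id\tposition\tstrand\trealization\n")
        for gid in sorted(truth.sites):
            for s in truth.sites[gid]:
                fh.write(f"{gid}\t{s.motif_id}\t{s.position}\t{s.strand}\t{s.realization}\n")


def write_library(lib: FragmentLibrary, path) -> None:
    """Inserts as FASTA; headers carry the source interval."""
    write_fasta(
        path,
        (
            (f"frag{i + 1}|{f.contig}:{f.start}-{f.end}({f.strand})", f.insert)
            for i, f in enumerate(lib.fragments)
        ),
    )
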