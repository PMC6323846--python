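"""In vitro selection model: affinity weights, round-wise enrichment, read emission.

Each selection round is a single multinomial draw of ``pool_size`` fragments
with probability proportional to (previous abundance x binding weight);
bench selection and PCR re-amplification are collapsed into that draw, the
simplest model that preserves proportionality to binding weight. Binding
weight is linear in motif content: a background weight plus one term per
motif occurrence, with the default ordering GGCTAA > GGCTGA reflecting the
factor's measured affinity preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, substream
from .motifscan import REGISTRY, scan_iupac
from .synthetic_data import FragmentLibrary


class DegenerateModelError(ValueError):
    """All fragment weights are zero; selection probabilities undefined."""


@dataclass
class AffinityModel:
    """Additive binding-weight model over motif occurrences.

    ``weight(fragment) = background + sum_m w_m * n_m(fragment)`` with
    ``n_m`` counted on both strands. Units are arbitrary; only ratios
    matter for selection.
    """

    background: float = 1.0
    motif_weights: dict[str, float] = field(
        default_factory=lambda: {
            "GGCTAA": 50.0,
            "GGCTGA": 25.0,
            "GGCTAG": 10.0,
            "CGGNTAAW": 25.0,
            "TTAGSCTAA": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background weight must be > 0")
        if any(w < 0 for w in self.motif_weights.values()):
            raise ValueError("motif weights must be >= 0")


def fragment_weight(fragment: str, model: AffinityModel) -> float:
    """Binding weight of one insert sequence under the affinity model."""
    w = model.background
    for mid, wm in model.motif_weights.items():
        if wm:
            w += wm * len(scan_iupac(fragment, REGISTRY.get(mid, mid)))
    return w


def library_weights(library: FragmentLibrary, model: AffinityModel) -> np.ndarray:
    return np.array([fragment_weight(f.insert, model) for f in library.fragments])


@dataclass
class SelectionRound:
    """Abundance multiset over library fragments after one selection round."""

    index: int
    abundance: np.ndarray  # integer counts per library fragment
    pool_size: int

    def __post_init__(self) -> None:
        if int(self.abundance.sum()) != self.pool_size:
            raise ValueError("abundances must sum to the pool size")


@dataclass
class EnrichmentCurve:
    """Mean pool binding weight per round, normalized so round 0 = 1."""

    values: list[float]

    def __post_init__(self) -> None:
        if abs(self.values[0] - 1.0) > 1e-12:
            raise ValueError("round-0 value must be exactly 1")


def run_selection(
    library: FragmentLibrary,
    model: AffinityModel | None = None,
    rounds: int = 3,
    pool_size: int | None = None,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> list[SelectionRound]:
    """Affinity-weighted multinomial selection over ``rounds`` rounds.

    Round 0 is the input library (abundance 1 per fragment unless
    ``pool_size`` resamples it); each later round draws ``pool_size``
    fragments with probability proportional to abundance x weight.
    Precomputed ``weights`` may be passed to avoid rescanning.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    model = model or AffinityModel()
    if weights is None:
        weights = library_weights(library, model)
    if not np.any(weights > 0):
        raise DegenerateModelError("all fragment weights are zero")
    n = len(library.fragments)
    pool_size = pool_size or n
    rng = substream(seed, "selection")
    abundance = np.ones(n, dtype=np.int64)
    if pool_size != n:
        abundance = rng.multinomial(pool_size, np.full(n, 1.0 / n))
    out = [SelectionRound(0, abundance, pool_size)]
    for r in range(1, rounds + 1):
        p = out[-1].abundance * weights
        total = p.sum()
        if total <= 0:
            raise DegenerateModelError("selection probabilities sum to zero")
        drawn = rng.multinomial(pool_size, p / total)
        out.append(SelectionRound(r, drawn, pool_size))
    return out


def relative_binding(
    rounds: list[SelectionRound],
    model: AffinityModel,
    library: FragmentLibrary | None = None,
    weights: np.ndarray | None = None,
) -> EnrichmentCurve:
    """Mean pool binding weight per round relative to the input pool.

    This is the sequencing-free readout of selection progress: the pool's
    average affinity for the factor, with round 0 set to 1.
    """
    if not rounds or rounds[0].index != 0:
        raise ValueError("round 0 (the input library) is required")
    if weights is None:
        if library is None:
            raise ValueError("either library or precomputed weights required")
        weights = library_weights(library, model)
    means = [float((r.abundance @ weights) / r.pool_size) for r in rounds]
    return EnrichmentCurve(values=[m / means[0] for m in means])


def emit_reads(
    sel_round: SelectionRound,
    library: FragmentLibrary,
    read_len: int = 75,
    n_read_pairs: int = 10_000,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Paired reads from a selected pool, linkers left on.

    Read 1 is the 5' prefix of linker5+insert+linker3; read 2 is the
    prefix of the reverse complement of the same molecule (so it starts
    in the 3' linker). Substitutions are uniform at the given per-base
    rate; qualities are flat. Returns (read1, read2) lists of
    (name, sequence) pairs.
    """
    if sel_round.pool_size == 0 or not np.any(sel_round.abundance > 0):
        raise ValueError("cannot emit reads from an empty round")
    if n_read_pairs < 0:
        raise ValueError("n_read_pairs must be >= 0")
    rng = substream(seed, f"reads-round{sel_round.index}")
    p = sel_round.abundance / sel_round.abundance.sum()
    picks = rng.choice(len(p), size=n_read_pairs, p=p)
    r1, r2 = [], []
    for i, idx in enumerate(picks):
        full = library.full_sequence(int(idx))
        fwd = full[:read_len]
        rev = revcomp(full)[:read_len]
        if substitution_rate > 0:
            fwd = _mutate(fwd, substitution_rate, rng)
            rev = _mutate(rev, substitution_rate, rng)
        name = f"rd{sel_round.index}_pair{i + 1}_frag{int(idx) + 1}"
        r1.append((name, fwd))
        r2.append((name, rev))
    return r1, r2


_OTHERS = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alts = _OTHERS.get(chars[i], list("ACGT"))
        chars[i] = alts[rng.integers(len(alts))]
    return "".join(chars)


def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Plain FASTQ with a flat quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header.strip().lstrip("@"), seq))
    return reads


def write_rounds(rounds: list[SelectionRound], path) -> None:
    with open(path, "w") as fh:
        fh.write("round\tfragment\tabundance\n")
        for r in rounds:
            for i in np.nonzero(r.abundance)[0]:
                fh.write(f"{r.index}\tfrag{i + 1}\t{r.abundance[i]}\n")


def write_enrichment_curve(curve: EnrichmentCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("round\trelative_binding\n")
        for i, v in enumerate(curve.values):
            fh.write(f"{i}\t{v:.6g}\n")
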