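"""Small DNA sequence helpers shared across the package."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNWSacgtnws", "TGCANWStgcanws")

#: Byte codes for the four bases, used by array-based routines.
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N/W/S preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the given GC content (default uniform)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return array_to_seq(rng.choice(BASES, size=length, p=p))


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream derived from one top-level seed.

    Every stage of the pipeline draws from its own stream so that changing
    the amount of randomness consumed in one stage cannot perturb another.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))
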