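"""Single-end 3'-tag read simulation with Phred qualities and substitution errors.

Reads are substrings of the source transcripts with injected substitution
errors.  Start positions are drawn with a tunable 3' bias implemented as a
truncated geometric distribution over the distance from the 3'-most
possible start (bias 0 gives uniform starts).  Read ids encode the source
coordinates (``accession|transcript|start|serial``) so provenance can be
checked exactly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..seqio import Read
from .sequences import BASES


def _draw_starts(
    s_max: int, size: int, bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Start offsets in [0, s_max]; ``bias`` in [0, 1) weights the 3' end."""
    if s_max == 0:
        return np.zeros(size, dtype=int)
    if bias <= 0:
        return rng.integers(0, s_max + 1, size=size)
    # truncated geometric over the distance j from the 3'-most start:
    # P(j) ~ (1-bias)^j for j = 0..s_max, sampled by inverse CDF
    u = rng.random(size)
    tail = (1.0 - bias) ** (s_max + 1)
    j = np.floor(np.log1p(-u * (1.0 - tail)) / np.log(1.0 - bias)).astype(int)
    j = np.clip(j, 0, s_max)
    return s_max - j


def simulate_reads(
    transcripts: Mapping[str, str],
    depth: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    three_prime_bias: float = 0.0,
    mean_quality: int = 35,
    quality_sd: float = 3.0,
    accession: str = "sample",
    seed: int = 0,
) -> list[Read]:
    """Simulate error-bearing single-end reads at a mean per-base coverage.

    ``depth`` is the target mean coverage per transcript base; the read
    count per transcript is Poisson with mean ``depth * L / read_length``.
    ``error_rate`` (in [0, 0.25]) injects per-base substitutions to a
    random different base.  Deterministic under a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0 <= error_rate <= 0.25):
        raise ValueError("error_rate must be in [0, 0.25]")
    if not (0 <= three_prime_bias < 1):
        raise ValueError("three_prime_bias must be in [0, 1)")
    shortest = min(len(s) for s in transcripts.values())
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest transcript ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    serial = 0
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        L = len(seq)
        n_reads = int(rng.poisson(depth * L / read_length))
        if n_reads == 0:
            continue
        starts = _draw_starts(L - read_length, n_reads, three_prime_bias, rng)
        for start in starts:
            frag = arr[start : start + read_length].copy()
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                for pos in errs:
                    frag[pos] = rng.choice(BASES[BASES != frag[pos]])
            quals = np.clip(
                np.rint(rng.normal(mean_quality, quality_sd, size=read_length)),
                2,
                41,
            ).astype(int)
            reads.append(
                Read(
                    f"{accession}|{tid}|{start}|{serial}",
                    frag.tobytes().decode("ascii"),
                    tuple(int(q) for q in quals),
                )
            )
            serial += 1
    return reads


def read_source(read: Read) -> tuple[str, str, int]:
    """Decode (accession, transcript, start) from a simulated read id."""
    acc, tid, start, _serial = read.id.split("|")
    return acc, tid, int(start)
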