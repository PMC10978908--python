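"""K-mer seeded, ungapped placement of 3'-tag reads on transcript references.

The aligner replaces a general-purpose short-read mapper for the narrow
case handled here: substitution-only divergence of a few percent between
reads and transcript references.  Candidate placements come from exact
k-mer seed hits; each candidate is scored by full-length ungapped mismatch
counting, and a read is placed only when its best placement is strictly
better than the runner-up (multi-mapping reads are discarded) and within
the mismatch budget.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .seqio import Read

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGTN"
_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _BASE_TO_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array of codes 0..4."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Placement:
    read_id: str
    transcript_id: str
    offset: int  # 0-based start on the transcript
    mismatches: int
    unique: bool = True
    strand: str = "+"


class KmerIndex:
    """Exact k-mer index over a transcript set.

    Every k-mer of every transcript is retrievable with all of its
    ``(transcript_id, offset)`` occurrences.
    """

    def __init__(self, reference: Mapping[str, str], k: int = 21):
        if k < 11:
            raise ValueError("seed length k must be >= 11")
        self.k = k
        self.transcripts: dict[str, str] = {}
        self.encoded: dict[str, np.ndarray] = {}
        self._table: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in reference.items():
            if tid in self.transcripts:
                raise ValueError(f"duplicate transcript id {tid!r}")
            seq = seq.upper()
            self.transcripts[tid] = seq
            self.encoded[tid] = encode_seq(seq)
            if len(seq) < k:
                logger.warning(
                    "transcript %s shorter than k=%d; contributes no seeds",
                    tid,
                    k,
                )
                continue
            table = self._table
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                hits = table.get(kmer)
                if hits is None:
                    table[kmer] = [(tid, off)]
                else:
                    hits.append((tid, off))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])

    def __len__(self) -> int:
        return len(self._table)


def build_index(reference: Mapping[str, str], k: int = 21) -> KmerIndex:
    """Build a :class:`KmerIndex` over ``reference`` (id -> sequence)."""
    return KmerIndex(reference, k=k)


def _candidates(seq: str, index: KmerIndex) -> set[tuple[str, int]]:
    k = index.k
    n = len(seq)
    starts = list(range(0, n - k + 1, k))
    if starts and starts[-1] != n - k:
        starts.append(n - k)
    out: set[tuple[str, int]] = set()
    for pos in starts:
        for tid, off in index.lookup(seq[pos : pos + k]):
            start = off - pos
            if start >= 0 and start + n <= len(index.transcripts[tid]):
                out.add((tid, start))
    return out


def align_read(
    read: Read,
    index: KmerIndex,
    max_mismatch_frac: float = 0.04,
    search_revcomp: bool = False,
) -> Placement | None:
    """Place a read on the reference, or return ``None`` if unalignable.

    The best candidate (fewest mismatches) is reported only when it is
    within the mismatch budget and strictly better than the second-best
    candidate; ties and over-budget placements are dropped.
    """
    n = len(read)
    if n <= index.k:
        return None
    budget = math.ceil(max_mismatch_frac * n)

    strands = [("+", read.sequence)]
    if search_revcomp:
        strands.append(("-", revcomp(read.sequence)))

    best: tuple[int, str, int, str] | None = None  # (mm, tid, start, strand)
    second_mm: int | None = None
    for strand, seq in strands:
        enc = encode_seq(seq)
        for tid, start in _candidates(seq, index):
            ref = index.encoded[tid]
            mm = int(np.count_nonzero(ref[start : start + n] != enc))
            if best is None or mm < best[0]:
                second_mm = None if best is None else best[0]
                best = (mm, tid, start, strand)
            elif second_mm is None or mm < second_mm:
                second_mm = mm
    if best is None:
        return None
    mm, tid, start, strand = best
    if mm > budget:
        return None
    if second_mm is not None and second_mm <= mm:
        return None  # multi-mapping / ambiguous
    return Placement(read.id, tid, start, mm, unique=True, strand=strand)


def align_reads(
    reads: Iterable[Read],
    index: KmerIndex,
    max_mismatch_frac: float = 0.04,
    search_revcomp: bool = False,
) -> Iterator[tuple[Read, Placement]]:
    """Yield ``(read, placement)`` pairs for uniquely placed reads."""
    for read in reads:
        placement = align_read(
            read, index, max_mismatch_frac=max_mismatch_frac,
            search_revcomp=search_revcomp,
        )
        if placement is not None:
            yield read, placement


@dataclass(frozen=True)
class PileupColumn:
    transcript_id: str
    position: int  # 0-based
    depth: int
    base_counts: tuple[int, int, int, int, int]  # A, C, G, T, N


class Pileup:
    """Per-position base counts over a transcript set."""

    def __init__(self, reference: Mapping[str, str]):
        self.reference = dict(reference)
        self.counts: dict[str, np.ndarray] = {
            tid: np.zeros((5, len(seq)), dtype=np.int32)
            for tid, seq in self.reference.items()
        }

    def add(self, read: Read, placement: Placement) -> None:
        tid = placement.transcript_id
        if tid not in self.counts:
            raise ValueError(f"unknown transcript {tid!r} in placement")
        arr = self.counts[tid]
        n = len(read)
        if placement.offset < 0 or placement.offset + n > arr.shape[1]:
            raise ValueError(
                f"placement of read {read.id!r} out of bounds on {tid!r}"
            )
        seq = read.sequence
        if placement.strand == "-":
            seq = revcomp(seq)
        codes = encode_seq(seq)
        np.add.at(arr, (codes, np.arange(placement.offset, placement.offset + n)), 1)

    def depth(self, tid: str) -> np.ndarray:
        """Total depth (including N) at every position of a transcript."""
        return self.counts[tid].sum(axis=0)

    def column(self, tid: str, pos: int) -> PileupColumn:
        col = self.counts[tid][:, pos]
        return PileupColumn(tid, pos, int(col.sum()), tuple(int(c) for c in col))

    def columns(self) -> Iterator[PileupColumn]:
        """Iterate covered positions only, in (transcript, position) order."""
        for tid in self.counts:
            arr = self.counts[tid]
            covered = np.nonzero(arr.sum(axis=0) > 0)[0]
            for pos in covered:
                yield self.column(tid, int(pos))

    def total_depth(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


def pileup(
    placements: Sequence[tuple[Read, Placement]],
    reference: Mapping[str, str],
) -> Pileup:
    """Tally per-position base counts from placed reads."""
    pile = Pileup(reference)
    for read, placement in placements:
        pile.add(read, placement)
    return pile


def write_placements_tsv(placements: Iterable[tuple[Read, Placement]], sink) -> int:
    """Dump placements as a placement table (read_id, transcript, offset, mismatches)."""
    from .seqio import _open_text  # shared helper

    handle = _open_text(sink, "wt")
    close = not hasattr(sink, "write")
    n = 0
    try:
        handle.write("read_id\ttranscript_id\toffset\tmismatches\tstrand\n")
        for _read, p in placements:
            handle.write(
                f"{p.read_id}\t{p.transcript_id}\t{p.offset}\t{p.mismatches}\t{p.strand}\n"
            )
            n += 1
    finally:
        if close:
            handle.close()
    return n
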