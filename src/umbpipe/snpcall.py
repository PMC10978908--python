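"""Homozygous SNP calling, iterative reference polishing, and genotype matrices.

Two calling regimes are provided as presets:

* ``polish`` — coverage >= 10 and alternative-base fraction >= 0.95; used
  inside the iterative align/call/substitute loop that rewrites a related
  species' transcripts toward the focal species.
* ``population`` — coverage >= 5 and alternative-base fraction strictly
  > 0.80; used for per-accession genotyping against the polished reference.

Only biallelic, homozygous (haploid-coded) SNPs are represented; indels are
out of scope (the aligner is ungapped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import align as _align
from .align import BASE_ORDER, Pileup, build_index, align_reads, pileup as _pileup
from .seqio import Read

logger = logging.getLogger(__name__)

MISSING = -1
REF = 0
ALT = 1


@dataclass(frozen=True)
class SNPCall:
    transcript_id: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float

    def __post_init__(self):
        if self.alt_base == self.ref_base:
            raise ValueError("alt base equals ref base")
        if not (0 < self.alt_fraction <= 1):
            raise ValueError("alt fraction must be in (0, 1]")


@dataclass(frozen=True)
class CallRegime:
    """Thresholds for a calling regime.

    ``strict`` selects a strict inequality for the alt-fraction test
    (fraction must exceed the threshold) instead of >=.
    """

    name: str
    min_coverage: int
    min_alt_fraction: float
    strict: bool = False

    def passes(self, depth: int, alt_fraction: float) -> bool:
        if depth < self.min_coverage:
            return False
        if self.strict:
            return alt_fraction > self.min_alt_fraction
        return alt_fraction >= self.min_alt_fraction


POLISH = CallRegime("polish", min_coverage=10, min_alt_fraction=0.95, strict=False)
POPULATION = CallRegime("population", min_coverage=5, min_alt_fraction=0.80, strict=True)

_REGIMES = {"polish": POLISH, "population": POPULATION}


def get_regime(name: str) -> CallRegime:
    try:
        return _REGIMES[name]
    except KeyError:
        raise ValueError(f"unknown regime {name!r}; expected one of {sorted(_REGIMES)}")


def call_snps(
    pile: Pileup, reference: Mapping[str, str], regime: CallRegime
) -> list[SNPCall]:
    """Call homozygous SNPs from a pileup.

    A column yields a call iff its non-N depth meets the regime's coverage
    minimum and the single most frequent non-reference base reaches the
    regime's alternative fraction (computed over non-N bases).
    """
    calls: list[SNPCall] = []
    for tid in sorted(pile.counts):
        if tid not in reference:
            raise ValueError(f"pileup transcript {tid!r} absent from reference")
        counts = pile.counts[tid][:4]  # A,C,G,T rows; N excluded from fractions
        depth = counts.sum(axis=0)
        ref_codes = _align.encode_seq(reference[tid])
        masked = counts.copy()
        valid_ref = ref_codes < 4
        cols = np.arange(counts.shape[1])
        masked[ref_codes[valid_ref], cols[valid_ref]] = -1
        alt_codes = masked.argmax(axis=0)
        alt_counts = counts[alt_codes, cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, alt_counts / np.maximum(depth, 1), 0.0)
        cov_ok = depth >= regime.min_coverage
        frac_ok = frac > regime.min_alt_fraction if regime.strict else frac >= regime.min_alt_fraction
        mask = cov_ok & frac_ok & (alt_counts > 0) & valid_ref
        for pos in np.nonzero(mask)[0]:
            calls.append(
                SNPCall(
                    tid,
                    int(pos),
                    BASE_ORDER[ref_codes[pos]],
                    BASE_ORDER[alt_codes[pos]],
                    int(depth[pos]),
                    float(frac[pos]),
                )
            )
    return calls


def substitute_reference(
    reference: Mapping[str, str], calls: Iterable[SNPCall]
) -> dict[str, str]:
    """Rewrite the reference with called alternative bases.

    Output is identical to the input except at call positions; lengths are
    preserved.  A call whose recorded reference base no longer matches the
    current reference is a hard error (stale call set).
    """
    out = {tid: bytearray(seq, "ascii") for tid, seq in reference.items()}
    for call in calls:
        if call.transcript_id not in out:
            raise ValueError(f"call on unknown transcript {call.transcript_id!r}")
        buf = out[call.transcript_id]
        if not (0 <= call.position < len(buf)):
            raise ValueError(
                f"call position {call.position} out of bounds on {call.transcript_id!r}"
            )
        if chr(buf[call.position]) != call.ref_base:
            raise ValueError(
                f"stale call at {call.transcript_id}:{call.position}: reference has "
                f"{chr(buf[call.position])!r}, call expects {call.ref_base!r}"
            )
        buf[call.position] = ord(call.alt_base)
    return {tid: buf.decode("ascii") for tid, buf in out.items()}


@dataclass
class SNPCountTrajectory:
    """Per-iteration detected-SNP totals of the polishing loop."""

    counts: list[int]
    converged_at: int | None  # 1-based iteration index, or None
    max_iterations: int

    def __post_init__(self):
        if len(self.counts) > self.max_iterations:
            raise ValueError("trajectory longer than max_iterations")


def polish_reference(
    reads: Sequence[Read],
    initial_reference: Mapping[str, str],
    max_iterations: int = 16,
    stop_tolerance: int = 0,
    regime: CallRegime = POLISH,
    k: int = 21,
    max_mismatch_frac: float = 0.04,
    search_revcomp: bool = False,
) -> tuple[dict[str, str], SNPCountTrajectory, list[list[SNPCall]]]:
    """Iteratively align reads, call SNPs, and substitute them into the reference.

    Stops when the detected-SNP count reaches zero, when the change between
    successive iteration counts is within ``stop_tolerance`` (default 0:
    exact plateau), or at ``max_iterations`` (default 16).  Returns the
    polished reference, the count trajectory with its convergence decision,
    and the per-iteration call sets.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    reference = dict(initial_reference)
    counts: list[int] = []
    call_history: list[list[SNPCall]] = []
    converged_at: int | None = None
    for iteration in range(1, max_iterations + 1):
        index = build_index(reference, k=k)
        placed = list(
            align_reads(
                reads, index, max_mismatch_frac=max_mismatch_frac,
                search_revcomp=search_revcomp,
            )
        )
        if iteration == 1 and not placed:
            raise RuntimeError(
                "no reads aligned to the initial reference; check read/reference "
                "compatibility, k, and the mismatch budget"
            )
        pile = _pileup(placed, reference)
        calls = call_snps(pile, reference, regime)
        counts.append(len(calls))
        call_history.append(calls)
        reference = substitute_reference(reference, calls)
        if len(calls) == 0:
            converged_at = iteration
            break
        if iteration >= 2 and abs(counts[-1] - counts[-2]) <= stop_tolerance:
            converged_at = iteration
            break
    trajectory = SNPCountTrajectory(counts, converged_at, max_iterations)
    return reference, trajectory, call_history


Locus = tuple[str, int, str, str]  # transcript, position, ref base, alt base


@dataclass
class GenotypeMatrix:
    """Biallelic loci x accessions, haploid-coded.

    ``calls`` holds 0 (reference allele), 1 (alternative allele), or -1
    (missing); ``depth`` holds the non-N supporting read depth per cell.
    No heterozygous state exists in the coding.
    """

    loci: list[Locus]
    accessions: list[str]
    calls: np.ndarray  # int8, (n_loci, n_accessions)
    depth: np.ndarray  # int32, (n_loci, n_accessions)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        shape = (len(self.loci), len(self.accessions))
        if self.calls.shape != shape or self.depth.shape != shape:
            raise ValueError("calls/depth shape does not match loci x accessions")
        if not np.isin(self.calls, (-1, 0, 1)).all():
            raise ValueError("calls must be coded -1/0/1")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return GenotypeMatrix(
            [self.loci[i] for i in keep],
            list(self.accessions),
            self.calls[keep],
            self.depth[keep],
        )

    def to_tsv(self, sink) -> None:
        from .seqio import _open_text

        handle = _open_text(sink, "wt")
        close = not hasattr(sink, "write")
        try:
            handle.write(
                "transcript_id\tposition\tref\talt\t"
                + "\t".join(self.accessions)
                + "\n"
            )
            for i, (tid, pos, ref, alt) in enumerate(self.loci):
                cells = [
                    f"{int(c)}:{int(d)}"
                    for c, d in zip(self.calls[i], self.depth[i])
                ]
                handle.write(f"{tid}\t{pos}\t{ref}\t{alt}\t" + "\t".join(cells) + "\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_tsv(cls, source) -> "GenotypeMatrix":
        from .seqio import _open_text

        handle = _open_text(source)
        close = not hasattr(source, "read")
        try:
            header = handle.readline().rstrip("\n").split("\t")
            accessions = header[4:]
            loci: list[Locus] = []
            calls: list[list[int]] = []
            depth: list[list[int]] = []
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                loci.append((parts[0], int(parts[1]), parts[2], parts[3]))
                row_c, row_d = [], []
                for cell in parts[4:]:
                    c, d = cell.split(":")
                    row_c.append(int(c))
                    row_d.append(int(d))
                calls.append(row_c)
                depth.append(row_d)
            return cls(
                loci,
                accessions,
                np.array(calls, dtype=np.int8).reshape(len(loci), len(accessions)),
                np.array(depth, dtype=np.int32).reshape(len(loci), len(accessions)),
            )
        finally:
            if close:
                handle.close()


def build_genotype_matrix(
    callsets: Mapping[str, Sequence[SNPCall]],
    pileups: Mapping[str, Pileup],
    reference: Mapping[str, str],
) -> GenotypeMatrix:
    """Assemble a genotype matrix from per-accession population-regime calls.

    The locus set is the union of called sites across accessions.  Per
    accession and locus the code is: alternative if called; reference if
    not called but the position has at least one confirmed (non-N) covering
    read; missing otherwise.  Loci with two or more distinct alternative
    bases across accessions are excluded as non-biallelic.
    """
    accessions = sorted(callsets)
    if set(pileups) != set(callsets):
        raise ValueError("callsets and pileups must cover the same accessions")
    site_alts: dict[tuple[str, int], set[str]] = {}
    site_ref: dict[tuple[str, int], str] = {}
    for acc in accessions:
        for call in callsets[acc]:
            key = (call.transcript_id, call.position)
            if key not in site_ref:
                site_ref[key] = call.ref_base
            elif site_ref[key] != call.ref_base:
                raise ValueError(
                    f"inconsistent reference base at {key}: calls were not made "
                    "against the same reference"
                )
            site_alts.setdefault(key, set()).add(call.alt_base)
    n_multi = sum(1 for alts in site_alts.values() if len(alts) > 1)
    if n_multi:
        logger.info("excluding %d multi-allelic loci", n_multi)
    loci: list[Locus] = sorted(
        (tid, pos, site_ref[(tid, pos)], next(iter(alts)))
        for (tid, pos), alts in site_alts.items()
        if len(alts) == 1
    )
    calls = np.full((len(loci), len(accessions)), MISSING, dtype=np.int8)
    depth = np.zeros((len(loci), len(accessions)), dtype=np.int32)
    called_at = {
        acc: {(c.transcript_id, c.position) for c in callsets[acc]}
        for acc in accessions
    }
    for j, acc in enumerate(accessions):
        pile = pileups[acc]
        for i, (tid, pos, _ref, _alt) in enumerate(loci):
            if tid not in pile.counts:
                raise ValueError(f"accession {acc!r} pileup lacks transcript {tid!r}")
            col = pile.counts[tid][:4, pos]  # confirmed = non-N coverage
            d = int(col.sum())
            depth[i, j] = d
            if (tid, pos) in called_at[acc]:
                calls[i, j] = ALT
            elif d >= 1:
                calls[i, j] = REF
    return GenotypeMatrix(loci, accessions, calls, depth)


def filter_covered_set(
    matrix: GenotypeMatrix,
    coverage_quantile: float,
    min_reads: int = 3,
) -> GenotypeMatrix:
    """Keep loci confirmed (non-missing, depth >= ``min_reads``) in at least
    ``coverage_quantile`` of accessions.

    The 100% set (quantile 1.0) has zero missing cells by construction.
    """
    if not (0 < coverage_quantile <= 1):
        raise ValueError("coverage_quantile must be in (0, 1]")
    confirmed = (matrix.calls != MISSING) & (matrix.depth >= min_reads)
    frac = confirmed.mean(axis=1)
    keep = frac >= coverage_quantile - 1e-12
    return matrix.subset_loci(keep)
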