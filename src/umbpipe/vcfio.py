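"""Minimal VCFv4.2 export/import for haploid homozygous SNP calls.

Internal coordinates are 0-based; VCF POS is 1-based.  Genotypes are
written as haploid GT values (0 or 1, ``.`` for missing), one sample
column per accession.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .seqio import _open_text
from .snpcall import ALT, MISSING, REF, GenotypeMatrix, Locus, SNPCall

_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternative base fraction">\n'
)


def write_calls_vcf(
    calls: Sequence[SNPCall],
    sink,
    sample: str = "sample",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a single-sample VCF of SNP calls (all genotypes are 1)."""
    handle = _open_text(sink, "wt")
    close = not hasattr(sink, "write")
    try:
        handle.write(_HEADER)
        if contig_lengths:
            for tid, length in contig_lengths.items():
                handle.write(f"##contig=<ID={tid},length={length}>\n")
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for call in sorted(calls, key=lambda c: (c.transcript_id, c.position)):
            info = f"DP={call.depth};AF={call.alt_fraction:.4f}"
            handle.write(
                f"{call.transcript_id}\t{call.position + 1}\t.\t{call.ref_base}\t"
                f"{call.alt_base}\t.\tPASS\t{info}\tGT\t1\n"
            )
    finally:
        if close:
            handle.close()


def read_calls_vcf(source) -> list[SNPCall]:
    """Read a VCF written by :func:`write_calls_vcf` back into calls."""
    handle = _open_text(source)
    close = not hasattr(source, "read")
    calls: list[SNPCall] = []
    try:
        for line in handle:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt = parts[:5]
            info = dict(
                kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv
            )
            calls.append(
                SNPCall(
                    chrom,
                    int(pos) - 1,
                    ref,
                    alt,
                    int(info.get("DP", 0)),
                    float(info.get("AF", 1.0)),
                )
            )
    finally:
        if close:
            handle.close()
    return calls


def write_matrix_vcf(matrix: GenotypeMatrix, sink) -> None:
    """Write a genotype matrix as a multi-sample haploid VCF."""
    handle = _open_text(sink, "wt")
    close = not hasattr(sink, "write")
    try:
        handle.write(_HEADER)
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accessions)
            + "\n"
        )
        for i, (tid, pos, ref, alt) in enumerate(matrix.loci):
            gts = [
                "." if c == MISSING else str(int(c)) for c in matrix.calls[i]
            ]
            handle.write(
                f"{tid}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_matrix_vcf(source) -> GenotypeMatrix:
    """Read a multi-sample haploid VCF into a genotype matrix.

    Depths are not stored in the VCF body; cells come back with depth 0
    for missing genotypes and 1 otherwise (presence-only).
    """
    handle = _open_text(source)
    close = not hasattr(source, "read")
    loci: list[Locus] = []
    rows: list[list[int]] = []
    accessions: list[str] = []
    try:
        for line in handle:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                accessions = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            loci.append((parts[0], int(parts[1]) - 1, parts[3], parts[4]))
            row = []
            for gt in parts[9:]:
                row.append(MISSING if gt == "." else (ALT if gt == "1" else REF))
            rows.append(row)
    finally:
        if close:
            handle.close()
    calls = np.array(rows, dtype=np.int8).reshape(len(loci), len(accessions))
    depth = (calls != MISSING).astype(np.int32)
    return GenotypeMatrix(loci, accessions, calls, depth)
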