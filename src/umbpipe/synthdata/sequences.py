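"""Lineage-structured transcriptome simulation with recorded ground truth.

A population is generated by walking a lineage tree: the root carries the
ancestral transcript set, each branch applies per-site Bernoulli
substitutions, and leaves are lineages.  Accessions are haploid (the
modelled species is selfing and only homozygous calls are made
downstream): each pure accession carries its lineage's haplotype plus
optional private substitutions; admixed accessions mosaic whole
transcripts from two parent lineages with the mixing fraction recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

Site = tuple[str, int, str, str]  # transcript, 0-based position, ancestral, derived


@dataclass
class LineageNode:
    """A node of the lineage tree; ``rate`` is the per-site substitution
    probability on the branch leading into this node."""

    name: str
    rate: float = 0.0
    children: list["LineageNode"] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.rate < 0.5):
            raise ValueError(f"branch rate must be in [0, 0.5); got {self.rate}")

    def leaves(self) -> list["LineageNode"]:
        if not self.children:
            return [self]
        out: list[LineageNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    @classmethod
    def from_dict(cls, spec: Mapping) -> "LineageNode":
        return cls(
            name=spec["name"],
            rate=float(spec.get("rate", 0.0)),
            children=[cls.from_dict(c) for c in spec.get("children", [])],
        )


@dataclass
class PopulationTruth:
    """Ground truth of a simulated population."""

    lineage_labels: dict[str, str]  # accession -> majority lineage
    admixture_fractions: dict[str, dict[str, float]]  # accession -> simplex
    divergent_sites: dict[str, list[Site]]  # lineage -> sites vs ancestor
    private_sites: dict[str, list[Site]]  # accession -> private sites
    mutation_rates: dict[str, float]  # lineage -> branch rate into its leaf
    seed: int

    def __post_init__(self):
        for acc, fracs in self.admixture_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"admixture fractions for {acc!r} sum to {total}, not 1"
                )
            if any(f < 0 for f in fracs.values()):
                raise ValueError(f"negative admixture fraction for {acc!r}")

    def is_admixed(self, accession: str) -> bool:
        fracs = self.admixture_fractions[accession]
        return max(fracs.values()) < 1.0 - 1e-9

    def admixed_accessions(self) -> list[str]:
        return [a for a in self.lineage_labels if self.is_admixed(a)]


@dataclass
class SimulatedPopulation:
    ancestor: dict[str, str]
    lineage_seqs: dict[str, dict[str, str]]
    accession_seqs: dict[str, dict[str, str]]
    truth: PopulationTruth


def random_transcripts(
    n_transcripts: int,
    length: int | tuple[int, int],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Generate random ACGT transcripts; ``length`` is fixed or a (lo, hi) range."""
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    out: dict[str, str] = {}
    for i in range(n_transcripts):
        if isinstance(length, tuple):
            lo, hi = length
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(length)
        if n < 1:
            raise ValueError("zero-length transcripts are not allowed")
        seq = rng.choice(BASES, size=n)
        out[f"tr{i:05d}"] = seq.tobytes().decode("ascii")
    return out


def mutate(
    seqs: Mapping[str, str], rate: float, rng: np.random.Generator
) -> tuple[dict[str, str], list[tuple[str, int, str, str]]]:
    """Apply per-site Bernoulli substitutions; returns (sequences, events)."""
    if not (0 <= rate < 0.5):
        raise ValueError("rate must be in [0, 0.5)")
    out: dict[str, str] = {}
    events: list[tuple[str, int, str, str]] = []
    for tid, seq in seqs.items():
        if rate == 0:
            out[tid] = seq
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < rate)[0]
        for pos in hits:
            old = arr[pos]
            choices = BASES[BASES != old]
            new = rng.choice(choices)
            arr[pos] = new
            events.append((tid, int(pos), chr(old), chr(new)))
        out[tid] = arr.tobytes().decode("ascii")
    return out, events


def mutate_at_sites(
    seqs: Mapping[str, str],
    sites: Sequence[tuple[str, int]],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[Site]]:
    """Substitute a random different base at each given (transcript, position)."""
    out = {tid: bytearray(seq, "ascii") for tid, seq in seqs.items()}
    events: list[Site] = []
    for tid, pos in sites:
        old = out[tid][pos]
        new = rng.choice(BASES[BASES != old])
        out[tid][pos] = int(new)
        events.append((tid, int(pos), chr(old), chr(new)))
    return {tid: buf.decode("ascii") for tid, buf in out.items()}, events


def _diff_sites(ancestor: Mapping[str, str], derived: Mapping[str, str]) -> list[Site]:
    sites: list[Site] = []
    for tid, anc in ancestor.items():
        der = derived[tid]
        a = np.frombuffer(anc.encode(), dtype=np.uint8)
        b = np.frombuffer(der.encode(), dtype=np.uint8)
        for pos in np.nonzero(a != b)[0]:
            sites.append((tid, int(pos), anc[pos], der[pos]))
    return sites


def gen_population(
    n_accessions: int,
    n_transcripts: int,
    transcript_length: int | tuple[int, int],
    lineage_config: LineageNode | Mapping,
    admixed_fraction: float = 0.0,
    accession_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedPopulation:
    """Simulate a lineage-structured population of haploid accessions.

    Each accession's transcripts derive from the ancestral set by
    lineage-shared plus private substitutions; admixed accessions mosaic
    transcripts from two parent lineages with the mixing fraction recorded
    in the truth.  Identical configuration and seed reproduce identical
    output byte for byte.
    """
    if not (0 <= admixed_fraction <= 1):
        raise ValueError("admixed_fraction must be in [0, 1]")
    root = (
        lineage_config
        if isinstance(lineage_config, LineageNode)
        else LineageNode.from_dict(lineage_config)
    )
    rng = np.random.default_rng(seed)
    ancestor = random_transcripts(n_transcripts, transcript_length, rng)

    lineage_seqs: dict[str, dict[str, str]] = {}
    rates: dict[str, float] = {}

    def walk(node: LineageNode, seqs: Mapping[str, str]) -> None:
        mutated, _events = mutate(seqs, node.rate, rng)
        if not node.children:
            lineage_seqs[node.name] = mutated
            rates[node.name] = node.rate
            return
        for child in node.children:
            walk(child, mutated)

    # the root's own rate applies before the first split (shared by all leaves)
    walk(root, ancestor)
    lineages = sorted(lineage_seqs)
    divergent = {
        name: _diff_sites(ancestor, lineage_seqs[name]) for name in lineages
    }

    n_admixed = int(round(admixed_fraction * n_accessions))
    labels: dict[str, str] = {}
    fractions: dict[str, dict[str, float]] = {}
    private: dict[str, list[Site]] = {}
    accession_seqs: dict[str, dict[str, str]] = {}
    tids = list(ancestor)
    for i in range(n_accessions):
        acc = f"acc{i:03d}"
        if i < n_accessions - n_admixed:
            lineage = lineages[i % len(lineages)]
            seqs = dict(lineage_seqs[lineage])
            labels[acc] = lineage
            fractions[acc] = {lineage: 1.0}
        else:
            pa, pb = rng.choice(len(lineages), size=2, replace=False)
            la, lb = lineages[pa], lineages[pb]
            frac = float(rng.uniform(0.35, 0.65))
            take_a = rng.random(len(tids)) < frac
            seqs = {
                tid: (lineage_seqs[la] if ta else lineage_seqs[lb])[tid]
                for tid, ta in zip(tids, take_a)
            }
            realized = float(take_a.mean())
            labels[acc] = la if realized >= 0.5 else lb
            fractions[acc] = {la: realized, lb: 1.0 - realized}
        if accession_rate > 0:
            seqs, events = mutate(seqs, accession_rate, rng)
            private[acc] = [(t, p, o, n) for t, p, o, n in events]
        else:
            private[acc] = []
        accession_seqs[acc] = seqs

    truth = PopulationTruth(
        lineage_labels=labels,
        admixture_fractions=fractions,
        divergent_sites=divergent,
        private_sites=private,
        mutation_rates=rates,
        seed=seed,
    )
    return SimulatedPopulation(ancestor, lineage_seqs, accession_seqs, truth)


def gen_structured_genotypes(
    n_per_group: Sequence[int],
    n_loci: int,
    fst: float = 0.3,
    n_admixed: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, list[int | None], np.ndarray]:
    """Directly simulate a haploid genotype matrix with K divergent groups.

    Group allele frequencies follow the Balding–Nichols model around a
    common ancestral frequency with divergence parameter ``fst``.  Admixed
    accessions draw each locus from one of two groups (50/50).  Returns
    ``(genotypes accessions x loci, labels, group_freqs)`` where admixed
    accessions have label ``None``.
    """
    if not (0 < fst < 1):
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    K = len(n_per_group)
    anc = rng.uniform(0.2, 0.8, size=n_loci)
    a = anc * (1 - fst) / fst
    b = (1 - anc) * (1 - fst) / fst
    freqs = rng.beta(a, b, size=(K, n_loci))
    rows: list[np.ndarray] = []
    labels: list[int | None] = []
    for k, n_k in enumerate(n_per_group):
        draws = rng.random((n_k, n_loci)) < freqs[k]
        rows.append(draws.astype(np.int8))
        labels.extend([k] * n_k)
    for _ in range(n_admixed):
        ga, gb = rng.choice(K, size=2, replace=False)
        pick_a = rng.random(n_loci) < 0.5
        p = np.where(pick_a, freqs[ga], freqs[gb])
        rows.append((rng.random(n_loci) < p).astype(np.int8)[None, :])
        labels.append(None)
    genotypes = np.vstack(rows)
    return genotypes, labels, freqs
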