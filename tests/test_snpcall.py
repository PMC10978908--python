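import io

import numpy as np
import pytest

from umbpipe.align import Pileup
from umbpipe.snpcall import (
    ALT,
    MISSING,
    POLISH,
    POPULATION,
    REF,
    CallRegime,
    GenotypeMatrix,
    SNPCall,
    build_genotype_matrix,
    call_snps,
    filter_covered_set,
    get_regime,
    polish_reference,
    substitute_reference,
)
from umbpipe.synthdata import random_transcripts, simulate_reads
from umbpipe.synthdata.sequences import mutate_at_sites
from umbpipe.vcfio import (
    read_calls_vcf,
    read_matrix_vcf,
    write_calls_vcf,
    write_matrix_vcf,
)

BASES = "ACGT"


def _pile_from_counts(ref, counts_by_pos):
    """Build a pileup with explicit base counts {pos: (a, c, g, t, n)}."""
    pile = Pileup(ref)
    for tid, per_pos in counts_by_pos.items():
        for pos, counts in per_pos.items():
            pile.counts[tid][:, pos] = counts
    return pile


class TestCallRegimes:
    def test_presets(self):
        assert get_regime("polish") == POLISH
        assert get_regime("population") == POPULATION
        assert POLISH.min_coverage == 10 and POLISH.min_alt_fraction == 0.95
        assert POPULATION.min_coverage == 5 and POPULATION.min_alt_fraction == 0.80

    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="unknown regime"):
            get_regime("strict")

    def test_polish_depth_9_no_call(self):
        # 9/9 alternative reads but coverage below 10 -> discarded
        ref = {"t": "A" * 50}
        pile = _pile_from_counts(ref, {"t": {10: (0, 9, 0, 0, 0)}})
        assert call_snps(pile, ref, POLISH) == []

    def test_polish_unanimous_depth_12(self):
        ref = {"t": "A" * 50}
        pile = _pile_from_counts(ref, {"t": {10: (0, 12, 0, 0, 0)}})
        calls = call_snps(pile, ref, POLISH)
        assert len(calls) == 1
        call = calls[0]
        assert (call.position, call.ref_base, call.alt_base) == (10, "A", "C")
        assert call.alt_fraction == 1.0 and call.depth == 12

    def test_population_exact_080_not_called(self):
        # strictly > 0.80 required: 8/10 is not a call, 9/10 is
        ref = {"t": "A" * 50}
        pile = _pile_from_counts(
            ref, {"t": {5: (2, 8, 0, 0, 0), 6: (1, 9, 0, 0, 0)}}
        )
        calls = call_snps(pile, ref, POPULATION)
        assert [c.position for c in calls] == [6]

    def test_n_bases_excluded_from_fractions(self):
        # 10 alt + 5 N: polish fraction is 10/10, depth 10 -> called
        ref = {"t": "A" * 50}
        pile = _pile_from_counts(ref, {"t": {3: (0, 10, 0, 0, 5)}})
        calls = call_snps(pile, ref, POLISH)
        assert len(calls) == 1

    def test_matches_exhaustive_threshold_oracle(self, rng):
        ref = {"t": "A" * 1000}
        per_pos = {}
        for pos in range(1000):
            counts = tuple(int(c) for c in rng.integers(0, 14, size=5))
            per_pos[pos] = counts
        pile = _pile_from_counts(ref, {"t": per_pos})
        for regime in (POLISH, POPULATION):
            got = {c.position for c in call_snps(pile, ref, regime)}
            expected = set()
            for pos, (a, c, g, t, n) in per_pos.items():
                depth = a + c + g + t  # non-N depth; ref is A
                alt_counts = {"C": c, "G": g, "T": t}
                best_base = max(alt_counts, key=lambda b: alt_counts[b])
                best = alt_counts[best_base]
                if depth < regime.min_coverage or best == 0:
                    continue
                frac = best / depth
                ok = (
                    frac > regime.min_alt_fraction
                    if regime.strict
                    else frac >= regime.min_alt_fraction
                )
                if ok:
                    expected.add(pos)
            assert got == expected


class TestSubstitute:
    def test_empty_call_set_identity(self, small_reference):
        assert substitute_reference(small_reference, []) == small_reference

    def test_single_call_single_base(self, small_reference):
        tid = next(iter(small_reference))
        ref_base = small_reference[tid][5]
        alt = "A" if ref_base != "A" else "G"
        out = substitute_reference(
            small_reference, [SNPCall(tid, 5, ref_base, alt, 12, 1.0)]
        )
        assert out[tid][5] == alt
        diffs = [
            (t, i)
            for t in small_reference
            for i in range(len(small_reference[t]))
            if small_reference[t][i] != out[t][i]
        ]
        assert diffs == [(tid, 5)]

    def test_stale_call_hard_error(self, small_reference):
        tid = next(iter(small_reference))
        ref_base = small_reference[tid][5]
        wrong = "C" if ref_base != "C" else "T"
        alt = "G" if wrong != "G" else "A"
        with pytest.raises(ValueError, match="stale"):
            substitute_reference(
                small_reference, [SNPCall(tid, 5, wrong, alt, 12, 1.0)]
            )

    def test_substitute_then_recall_is_clean(self, rng):
        # self-consistency: after substitution, calling against the new
        # reference on the same reads yields nothing at the old sites
        ref = random_transcripts(10, 400, rng)
        sites = [(tid, int(pos)) for tid in ref for pos in rng.integers(160, 240, 2)]
        derived, _events = mutate_at_sites(ref, sites, rng)
        reads = simulate_reads(derived, depth=30, read_length=150, seed=8)
        polished, trajectory, _history = polish_reference(reads, ref, max_iterations=3)
        assert trajectory.counts[-1] == 0


class TestPolish:
    def test_identical_source_trajectory_zero(self, small_reference):
        reads = simulate_reads(small_reference, depth=20, read_length=150, seed=1)
        _ref, trajectory, _hist = polish_reference(reads, small_reference)
        assert trajectory.counts == [0]
        assert trajectory.converged_at == 1

    def test_m_divergent_sites_recovered_then_zero(self, rng):
        ref = random_transcripts(20, 500, rng)
        chosen = set()
        while len(chosen) < 40:
            tid = f"tr{rng.integers(20):05d}"
            chosen.add((tid, int(rng.integers(160, 340))))
        derived, events = mutate_at_sites(ref, sorted(chosen), rng)
        reads = simulate_reads(derived, depth=30, read_length=150, seed=2)
        polished, trajectory, history = polish_reference(reads, ref)
        assert trajectory.counts[0] == len(events)
        assert trajectory.counts[1] == 0
        assert trajectory.converged_at == 2
        # polished reference equals the read source at every recorded site
        for tid, pos, _anc, derived_base in events:
            assert polished[tid][pos] == derived_base

    def test_trajectory_capped_at_max_iterations(self, small_reference):
        reads = simulate_reads(
            small_reference, depth=15, read_length=150, error_rate=0.01, seed=3
        )
        _ref, trajectory, _h = polish_reference(
            reads, small_reference, max_iterations=16
        )
        assert len(trajectory.counts) <= 16
        assert trajectory.max_iterations == 16

    def test_no_aligned_reads_diagnostic(self, small_reference, rng):
        other = random_transcripts(3, 300, np.random.default_rng(999))
        reads = simulate_reads(other, depth=5, read_length=150, seed=4)
        with pytest.raises(RuntimeError, match="no reads aligned"):
            polish_reference(reads, small_reference)


class TestGenotypeMatrix:
    def _two_acc_setup(self):
        ref = {"t": "A" * 60}
        pile_a = _pile_from_counts(ref, {"t": {10: (0, 8, 0, 0, 0)}})
        pile_b = _pile_from_counts(ref, {"t": {10: (7, 0, 0, 0, 0)}})
        calls_a = call_snps(pile_a, ref, POPULATION)
        return ref, {"a1": calls_a, "a2": []}, {"a1": pile_a, "a2": pile_b}

    def test_one_snp_two_accessions(self):
        ref, callsets, pileups = self._two_acc_setup()
        matrix = build_genotype_matrix(callsets, pileups, ref)
        assert matrix.loci == [("t", 10, "A", "C")]
        assert matrix.calls[0].tolist() == [ALT, REF]

    def test_missing_when_uncovered(self):
        ref = {"t": "A" * 60}
        pile_a = _pile_from_counts(ref, {"t": {10: (0, 8, 0, 0, 0)}})
        pile_b = Pileup(ref)  # no coverage at all
        callsets = {"a1": call_snps(pile_a, ref, POPULATION), "a2": []}
        matrix = build_genotype_matrix(callsets, {"a1": pile_a, "a2": pile_b}, ref)
        assert matrix.calls[0].tolist() == [ALT, MISSING]

    def test_multiallelic_excluded(self):
        ref = {"t": "A" * 60}
        pile_a = _pile_from_counts(ref, {"t": {10: (0, 8, 0, 0, 0)}})
        pile_b = _pile_from_counts(ref, {"t": {10: (0, 0, 0, 9, 0)}})
        callsets = {
            "a1": call_snps(pile_a, ref, POPULATION),
            "a2": call_snps(pile_b, ref, POPULATION),
        }
        assert callsets["a1"][0].alt_base != callsets["a2"][0].alt_base
        matrix = build_genotype_matrix(callsets, {"a1": pile_a, "a2": pile_b}, ref)
        assert matrix.n_loci == 0

    def test_tsv_roundtrip(self):
        ref, callsets, pileups = self._two_acc_setup()
        matrix = build_genotype_matrix(callsets, pileups, ref)
        sink = io.StringIO()
        matrix.to_tsv(sink)
        back = GenotypeMatrix.from_tsv(io.StringIO(sink.getvalue()))
        assert back.loci == matrix.loci
        assert np.array_equal(back.calls, matrix.calls)
        assert np.array_equal(back.depth, matrix.depth)


class TestCoveredSets:
    def _random_matrix(self, rng, n_loci=200, n_acc=114):
        calls = rng.integers(0, 2, size=(n_loci, n_acc)).astype(np.int8)
        depth = rng.integers(0, 10, size=(n_loci, n_acc)).astype(np.int32)
        missing = rng.random((n_loci, n_acc)) < 0.05
        calls[missing] = MISSING
        loci = [(f"t{i}", i, "A", "G") for i in range(n_loci)]
        return GenotypeMatrix(loci, [f"a{j}" for j in range(n_acc)], calls, depth)

    def test_locus_missing_in_one_of_114(self):
        n_acc = 114
        calls = np.zeros((1, n_acc), dtype=np.int8)
        depth = np.full((1, n_acc), 5, dtype=np.int32)
        calls[0, 7] = MISSING
        m = GenotypeMatrix([("t", 0, "A", "G")], [f"a{j}" for j in range(n_acc)],
                           calls, depth)
        assert filter_covered_set(m, 1.0).n_loci == 0
        assert filter_covered_set(m, 0.95).n_loci == 1  # 113/114 ~ 0.991

    def test_fully_covered_identity(self, rng):
        m = self._random_matrix(rng)
        m.calls[m.calls == MISSING] = 0
        m.depth[:] = 5
        out = filter_covered_set(m, 1.0)
        assert out.n_loci == m.n_loci

    def test_nesting_and_count_oracle(self, rng):
        m = self._random_matrix(rng)
        kept = {}
        for quantile in (1.0, 0.95, 0.90):
            sub = filter_covered_set(m, quantile)
            kept[quantile] = {locus for locus in sub.loci}
            # independent row-count oracle
            expected = set()
            for i, locus in enumerate(m.loci):
                good = sum(
                    1
                    for j in range(len(m.accessions))
                    if m.calls[i, j] != MISSING and m.depth[i, j] >= 3
                )
                if good / len(m.accessions) >= quantile - 1e-12:
                    expected.add(locus)
            assert kept[quantile] == expected
        assert kept[1.0] <= kept[0.95] <= kept[0.90]

    def test_100pct_set_has_no_missing(self, rng):
        m = self._random_matrix(rng)
        out = filter_covered_set(m, 1.0)
        assert (out.calls != MISSING).all()


class TestVcfRoundtrip:
    def test_boundary_positions_roundtrip(self):
        length = 500
        calls = [
            SNPCall("t1", 0, "A", "G", 12, 1.0),
            SNPCall("t1", length - 1, "C", "T", 15, 0.97),
        ]
        sink = io.StringIO()
        write_calls_vcf(calls, sink, contig_lengths={"t1": length})
        text = sink.getvalue()
        assert "\t1\t.\tA\tG" in text  # 0-based 0 -> POS 1
        assert f"\t{length}\t.\tC\tT" in text  # 0-based L-1 -> POS L
        back = read_calls_vcf(io.StringIO(text))
        assert [(c.transcript_id, c.position, c.ref_base, c.alt_base) for c in back] \
            == [(c.transcript_id, c.position, c.ref_base, c.alt_base) for c in calls]

    def test_matrix_vcf_roundtrip(self, rng):
        calls = rng.integers(0, 2, size=(5, 3)).astype(np.int8)
        calls[0, 1] = MISSING
        depth = np.full((5, 3), 4, dtype=np.int32)
        m = GenotypeMatrix(
            [(f"t{i}", 2 * i, "A", "G") for i in range(5)],
            ["x", "y", "z"],
            calls,
            depth,
        )
        sink = io.StringIO()
        write_matrix_vcf(m, sink)
        back = read_matrix_vcf(io.StringIO(sink.getvalue()))
        assert back.loci == m.loci
        assert np.array_equal(back.calls, m.calls)


class TestTrajectoryProperty:
    def test_error_free_counts_non_increasing_to_zero(self, rng):
        ref = random_transcripts(10, 500, rng)
        sites = sorted(
            {(f"tr{int(rng.integers(10)):05d}", int(rng.integers(160, 340)))
             for _ in range(30)}
        )
        derived, _ = mutate_at_sites(ref, sites, rng)
        reads = simulate_reads(derived, depth=40, read_length=150, seed=5)
        _p, trajectory, _h = polish_reference(reads, ref)
        counts = trajectory.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0
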