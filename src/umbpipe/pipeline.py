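"""End-to-end pipeline orchestration from a single YAML-able config.

Stages run in dependency order — simulate, trim, align, polish, callsnps,
snpset, structure, fst, tree, pheno, climate — with each stage's outputs
feeding the next.  All intermediate artifacts are plain-text standard
formats (FASTA/FASTQ/VCF/TSV/Newick/CSV) so every stage is independently
testable.  A single global seed deterministically derives per-stage
substreams, and a stage is skipped on rerun when its parameter/input hash
matches the cached signature.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, seqio
from .align import build_index, align_reads, pileup as make_pileup
from .geoclimate import climate_pca, cline_table, seasonal_means
from .phenostats import bpca_impute, fit_glmm, flowering_dendrogram, pca, scale_uv
from .popgen import (
    align_runs,
    assign_lineages,
    evanno_delta_k,
    fst_weir_cockerham,
    run_structure,
)
from .popgen.tree import bootstrap_support, tree_to_newick
from .snpcall import (
    GenotypeMatrix,
    build_genotype_matrix,
    call_snps,
    filter_covered_set,
    get_regime,
    polish_reference,
)
from .synthdata import (
    GLMMSpec,
    LineageNode,
    gen_geoclimate,
    gen_phenotypes,
    gen_population,
    make_design,
    simulate_reads,
)
from .vcfio import write_calls_vcf, write_matrix_vcf

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "trim",
    "polish",
    "align",
    "callsnps",
    "snpset",
    "structure",
    "fst",
    "tree",
    "pheno",
    "climate",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class StageReport:
    name: str
    n_inputs: int
    n_outputs: int
    seconds: float
    params: dict
    cached: bool = False


@dataclass
class RunReport:
    stages: list[StageReport] = field(default_factory=list)
    seed: int = 0
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "stages": [vars(s) for s in self.stages],
            },
            indent=2,
            default=str,
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed so toggling one stage does not
    perturb another's randomness."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def default_config() -> dict:
    return {
        "stages": {name: True for name in STAGES},
        "simulate": {
            "n_accessions": 12,
            "n_transcripts": 200,
            "transcript_length": 250,
            "lineages": {
                "name": "root",
                "rate": 0.0,
                "children": [
                    {"name": "L1", "rate": 0.0, "children": [
                        {"name": "L1e", "rate": 0.01},
                        {"name": "L1w", "rate": 0.01},
                    ]},
                    {"name": "L2", "rate": 0.02},
                ],
            },
            "admixed_fraction": 0.0,
            # private within-accession variation keeps SNP-only K2P
            # distances away from saturation, as in real panels
            "accession_rate": 0.004,
            "depth": 30.0,
            "read_length": 100,
            "error_rate": 0.002,
            "three_prime_bias": 0.0,
            "phenotype": {
                "beta0": 100.0,
                "beta1": {"L1e": 0.0, "L1w": 10.0, "L2": 5.0},
                "beta2": {"s1": 0.0, "s2": 2.0},
                "sigma_gamma": 1.0,
                "sigma_eps": 1.0,
                "replicates": 2,
            },
            "lat_ranges": {"L1e": (33.0, 37.0), "L1w": (36.0, 40.0),
                           "L2": (37.0, 41.0)},
            "climate_gradients": {"srad": -400.0, "temp": -0.7},
            "climate_noise_sd": 0.1,
        },
        "trim": {"window": 4, "mean_quality_threshold": 20, "min_length": 75},
        "align": {"k": 21, "max_mismatch_frac": 0.04},
        "polish": {"max_iterations": 16, "stop_tolerance": 0,
                   "regime": "polish", "accession": None},
        "callsnps": {"regime": "population"},
        "snpset": {"coverage_quantile": 1.0, "min_reads": 3},
        "structure": {"k_min": 2, "k_max": 4, "n_runs": 3, "n_sweeps": 800,
                      "burnin": 300, "alpha": 1.0, "q_threshold": 0.8,
                      "assign_k": None},
        "fst": {},
        # deduplication of identical genotype columns is meant for large
        # panels; with a 12-accession fixture it collapses too many loci
        "tree": {"n_bootstrap": 100, "deduplicate": False},
        "pheno": {"trait": "days_to_flowering", "chains": 2,
                  "iterations": 600, "burnin": 200, "n_components": 2,
                  "bpca_steps": 100},
        "climate": {"predictors": ["lat", "lon"], "trait": "days_to_flowering"},
    }


def fixture_config() -> dict:
    """Config of the bundled 12-accession / 3-lineage / 200-transcript
    smoke-test dataset."""
    return default_config()


def load_config(path) -> dict:
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    config = _merge(default_config(), user)
    validate_config(config)
    return config


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> None:
    unknown = set(config.get("stages", {})) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages in config: {sorted(unknown)}")
    trim = config.get("trim", {})
    if trim.get("window", 1) < 1 or trim.get("min_length", 1) < 1:
        raise ValueError("trim: window and min_length must be >= 1")
    get_regime(config.get("callsnps", {}).get("regime", "population"))
    st = config.get("structure", {})
    if st.get("k_min", 1) > st.get("k_max", 1):
        raise ValueError("structure: k_min must be <= k_max")


def _signature(params: dict, inputs: list[Path]) -> str:
    h = hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode())
    for path in sorted(inputs):
        h.update(path.name.encode())
        h.update(hashlib.sha256(path.read_bytes()).digest())
    return h.hexdigest()


class Pipeline:
    """Executes enabled stages in order, caching on parameter/input hashes."""

    def __init__(self, config: dict, outdir, seed: int = 0):
        validate_config(config)
        self.config = config
        self.outdir = Path(outdir)
        self.seed = seed
        self.report = RunReport(seed=seed)

    # ---- helpers ---------------------------------------------------------

    def _stage_dir(self, name: str) -> Path:
        path = self.outdir / name
        path.mkdir(parents=True, exist_ok=True)
        return path

    def _cached(self, name: str, params: dict, inputs: list[Path]) -> bool:
        sig_file = self.outdir / name / ".signature"
        sig = _signature({**params, "seed": self.seed}, inputs)
        if sig_file.exists() and sig_file.read_text() == sig:
            return True
        return False

    def _write_signature(self, name: str, params: dict, inputs: list[Path]):
        sig_file = self.outdir / name / ".signature"
        sig_file.write_text(_signature({**params, "seed": self.seed}, inputs))

    def _accessions(self) -> list[str]:
        labels = pd.read_csv(self.outdir / "simulate" / "truth_labels.tsv", sep="\t")
        return list(labels["accession"])

    # ---- stages ----------------------------------------------------------

    #: per-stage input directories, used for cache-signature hashing
    INPUT_DIRS = {
        "simulate": [],
        "trim": ["simulate"],
        "polish": ["trim", "simulate"],
        "align": ["trim", "polish"],
        "callsnps": ["trim", "polish"],
        "snpset": ["trim", "polish"],
        "structure": ["snpset"],
        "fst": ["snpset", "structure"],
        "tree": ["snpset"],
        "pheno": ["simulate"],
        "climate": ["simulate"],
    }

    def _input_files(self, name: str) -> list[Path]:
        files: list[Path] = []
        for dep in self.INPUT_DIRS[name]:
            dep_dir = self.outdir / dep
            if dep_dir.is_dir():
                files.extend(
                    p for p in sorted(dep_dir.iterdir())
                    if p.is_file() and p.name != ".signature"
                )
        return files

    def run(self) -> RunReport:
        self.outdir.mkdir(parents=True, exist_ok=True)
        for name in STAGES:
            if not self.config.get("stages", {}).get(name, False):
                continue
            params = self.config.get(name, {})
            inputs = self._input_files(name)
            if self._cached(name, params, inputs):
                logger.info("stage %s: cached outputs reused", name)
                self.report.stages.append(
                    StageReport(name, 0, 0, 0.0, params, cached=True)
                )
                continue
            start = time.monotonic()
            try:
                n_in, n_out = getattr(self, f"_stage_{name}")(params)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, str(exc)) from exc
            elapsed = time.monotonic() - start
            self._write_signature(name, params, inputs)
            self.report.stages.append(
                StageReport(name, n_in, n_out, elapsed, params)
            )
            logger.info("stage %s finished in %.1fs", name, elapsed)
        (self.outdir / "report.json").write_text(self.report.to_json())
        return self.report

    def _stage_simulate(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("simulate")
        seed = stage_seed(self.seed, "simulate")
        pop = gen_population(
            params["n_accessions"],
            params["n_transcripts"],
            params["transcript_length"],
            LineageNode.from_dict(params["lineages"]),
            admixed_fraction=params.get("admixed_fraction", 0.0),
            accession_rate=params.get("accession_rate", 0.0),
            seed=seed,
        )
        seqio.write_fasta(pop.ancestor, out / "ancestor.fa")
        for i, (acc, seqs) in enumerate(sorted(pop.accession_seqs.items())):
            reads = simulate_reads(
                seqs,
                depth=params["depth"],
                read_length=params["read_length"],
                error_rate=params["error_rate"],
                three_prime_bias=params.get("three_prime_bias", 0.0),
                accession=acc,
                seed=seed + 1 + i,
            )
            seqio.write_fastq(reads, out / f"{acc}.fastq")
        truth = pop.truth
        pd.DataFrame(
            [
                {"accession": acc, "lineage": lin,
                 "admixed": truth.is_admixed(acc)}
                for acc, lin in sorted(truth.lineage_labels.items())
            ]
        ).to_csv(out / "truth_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"lineage": lin, "transcript_id": t, "position": p,
                 "ancestral": a, "derived": d}
                for lin, sites in truth.divergent_sites.items()
                for (t, p, a, d) in sites
            ]
        ).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        # phenotypes
        ph = params["phenotype"]
        spec = GLMMSpec(
            beta0=ph["beta0"],
            beta1=ph["beta1"],
            beta2=ph["beta2"],
            beta3={},
            sigma_gamma=ph.get("sigma_gamma", 0.0),
            sigma_eps=ph.get("sigma_eps", 0.0),
        )
        by_lineage: dict[str, list[str]] = {}
        for acc, lin in truth.lineage_labels.items():
            by_lineage.setdefault(lin, []).append(acc)
        design = make_design(by_lineage, spec.seasons, ph.get("replicates", 1))
        pheno = gen_phenotypes(
            spec, design, trait=self.config["pheno"]["trait"], seed=seed + 7919
        )
        pheno.to_csv(out / "phenotypes.csv", index=False)
        geo = gen_geoclimate(
            truth,
            {k: tuple(v) for k, v in params["lat_ranges"].items()},
            climate_gradients=params.get("climate_gradients"),
            noise_sd=params.get("climate_noise_sd", 0.0),
            seed=seed + 104729,
        )
        geo.to_csv(out / "geoclimate.csv", index=False)
        with open(out / "config_echo.yaml", "w") as handle:
            yaml.safe_dump(params, handle)
        return params["n_accessions"], params["n_accessions"] + 5

    def _stage_trim(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("trim")
        policy = seqio.TrimPolicy(
            params["window"], params["mean_quality_threshold"], params["min_length"]
        )
        fastqs = sorted((self.outdir / "simulate").glob("*.fastq"))
        if not fastqs:
            raise ValueError("no FASTQ inputs from the simulate stage")
        n_in = n_out = 0
        for path in fastqs:
            reads = list(seqio.parse_fastq(path))
            n_in += len(reads)
            kept = list(seqio.trim_reads(reads, policy))
            n_out += seqio.write_fastq(kept, out / path.name)
        return n_in, n_out

    def _stage_polish(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("polish")
        reference = seqio.read_fasta(self.outdir / "simulate" / "ancestor.fa")
        acc = params.get("accession") or self._accessions()[0]
        reads = list(seqio.parse_fastq(self.outdir / "trim" / f"{acc}.fastq"))
        aln = self.config["align"]
        polished, trajectory, history = polish_reference(
            reads,
            reference,
            max_iterations=params["max_iterations"],
            stop_tolerance=params["stop_tolerance"],
            regime=get_regime(params["regime"]),
            k=aln["k"],
            max_mismatch_frac=aln["max_mismatch_frac"],
        )
        seqio.write_fasta(polished, out / "polished.fa")
        with open(out / "trajectory.tsv", "w") as handle:
            handle.write("iteration\tsnp_count\n")
            for i, count in enumerate(trajectory.counts, start=1):
                handle.write(f"{i}\t{count}\n")
        lengths = {tid: len(seq) for tid, seq in reference.items()}
        for i, calls in enumerate(history, start=1):
            write_calls_vcf(calls, out / f"iter{i:02d}.vcf", sample=acc,
                            contig_lengths=lengths)
        return len(reads), len(trajectory.counts)

    def _stage_align(self, params: dict) -> tuple[int, int]:
        from .align import write_placements_tsv

        out = self._stage_dir("align")
        reference = seqio.read_fasta(self.outdir / "polish" / "polished.fa")
        index = build_index(reference, k=params["k"])
        n_in = n_out = 0
        for path in sorted((self.outdir / "trim").glob("*.fastq")):
            reads = list(seqio.parse_fastq(path))
            n_in += len(reads)
            placed = list(
                align_reads(reads, index,
                            max_mismatch_frac=params["max_mismatch_frac"])
            )
            n_out += write_placements_tsv(
                placed, out / (path.stem + ".placements.tsv")
            )
        return n_in, n_out

    def _stage_callsnps(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("callsnps")
        reference = seqio.read_fasta(self.outdir / "polish" / "polished.fa")
        index = build_index(reference, k=self.config["align"]["k"])
        regime = get_regime(params["regime"])
        lengths = {tid: len(seq) for tid, seq in reference.items()}
        n_in = n_out = 0
        for path in sorted((self.outdir / "trim").glob("*.fastq")):
            acc = path.stem
            reads = list(seqio.parse_fastq(path))
            placed = list(
                align_reads(
                    reads, index,
                    max_mismatch_frac=self.config["align"]["max_mismatch_frac"],
                )
            )
            pile = make_pileup(placed, reference)
            calls = call_snps(pile, reference, regime)
            n_in += len(reads)
            n_out += len(calls)
            write_calls_vcf(calls, out / f"{acc}.vcf", sample=acc,
                            contig_lengths=lengths)
        return n_in, n_out

    def _stage_snpset(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("snpset")
        reference = seqio.read_fasta(self.outdir / "polish" / "polished.fa")
        index = build_index(reference, k=self.config["align"]["k"])
        regime = get_regime(self.config["callsnps"]["regime"])
        callsets = {}
        pileups = {}
        for path in sorted((self.outdir / "trim").glob("*.fastq")):
            acc = path.stem
            reads = list(seqio.parse_fastq(path))
            placed = list(
                align_reads(
                    reads, index,
                    max_mismatch_frac=self.config["align"]["max_mismatch_frac"],
                )
            )
            pile = make_pileup(placed, reference)
            pileups[acc] = pile
            callsets[acc] = call_snps(pile, reference, regime)
        matrix = build_genotype_matrix(callsets, pileups, reference)
        filtered = filter_covered_set(
            matrix, params["coverage_quantile"], params["min_reads"]
        )
        matrix.to_tsv(out / "genotypes_all.tsv")
        filtered.to_tsv(out / "genotypes.tsv")
        write_matrix_vcf(filtered, out / "genotypes.vcf")
        return matrix.n_loci, filtered.n_loci

    def _stage_structure(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("structure")
        matrix = GenotypeMatrix.from_tsv(self.outdir / "snpset" / "genotypes.tsv")
        ks = list(range(params["k_min"], params["k_max"] + 1))
        runsets = run_structure(
            matrix,
            ks,
            n_runs=params["n_runs"],
            n_sweeps=params["n_sweeps"],
            burnin=params["burnin"],
            alpha=params["alpha"],
            seed=stage_seed(self.seed, "structure"),
        )
        for K, rs in runsets.items():
            for i, run in enumerate(rs.runs):
                pd.DataFrame(
                    run.memberships,
                    index=run.accessions,
                    columns=[f"Q{j + 1}" for j in range(K)],
                ).to_csv(out / f"q_K{K}_run{i}.tsv", sep="\t")
        best_k = params.get("assign_k")
        if len(ks) >= 3:
            evanno = evanno_delta_k(runsets)
            evanno.to_csv(out / "evanno.tsv", sep="\t")
            if best_k is None:
                best_k = int(evanno["delta_k"].idxmax())
        if best_k is None:
            best_k = ks[-1]
        consensus = align_runs(runsets[best_k].runs)
        pd.DataFrame(
            consensus.memberships,
            index=consensus.accessions,
            columns=[f"Q{j + 1}" for j in range(best_k)],
        ).to_csv(out / "consensus.tsv", sep="\t")
        assignment = assign_lineages(consensus, params["q_threshold"])
        pd.DataFrame(
            [
                {"accession": acc,
                 "lineage": "" if lin is None else f"cluster{lin + 1}"}
                for acc, lin in assignment.labels.items()
            ]
        ).to_csv(out / "assignment.tsv", sep="\t", index=False)
        return matrix.n_loci, len(assignment.labels)

    def _read_assignment(self) -> dict[str, str | None]:
        table = pd.read_csv(
            self.outdir / "structure" / "assignment.tsv", sep="\t",
            keep_default_na=False,
        )
        return {
            str(row.accession): (row.lineage or None)
            for row in table.itertuples()
        }

    def _stage_fst(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("fst")
        matrix = GenotypeMatrix.from_tsv(self.outdir / "snpset" / "genotypes.tsv")
        table = fst_weir_cockerham(matrix, self._read_assignment())
        table.to_csv(out / "fst.tsv", sep="\t", index=False)
        return matrix.n_loci, len(table)

    def _stage_tree(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("tree")
        matrix = GenotypeMatrix.from_tsv(self.outdir / "snpset" / "genotypes.tsv")
        tree = bootstrap_support(
            matrix,
            n_replicates=params["n_bootstrap"],
            seed=stage_seed(self.seed, "tree"),
            deduplicate=params.get("deduplicate", True),
        )
        (out / "nj_k2p.nwk").write_text(tree_to_newick(tree) + "\n")
        with open(out / "tree_meta.txt", "w") as handle:
            handle.write(
                "method: neighbor joining on Kimura 2-parameter distances\n"
                "note: replaces maximum-likelihood topology search; the "
                "substitution model (K2P) follows the source protocol\n"
            )
        return matrix.n_loci, 1

    def _stage_pheno(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("pheno")
        pheno = pd.read_csv(self.outdir / "simulate" / "phenotypes.csv")
        trait = params["trait"]
        sub = pheno[pheno["trait"] == trait]
        # wide accession-x-season means for the dendrogram
        wide = sub.pivot_table(
            index="accession", columns="season", values="value"
        )
        dend = flowering_dendrogram(wide)
        (out / "flowering_dendrogram.nwk").write_text(dend.to_newick() + "\n")
        dend.merge_table().to_csv(out / "flowering_merges.tsv", sep="\t",
                                  index=False)
        # PCA over per-(accession, season) trait matrix
        trait_matrix = pheno.pivot_table(
            index=["accession", "season"], columns="trait", values="value"
        )
        if trait_matrix.shape[1] >= 2:
            scaled = scale_uv(trait_matrix)
            completed = bpca_impute(
                scaled,
                n_components=min(params["n_components"],
                                 trait_matrix.shape[1] - 1),
                n_steps=params["bpca_steps"],
            )
            result = pca(completed)
            result.scores.to_csv(out / "pca_scores.csv")
            result.loadings.to_csv(out / "pca_loadings.csv")
            pd.Series(result.contributions, name="contribution_pct").to_csv(
                out / "pca_contributions.csv"
            )
        summary = fit_glmm(
            sub,
            chains=params["chains"],
            iterations=params["iterations"],
            burnin=params["burnin"],
            seed=stage_seed(self.seed, "pheno"),
        )
        summary.table.to_csv(out / f"glmm_{trait}.csv")
        return len(pheno), len(summary.table)

    def _stage_climate(self, params: dict) -> tuple[int, int]:
        out = self._stage_dir("climate")
        geo = pd.read_csv(self.outdir / "simulate" / "geoclimate.csv")
        seasonal = seasonal_means(geo)
        seasonal.to_csv(out / "seasonal.csv", index=False)
        result = climate_pca(seasonal)
        result.loadings.to_csv(out / "climate_pca_loadings.csv")
        pd.Series(result.contributions, name="contribution_pct").to_csv(
            out / "climate_pca_contributions.csv"
        )
        pheno = pd.read_csv(self.outdir / "simulate" / "phenotypes.csv")
        trait_means = (
            pheno[pheno["trait"] == params["trait"]]
            .groupby("accession")["value"]
            .mean()
        )
        merged = seasonal.merge(
            trait_means.rename(params["trait"]),
            left_on="accession",
            right_index=True,
        )
        clines = cline_table(merged, params["predictors"], [params["trait"]])
        clines.to_csv(out / "clines.tsv", sep="\t", index=False)
        return len(geo), len(clines)


def run_pipeline(config: dict, outdir, seed: int = 0) -> RunReport:
    """Validate the config and execute all enabled stages."""
    return Pipeline(config, outdir, seed=seed).run()
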