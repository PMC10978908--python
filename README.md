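# umbpipe

A reusable, tested pipeline for studying lineage differentiation and
flowering-time clines in selfing plant panels genotyped by 3'-tag RNA-seq.
It covers, end to end on synthetic data with known ground truth:

- **synthdata** — lineage-structured transcriptome, 3'-biased read,
  phenotype (lineage × season mixed-model), and latitude-structured climate
  simulators, all with recorded truth and byte-level reproducibility.
- **seqio** — FASTA/FASTQ (Phred+33) I/O and sliding-window quality
  trimming with the two preset regimes (`4:20/75` and `4:30/100`).
- **align** — k-mer seeded, ungapped read placement on transcript
  references (multi-mapping reads discarded) and per-position pileups.
- **snpcall** — homozygous SNP calling under two threshold regimes
  (*polish*: ≥10×, alt ≥95%; *population*: ≥5×, alt >80%), iterative
  reference polishing to a SNP-count plateau (default cap 16 iterations),
  haploid genotype matrices, and the 100/95/90%-coverage SNP sets.
  Minimal VCFv4.2 export/import.
- **popgen** — Gibbs-sampled admixture model (independent allele
  frequencies, Dirichlet memberships), ln P(X|K) and Evanno ΔK model
  selection, CLUMPP-style run alignment, the Q>0.8 lineage rule,
  Weir–Cockerham F_ST for haploid-coded data, Kimura 2-parameter
  distances, and neighbor-joining trees with locus-resampling bootstrap.
- **phenostats** — unit-variance scaling, EM probabilistic-PCA imputation
  of missing values, PCA with contributions, Ward clustering of trait
  loadings, a conjugate Gibbs sampler for the lineage × season Bayesian
  mixed model with split-chain Rhat, and the per-season flowering
  dendrogram.
- **geoclimate** — winter (Nov–Feb) / summer (Mar–Jun) climate means,
  normalized climate+elevation PCA, and OLS/Pearson cline tests
  (WorldClim 2.1 monthly column convention: `{temp,prec,srad,vapr,wind}_{01..12}`).
- **pipeline / CLI** — a single-config orchestrator with per-stage seeds,
  hash-based caching, and a bundled 12-accession / 3-lineage /
  200-transcript smoke fixture.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py` (the desk-scale acceptance
criteria; the full run takes a few minutes, dominated by the
90-accession structure-recovery and GLMM-calibration checks).
One test, `test_c6b_k2p_transversions_closed_form`, is intentionally red:
it asserts a quoted target value whose arithmetic contradicts the Kimura
formula (see the comment in the test).

## CLI

```sh
umbpipe config > pipeline.yaml          # dump the default config
umbpipe run --config pipeline.yaml --out out/ --seed 1
umbpipe fixture --out fixture/ --seed 1 # bundled smoke-test dataset

umbpipe trim in.fastq out.fastq --window 4 --qual 20 --minlen 75
umbpipe polish --ref init.fa --reads reads.fastq --out polish/ --max-iter 16
umbpipe callsnps --ref polished.fa --reads reads.fastq --out calls.vcf --regime population
umbpipe snpset --matrix genotypes.tsv --out covered.tsv --coverage 1.0 --min-reads 3
umbpipe structure --matrix covered.tsv --out structure/ --k-min 1 --k-max 5 --runs 10
umbpipe fst --matrix covered.tsv --assignment structure/assignment.tsv --out fst.tsv
umbpipe tree --matrix covered.tsv --out tree.nwk --bootstrap 1000
umbpipe pheno pca --table phenotypes.csv --out pheno/ --npcs 4 --bpca-steps 100
umbpipe pheno glmm --table phenotypes.csv --trait days_to_flowering --out glmm.csv
umbpipe climate pca --table geoclimate.csv --out climate/
umbpipe climate cline --table seasonal.csv --x lat --y days_to_flowering
```

All artifacts are plain text (FASTA/FASTQ/VCF/TSV/CSV/Newick/JSON), so
every stage is independently inspectable and testable.

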