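# seldrift

Statistical tests for negative selection at a small candidate SNP set,
built for sparsely genotyped, unlinked markers across three cohorts.

Two complementary tests are provided, each comparing the candidate set
against an exhaustive empirical null of all possible 3-SNP subsets drawn
from the filtered background panel:

1. **Pairwise MAF-change test** (`test-m1`) — for two cohorts, the per-SNP
   change in minor-allele frequency (minor allele fixed by a reference
   cohort), averaged over a 3-SNP set, optionally variance-adjusted by a
   Welch-type t statistic; significance is the proportion of all C(n, 3)
   subsets with a statistic at least as small as the candidate set's.
2. **Beta-binomial drift-model test** (`test-m2`) — cohort allele counts
   are modelled as binomial draws from beta-distributed population
   frequencies around a shared ancestral frequency (variance scaled by a
   per-cohort drift parameter, uniform prior on the ancestral frequency
   integrated numerically). Drift is estimated by grid maximum
   likelihood across all retained SNPs; each SNP then gets a conditional
   tail probability Pr(X_target <= x | other cohorts, drift), and the
   candidate mean is ranked against all 3-SNP subset means (strict <).

The package also implements the two SNP-filtering cascades the tests
require (call rate, monomorphic, LD r² pruning — removal for the pairwise
test, per-cohort masking for the drift model) and a synthetic-data module
that generates three-cohort panels under the same generative model, with
deterministic fixtures that reproduce exact per-stage filter counts.

## CLI

```bash
# simulate three cohort panels (TSV + VCF mirrors)
seldrift simulate --config sim.yaml --out-dir panels/

# filtering cascades
seldrift filter pairwise --a gam.tsv --b eur.tsv --call-rate 0.9 --r2 0.8
seldrift filter threeway --g gam.tsv --c eur.tsv --m mkk.tsv

# Method 1 (cohort B defines minor alleles)
seldrift test-m1 --a gam.tsv --b eur.tsv --candidates rs1,rs2,rs3 --adjusted

# Method 2 (target cohort in the tail position)
seldrift test-m2 --g gam.tsv --c eur.tsv --m mkk.tsv \
    --candidates rs1,rs2,rs3 --target G

# full five-comparison pipeline (3 pairwise + 2 drift-model runs)
seldrift run-all --config run.yaml --out-dir out/
```

Genotype panels are TSV (`snp_id chrom pos allele_a allele_b <ind>…`,
dosages `0|1|2|NA` counting allele_b) or plain bi-allelic GT-only VCF 4.2.
A `run-all` config needs either `panels: {G: …, C: …, M: …}` plus
`candidates: [… 3 ids …]`, or `scenario: paper_like` with a `seed`.

## Layout

- `src/seldrift/cohort.py` — panels, minor-allele assignment, MAF/variance
  statistics, pairwise dosage r²
- `src/seldrift/io.py` — TSV and VCF readers/writers
- `src/seldrift/filtering.py` — pairwise and three-way cascades
- `src/seldrift/method1.py` — MAF-change statistics + exhaustive subset null
- `src/seldrift/method2.py` — beta-binomial model, grid MLE, tail test
- `src/seldrift/simulate.py` — generative simulator + filter fixtures
- `src/seldrift/pipeline.py`, `cli.py` — orchestration and CLI
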