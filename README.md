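# driftkit

Statistical toolkit for population-genetic analysis of low-coverage,
pseudohaploid genotype panels: consistent f-statistic estimation under
missing data, ancestry-stream rank tests and mixture-proportion fitting,
excess-relatedness residuals with a geographic decay-curve fit, allele-
mismatch kin detection, and runs-of-homozygosity based inference of recent
effective population size — plus a synthetic-data generator with known
truth for every stage.

## Modules

| module | what it does |
| --- | --- |
| `driftkit.io_formats` | EIGENSTRAT geno/snp/ind I/O, genetic-map interpolation (PLINK `.map` / HapMap dialects), pseudohaploid calling and Phred-scaled genotype likelihoods from read counts |
| `driftkit.synthdata` | Admixture-graph frequency simulation (Balding–Nichols drift), read-level coverage/contamination models, geographic cline scenarios with calibrated excess shared drift, ROH-length and decay-point generators, truth records |
| `driftkit.fstats` | Block-jackknifed f2/f3/f4 with finite-sample bias corrections, `allsnps`-style per-statistic SNP sets, and a consistent f2-basis solved by weighted least squares over f-statistic identities |
| `driftkit.structure` | f4-matrix rank tests (tail and taildiff P values), mixture-proportion GLS fits, the independent-mixture outgroup-f3 residual model ("excess relatedness"), allele-mismatch kin ratios |
| `driftkit.spatial_decay` | Haversine distances (with the 0.001 km dummy offset) and the inverse-variance-weighted fit of `y = 1/(mx + a) + b` with decay scale `(e−1)·a/m` |
| `driftkit.roh_ne` | Two-state HMM ROH caller on genotype likelihoods, block merge/filter rules, and maximum-likelihood recent Ne from ROH length spectra with profile-likelihood CIs (upper limit may be unbounded) |

## CLI

```sh
driftkit fstat --prefix data --stat f4 --pops A,B,C,D --mode allsnps
driftkit qpfstats --prefix data --pops A,B,C,D --out basis.json
driftkit rank --prefix data --left S1,S2,S3 --right OUT,R2,R3,R4,R5
driftkit mixfit --prefix data --target T1 --sources S1,S2,S3 --right OUT,R2,R3,R4,R5
driftkit residuals --prefix data --outgroup OUT --alphas alphas.json --out scores.tsv
driftkit decay --points scores_with_distance.tsv --drop-same-site
driftkit roh --counts counts.tsv --af 0.4 --out blocks.tsv
driftkit ne --blocks blocks.tsv --window 4,inf
driftkit simulate cline --config scenario.json --seed 1 --out synth
driftkit pseudohaploid --counts counts.tsv --seed 1 --out calls
driftkit likelihoods --counts counts.tsv --eps 0.01 --out pl.tsv
```

Genotype data are EIGENSTRAT prefixes (`<prefix>.geno/.snp/.ind`); read
counts are long-format TSV (`snp_id ind_id n_allele1 n_allele2`).

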