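# imphazard

Masking experiments that quantify how reference-panel bias corrupts
haplotype-copying genotype imputation at disease-associated loci.

The package simulates case–control cohorts in which risk alleles ride
haplotypes that are enriched in cases relative to a phased reference panel,
then masks the associated SNPs and re-infers them with a Li–Stephens-style
copying HMM anchored on the remaining scaffold SNPs. It measures what the
original study design measures: concordance between observed and imputed
genotypes, allele-resolved error counts, per-site info scores, monomorphic
call sets, and associations that turn false-negative after imputation —
under three masking designs (simultaneous masking at low and high scaffold
density, and leave-one-out).

## Modules

| module | what it does |
| --- | --- |
| `imphazard.core` | shared types: `SiteInfo`, `HaplotypePanel`, `CohortStudy` |
| `imphazard.synthetic_data` | founder-resampling simulator with group-specific haplotype frequencies, flip noise and single crossovers; three-region emulation preset (118/59/20 sites, 92 cases / 93 controls, 1000 reference haplotypes) |
| `imphazard.io_formats` | VCF 4.2 + sample-group sidecar, hap/legend reference panels, TSV report tables |
| `imphazard.qc_association` | MAF / control-HWE filters, allelic chi-square with risk-oriented odds ratios, LD r², observed-vs-imputed error tallies |
| `imphazard.phasing` | EM haplotype-frequency phasing for small regions with MAP-diplotype posteriors and the 0.9-posterior exclusion filter |
| `imphazard.imputation_engine` | haploid copying HMM (forward–backward, exact duplicate-state collapse), genotype calling at a posterior threshold, info scores |
| `imphazard.masking_experiments` | masking-plan construction and the mask → phase → impute → call → evaluate loop |
| `imphazard.haplotype_compare` | haplotype frequency tables (cases / controls / pooled / reference) and mono- vs polyphyletic risk-lineage classification |
| `imphazard.pipeline_cli` | end-to-end orchestration plus the `hazard` CLI |

## CLI

```sh
hazard run-all --preset paper --seed 1 --out results/run1
hazard run-all --preset null  --seed 1 --out results/null1
hazard simulate --preset paper --seed 1 --out data/
hazard qc   --vcf data/regionC.vcf --groups data/regionC.groups.tsv --out data/
hazard plan --vcf data/regionC.vcf --groups data/regionC.groups.tsv \
            --experiment leave_one_out --out plans.json
hazard impute --vcf data/regionC.vcf --groups data/regionC.groups.tsv \
              --hap data/regionC.reference.hap --legend data/regionC.reference.legend \
              --experiment simultaneous_high --out results/
hazard haplotypes --vcf data/regionC.vcf --groups data/regionC.groups.tsv \
                  --hap data/regionC.reference.hap --legend data/regionC.reference.legend
```

`run-all` writes, per region and experiment, a per-site report TSV
(observed/imputed chi-square, info score, MAFs, risk-allele error counts,
monomorphic and false-negative flags), a haplotype frequency table, a run
summary, and a `manifest.json` with sha256 hashes. Every output carries a
header comment with the package version, seed, and config hash; identical
configs and seeds reproduce outputs byte for byte. A YAML config can replace
the flags (`hazard run-all --config run.yaml`).

The low-density design automatically skips regions too short to reach the
density target, and `--reference self` swaps in the pooled study's own
phased haplotypes as the reference panel.

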