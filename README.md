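# hhmap

Homozygosity-haplotype (HH) scanning of multiplex-family genotypes and
rare-variant prioritization inside the shared regions it finds.

The pipeline has two stages:

1. **HH scan.** Genotypes are reduced to homozygous-only haplotypes.
   Regions of conserved homozygosity between individuals are bounded by
   discordant homozygous markers (dhSNPs: AA vs BB) or chromosome ends.
   Per family, chromosome windows are scanned for the region shared by the
   largest set of affected individuals; sharing is compared between the
   patient and control pools with a pooled one-sided two-proportion z-test,
   and regions passing a -log10(p) threshold (default 1.2; region length
   cutoff default 7 cM) are kept. Each kept region gets a seeded Monte-Carlo
   estimate of the probability that genotyping error alone creates a dhSNP
   inside it (reliable when < 0.001).
2. **Variant prioritization.** Annotated exome variants inside the
   significant regions are filtered: synonymous and "benign" variants are
   excluded; both population MAFs (1000 Genomes, gnomAD) must be unknown or
   < 0.001. Carrier counts over affected/unaffected sequenced members are
   reported, plus an upset-style summary of genes shared between families.

A synthetic-cohort generator (gene dropping over a three-generation
pedigree, Haldane crossovers on a cM map, an implanted founder segment
co-segregating with affection, genotyping error/missingness, and an
annotated variant table with a causal rare variant) makes every stage
testable without external data. Machine-readable copies of the study's
three summary tables ship with the package.

## CLI

```sh
hhmap simulate --seed 1 --out-dir sim/            # PED/MAP + variants.csv + truth.json
hhmap scan --ped sim/cohort.ped --map sim/cohort.map --out scan.tsv
hhmap reliability --ped sim/cohort.ped --map sim/cohort.map \
    --region chr1:45090406-54910095 --samples G1_1,G2_1 --epsilon 0.001
hhmap filter-variants --variants sim/variants.csv --ped sim/cohort.ped \
    --map sim/cohort.map --family SIM1 --region chr1:45090406-54910095 --out vars.tsv
hhmap overlap --gene-sets sets.json --out overlap.tsv
hhmap report --config run.yaml                     # full two-stage pipeline
hhmap fixtures                                     # packaged-table summary
```

`hhmap report` reads a YAML file with the fields of
`hhmap.pipeline.RunConfig` (paths or a nested `simulation:` block, cutoff,
window, threshold, epsilon, reliability replicates, seed, family list) and
writes `scan_report.tsv`, `significant_regions.tsv`, `reliability.tsv`,
`variant_report.tsv`, `gene_overlap.tsv`, and a timestamped `run.log`.
Exit code 2 flags input/format errors. Reports are byte-deterministic for a
given config and seed.

## Input formats

- **PED/MAP** (PLINK classic text): MAP columns chrom / id / cM / bp; PED
  six metadata columns then two allele codes per marker (`0` = missing).
- **Variant CSV**: named columns `chrom, start, end, ref, alt, function,
  gene, maf_1000g, maf_gnomad, pathogenicity` plus one carrier column per
  sample (`carrier` / `non_carrier` / `missing`, or `1` / `0` / `.`).
- **VCF** (minimal 4.2 subset, GT only): any alt allele in GT means carrier.

Coordinates are 1-based closed intervals; genome builds are carried as
opaque tags and never converted.

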