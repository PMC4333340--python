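# finecross

Forward simulation of experimental rodent crosses and fine-mapping of an
incompletely dominant, incompletely penetrant causal locus, plus the
categorical statistics and variant/PCR diagnostics used alongside such a
mapping study.

The package provides:

- **genome_model** — marker maps (physical Mb, derived genetic cM via a
  configurable linear rate, default 0.5 cM/Mb), genotype/phenotype tables
  with strain-role-based codes (`C`/`H`/`N`/`-`), the Haldane map function,
  validation and TSV interchange.
- **cross_sim** — seeded forward simulation of F2 intercrosses, backcrosses
  and marker-assisted congenic breeding programs. Meiosis follows the
  Haldane (no-interference) model with per-interval recombination draws;
  the causal position rides along as a pseudo-locus. Phenotypes are drawn
  from a penetrance model (defaults: 13.4% in carrier homozygotes, half
  that in heterozygotes, 0 in non-carriers; anomaly classes URA/URH/HUN
  mixed 0.678/0.188/0.134; URA right-sided with probability 0.84).
- **fine_mapping** — exclusion mapping for dominant carrier alleles (a
  phenotype-positive animal homozygous non-carrier at a marker excludes
  that marker) and inclusion mapping for recessive alleles, with a
  configurable phenocopy tolerance and outer-bound candidate intervals.
- **progeny_testing** — donor-segment inference at marker resolution with
  breakpoint-uncertainty gaps, recombinant classification, and
  conservative/minimal intersection of phenotype-conferring segments.
- **incidence_stats** — exact binomial incidence with Clopper-Pearson CIs,
  two-sided Fisher exact tests (minimum-likelihood rule), and exact
  binomial laterality-bias tests (Fisher-style variant behind a flag).
- **variant_screen** — strain-unique variant filtering across multi-strain
  call sets (within-strain discordance surfaced, never dropped), VCF
  ingestion via cyvcf2, and PCR amplicon-size prediction/inversion for
  empty-site / solitary-LTR / full-ERV insertion alleles.
- **cli / pipeline / fixtures** — a unified CLI, an end-to-end seeded
  pipeline with a machine-readable manifest, and programmatic builders for
  all worked-example fixtures.

## Command line

Everything is available under the `finecross` group and as standalone
scripts (`simulate-cross`, `map-exclusion`, `progeny-test`, `congenic-sim`,
`stats`, `variant-screen`, `amplicon`, `make-fixtures`):

```sh
# simulate an F2 intercross on the built-in chromosome-14 marker map
simulate-cross --design f2 --n 5000 --seed 1 --out-prefix out/f2

# exclusion-map the affected animals
map-exclusion --genotypes out/f2.genotypes.tsv --phenotypes out/f2.phenotypes.tsv \
  --tolerance 0 --mode dominant --out-prefix out/excl

# progeny-test refinement of a prior region
progeny-test --genotypes recombinants.tsv --progeny progeny_counts.tsv \
  --region 14:34.25-36.25

# statistics
stats incidence --affected 351 --n 4994
stats fisher --table 49,189,35,263
stats side-bias --right 200 --n 238

# variant screen and insertion-allele diagnostics
variant-screen --vcf calls.vcf --samples samples.tsv \
  --interval 14:34730000-35110000 --carrier ACI --contrast BN,COP,F344
amplicon --pair AB --allele irish

# write all worked-example fixtures as plain-text files
make-fixtures --out-dir fixtures/

# full seeded pipeline: simulate -> map -> progeny-test -> stats
finecross pipeline --seed 1 --n 2000 --out-prefix out/run
```

File formats: marker map TSV (`marker chrom pos_mb [pos_cm]`), genotype TSV
(rows = animals, cells in `C`/`H`/`N`/`-`), phenotype TSV
(`animal anomaly side`), VCF v4.x plus a `sample strain sequence_id`
mapping TSV for the variant screen.

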