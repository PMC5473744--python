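# strainvar

Probabilistic haplotype-based genotype and diplotype imputation for
multiparental recombinant inbred strain panels (such as the Collaborative
Cross), with on-demand F1 cross simulation and uncertainty-preserving
functional-consequence annotation.

Given founder sequencing calls (VCF), sparse marker diplotype
probabilities (the output of an upstream haplotype-reconstruction HMM),
exon annotations (BED/GFF3), and per-allele consequence terms (VEP-style
CSQ or a side TSV), `strainvar`:

- interpolates each strain's unphased founder-pair (diplotype)
  distribution from the two flanking markers onto every variant position;
- derives the strain's unphased genotype distribution by marginalizing
  over phasing, founder genotype uncertainty (including residual founder
  heterozygosity), and independent allele transmission;
- stores pruned distributions in one embedded SQLite database per
  chromosome, indexed by (variant, strain);
- answers genotype / diplotype / genotype-cross / diplotype-cross queries
  with max-only, probability-threshold, zygosity, and consequence
  restrictions, emitting the 12-column query schema;
- simulates F1 offspring distributions for any two stored strains on
  demand; and
- computes residual-heterozygosity, reference-identity, and
  consequence-spectrum summaries.

A fully ground-truthed synthetic data generator (`strainvar.synthetic`)
emits mutually consistent founder VCF + marker CSV + exon BED +
consequence TSV sets so that every stage is testable without downloads.

## CLI

```sh
# generate a synthetic input set (seed recorded in every file header)
strainvar simulate --out data/ --seed 1 --strains 20 --variants 500

# build the per-chromosome store (variant ids are deterministic)
strainvar build --vcf data/founders.vcf --markers data/markers.csv \
    --exons data/exons.bed --consequences data/consequences.tsv \
    --out store/ --prune 0.001 --interpolation proximal

# query genotypes in a window, diplotypes, or simulated F1 crosses
strainvar query genotype --store store/ --strains CC001,CC002 \
    --region 1:1-2000000 --zygosity het --out het.csv
strainvar query diplotype --store store/ --strains CC001 \
    --region 1:1-2000000 --max-only --out dip.csv
strainvar cross genotype --store store/ --strains CC001,CC002 \
    --region 1:1-2000000 --consequence stop_gained --out cross.csv

# summaries
strainvar stats het --store store/
strainvar stats refid --store store/
strainvar stats spectrum --store store/
```

A `key=value` config file passed as `strainvar --config FILE ...`
supplies defaults for any long option.

Interpolation weighting: the default `proximal` mode weights each flanking
marker by the distance to the opposite marker, so a variant coinciding
with a marker takes that marker's distribution exactly; `as-printed`
applies each distance to its own marker instead. Distribution entries
below the prune threshold (default 0.001) are dropped without
renormalization, so stored distributions may sum to slightly less than 1.

## Layout

- `src/strainvar/core.py` — domain types, unordered-pair canonicalization,
  distribution primitives.
- `src/strainvar/imputation.py` — marker interpolation, phasing,
  transmission, genotype imputation, pruning.
- `src/strainvar/cross.py` — F1 genotype/diplotype simulation and
  per-consequence transmission probabilities.
- `src/strainvar/annotation.py` — row expansion per (gene, transcript)
  with per-allele consequence lookup and `is_max` flags.
- `src/strainvar/io.py` — VCF/BED/GFF3/CSV/TSV readers, build filter,
  query CSV writers.
- `src/strainvar/query.py` — store build, the four query types,
  restrictions, summary statistics.
- `src/strainvar/synthetic.py` — ground-truthed input generator.
- `tests/` — unit, property, and acceptance tests (`tests/_oracles.py`
  holds the independent enumeration and sampling oracles).
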