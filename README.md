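# canopygwas

Haplotype-based GWAS of time-course canopy traits derived from remote-sensing
rasters, for a MAGIC-style (8-founder) rice population — with a full synthetic
data generator so every stage is testable without field data.

The pipeline has four analysis stages plus I/O plumbing:

| module | what it does |
| --- | --- |
| `canopygwas.simdata` | MAGIC founder-label mosaic simulator, time-course/endpoint trait simulator with planted QTL architecture, and an orthomosaic + DSM scene renderer |
| `canopygwas.imaging` | per-plot canopy height (DSM difference vs a pre-transplant baseline), vegetation fraction (Otsu threshold on CIELAB a\*), and leaf colour (mean −a\* over plant pixels) |
| `canopygwas.gwas` | per-SNP tie-corrected Kruskal–Wallis scan over founder-haplotype classes; two-year SNP selection (p < 1e-2 in both years and p₁·p₂ < 1e-5); 2-Mb merging of selected SNPs into QTL calls with per-timepoint detection flags and stage labels |
| `canopygwas.effects` | haplotype-effect profiles (class n / mean / ratio to population mean, n ≥ 4 rule), quadratic phenology fits, cross-trait effect correlations, hierarchical QTL clustering (1 − r, average linkage), allele-class tests and top-vs-bottom contrasts |
| `canopygwas.pipeline` | single-config orchestration with config-hash stamped, resumable plain-text intermediates |
| `canopygwas.io_formats` | validated TSV/CSV/TIFF/PNG/Newick readers and writers |

## CLI

Everything is reachable from one entry point:

```bash
# full pipeline from a YAML config
canopygwas run --config config.yaml --outdir out/ [--seed 7]

# individual stages
canopygwas simdata --seed 5 --outdir sim/
canopygwas imaging --rgb scene_rgb.png --dsm scene_dsm.tif \
    --baseline-dsm scene_baseline_dsm.tif --layout scene_layout.tsv --out plots.csv
canopygwas gwas scan --traits traits.csv --haplotypes hap.tsv --panel panel.tsv \
    --year 2019 --dat 83 --out scan_2019_83.tsv
canopygwas gwas call --scan-pair scan_2019_83.tsv scan_2018_83.tsv \
    --panel panel.tsv --out qtls.tsv
canopygwas effects profile --traits traits.csv --haplotypes hap.tsv \
    --qtls qtls.tsv --out profiles.csv
canopygwas effects cluster --profiles profiles.csv --out tree.nwk
```

A minimal config:

```yaml
seed: 7
n_lines: 165
n_snps: 1000
n_chromosomes: 5
chrom_length_bp: 8000000
recombination_rate_per_bp: 3.0e-7
noise_sd: 5.0
qtls:
  - chromosome: 1
    position_bp: 4000000
    effects_cm: {RU: 10.0}            # constant across stages
  - chromosome: 2
    position_bp: 4000000
    effects_cm: {TC: 10.0}
    stages: [heading]                 # stage-specific
  - chromosome: 3
    position_bp: 4000000
    effects_cm: {AK: -8.0, RU: 8.0}
    pleiotropy: {PW: -0.4, SLW: 0.4}  # biomass-allocation trade-off
imaging:
  enabled: false                      # true: render scenes and re-extract traits
```

Conventions: genomic positions are 1-based base pairs; plot rectangles are
0-based half-open pixel coordinates; founder codes AK, BE, TC, MI, SU, TK,
HO, RU map to labels 1–8; timepoints are days after transplanting (DAT) on
two yearly grids paired as 40↔39, 56↔54, 69↔68, 83↔83, 97↔97, 111↔113 with
stage windows tillering / heading / maturation (two pairs each).

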