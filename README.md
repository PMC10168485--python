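# presbyscan

Reusable pipeline for genetic analysis of adult-onset hearing loss from
audiometric and exome-style data:

* **Audiogram phenotype classification** — each ear's pure-tone thresholds are
  decomposed into canonical *metabolic* and *sensory* hearing-loss components
  by non-negative least squares; an ordered rule set assigns participants to
  OlderNormal / Metabolic / Sensory / Unclassified / Unselected categories.
* **Multi-caller variant consensus + QC** — per-caller genotype calls (GATK /
  BCFtools / Freebayes schema) are merged by majority vote and filtered by a
  tranche-aware combination rule, an exact one-sided heterozygote-excess test,
  a cohort-AF anomaly rule (AF > MAF + 0.4), and a high-impact & MAF < 0.1
  filter, with mitochondrial VAF-based genotype handling.
* **Gene variant-load outlier regression** — per-gene allele loads per
  phenotype group, OLS of one group on another, outliers beyond
  Q3 + 6·(Q3−Q1) / Q1 − 6·(Q3−Q1) of the residuals, hypergeometric gene-set
  enrichment, and list combination/intersection.
* **Threshold-difference scan** — per-variant carrier groups (het / hom_alt ×
  all / male / female) are screened for ≥ 20 dB mean threshold differences
  with frequency-banded SD caps (≥ 2 passing frequencies per ear), then
  permutation-tested (20,000 sex-preserving shuffles; > 1,000 similar results
  ⇒ rejected), with direction labelling and second-cohort replication.
* **Synthetic cohort generator** — audiograms composed of scaled canonical
  profiles plus Gaussian noise, binomial genotypes with configurable
  per-caller disagreement, planted carrier threshold shifts, and full ground
  truth, so every stage is testable without restricted data.

## CLI

```bash
presbyscan simulate --n-participants 200 --n-variants 100 --seed 1 --out cohort/
presbyscan classify --audiograms cohort/audiograms.csv --metadata cohort/metadata.csv \
    --out classification.csv --summary-out summary.csv
presbyscan qc --variants cohort/variants.tsv --out consensus.tsv
presbyscan outliers --variants cohort/variants.tsv --classification classification.csv \
    --predictor OlderNormal --response Metabolic --out outliers.csv
presbyscan threshscan --variants cohort/variants.tsv --audiograms cohort/audiograms.csv \
    --metadata cohort/metadata.csv --seed 1 --out scan.tsv
presbyscan report --classification classification.csv --metadata cohort/metadata.csv \
    --out table1.csv
presbyscan run-all --config run.yaml
```

`run-all` takes a single YAML config (stage toggles, simulation parameters,
file paths, scan criteria, seed) and writes every stage output plus a
`report.json` with per-filter counts; outputs are stamped with run id, seed
and config hash, and deterministic stages reproduce byte-identical files.

## File formats

* **Audiogram CSV** — `participant_id, ear{L|R}, thr_<freq_kHz>...` (dB HL).
* **Metadata CSV** — `participant_id, sex{M|F}, age, noise_history{0|1}`.
* **Variant TSV** (long multi-caller dialect) — `variant_id, chrom, pos, ref,
  alt, gene, impact, maf, tranche, caller, passed_filter, sample, gt` with
  VCF-style genotypes (`0/0`, `0/1`, `1/1`, `./.`); one row per
  variant × caller × sample.
* **Truth JSON** (synthetic fixtures) — planted category per participant,
  planted `(m, s)` per ear, planted effect-variant ids, seed.
* **Profile basis YAML** — `grid`, `metabolic`, `sensory` lists. The shipped
  default shapes are normalised placeholders (metabolic: gently sloping,
  half-maximal at the lowest frequency; sensory: flat through 1 kHz then
  steeply rising); substitute empirically derived shapes via `--basis`.
* **Gene sets** — one symbol per line.

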