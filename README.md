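# oxhmc

Quantification and comparative analysis of 5-hydroxymethylcytosine (5hmC)
from paired bisulfite (BS) / oxidative-bisulfite (oxBS) methylation-array
beta matrices.

The per-sample 5hmC proxy is the difference of betas, delta-beta =
beta(BS) − beta(oxBS). Technical noise produces a negative delta-beta tail
at 5hmC-free probes; the pipeline estimates an empirical detection
threshold from that tail, calls per-tissue "detectable" 5hmC, and layers
comparative analyses on top.

## Components

| module | role |
|---|---|
| `oxhmc.core_io` | beta/detection-p matrices, sample sheet, probe annotation, gene models, BS/oxBS pairing, BED export |
| `oxhmc.qc` | detection-p filtering, SNP/cross-reactive masking, BS-kit concordance, rs-probe genotype concordance |
| `oxhmc.hmc_calling` | delta-beta, negative-tail threshold, detectable calls, level/variability/tissue-difference rankings |
| `oxhmc.enrichment` | Fisher's-exact feature enrichment (CGI context, gene features, TFBS/DHS, alternative-transcription events) |
| `oxhmc.tissue_comparison` | cross-tissue correlation, discovery/validation concordance, BS-difference decomposition into 5mC/5hmC parts |
| `oxhmc.pathway_enrichment` | logistic-regression gene-set tests controlling for probes-per-gene, with redundancy grouping |
| `oxhmc.metagene_profile` | sliding-window profiles over a normalized gene axis (5 kb flanks + body) |
| `oxhmc.synthetic_data` | fully in-silico datasets with known per-probe truth for every stage |
| `oxhmc.cli_pipeline` | `oxhmc` command-line interface |

## CLI

Each stage reads/writes plain TSV/JSON in a run directory and records a
manifest with parameter values and output checksums, so stages can be
re-run individually.

```sh
# end-to-end on synthetic data
oxhmc all --outdir run --seed 1

# or stage by stage
oxhmc simulate --outdir run --seed 1
oxhmc qc --betas run/betas.tsv --detp run/detp.tsv --annotation run/annotation.tsv --outdir run
oxhmc call --workdir run
oxhmc enrich --workdir run --annotation run/annotation.tsv
oxhmc compare --workdir run
oxhmc pathways --workdir run --annotation run/annotation.tsv --gmt run/pathways.gmt
oxhmc metagene --workdir run --annotation run/annotation.tsv --genes run/genes.tsv
oxhmc export-bed --workdir run --annotation run/annotation.tsv
```

A YAML config (`--config`) can override thresholds, ranking sizes, pathway
size bounds, metagene windowing, and the `simulate:` block (probe count,
donors per cohort, noise SD, injected effects).

## Conventions

- Betas and detection p-values live in [0, 1]; missing values propagate
  through delta-beta and are excluded pairwise from means.
- Annotation coordinates are 1-based (array-manifest convention); BED
  output is 0-based half-open.
- Threshold quantiles use linear interpolation at `q * (n - 1)`;
  "detectable" is a strict inequality against the threshold.
- Enrichment uses the inclusive background (the foreground is counted
  inside the background), cross-product odds ratios, Woolf logit 95% CIs,
  and two-sided Fisher exact p-values.
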