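# ppredit

Detection, filtering and recognition-code analysis of C-to-U RNA editing
events from strand-specific per-site base counts, plus quantification of the
companion binding/editing assays and a synthetic-data generator that makes
the whole pipeline exercisable at desk scale with known ground truth.

## What it does

- **editing_detection** — reads per-site stranded base-count TSVs, orients
  them to the transcript strand (C→T forward / G→A reverse), computes editing
  fractions and a per-site RNA-vs-DNA confidence score (2×2 G statistic), and
  emits candidate events.
- **filter_cascade** — applies, in order: a minimum RNA−DNA editing-fraction
  difference (1%) with a DNA-error bound (1% of the RNA fraction), a depth
  filter at the 1% lower quantile, a score filter at the 95th/98th percentile
  (chosen by the site's editing rate vs 10%), and subtraction of events found
  in negative-control samples. Writes VCF v4.2, BED6 and a per-filter audit.
- **ppr_code** — models a PPR factor (ordered P/L/S…E1/E2/DYW motifs with
  5th/last specificity residues), scores cis-elements position-by-position
  with a (residue pair × nucleotide) table, and scans genomes for predicted
  targets.
- **motif_logo** — editing-extent-weighted position frequency matrices over
  the −15..+1 window, information content, consensus calls.
- **assay_quant** — Sanger-trace editing extents, REMSA fraction bound, and
  Kd estimation by bounded least squares on the 1:1 binding isotherm.
- **reporting** — cross-sample extent/significance matrices, multiplicity
  histograms, per-sample off-target counts, efficiency-vs-off-target and
  score-vs-extent regressions. A packaged fixture provides a full published
  comparison table for exact desk-scale checks.
- **synthetic_data** — genomes, planted target/off-target cis-elements with
  controlled code deviations, negative-binomial depths, binomially edited
  read counts, strand-symmetric errors, and noisy titrations — all seeded.

## CLI

```sh
ppredit simulate --seed 1 --genome-length 2000 --out sim/
ppredit detect  --genome sim/genome.fasta --rna sim/counts_rna1.tsv \
                --dna sim/counts_dna.tsv --control sim/counts_neg1.tsv \
                --out detect/
ppredit report  --genome sim/genome.fasta --rna sim/counts_rna1.tsv \
                --dna sim/counts_dna.tsv --factor sim/factor.tsv \
                --scoring-table sim/scoring_table.tsv --out report/
ppredit scan    --genome sim/genome.fasta --min-total 5 --out scan.tsv
ppredit pprscore --genome sim/genome.fasta --site synth:1234:+
ppredit fit-kd  --titration titration.tsv
ppredit logo    --genome sim/genome.fasta --events detect/rna1.events.vcf --out logo/
```

Configuration can also be supplied as YAML (`--config`); flags override file
values, and every subcommand writes a `manifest.json` echoing its effective
configuration.

### Count-table schema

```
chrom  pos  ref  fA fC fG fT  rA rC rG rT  sample
```

1-based positions; `f*`/`r*` are base counts from forward/reverse-oriented
reads, both expressed as genome-forward base identities.

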