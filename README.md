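# cfimmune

Quantification of immune-cell-type-specific cell-free DNA (cfDNA) from
targeted bisulfite amplicon sequencing, plus the surrounding analysis
toolchain:

- **`cfimmune.atlas`** — discovery of cell-type-specific hypomethylated CpG
  markers from a reference methylation atlas (beta matrix over tissues and
  sorted cells): target beta < 0.3, > 90% of other columns above 0.8,
  ≥ 6 CpGs within a centered 150 bp window, top-10 ranking by beta
  separation.
- **`cfimmune.panel`** — amplicon panel model (marker loci, CpG offsets,
  strict / allow-one-exception unmethylated-call rules) and
  bisulfite-converted reference derivation; ships a 16-marker /
  7-cell-type fixture panel with synthetic stand-in sequences.
- **`cfimmune.readcall`** — read interpretation: assignment to markers by
  ungapped identity against converted references (≥ 80%, both
  orientations, CpG positions wildcarded), quality filtering, CG/TG CpG
  calling, non-CpG-cytosine conversion QC, and per-marker
  fully-unmethylated-molecule fractions.
- **`cfimmune.quantify`** — per-cell-type fractions, calibration divisors
  (neutrophil default 0.69), and conversion to genome equivalents per ml
  (× cfDNA ng/ml × 303).
- **`cfimmune.spikein`** — leukocyte-into-background dilution designs,
  linear recovery fits, and calibration-coefficient derivation.
- **`cfimmune.cohort`** — longitudinal statistics: intra-individual CV and
  balanced inter-individual CV (exhaustive six-donor subset enumeration),
  baseline fold change, HI-titer responder classification (cutoff 40),
  ROC/AUC, rank-based group tests, cfDNA/count ratios.
- **`cfimmune.simulate`** — synthetic atlases with planted markers,
  bisulfite amplicon reads from cell-type mixtures (conversion failure +
  sequencing error), and cohort scenarios (healthy, vaccination, EoE,
  lymphoma) driven by a turnover model (cell number / lifespan).

## CLI

Everything is reachable through the `cfimmune` entry point:

```bash
# simulate an atlas and discover markers
cfimmune sim atlas --n-cpgs 1000 --seed 0 --out atlas.tsv
cfimmune discover --atlas atlas.tsv --targets neutrophil,b_cell --out markers.tsv

# simulate reads, call them, quantify
cfimmune sim reads --mixture "neutrophil=0.5,background=0.5" --depth 2000 \
    --seed 0 --out sample.fastq
cfimmune call --fastq sample.fastq --out counts.tsv
cfimmune quantify --counts counts.tsv --sample-id s1 --cfdna-conc 1.2 \
    --out quant.tsv

# cohort statistics
cfimmune sim cohort --scenario vaccination --out long.csv --titers-out titers.csv
cfimmune cv --table long.csv --analyte b_cell --source cfDNA
cfimmune foldchange --table long.csv --out fc.csv
cfimmune responders --titers titers.csv --out responders.csv
```

`cfimmune <subcommand> --help` lists all flags; filter thresholds
(identity 80%, mean Phred 30, conversion 0.95) and marker-selection
criteria are all overridable.

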