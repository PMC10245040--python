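# svjunction

Detection and quantification of circulating tumor DNA (ctDNA) via
structural-variant (SV) breakpoint junctions. The package covers the full
tumor-informed workflow:

- **`sv_panel`** — select high-confidence patient-specific SVs from somatic
  caller output (score, chromosome, repeat/gap, recurrence, span and
  copy-number-step filters) and build synthetic junction reference
  sequences (150 bp of flank on each side of the breakpoint).
- **`amplicon`** — classify multiplex-PCR read pairs against a
  patient-specific amplicon panel with fuzzy primer and amplicon matching
  (unit-cost Levenshtein; ≤ 2 edits per primer, ≤ 5 per amplicon, ≥ 25 bp
  product, both reads must resolve to the same amplicon) and tabulate
  per-(SV, well) counts for the digital assay.
- **`junction`** — count junction-supporting reads in alignments:
  soft-clip screening (≥ 10 clipped bases), two-flank fuzzy matching with
  a 2.5 %-of-read-length edit budget for WGS modes, perfect ±20 bp window
  counting for hybrid capture, and UMI-based molecule deduplication.
- **`quantify`** — control-thresholded detection calls (strict
  `count > 2 × max control`), linear and Poisson-corrected allele-fraction
  estimators, theoretical limit of detection `1/(copies × SVs)`,
  assay-design inversions, log10–log10 dilution regressions, and
  cross-assay correlation.
- **`fragments`** — in-silico cfDNA fragment size selection (90–150 bp,
  inclusive) and size histograms.
- **`simdata`** — seeded generators for every input: toy genomes with
  planted SVs (all four breakpoint orientations plus filter decoys),
  amplicon read pairs with PCR/sequencing errors, the seven-level tumor
  dilution design, soft-clipped WGS alignments with UMIs, and fragment-size
  mixtures — each with a machine-readable truth record per read.

## CLI

All functionality is exposed through the `svjunction` entry point:

```sh
# panel building
svjunction panel filter calls.vcf --cn-segments cn.bed --mask mask.bed \
    --pooled-calls cohort.tsv -o report.tsv
svjunction panel junctions calls.tsv genome.fa -o junctions.fa

# multiplex PCR
svjunction amplicon match R1.fastq R2.fastq --panel panel.tsv -o counts.tsv

# WGS / hybrid capture
svjunction wgs junctions aln.sam --junctions junctions.fa -o sv_counts.tsv
svjunction capture count capture.sam --junctions junctions.fa -o counts.tsv

# quantification
svjunction quantify multiplex counts.tsv --n-svs 47 --max-control-reads 5
svjunction quantify lod --copies 4500 --n-svs 47
svjunction quantify design --af 0.0000024 --copies 4500
svjunction quantify dilution-fit points.tsv

# fragment size selection and simulation
svjunction sizeselect in.sam out.sam --lo 90 --hi 150
svjunction simulate genome --seed 7 --out-prefix toy
svjunction simulate dilution --n-svs 47 --expectation -o points.tsv
```

Junction FASTA records carry the junction point as a `center=<int>` header
tag. SV calls are accepted as VCF 4.x breakend (BND) records with mate
pairs or as a TSV with explicit breakpoint columns.

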