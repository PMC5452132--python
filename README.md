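# chloredit

Quantification of chloroplast C→U RNA editing from short-read libraries and
allele-specific qPCR, with a fully seeded synthetic-data generator so the
whole pipeline runs and is testable offline.

The package implements five analysis stages plus an orchestrator:

- **synthetic_data** — seeded generation of reference sequences
  (chloroplast genome with embedded CDSs, tRNAs, nuclear/mitochondrial
  decoys), editing-site tables with planted per-condition fractions, FASTQ
  read libraries with truth tables, and qPCR plates whose Ct values encode
  edited/unedited template ratios.
- **align_filter** — forward-strand, ungapped, ≤2-mismatch read matching
  and the three-round subtractive filter: chloroplast+CDS+tRNA at 0
  mismatches (`cp_m0`), nuclear/mito subtraction, then chloroplast+CDS at
  ≤2 mismatches (`cp_m2`); retained reads are realigned onto CDS
  coordinates and written as SAM.
- **edit_call** — per-site, per-library pileups of edited (T) / unedited
  (C) / other bases; a one-sided binomial detection test against a
  sequencing-error rate (coverage ≥ 5, p ≤ 1e-2); editing fractions; a
  control-vs-salt t-test; and the per-site report with a total-coverage
  selection rule (≥ 4 reads).
- **expression** — gene × library count table, median-of-ratios size
  factors, and a per-gene t-test on log2 normalized counts with
  Benjamini–Hochberg adjustment.
- **qpcr** — Ct calling (log-interpolated threshold crossing),
  window-of-linearity amplification-efficiency estimation with iterative
  baseline refinement, strict efficiency filtering (> 1.75), edited
  fractions from allele-specific Ct pairs (`Q_T/(Q_T+Q_C)`,
  `Q = E^-Ct`), treatment comparison, and allele-specific primer design.
- **pipeline** — `run_all` executes every stage from one (YAML-able)
  config with derived per-stage seeds and writes a manifest; outputs are
  byte-identical for a fixed seed.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: worked
report-fraction examples, exact equivalence of the aligner with an
exhaustive Hamming-scan oracle, subtractive-round semantics against
simulation truth tables, exact binomial-tail agreement, planted-fraction
recovery through the full alignment+pileup path, qPCR efficiency/fraction
recovery, expression null calibration, and end-to-end determinism.

## CLI

```sh
chloredit run-all --outdir demo_run --seed 42          # synthetic end-to-end demo
chloredit simulate --outdir demo_run                   # inputs only
chloredit align --reads Cnt-1=reads.fastq --cp cp.fasta --cds cds.fasta \
    --trna trna.fasta --nuclear nuc.fasta --mito mito.fasta --max-mm 2
chloredit call-edits --sam Cnt-1=Cnt-1.cds.sam --sites sites.tsv --cds cds.fasta \
    --groups "control:Cnt-1,Cnt-2 salt:Salt-1,Salt-2"
chloredit expression --sam ... --cds cds.fasta --groups "control:... salt:..."
chloredit qpcr --plate plate.csv --map plate_map.csv --min-eff 1.75
```

All stages read/write plain-text formats: FASTA/FASTQ references and
reads, TSV site tables and reports, SAM alignments, CSV plate data.

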