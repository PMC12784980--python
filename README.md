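# hmmpeaks

Universal unsupervised peak caller for ChIP-seq and ATAC-seq built on a
constrained three-state hidden Markov model (zero / noise / signal states
with negative-binomial emissions). One pipeline handles narrow transcription
factor peaks, broad histone domains, mixed-length marks, and controlless
experiments — the only user-facing parameter that matters is the FDR.

## Pipeline

1. **Preprocessing** — duplicate read filtering, fragment-size estimation
   (strand cross-correlation for single-end, median insert for paired-end),
   tag shifting toward fragment centers, fixed-width binning (default
   200 bp), and optional beta control correction (beta chosen on a grid to
   minimize the correlation between corrected signal and control).
2. **Constrained model fitting** — a genome-wide three-state HMM fitted by
   Baum–Welch with method-of-moments initialization; after each iteration
   the parameters are projected into data-dependent boundaries (noise
   floor, minimal signal-to-noise ratio, signal mean within the data range,
   noise/signal swap guard). A posterior error probability (PEP) of "no
   signal" is computed per bin.
3. **Peak computation** — log-scale PEP threshold scan, pivotal points and
   saturation-based threshold selection, candidate grouping, block-wise
   local-Poisson scoring of the top-50% most confident bins, BH/Bonferroni
   adjustment, coverage-based boundary refinement, optional summit calling.
   Peaks are written in BED 6+3 format (chrom, start, end, name, score,
   strand, fold, −log10 p, −log10 q).

A built-in simulator (`hmmpeaks simulate`) generates synthetic tag tracks
with ground-truth peaks at a tunable quality (fraction of reads from
peaks), narrow/broad/mixed length regimes, minimum inter-peak spacing, and
matched uniform control tracks; it backs the entire test suite.

## Usage

```bash
# simulate a toy experiment
printf 'chrT\t10000000\n' > toy.chrom.sizes
hmmpeaks simulate --chrom-sizes toy.chrom.sizes --n-peaks 500 \
    --n-reads 1000000 --quality 0.5 --seed 1 --out-dir sim/

# call peaks (BAM/SAM/CRAM/BED/BED.gz/BigWig treatment, optional control)
hmmpeaks analyze -t sim/treatment.bed -c sim/control.bed \
    --chrom-sizes toy.chrom.sizes --fdr 0.05 -o peaks.bed

# ATAC-seq style: no control, no tag shifting, with summit calling
hmmpeaks analyze -t atac.bam --chrom-sizes hg38.chrom.sizes \
    --fragment 0 --summits -o atac_peaks.bed

# autocorrelation diagnostics (raw signal + PEP)
hmmpeaks diagnose -t sim/treatment.bed --chrom-sizes toy.chrom.sizes -o diag
```

`analyze` writes the peaks BED, a reloadable model dump
(`<output>.model.tsv`), a run manifest (`<output>.manifest.json`), and —
with `--summits` — a companion BED6 summit file.

## Tests and acceptance report

```bash
python -m pytest tests/          # full suite (~1–2 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes, from scratch on the built-in simulator:
the called-peak count at maximal quality versus 500 simulated truth peaks
(t1), the Jaccard index between peaks called with and without a matched
control (t2), and the number of constrained EM iterations to likelihood
saturation (t3).

## Layout

| module | role |
| --- | --- |
| `hmmpeaks.genome_io` | chrom.sizes / tag / BigWig input, BED 6+3 output |
| `hmmpeaks.preprocess` | dedup, fragment size, shift+bin, control correction |
| `hmmpeaks.hmm` | constrained three-state HMM, PEPs, model persistence |
| `hmmpeaks.peaks` | threshold selection, scoring, refinement, summits |
| `hmmpeaks.diagnostics` | raw / PEP autocorrelation profiles |
| `hmmpeaks.simulate` | ground-truth track simulator |
| `hmmpeaks.cli` | `analyze` / `simulate` / `diagnose` subcommands |
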