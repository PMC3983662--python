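# peakscape

Downstream analysis toolkit for multi-subunit ChIP-seq experiments:
coverage-track normalization, consensus peak construction across replicates
and subunits, permutation-based overlap enrichment, anchored signal/GC
profiles, binding–expression integration, PWM motif-context statistics and
chromatin-feature classification — exercised end-to-end on a bundled
synthetic-data generator, so the whole pipeline is testable without any
external download.

## Layout

| module | what it does |
|---|---|
| `peakscape.core` | genome model, interval/track/peak/annotation types, BED/GFF3/bedGraph/wiggle/FASTA I/O, interval algebra (intersect, merge, promoters/3′ regions) |
| `peakscape.simulate` | deterministic synthetic genome + sequence + annotations + per-subunit replicate coverage tracks + expression/DE tables + TF sets, with ground-truth files for parameter-recovery tests |
| `peakscape.signal` | median normalization, input subtraction, replicate averaging, background z-scoring, X/autosome split normalization, mutant/WT region ratios |
| `peakscape.consensus` | majority-replicate filtering, base-wise k-of-n subunit consensus, summit calling, valley-rule peak splitting (separation float) |
| `peakscape.enrichment` | length-preserving genome-wide shuffles, empirical two-sided p-values (floor 0.0002 at N=10,000), fold enrichment, TF/HOT overlap tables, count-vs-covered-length fits |
| `peakscape.profiles` | summit/TSS anchored matrices (median per 50 bp bin), expression-class metagene curves with 95% bands, 15 bp sliding-window GC profiles with random-coordinate controls |
| `peakscape.expression` | promoter signal, Spearman binding–expression correlation, bound-gene classification, DE × binding contingency tables |
| `peakscape.motifs` | PWM construction (counts / sequences / IUPAC consensus), two-strand log-odds scanning, motif-bound fraction, chromatin-context conditioning, clustering-effect fold |
| `peakscape.features` | window feature matrices, Pearson correlation + hierarchical leaf order, bound/unbound window labels, permutation feature importance (mean decrease in accuracy) |
| `peakscape.pipeline` / `peakscape.cli` | stage orchestration with a sha256 reproducibility manifest; `peakscape` console entry point |

## CLI

```bash
peakscape simulate --config sim.yaml --out data/ --seed 17
peakscape signal normalize --chromsizes g.sizes --track chip.bedgraph --out norm.bedgraph
peakscape signal subtract --chromsizes g.sizes --chip chip.bg --input input.bg --out enr.bg
peakscape peaks consensus --chromsizes g.sizes --k 2 a.bed b.bed c.bed --out cons.bed
peakscape peaks summits --chromsizes g.sizes --peaks cons.bed --track enr.bg --out summits.bed
peakscape peaks split --chromsizes g.sizes --peaks summits.bed --track enr.bg --separation 0.85 --out split.bed
peakscape enrich test --chromsizes g.sizes --peaks x.bed --annotation y.bed --n 10000 --seed 7 --out report.tsv
peakscape motifs scan --fasta genome.fa --consensus GCGCAGGGCG --out hits.bed
peakscape run --out results/run1 --seed 17          # full synthetic pipeline
```

`peakscape run` executes simulate → signal → peaks → enrich → profiles →
expression → motifs → features and writes `manifest.json` recording configs,
seeds, per-stage timings and a sha256 digest of every output; rerunning with
the same seed reproduces every file byte-identically. Configuration is a YAML
file with `simulation:` and `analysis:` sections mirroring
`SimulationConfig` / `AnalysisConfig` (all defaults are the published
parameter values: 10,000 permutations, ±200 bp summit windows, 1 kb
promoters, 0.85 separation float, 2-of-3 consensus, 250 bp/1 kb windows,
15 bp GC window, …). The default simulation genome is 6 × 200 kb; pass a
smaller config for quick experiments — track output is per-base.

## Conventions

* Coordinates are 0-based half-open internally; BED/bedGraph are native, GFF3
  and wiggle are converted at the I/O boundary.
* Overlap is strand-blind with a ≥1 bp default; strand is used only for
  promoters/3′ regions and TSS/TES anchors.
* Shuffle null: each interval keeps its length and is re-placed uniformly
  over the non-excluded genome (chromosome chosen ∝ placeable length);
  p = min(1, 2·(r+1)/(N+1)), two-sided, reported to 4 decimals.
* All stochastic code takes an explicit seed or `numpy.random.Generator`;
  fixed seed ⇒ byte-identical outputs.
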