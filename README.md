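# paleomito

Desk-scale toolkit for authenticating an ancient (museum/mummified) mitochondrial
genome and assigning it to a geographic mitochondrial clade. The package covers
the full analysis chain as reusable, tested components:

- **`paleomito.sim`** — synthetic ancient-DNA generator: multi-clade mitogenome
  panels with planted fixed differences, circular-genome reads with terminal
  C→T / G→A damage (geometric decay), sequencing error, exact PCR duplicates,
  and contaminant admixture — all with complete ground-truth tables.
- **`paleomito.readqc`** — quality trimming (LEADING / TRAILING /
  SLIDINGWINDOW / MINLEN / AVGQUAL, configurable order; defaults
  20/20/4:20/30/30).
- **`paleomito.mapping`** — seeded ungapped mapping to small circular
  references with origin-wrap handling, best-reference selection across a
  candidate set, unique-placement stringency filtering, coordinate-based
  deduplication, and pileup construction.
- **`paleomito.samio`** — minimal SAM import/export (pysam); imported gapped
  alignments feed the indel tracks of the damage profile.
- **`paleomito.damage`** — terminal misincorporation and indel frequency
  profiles over the first/last 25 read positions (conditional on the reference
  source base, read-orientation aware).
- **`paleomito.consensus`** — majority consensus with minimum-depth masking
  (depth < 2 → N, ties → N), depth/breadth statistics, the breadth-at-3× ≥ 80%
  retention gate, GC content.
- **`paleomito.diagnostics`** — clade-diagnostic site discovery (inter-clade
  fixed differences; sites fixed in a focal clade but divergent in a query
  consensus), per-site read agreement with median/IQR, diagnostic-site clade
  assignment, alignment region extraction and missing-data filtering.
- **`paleomito.network`** — haplotype collapsing, minimum-spanning networks
  (union of all MSTs), and median-joining networks with median-vector pruning.
- **`paleomito.pipeline` / `paleomito.cli`** — end-to-end orchestration with a
  flat config file, stable per-stage seed derivation, and a JSON report.

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and brute-force oracles
(exhaustive trimming scanner, per-column site scans, pileup recounts,
spanning-tree enumeration) plus `tests/test_acceptance.py`, which implements
the desk-scale acceptance criteria (planted-site round trips, binomial
damage/duplicate/contamination calibration, assignment recovery over 100
seeds, consensus fidelity, network properties).

## CLI

```sh
paleomito simulate --out simdir --n-fragments 2000 --d5 0.03 --seed 1
paleomito trim --in simdir/reads.fastq --out trimmed.fastq --window 4:20 --minlen 30 --avgqual 30
paleomito map --reads trimmed.fastq --refs simdir/references.fa --out mapped.sam --select-best
paleomito damage --sam mapped.sam --ref simdir/references.fa --n 25 --out damage.tsv
paleomito consensus --sam mapped.sam --ref simdir/references.fa --min-depth 2 --breadth3 0.8 --out cons.fa
paleomito diagnose --panel simdir/panel.fa --labels simdir/panel_labels.tsv \
    --query cons.fa --sam mapped.sam --focal-clade clade1 --out diagdir
paleomito assign --panel simdir/panel.fa --labels simdir/panel_labels.tsv --query cons.fa
paleomito network --alignment simdir/panel.fa --epsilon 0 --out netdir
paleomito run --config pipeline.cfg --out rundir        # full pipeline
```

`pipeline.cfg` is a flat `key = value` file; see
`paleomito.pipeline.PipelineConfig` for the available keys and defaults.

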