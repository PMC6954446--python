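# rnaxl

Calling RNA–protein crosslink sites and single-strandedness signals from
mutational profiles in virion RNA sequencing data, and relating the called
sites to RNA secondary structure.

The core idea: a treated sample (UV-crosslinked, or chemically probed) is
compared position-by-position against a matched untreated control from the
same RNA. The per-position **signal** is the fold change of the substitution
rate (U→C transitions for crosslinking; A/C any-mismatch for structure
probing), which cancels genuine minority variants present in both samples.
Calling applies a coverage mask (default ≥10k), a background filter at the
control's top-5% rate (nearest-rank percentile), replicate consensus
(positions passing in every replicate), and mean + k·σ outlier selection.
Strong single-strandedness signals can be exported as unpaired constraints
for an external thermodynamic folding engine (file interface: FASTA + CON
out, CT back in); site-level analyses quantify double-strand enrichment (1-df
χ²) and clustering (adjacent-site spacing against analytic and Monte-Carlo
random-uridine nulls).

A ground-truth read simulator makes every stage testable offline: it emits
FASTQ or pre-aligned SAM for paired test/control arms with configurable
per-site crosslink rates, both-arm minority variants, structure-dependent
probing rates and uniform sequencing error.

## Layout

| module | role |
|---|---|
| `rnaxl.preproc` | adapter/prefix trimming and quality filtering (FASTQ) |
| `rnaxl.pileup` | SAM/BAM → per-position base counts and rate profiles |
| `rnaxl.mutsignal` | fold-change signals, background filter, consensus, statistics |
| `rnaxl.structure` | constraint export (CON), CT/dot-bracket parsing, metrics, built-in max-pairing folder |
| `rnaxl.sites` | structural context, ds-enrichment χ², spacing statistics and nulls |
| `rnaxl.simdata` | synthetic genomes/reads with recorded truth |
| `rnaxl.cli` | `rnaxl` command-line interface and end-to-end runner |

## CLI

```sh
# end-to-end: simulate triplicate pairs, call sites, report
rnaxl run --config run.yaml --outdir out/

# stage by stage
rnaxl simulate --length 3000 --n-sites 20 --rate 0.02 --depth 20000 --outdir sim/
rnaxl preproc in.fastq out.fastq --adapter AGATCGGAAGAGC --min-len 40 --trim-prefix 6
rnaxl counts sim/rep1_test.sam sim/genome.fasta test_counts.tsv
rnaxl signal test_counts.tsv ctrl_counts.tsv sim/genome.fasta signal.tsv --min-cov 10000
rnaxl sites consensus.tsv genome.fasta --sigma 2
rnaxl constraints signal.tsv constraints.con --rule sigma:2   # or top:0.05
rnaxl structure-metrics --a unconstrained.ct --b constrained.ct
```

A minimal `run.yaml`:

```yaml
seed: 1
genome: {simulate: {length: 3000, seed: 1}}
simulate:
  n_replicates: 3
  depth: 20000
  crosslink: {n_sites: 20, rate: 0.02}
  base_error: 0.001
min_cov: 10000
top_frac: 0.05
sigma_levels: [1, 2]
toy_fold: false
```

Every number in the JSON run report is traceable to a TSV written alongside
it, and fixed seeds reproduce all outputs byte-for-byte.

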