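# snvscreen

Toolkit for saturation single-nucleotide variant screens of a coding
sequence: enumerate the full substitution space, simulate random-mutagenesis
libraries under ligand-dependent clonal selection, score per-variant
enrichment with FDR-controlled hit calling, and run the small statistics
used to validate individual hits.

## What it does

- **`snvscreen.variant_space`** — validate a CDS, enumerate all 3L possible
  single-nucleotide substitutions with nucleotide- and amino-acid-level
  identities and effect classes (synonymous / missense / nonsense /
  stop-altering), tabulate transition/transversion spectra, and compute
  observed-versus-theoretical coverage and the expected coding-variant load
  per mutagenized insert.
- **`snvscreen.simulate`** — synthetic screens with known ground truth:
  Poisson mutation load per insert with a configurable substitution
  spectrum, clone-level exponential selection with periodic passaging
  (deterministic or stochastic thinning), and per-locus multinomial
  sequencing sampling. Clones are tracked at the insert level, so in-cis
  passenger hitchhiking emerges naturally.
- **`snvscreen.counts_io`** — the TSV interchange dialects (per-variant
  count tables with locus totals, results tables, annotated-variant
  imports) and the YAML screen manifest. Readers reject invalid rows with
  row numbers; frequencies are always recomputed from counts.
- **`snvscreen.enrichment`** — variant frequency (reads / locus total),
  fold change versus the plasmid library (with pseudocount or strict
  zero-library policy), exact conditional 2x2 test per variant (normal
  approximation available), Benjamini-Hochberg q-values, hit calling at
  fold-change and q thresholds, replicate-screen overlap, and report
  tables for position-versus-fold-change scatter plots.
- **`snvscreen.assay_stats`** — doubling time from exponential growth,
  four-parameter log-logistic dose-response fits (`ll4` and log-IC50
  `ll2_4` parametrizations) with multistart optimization, Welch two-sample
  IC50 comparison, and Welch+BH families for growth comparisons.

## CLI

```sh
# enumerate the substitution space of a CDS
snvscreen enumerate cds.fasta --out space.tsv

# run a seeded synthetic screen (library + timepoint counts + ground truth)
snvscreen simulate -c scenario.yaml -o sim_dir --seed 1

# score timepoints against the library per the written manifest
snvscreen score -m sim_dir/manifest.yaml -o scored_dir

# fit dose-response curves and report IC50s
snvscreen doseresponse -i doses.tsv -o fits.tsv
```

Exit codes: 0 success, 1 validation error, 2 runtime error. Logs go to
stderr; outputs are files (TSV/JSON) only. `simulate` writes provenance
metadata (seed, config hash, version) and reruns are byte-identical.

A scenario config is a YAML mapping; all keys are optional:

```yaml
cds: {n_codons: 900}          # or cds_fasta: path/to/cds.fasta
n_inserts: 60000
mutagenesis: {mean: 2.59}
fitness: {baseline_rate: 0.3, n_activating: 10, delta_min: 0.75, delta_max: 1.0}
schedule: {duration_days: 8, sampling_days: [8], passage_trigger: 1.0e7, dilution_factor: 0.1}
sequencing: {depth: 100000, error_rate: 0.0}
mode: deterministic
```

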