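# File formats

All outputs are plain tab-separated text (or JSON for the run report).
Version: 1.0.

## Input: peptide list

Tabular (default): one peptide per line in one-letter amino-acid code,
optionally followed by a whitespace-separated label (no spaces inside the
label).  Blank lines and lines starting with `#` are ignored.  Case is
normalized to upper.

    AADIFYSRY HLA-A0101
    KSDPIVAQY HLA-A0101

FASTA is auto-detected by a leading `>`; record ids become labels.

## Clustering file (`clustering.<g>g.tsv`)

One row per input peptide, in input order.

| column   | meaning |
|----------|---------|
| group    | 1-based cluster number of the solution, or `Trash` |
| sequence | input peptide (uppercased) |
| core     | aligned core: motif columns uppercase, insertion gaps `-`, bulged (deleted) residues lowercase between motif columns; `-` for trash |
| offset   | 0-based start of the consumed window in the peptide; `-` for trash |
| indel    | `-`, `ins@P:L` (gap of length L at motif position P) or `del@P:L` (bulge of length L at within-core index P) |
| score    | log-odds score of the placed core in bits (4 decimals); `NA` for trash |
| label    | input label or `-` |

## Matrices (`matrices.<g>g/gibbs.<k>of<K>.{freq,pssm}.mat`)

`K` is the number of non-empty clusters in the solution, `k` the 1-based
cluster number.  Header row: the 20 residues in alphabetical one-letter
order.  One line per motif position, tab-separated, 6 decimals.  `freq`
holds pseudocount-corrected frequencies (rows sum to 1); `pssm` holds
log2(freq/background) in bits.

## KLD report (`kld.tsv`)

One row per scanned cluster count:

    g  kld_total  kld_per_cluster  cluster_sizes

`kld_per_cluster` and `cluster_sizes` are comma-separated lists over the
non-empty clusters of the best restart (the stacked blocks of the
barplot).  The final line is `suggested_g <g>`.  With `--plot`, a
companion `kld.png` renders the stacked bars.

## Run report (`report.json`)

Run id, the full resolved configuration, input/dropped peptide counts, the
best KLD per cluster count, the suggested count and the list of emitted
files (relative to the output directory).
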