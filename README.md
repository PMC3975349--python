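# pseaac

Fixed-length numeric descriptors for protein sequences: a fast, extensible
generator of the general-form pseudo-amino-acid composition (PseAAC) and
its relatives, built for converting whole FASTA databases into feature
matrices for machine-learning studies of protein structure and function.

Machine-learning models need every protein represented by a vector of the
same length, but sequences vary in length and their order matters. Chou's
pseudo-amino-acid composition solves this by augmenting the 20 amino-acid
frequencies f_u with λ sequence-order correlation factors τ_j and
renormalizing, so the vector keeps partial order information at fixed
dimension. The *general form* admits arbitrary feature sources — GO terms,
functional domains, PSSM profiles — as components of the same kind of
vector. This package implements 13 built-in modes plus a plugin mechanism
for user-defined ones:

| mode | features | description |
|---|---|---|
| `aac` / `dpc` / `tpc` | 20 / 400 / 8000 | amino-acid, di-peptide, tri-peptide composition |
| `pseaac1` | 20 + λ | Type I PseAAC: x_u = f_u / (Σf + wΣτ), τ_j = mean_i Θ(R_i, R_{i+j}) with Θ the mean squared difference of standardized properties |
| `pseaac2` | 20 + 2λ | Type II (amphiphilic) PseAAC: per-tier hydrophobicity/hydrophilicity product factors |
| `nmbroto` / `moran` / `geary` | properties × D | autocorrelation profiles of a physicochemical property over lags 1..D |
| `ctd` | 21 × groupings | composition-transition-distribution over 3-class partitions |
| `qso` | (20 + D) × matrices | quasi-sequence-order from squared amino-acid distances |
| `go` / `fdom` | universe size | binary annotation presence vectors |
| `psepssm` | 20 + 20ξ | pseudo-PSSM from PSI-BLAST profiles (column means + lagged squared differences) |

In every property-driven mode, any entry of a user-supplied AAindex1-style
property table can be selected (a 544-entry table gives > 20,000
descriptor values across the built-in modes at default parameters). All
execution is streaming: memory is independent of the number of sequences.

## Worked example

```sh
$ cat demo.fasta
>demo1 synthetic decapeptide
ACDEFGHIKL
$ pseaac run --mode pseaac1 --in demo.fasta --out demo.csv --param lam=2 --param w=0.05
mode=pseaac1 read=1 written=1 skipped=0 dim=22 elapsed=0.00s
```

`demo.csv` holds one row of 22 named features. The ten distinct residues
each occur once, so all 20 composition components are either 0 or

```
PAAC1_A      0.0802344808724
...
PAAC1_lam1   0.109603938665
PAAC1_lam2   0.088051252611
```

i.e. f_u = 1/10 shrunk by the common denominator 1 + w(τ_1 + τ_2); the two
tail components are the weighted lag-1 and lag-2 correlation factors
computed from the bundled hydrophobicity / hydrophilicity / side-chain-mass
triple. The components sum to exactly 1.

Other entry points:

```sh
$ pseaac modes                              # list the 13 built-in modes with dims
$ pseaac enumerate --property-count 544
57977 descriptor values across 13 built-in modes (544 properties)
$ pseaac run --mode qso --in db.fasta --out qso.tsv --format tsv
$ pseaac run --mode seqlen --in db.fasta --out len.csv --plugin my_mode.py
```

A plugin is a Python module exporting `MODE`, a
`pseaac.registry.ModeSpec` with a name, parameter schema, dimensionality
function and compute function; it then runs exactly like a built-in mode.
The library API mirrors the CLI (`pseaac.type1_pseaac`,
`pseaac.run_batch`, ...); see `docs/methods.md` for formulas, parameter
conventions and numerical choices.

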