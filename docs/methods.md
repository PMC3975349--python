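# Methods

This note records the exact formulas implemented, the parameter and
normalization conventions chosen where the literature admits more than
one dialect, and what the synthetic fixtures do and do not exercise.

## Sequence model and input handling

Sequences are strings over the 20 canonical amino acids in the internal
alphabetical order `ACDEFGHIKLMNPQRSTVWY`; formats that use the
historical `ARNDCQEGHILKMFPSTWYV` column order (AAindex1 flat files,
PSI-BLAST ASCII PSSMs) are re-mapped at parse time so a single internal
order holds everywhere. Non-canonical residues are governed by an
explicit policy, default `error`: silent corruption of descriptors is
worse than a hard stop. `map_to_nearest` applies the conventional
substitutions B→D, Z→E, U→C, O→K, J→L and still skips records containing
X, which carries no usable information. FASTA reading is streaming (one
record in memory at a time), which is what makes whole-database batch
conversion feasible.

## Property standardization

Every correlation-based family consumes properties standardized over the
20 amino acids: P'(a) = (P(a) − mean) / SD with the **population SD
(divisor 20)**. The sample-SD (divisor 19) dialect also circulates;
values produced by tools using it differ by a constant factor
√(20/19) per property. Constant properties are rejected as degenerate
rather than silently zeroed. The bundled 3-property table holds the
classic hydrophobicity, hydrophilicity and side-chain-mass triple;
arbitrary AAindex1 or TSV tables can replace or extend it, and entries
containing `NA` are dropped with an audit count.

## Descriptor families

**Composition** (`aac`, `dpc`, `tpc`): overlapping-window frequencies,
counts divided by the number of windows (L, L−1, L−2). Each family sums
to exactly 1, so vectors are length-independent.

**Type I PseAAC** (20 + λ): Θ(a,b) = (1/k) Σ_p (P'_p(b) − P'_p(a))²,
τ_j = (1/(L−j)) Σ_i Θ(R_i, R_{i+j}), x_u = f_u / (Σf + wΣτ),
x_{20+j} = wτ_j / (same). Θ ≥ 0 guarantees a positive denominator and a
non-negative vector summing to 1.

**Type II PseAAC** (20 + 2λ): per-tier product factors
τ_{2j−1} = (1/(L−j)) Σ_i H1'(R_i)H1'(R_{i+j}) and likewise τ_{2j} for
H2'; x = (f, wτ) / (1 + wΣτ). Products can be negative, so the
denominator is checked and a non-positive value is a hard error naming
the τ sum — shrinking w is the remedy. Type II standardizes H1/H2 with
the same divisor-20 convention as Type I.

**Autocorrelation**: normalized Moreau-Broto
AC(d) = (1/(L−d)) Σ P'_i P'_{i+d}; Moran
I(d) = [(1/(L−d)) Σ (P'_i−P̄)(P'_{i+d}−P̄)] / [(1/L) Σ (P'_i−P̄)²];
Geary C(d) = [(1/(2(L−d))) Σ (P'_i−P'_{i+d})²] / [(1/(L−1)) Σ (P'_i−P̄)²].
The variance denominators (L for Moran, L−1 for Geary) follow the
classical definitions of the two statistics; both forms exist in
descriptor code bases, so cross-tool comparisons should check this.
Zero-variance sequences return 0 with a logged warning instead of NaN,
keeping batch matrices finite while staying auditable.

**CTD**: each attribute partitions the alphabet into 3 classes;
composition and transition are percentages of residues / adjacent
crossing pairs, and distribution reports the positions (as percent of L)
of the first, 25%, 50%, 75% and 100% occurrences of each class, with
occurrence index ceil(q·n_k). Absent classes emit five zeros (not NaN).
The percent (×100) scale is used throughout; a [0,1] dialect also
circulates. The seven standard attribute groupings (hydrophobicity,
normalized van der Waals volume, polarity, polarizability, charge,
secondary structure, solvent accessibility) ship as a reviewed TSV.

**Quasi-sequence-order**: τ_d = Σ_i d(R_i, R_{i+d})² over a 20×20
distance matrix; vector (f, wτ) / (Σf + wΣτ). Two matrices are applied
by default, concatenated. The bundled Grantham matrix is *computed* from
Grantham's composition/polarity/volume formula (α = 1.833, β = 0.1018,
γ = 0.000399, mean-100 scaling, integer rounding); spot values match the
familiar published table (Leu-Ile 5, Trp-Cys 215, Asp-Glu 45). The
second matrix, `synthetic_schneider_wrede`, is a **synthetic stand-in**
for the Schneider-Wrede physicochemical distance — Euclidean distance
over the z-scored classic property triple, max-scaled to 1 — labelled as
such in its filename and loader; substitute the published matrix via
`--distance-matrix` for production feature sets. All QSO invariants
(non-negativity, sum-to-1, c² scaling) are matrix-agnostic.

**Annotation modes** (`go`, `fdom`): binary presence vectors over a
lexicographically sorted term universe, loaded from a TSV
`accession<TAB>term1;term2;...` with an optional explicit universe file.
Flat presence only — no propagation of GO annotations to ancestor terms,
and no term-frequency weighting; both are documented variants left out
deliberately. Unannotated proteins keep an all-zero row (warned, never
dropped) so matrix rows align with FASTA order. A compact binary cache
(`PSBEM1` header, bitset rows) accelerates reload of large universes;
annotation provenance and refresh are the user's responsibility — the
package performs no online lookups.

**Pseudo-PSSM** (`psepssm`): rows of a caller-supplied PSI-BLAST ASCII
PSSM are standardized (z-score over the 20 scores of the row, divisor
20; constant rows → zeros with a warning), then 20 column means and, per
lag g = 1..ξ, 20 mean squared column differences are emitted. Row
z-scoring is chosen over the 1/(1+e^−x) squashing dialect that also
appears in the literature because it is scale-free and keeps the
degenerate-row case explicit; note that with row-wise standardization
the lagged θ values are *not* invariant to adding a constant to a single
column of the raw matrix (they are under column-wise normalization
dialects). The package never runs PSI-BLAST.

## Defaults

| parameter | default | meaning |
|---|---|---|
| λ (`lam`) | 30 | correlation tiers, Type I/II; requires L > λ |
| w (Type I/II) | 0.05 | composition-vs-correlation weight |
| D (`max_lag`) | 30 | autocorrelation and QSO lag depth; requires L > D |
| w (QSO) | 0.1 | QSO weight |
| ξ (`xi`) | 10 | pseudo-PSSM lag depth; requires L > ξ |

These are the conventional values in the descriptor literature; all are
CLI-exposed. Sequences shorter than the requirement are rejected, not
padded — silent padding biases τ. Output floats are printed at 12
significant digits, which round-trips bit-stably.

## Synthetic fixtures

The generator draws residues i.i.d. uniform over the alphabet, property
values i.i.d. standard normal, Poisson-sized GO term sets, and PSSMs as
uniform integer scores with a bump on the query residue, all from
`numpy.random.default_rng(seed)` — byte-reproducible across runs. This
exercises descriptor arithmetic, dimensionality, streaming and
determinism. It does **not** emulate real-sequence structure:
non-uniform amino-acid usage, local hydrophobicity runs, domain
architecture, or realistic PSSM conservation patterns. Passing tests
therefore certify the computations and contracts, not biological signal
in the descriptors.

Test problem sizes: oracle equivalence runs on 100 fuzzed sequences of
length 35-120 per family against independently written loop evaluators
(agreement to 1e-12); the distributional Moran check uses 500 sequences;
the streaming check pushes 10,000 records through a correlation mode
with a bounded-write-lag assertion proving record-count-independent
memory.

## Known limitations

* Only 3-class CTD partitions; no reduced-alphabet or gapped-k-mer
  compositions; no cross-correlation between different properties.
* The second QSO matrix is a synthetic stand-in (above).
* Ambiguity handling is per-record; there is no partial-sequence rescue.
* Nucleotide sequences and profile formats other than PSI-BLAST ASCII
  PSSMs are out of scope.
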