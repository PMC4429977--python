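# coiprot

Conservation-of-information analysis of protein systems: does a corpus of
proteins, viewed purely as strings of discrete symbols, organize itself the
way an information-conservation principle predicts?

Each protein *i* is reduced to a dual (*tᵢ*, *aᵢ*): its length in residues
and its **unique amino acid count** — the number of distinct residue symbols
occurring at least once in the sequence, with every post-translationally
modified form (phosphoserine, O-GlcNAc serine, …) counting as a symbol of
its own. A system of *M* proteins conserves the total token count and the
total Hartley–Shannon information,

```
T = Σᵢ tᵢ,        I = Σᵢ tᵢ ln aᵢ ,
```

and the most likely partition of *T* under those constraints is a power law

```
tᵢ/T = aᵢ^(−β) / Q(β),     Q(β) = Σ a^(−β),
```

with the dual solution `aᵢ/A = tᵢ^(−1/β) / Σⱼ tⱼ^(−1/β)`, `A = Σᵢ aᵢ`.
This implies five testable global predictions: a power-law tail in the
unique-count distribution (P1); a constant average length for proteins of a
fixed unique count, i.e. per-species total length linear in protein count
(P2); a power-law tail in lengths (P3); a constant average unique count at
fixed length (P4); and scale independence under random subsetting (P5).

The package is for computational biologists who want to run this analysis
on a SwissProt-style flat file (ID/OC/FT/SQ records), or to study its
statistical behaviour on synthetic corpora with known ground truth. It
provides:

- `flatfile_io` — a parser/writer for the flat dialect (tab- or
  space-separated feature tables, wrapped descriptions) and the two-column
  per-protein PTM count table; single-site MOD_RES/LIPID/CARBOHYD/DISULFID
  features become PTM sites, one per position, first in file wins;
- `counting` — unique counts in three modes: raw letters, additive
  (`Y = X + P` from a PTM table) and direct recount (modified symbols
  re-tallied, exposing the cases where additivity fails);
- `coi_model` — the conserved totals, the equilibrium pmf and its dual, and
  the log–log CCDF tail regression (slope, stderr, adjusted R², F, df, p);
- `predictions` — tests P1–P5, adjusted-R² grids over conditioning windows,
  per-domain average lengths, and the PTM-abundance multi-proportion test;
- `bias_audit` — initiator-methionine repair, signal-peptide excision, and
  a seeded Monte-Carlo perturbation of the additive-count assumption, with
  a comparison table of tail fits across all variants;
- `synthetic_corpus` — a seeded generator of annotated flat-file corpora
  with per-protein ground truth;
- a `coiprot` command-line interface (`simulate` / `pairs` / `predict` /
  `audit`).

## Worked example

Generate a 20,000-protein synthetic corpus, extract the (t, a) table, and
run the prediction tests and the bias audit:

```bash
coiprot simulate --seed 42 -m 20000 --n-species 200 -o demo
coiprot pairs demo/corpus.dat -o demo/pairs.tsv
coiprot predict demo/pairs.tsv -o demo/reports
coiprot audit demo/corpus.dat --seed 42 -o demo/audit.tsv
```

The predict step logs one line per test:

```
INFO p1: slope=-20.1006 adj_r2=0.9994
INFO p2: slope=1006.6595 adj_r2=0.9995
INFO p3: slope=-1.5408 adj_r2=0.5963
INFO p4: slope=15.8894 adj_r2=0.9997
```

Reading these numbers: the corpus was generated with a unique-count tail
exponent β = 22.914 on a ∈ [20, 30], and the fitted CCDF tail slope is
−20.1 ± 0.2 (the cumulative slope of a steep pmf over a short window is
slightly shallower than the pmf exponent; the two are reported separately
and never conflated). P2's slope, 1006.7, is the common average protein
length — the generator draws lengths uniformly on [a, 2000], whose mean is
≈ 1006 — with adjusted R² = 0.9995 across 199 species. P4's slope, 15.9,
is the average unique count of proteins 100–500 residues long. P3 is *not*
linear on this corpus (adjusted R² = 0.60): a mixture of conditional
uniforms has no power-law length tail, so the corpus only supports P3 when
lengths are drawn from `sample_powerlaw_lengths`.

The audit table compares the P1 tail fit across bias-corrected variants:

```
Dataset      Slope     Std. error  Adj R2   F        DF  p
baseline     -20.1006  0.2049      0.99938  9624.9   5   2.09e-09
M-fixed      -20.1429  0.1958      0.99943  10580.7  5   1.65e-09
no-peptides  -20.0234  0.2346      0.99918  7282.8   5   4.19e-09
Monte Carlo  -20.1113  0.1996      0.99941  10280.5  5   1.91e-09
```

All four rows keep an emphatic linear tail, and the methionine fix and the
Monte-Carlo perturbation move the slope by well under one standard error.

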