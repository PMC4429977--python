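# Methods

## The model

A system of M proteins is described only by the duals (tᵢ, aᵢ): length in
residues and unique amino acid count. Two totals are treated as conserved —
the token count T = Σ tᵢ and the Hartley–Shannon information
I = Σ tᵢ ln aᵢ (natural log; the information content of one protein is the
log of the number of possible orderings of its alphabet over its length,
tᵢ ln aᵢ). Maximizing the likelihood of a partition of T under both
constraints gives the equilibrium distribution

    p(a) = tᵢ/T = a^(−β) / Q(β),   Q(β) = Σ_support a^(−β),

which has the dual form a/A = t^(−1/β)/Σ t^(−1/β), A = Σ aᵢ.
`verify_duality` checks the substitution numerically: it builds lengths
proportional to p(a), pushes them through the dual form and compares with
a/Σa; the residual is at rounding level (< 1e−10 asserted) for every β > 0
tested. Both pmfs are evaluated in log space so steep exponents
(β ≈ 23 over a support up to 37 spans ~35 decades) never underflow.

The derivation itself is taken as given; the package implements its
consequences and their empirical tests.

## Counting

The unique amino acid count is order- and multiplicity-invariant. The
alphabet is the 20 canonical letters plus U, O and the ambiguity codes
B, Z, X, each counting as one distinct symbol when present; whether
ambiguity codes should contribute is not settled, so the alphabet is a
parameter of `unique_count`. The empty sequence is an error, not (0, 0).

PTM-aware counting comes in two modes:

- **additive (eq6)** — Y = X + P with P looked up in a per-protein table.
  This is the default pipeline mode; it assumes every modification adds a
  fresh symbol.
- **recount** — each annotated single site is rewritten to the symbol
  (residue letter, normalized description) and distinct symbols are
  re-tallied. Normalization collapses whitespace, strips a trailing period
  and lowercases, so a wrapped "Phosphoserine." equals "phosphoserine"
  while phosphoserine and O-GlcNAc serine stay distinct. Y then falls
  short of X + P exactly when a modification consumes the sole occurrence
  of a letter or two sites carry the same modified symbol; the shortfall
  (X + P) − Y ≥ 0 is the *violation* audited by the Monte-Carlo.

Recount-mode Y never exceeds additive-mode Y, and equality holds iff the
violation is zero; this pair of modes is the basis of the ambiguity audit.

## Tail fitting

Empirical distributions are summarized as complementary cumulative counts
(number of items ≥ v; the ≥ convention matches upper-tail heavy-tail
plotting) and fitted by unweighted OLS of log₁₀(count) on log₁₀(x) with an
intercept over an inclusive window — [20, 30] for unique counts, [300,
10000] for lengths. The report carries slope, slope standard error,
adjusted R² = 1 − (1 − R²)(n−1)/(n−2), F = t², df = n − 2 and the two-sided
p — the exact layout of lm() output, so results are directly comparable
with analyses done in R. Zero-count points inside the window (the empty
top of a steep tail at finite M) are dropped with a warning; fewer than
three usable points is an error. The fitted cumulative slope is reported
as-is and never algebraically converted into the pmf exponent β: over a
finite window the two differ, and conflating them would bias comparisons.

A caution that shaped the tests: the OLS standard error of a slope fitted
to cumulative points is not a calibrated standard error, because
neighbouring CCDF points share most of their counts. For recovery checks
the package's tests therefore estimate the slope's sampling SD from
replicate corpora (a plain Monte-Carlo standard error) and compare the
fitted slope to the noiseless slope of the generating pmf's CCDF computed
over the same surviving x-points. The per-fit OLS stderr is still reported
— it is the conventional descriptive statistic — but it is not used as a
recovery tolerance.

## Prediction tests

- **P1/P3**: tail fit of the CCDF of a (resp. t).
- **P2/P4**: per-species aggregates (n_p, l_p, l_a) — protein count, total
  length, total unique count, with n_p ≤ l_a ≤ l_p by construction — are
  regressed (l_p or l_a on n_p, with intercept, one point per species,
  species equally weighted). The slope estimates the common average length
  (average unique count); linearity is the prediction. Windows on the
  conditioning variable are applied to proteins before aggregation;
  species left without qualifying proteins drop out.
- **R² grids**: the P2/P4 regression over every (low, high) window pair on
  a lattice — unit steps over 1–30 for unique counts, 50-residue steps
  over 50–2000 for lengths (the plotted granularity; both configurable).
  Cells with fewer than 3 contributing species are reported as absent
  (None), never as zero.
- **P5**: seeded uniform subsamples without replacement at a ladder of
  fractions, a tail fit per replicate, and slope dispersion per fraction.
  Sub-seeds are spawned from one SeedSequence, so replicates are
  bit-reproducible.
- **PTM abundance**: for each unique-count group (defaults 6, 7, 8 vs 14,
  15, 16) the proportion of proteins with ≥ 1 retained PTM site; equality
  of proportions is tested with the uncorrected Pearson chi-squared on the
  k × 2 table, df = k − 1 (at the corpus sizes involved a continuity
  correction would be negligible and the published statistic is plainly
  uncorrected). The implementation calls scipy's contingency test; the
  unit test checks it against the textbook formula written out by hand.
- **Domain averages**: the P2 regression restricted to one domain and to
  proteins up to 1000 residues; the slope is that domain's average length.

## Bias audits

1. **Initiator methionine.** If a sequence does not start with M, M is
   prepended — plain M for eukaryotes, archaea and viruses, N-formyl
   methionine for bacteria. fMet is treated as a distinct modified symbol
   (realized as M plus a MOD_RES annotation at position 1, visible to
   recount mode); the convention is configurable because desk-scale
   effects are insensitive to it. If M already occurs in the sequence the
   unique count is unchanged by construction. Idempotent.
2. **Signal peptides.** SIGNAL ranges (merged if overlapping) are excised;
   PTM sites inside an excised range are dropped and surviving sites are
   remapped to mature coordinates. PEPTIDE ranges are left in place by
   default, with a flag to excise them too for sensitivity. A record whose
   annotation would empty the sequence is kept intact with a warning.
3. **Additive-count Monte Carlo.** Per protein and replicate, a violation
   v is drawn from an empirical distribution (default: the curated-subset
   audit — 99.31% zero, 0.65% one, rapidly vanishing above; stored as raw
   counts and renormalized exactly) and Y is set to max(X, X + P − v), so
   Y never leaves [X, X + P].

`run_bias_suite` fits the P1 tail for baseline, M-fixed, no-peptides and
the Monte-Carlo replicates (reported as mean fit statistics, per-replicate
fits retained) in one table with columns Dataset / Slope / Std. error /
Adj R² / F / DF / p. Note what "negligible" means here: the M fix and the
Monte-Carlo perturbation move the slope by a small fraction of its
standard error, but excising signal peptides genuinely shifts a steep
tail's fitted slope — the robust finding is that the emphatic power-law
*linearity* (adjusted R², significance) survives all three corrections,
and the suite's tests assert exactly that.

## Synthetic corpus

The generator emulates the corpus structure the analysis assumes, with
defaults chosen as the study conditions:

- a-distribution: mixture of a bulk body (95%) and an equilibrium tail
  p(a) ∝ a^(−β), β = 22.914, over a ∈ [20, 30]. The bulk is a shifted
  beta-binomial (2 + BetaBinom(17, 8, 2)): unimodal with its peak a few
  counts below the tail onset and a long left shoulder, so small alphabets
  are rare but represented. The body shape is a modelling choice, not a
  claim about any particular database.
- lengths: t | a uniform on [a, 2000] — the equilibrium premise behind
  P2/P4. Consequently the marginal length distribution is *not* a power
  law; P3 studies use `sample_powerlaw_lengths` instead.
- species: 500 species with lognormal(σ = 1.5) size weights; each species
  belongs to one domain, drawn from (archaea 3.5%, bacteria 60.8%,
  eukaryota 32.7%, viruses 3.0%).
- annotations: a is decomposed as X raw letters (capped at the 20
  canonical) plus P single-site PTM feature lines with unique synthetic
  descriptions; sequence letters stay canonical, exactly as in real
  records, so counting must merge annotations rather than read special
  characters. Violations are drawn first from the configured distribution
  (defaulting to the audit distribution above) and force P ≥ v; a
  violating site is placed on a letter occurring exactly once, every other
  site on a letter with a surviving unmodified copy, so the ground-truth
  recount Y = X + P − v holds exactly by construction.
- biases: 1% of records lack the initiator M (61% of those still contain
  M elsewhere, matching the curated proportion); 3% carry an N-terminal
  SIGNAL range of 15–30 residues. M is otherwise always present and
  pinned to position 1, as for real initiator methionines.
- every record round-trips exactly through the flat-file writer/parser,
  and all generation is a pure function of (config, seed).

What the generator does **not** emulate: biological sequence content
(motifs, composition beyond optional background weighting), homology
between proteins, real lineage strings, or the empirical joint
distribution of PTM count and length (the PTM-vs-alphabet coupling is a
configurable linear trend). Passing tests therefore demonstrate that the
pipeline's statistics behave correctly under the model's assumptions —
they do not certify any statement about a real database, whose absolute
fitted values require the original snapshots.

## Problem sizes and numerical choices

Tests run the tail-recovery checks at M = 10⁵ sampled duals (12 replicate
corpora for the Monte-Carlo standard error), the P2/P4 linearity checks at
M = 10⁵ over 500 species, round-trip checks on 1,000 fully realized
records, and the bias suite on a 20,000-record annotated corpus; these
sizes keep every check well-populated while remaining desk-scale. Fit
windows default to the published ones ([20, 30] for unique counts,
[300, 10⁴] for lengths, [100, 500] for P4, 1000-residue cutoff for domain
averages). Ties and degenerate inputs follow fixed rules spelled out
above: first-in-file wins at a shared PTM position, zero-count CCDF points
are dropped with a warning, windows with < 3 points or regressions with
< 3 species are errors, and empty sequences are rejected everywhere.

## Known limitations

- The flat-file parser targets the classic line dialect (including the
  tab-separated variant); it does not read UniProt XML or the post-2019
  feature-table layout.
- The tail regression is the cumulative-plot OLS procedure it reproduces;
  it is not a maximum-likelihood discrete power-law estimator, and its
  stderr is descriptive, not a calibrated standard error (see above).
- Additive (eq6) counting can exceed the true post-modification alphabet;
  the size of that effect is exactly what the Monte-Carlo audit bounds.
- Absolute published statistics (tail slopes near −23, domain average
  lengths, the PTM-abundance chi-squared) depend on the original database
  snapshots and are out of scope; the package emits every report in the
  same schema so holders of those snapshots can compare directly.
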