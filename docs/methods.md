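# Methods

## The property space

A substitution's physicochemical score is a scaled Euclidean distance in a
7-dimensional space of AAindex property vectors. The packaged table uses:

| Accession  | Property                                   | Facet            |
|------------|--------------------------------------------|------------------|
| RADA880102 | transfer free energy, octanol → water      | hydrophobicity   |
| FAUJ880103 | normalized van der Waals volume            | steric bulk      |
| ZIMJ680104 | isoelectric point                          | electrostatics   |
| GRAR740102 | polarity                                   | polarity         |
| CRAJ730103 | normalized frequency of turn               | secondary struct.|
| DAWD720101 | residue size                               | steric bulk      |
| CHAM820102 | free energy of solution in water           | hydrophobicity   |

Distances are computed on the **raw** property values and divided by the
largest pairwise distance over the 190 unordered residue pairs (attained
by glycine–tryptophan, D_max ≈ 11.4604), so the most dissimilar pair
scores exactly 1 and self-substitutions exactly 0.

### Why raw values and this seventh entry

Neither the scaling scheme nor one of the seven accessions is uniquely
determined by the method's published description, so both were fixed by
calibration against the four benchmark substitutions with known scores
(W→S 0.80, G→V 0.56, I→V 0.14, R→Q 0.54 at 2-decimal display). An
exhaustive search over every complete AAindex entry as the seventh
property, crossed with per-property min–max, z-score, divide-by-max and
raw coordinate treatments and with global-max or √7 distance scaling,
leaves exactly one combination reproducing all four values: raw
coordinates, global-max scaling, and DAWD720101 (Dawson's residue size)
as the seventh entry. That combination is the default
(`scheme="raw-global-max"`).

Two consequences are worth stating plainly. First, with raw coordinates
the properties are implicitly weighted by their numeric ranges — polarity
(range 8.1) and isoelectric point (range 8.0) dominate, turn propensity
(range ~1) contributes little. Second, scores are **not** invariant to
affine rescaling of a property vector under the default scheme; users who
want range-free weighting can select `minmax-global-max` (each property
min–max rescaled to [0, 1] before distances, most dissimilar pair still
scores 1) or `minmax-sqrt7` (distance divided by the analytic ceiling √7,
so no pair reaches 1). Every scored report records the scheme in its
header. An alternative helix-propensity seventh entry (CRAJ730101) is
vendored and selectable via `--seventh` / `load_packaged_table()`.

`NormalizedPropertyTable.norm_values` always carries the per-property
min–max rescaled values (min 0, max 1 over the 20 residues) regardless of
scheme; a property constant across all residues is rejected, since it
cannot be rescaled and carries no discriminating information.

## The conservation score

MSAC at a site is C = r(1 − 0.95^N): N aligned sequences, r the fraction
carrying the residue of interest. 1 − 0.95^N is the probability that N
random sequences with equal residue frequencies (1/20) exhibit a given
residue at least once at a position, so C discounts conservation observed
in shallow alignments: at N = 1 a fully "conserved" site scores only
0.05, and C → r as N → ∞. C < 1 always, C = 0 iff r = 0, and C increases
strictly in both N (for r > 0) and r.

Decisions where the formula's inputs were underdetermined:

- **Which rows count.** By default N counts every alignment row and a gap
  at the scored column counts as a mismatch (`gap_policy="all-rows"`);
  `"ungapped-rows"` drops gapped rows from both N and the match count.
  The query itself is included among the N sequences.
- **Which residue is scored.** The reference residue of the substitution.
  If it disagrees with the query row at that site the result is flagged
  (`reference_mismatch`); strict mode raises instead.
- **Coordinates.** Substitution positions are 1-based on the ungapped
  query; alignment columns are 0-based internally, 1-based in output.

Homolog pre-filtering keeps hits with E-value ≤ 0.01 (inclusive, the
conventional search-tool reading) and then the single lowest-E-value hit
per species; ties keep the first by input order, and the output is sorted
by ascending E-value, so filtering is deterministic.

## The combined score

PASEC is the plain product S = P·C, kept at full precision inside
`ScoreRecord` and rounded (2 decimals, half-up) only at serialization.
The benchmark table's own arithmetic multiplies the *displayed* 2-decimal
factors (0.56 × 0.93 → 0.52, where the full-precision product 0.5254
would display as 0.53); the acceptance script follows that convention
when reproducing those four numbers, while pipeline output always derives
PASEC from full-precision factors.

One inconsistency in the benchmark data: the summary table pairs
conservation 0.93 with I199V and 0.85 with R200Q, while the accompanying
description assigns 0.85 to site 199 and 0.93 to site 200 — and only the
latter reproduces the stated combined scores (0.14×0.85 → 0.12,
0.54×0.93 → 0.50). The implementation and tests follow the assignment
that is arithmetically consistent.

`summarize_by_threshold` reports, for each score bound b, the percentage
of positively-labelled records among those scoring ≥ b (cumulative
reading, matching the "at scores above 0.8" phrasing of the published
enrichment analysis); half-open per-interval bins are available with
`cumulative=False`. Empty bins report NaN, never 0%. External
tolerated/deleterious-style labels are carried through as opaque strings.

## Synthetic fixtures

`make_alignment` builds gapless alignments whose per-column conservation
is controlled exactly: with N rows and target fraction r, exactly
round(r·N) rows carry the reference residue (the query row included
whenever that count is ≥ 1) and the rest draw uniformly from the other 19
residues. Scoring such an alignment therefore recovers the closed form
with zero sampling noise, which is what the recovery tests assert; a
Bernoulli-per-row stochastic mode exists for tolerance-based property
tests. `make_substitutions` samples distinct positions without
replacement with the alternate residue uniform over the 19 non-reference
codes. Both are deterministic given a seed (NumPy `default_rng`).

What the generator does **not** emulate: gaps, phylogenetic correlation
between rows, substitution-matrix-biased residue draws, and realistic
E-value distributions. Passing recovery tests therefore demonstrate the
scoring arithmetic and plumbing, not robustness to real alignment
pathologies (misalignment, fragmentary homologs, paralog contamination).

Test problem sizes — alignments up to 100 × 5 for the recovery grid,
40-residue queries with ≤ 14 homologs for end-to-end runs, 200 random
hit lists for the filtering oracle — keep the full suite under a minute
while still exercising every code path exhaustively where the domain is
finite (all 400 residue pairs, all 8 000 triples).

## Numerical notes

- Pairwise distances are computed once per property table into a 20×20
  matrix with symmetric assignment, so symmetry is exact and the matrix
  maximum equals the scale factor bit-for-bit (the top pair scores
  exactly 1.0).
- Display rounding is decimal half-up (`0.125 → 0.13`), applied only at
  serialization; all arithmetic is double precision.
- Non-canonical residue codes (X, B, Z, U, O, `*`) are rejected with the
  offending code named, never silently skipped; the batch scorer can
  skip out-of-range records under an explicit `skip_invalid` flag, and
  reference mismatches are flags by default, errors under `strict`.

## Limitations

- The seven-property table treats all sites alike; no structural context
  (burial, membrane span, active sites) enters the score.
- MSAC is deliberately simple — no phylogenetic weighting, no entropy —
  and is meant as an illustration of combining conservation with the
  property score; any conservation measure in [0, 1] can be substituted
  in `combine`.
- PASEC is a ranking score, not a calibrated probability of
  deleteriousness.
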