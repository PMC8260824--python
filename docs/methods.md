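# Methods

## Degenerate codon algebra

The 15 IUPAC ambiguity symbols map bijectively to the nonempty subsets of
{A, C, G, T} (B = C/G/T, D = A/G/T, H = A/C/T, K = G/T, M = A/C, N =
A/C/G/T, R = A/G, S = C/G, V = A/C/G, W = A/T, Y = C/T, plus the four
concrete bases).  A degenerate codon is three such symbols; its expansion is
the Cartesian product of the three base sets (1–64 concrete codons), and its
profile counts how many expanded codons translate to each amino acid under
the standard genetic code (NCBI table 1; stops tallied as `*`).  Parsing is
case-insensitive and `U` is accepted as a synonym for `T` on input (the
library chemistry uses dU templates) but never emitted.  Only the standard
code is built in: the method targets *E. coli* expression, and alternative
translation tables would change every downstream profile silently.

## Mixture selection (MSCS)

With 15 choices per position there are exactly 15³ = 3375 synthesizable
codon mixtures, few enough to evaluate exhaustively; no heuristic search is
used.  Each mixture is scored against the weighted request as described in
the README.  The scoring constants default to

| parameter | default | rationale |
|---|---|---|
| `penalty_missing` | 1.0 | a missing requested amino acid cancels roughly one encoded one |
| `penalty_extra` | 0.5 | extras dilute a library but do not break it; the term is the *fraction* of codons wasted, so it is scale-free in mixture size |
| `penalty_stop` | 2.0 | stop codons truncate the protein, the most harmful outcome |

Negative-weight amino acids subtract their weight when encoded and never
incur a missing penalty.  Ties in score are broken by more requested amino
acids encoded, then fewer codons (compact mixtures sample each variant more
often at fixed library size), then less codon mass on unrequested amino
acids, then lexicographic code — making the ranking a deterministic
permutation of all 3375 mixtures.

Report lines follow the `k/n Encoded: … Missing: … Extra: … Codons: …
Code: …` layout, including the historical quirks `Missing:0` (no space) and
`Extra: 0` (with space) for empty lists.  Within the Encoded field amino
acids are listed by multiplicity descending with ties in request order;
within Extra by multiplicity descending with ties alphabetical; Missing in
request order.  These orders are a deliberate, documented convention: no
single deterministic rule reproduces the intra-field ordering of earlier
report output, which is internally inconsistent, so only field *content* is
treated as meaningful.

## Library specification and diversity

A `LibrarySpec` is a concrete coding-strand template plus ordered,
non-overlapping mutation sites, each replacing `reference` (template-exact)
with a degenerate `replacement`.  Coordinates are 0-based half-open
internally and 1-based in reports.  Codon-level diversity is the exact
integer product over sites of each replacement's expansion count;
protein-level diversity multiplies the number of *distinct* amino acids
(stop included when encoded) per site and is defined only when every site
substitutes exactly one whole in-frame codon — anything else raises a frame
error rather than guessing a reading frame through an indel.
`variant_count(L, k, n) = C(L, n)·kⁿ` gives the standard count of n-site
protein variants with k alternatives per site.  (Some published figures for
multi-site variant counts exceed this formula — e.g. "over 2.5 million"
where C(100,2)·19² = 1 786 950 — under an unstated counting convention; the
standard formula is implemented and the discrepancy is noted, not
reconciled.)

Expected base fractions assume equimolar synthesis: 1/|base_set| per base of
a mutated position's symbol, 1.0 for the template base elsewhere.

## Donor primer design

Donor primers are represented in coding-strand sense (they anneal to the
retained bottom-strand ssDNA, so their sequence equals the coding strand
over their footprint) and are always flagged 5′-phosphorylated, as ligation
requires.  Flanks start at 15 nt per side and grow one base at a time —
shorter side first, left first on ties — until the combined-flank melting
temperature reaches 55 °C or both flanks reach 20 nt.  Tm uses the Wallace
rule, 4·(G+C) + 2·(A+T) °C, over both flanks concatenated and excluding the
mutated core; it keeps every example hand-checkable, and a
nearest-neighbour method can be added behind the same interface.  Whether
the threshold should apply per flank or to the combined flanks is an open
convention; combined is implemented.  Out-of-range requests are permissive:
flank lengths outside 15–20 nt and total lengths outside the validated
29–68 nt range return the primer with an explicit warning rather than an
error, since short (10 nt flank) and long primers have been used
successfully and the caller may know better.  Only a site too close to the
template edge for the minimum flank is a hard error.

Primer compatibility: donor primers must not overlap within one annealing
reaction (touching is allowed; intervals are half-open).  `check_primer_set`
reports all overlapping pairs and partitions the donors into the minimum
number of pairwise-compatible sub-libraries by greedy coloring of intervals
sorted by start — optimal because interval graphs are perfect, so the
number of sub-libraries equals the maximum overlap depth.

## Sequencing QC

The pileup walks each SAM record's CIGAR: M/=/X blocks contribute read bases
to their reference columns; I and S consume query only; D and N consume
reference only (deletions are tallied separately and excluded from depth,
which counts A/C/G/T bases only).  Unmapped, secondary and supplementary
records are skipped.  No base- or mapping-quality filter is applied by
default — the reference pileup computation applies none — but both are
configurable for real data.

Region summaries label each mutated position `pos templateBase > symbol`
and carry two boolean facets per base, *encoded by primer* (in the symbol's
base set) and *encoded by template*, replacing typographic conventions
(bold/lower-case) with explicit columns in TSV/JSON.

Error rate: at a non-mutated position the unexpected-base fraction is
`1 − fraction(template base)`; the statistic is its mean and population SD
(switchable to sample SD) over positions after trimming 25 nt at the 5′ end
by default (ends are sequencing-artifact prone), excluding mutated
positions, optionally positions within `near_exclusion` nt of one, and
zero-depth positions.  The SD is across positions, not across reads — the
natural choice for a per-position summary.  `compare_observed_expected`
reports, per mutated position, the maximum absolute deviation from the
equimolar 1/|base_set| expectation and a descriptive chi-square with
|base_set|−1 degrees of freedom (expected counts = depth/|base_set|; no
multiple-testing correction).

## Synthetic reads

The simulator emulates shotgun sequencing of a library amplicon: per read it
(1) draws a base at every mutated position, uniformly over the site's base
set unless per-position weights are given; (2) places the read uniformly
where it fits; (3) applies substitution errors independently per base at
rate ε, uniform over the three alternatives; (4) emits a correctly placed
SAM record with full-match CIGAR.  A configurable fraction of reads instead
carries soft clips and an internal deletion or insertion, purely to
exercise the CIGAR walker.  Reads are single-end with constant quality
strings (QC applies no quality filter by default); errors never produce
ambiguity codes.  Everything is deterministic given the seed, and the
returned truth object records every variant base and error position.

What the generator does *not* emulate: quality-dependent or indel error
profiles, strand bias, fragment-size distributions, paired-end mates, PCR
duplicates and coverage ramps other than the geometric edge effect.
Passing QC tests on synthetic data therefore validates the *computations*
(pileup arithmetic, estimator recovery, convergence to equimolar
expectations), not robustness to real-instrument artifacts.

The bundled fixture `cre_like_spec` places the five-site mixture set RRK,
VNA, VNA, DSC, VDS as in-frame codon substitutions on a generated 1050 nt
template (the scale of the recombinase amplicon), spaced ~50 bp apart so
that default-designed donor primers are non-overlapping.

## Problem sizes used in tests

The suite simulates at desk scale chosen so binomial noise stays well inside
the asserted bounds: error-rate recovery uses 20 independent runs of 1400 ×
150 nt reads over a 1 kb template (~210× depth; the pooled estimate is
tested at 3 standard errors, each run at 4); equimolar convergence uses
~10 000× depth, where the per-base standard deviation of an observed
fraction is ≈ 0.004 against a 0.02 bound; uniformity of the variant draw
uses 10⁵ molecules with a chi-square test at α = 0.001.

## Known limitations

- Real-instrument NGS summaries (published percentage tables, error rates
  around 0.1–0.2 %) require the original read sets; the module reproduces
  the computation and is validated on synthetic data only.
- Protein diversity for insertion/deletion libraries is intentionally
  undefined (frame error) rather than approximated.
- No hairpin/self-dimer screening or nearest-neighbour Tm; no restriction
  site insertion; single-template specs only.
- The simulator's truth coordinates refer to molecule windows; reads with
  injected complex CIGARs are content-agnostic test material and are not
  tracked against per-position truth.
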