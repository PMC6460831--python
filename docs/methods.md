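# Methods

## Model

A donor splice-site candidate is any GT dinucleotide with full flanks; the
classifier sees only the 11-nt window (−3…−1, +1…+8 relative to the GT,
which is excluded) and assumes the window's 27 features — 11 positional
base identities and 16 dinucleotide counts — carry the discriminative
signal. No positional independence is assumed: the rule partition is built
conditionally, each feature re-discretised inside every current rule cell.

Chi-square statistics are plain Pearson sums Σ(O−E)²/E without continuity
correction; cells with zero expectation contribute nothing. This choice is
pinned by the worked-example tables, whose printed values (109.2, 110.1,
46.2, 45.9) reproduce only without the Yates correction. Counts may be
real-valued — the rebalanced table scales the negative row by θ = N₊/N₋
and the statistic applies unchanged; weighted counts are never rounded
internally (1-decimal values are display-only, and the 46.2/45.9 pair
only reproduces from unrounded weights).

### Compression

Column merging is greedy with a backtracking stop: among admissible pairs
(all pairs for categorical features; adjacent pairs only for the ordinal
count features) the merge maximising the merged table's chi-square is
proposed, and accepted iff a local 2×2 test of the two columns gives
p ≥ α. The first rejection ends compression. α defaults to 0.01, the
threshold implied by the method's own accept example ("0.8933 > 0.01");
it is configurable everywhere. Two deliberate conventions:

- A column with zero total merges with p := 1. Status values unseen in a
  training cell are therefore always absorbed into some group, which is
  what makes every fitted rule set exhaustive over the full feature
  space (tested on 10⁵ random windows).
- Equal chi-square ties go to the pair with the smaller leftmost column
  index, making builds bit-reproducible.

Degrees of freedom for a 2×r table are r−1. p-values are computed in log
space (`chi2.logsf`), so the per-position importance profile log₁₀(1/p)
stays finite at values in the hundreds where the plain p-value
underflows. The profile uses base-10 logarithms; the base only rescales
the ranking.

### Feature introduction

Each round, every remaining feature is compressed within every current
cell; a feature keeping ≥ 2 groups in at least one cell is a candidate.
Candidate gain is the reduction in class entropy from the refined
partition relative to the current one, with all weights |Dʲ|/|D| taken
over the whole training set; the intrinsic value IV is the size entropy
of the refined partition's nonempty cells. In round one this is exactly
the textbook gain / gain-ratio pair. Among candidates with gain ≥ the
candidates' arithmetic mean (inclusive), the highest gain ratio is
introduced; gain-ratio ties resolve to the earliest feature in canonical
order (positions 5′→3′, then dinucleotides alphabetically). Cells where
the winning feature collapsed to one group are left unsplit — hence
variable-length rules. A feature is introduced at most once, globally,
with per-cell groupings; these semantics are fixed and should not be
changed silently, as other readings (per-branch re-introduction, pooled
status values) produce different rule structures. Introduction stops when
no candidate remains. No minimum-cell-size floor is applied by default
(none is part of the method); `min_cell_size` exists as an optional
guard.

### Decision rule

χ²ᵢ₊ perturbs the matched rule's positive count by +1, χ²ᵢ₋ its
*weighted* negative count by +1 (the stored-weights reading: the worked
example "replace 9.7 with 9.7 + 1" operates on the weighted value).
Positive iff χ²ᵢ₊ > χ²ᵢ₋; exact ties — including the degenerate
single-rule table, where both statistics are 0 — are called negative.
The continuous score χ²ᵢ₊ − χ²ᵢ₋ used for ROC/PR ranking is this
package's plumbing choice; the method itself defines only the label.

## Evaluation

Q⁹ follows the three-branch definition (degenerate single-class truth
reduces to the other class's signed accuracy) with Q⁹ = (1+q⁹)/2. MCC
with a zero marginal is reported as 0 with an explicit
`mcc_defined=False` flag. ROC AUC is trapezoidal with tied scores
grouped into single threshold steps (equal to the tie-corrected
Mann–Whitney statistic, tested). PR AUC interpolates in (TP, FP) count
space — intermediate points at every integer TP with FP accruing at the
local skew — and integrates the densified curve; linear interpolation in
precision would be wrong for skewed data. k-fold splitting is seeded and
stratified by default (each fold preserves the class ratio to integer
resolution).

## Synthetic data

The generator emulates the benchmark layout: 140-nt sequences, GT forced
at 1-based 71–72. Positive windows draw each offset from a donor
position-weight model; both classes share one background composition
(A/T 0.27, C/G 0.23), so discrimination must come from positional
structure — the GT-decoy problem in its purest form. The default columns
encode the canonical donor consensus (MAG|GT RAGT: C/A at −3, A at −2,
G at −1, A/G, A, G, T at +1…+4; +5 weakly G, +6…+8 background). A single
`sharpness` knob controls conservation: values in [0,1] mix columns
linearly toward background, 1 is the consensus, values above 1 apply a
power transform p ∝ p^s that concentrates each column on its preferred
bases — the "strongly conserved site" regime used by the recovery tests.
One global seed feeds named substreams (positives / negatives / indels),
so datasets are byte-reproducible.

The frameshift mutator hits each position independently at the given
rate (1% in the benchmark protocol); a hit deletes the base or inserts a
uniform random base with equal probability, leaving expected length
unchanged. Mutated test windows are re-anchored at the GT nearest the
original site (records whose nearest GT moved more than 5 nt are treated
as lost), mirroring candidate re-extraction from corrupted sequences.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: real exon/intron compositional contrast
(windows straddle a boundary whose two sides differ in GC and
pyrimidine content), inter-position dependencies, and the empirical
HS³D base statistics. One measured consequence: the documented
real-data finding that compositional features buy tolerance to
frameshift errors does **not** reproduce here. Because negatives share
the positives' background composition by design, dinucleotide counts
carry only the weak consensus-induced signal; the fitted partition
routes through positional splits first in every branch, so an in-window
indel mis-routes a sample identically with or without compositional
conditions. The corresponding test asserts the real-data direction at
fixed seeds and fails under this generator — retained as an honest
negative result rather than weakened, since the gap is a property of
the deliberately composition-matched simulation, not of the classifier.

## Test problem sizes

Synthetic training sets in the suite use 150–500 positives against up to
30 000 negatives (ratios 1:1 to 1:100) with 400–4000-sample test sets;
oracle-equivalence checks run 1000 random 2×r tables (r ≤ 5) against an
independently coded merge search, and 20-point score sets against
brute-force threshold enumeration. These sizes give the properties being
tested comfortable statistical margins while keeping the default suite
quick.

## Known limitations

- Acceptor sites (AG-anchored) are out of scope.
- Only the given strand is scanned by default; `chidt scan --reverse`
  additionally scans the reverse complement, reporting minus-strand hits
  in plus-strand coordinates.
- Scores are not calibrated probabilities.
- Training-time complexity is rounds × features × cells × compress; very
  deep partitions on large feature domains are the slow path.
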