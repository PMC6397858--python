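# Methods

## Feature model

A record is a sequence `S` over {A, C, G, U} of length `L ≥ 4` together
with a dot-bracket secondary structure of the same length and its folding
free energy. Both strings are scanned with sliding windows of width 2 and
3, and each window is binned as an **unordered multiset** of symbols. Over
a 4-letter alphabet there are 10 distinct 2-multisets and 20 distinct
3-multisets; over the 3-symbol structure alphabet ("(" < "." < ")"), 6 and
10. Unordered binning makes every MI feature invariant under reversal of
the string, which the test suite asserts as a property.

Per-record probabilities are `p(x) = (N_x + ε)/L`,
`p(x,y) = (N_xy + ε)/(L−1)`, `p(x,y,z) = (N_xyz + ε)/(L−2)` with
`ε = 1e−8` by default. From these, three quantities per bin:

- pointwise pair MI: `MI(x,y) = p(x,y)·log₂(p(x,y)/(p(x)p(y)))` — one
  scalar per unordered pair (not a sum over the alphabet; the 10/6 pair
  feature counts force this reading);
- conditional MI: `MI(x,y|z) = H(x|z) − H(x|y,z)` with
  `H(x|z) = −(p(x,z)/p(z))·log₂(p(x,z)/p(z))` and the analogous 3-gram
  term;
- 3-tuple MI: `MI(x,y,z) = MI(x,y) − MI(x,y|z)`, an interaction-information
  style quantity. It is not symmetric in its roles, so roles are fixed by
  the canonical ascending order of the multiset (`x ≤ y ≤ z`, `z` largest).

**Zero-count convention.** Any MI or entropy term whose joint n-gram was
never observed contributes exactly 0 (the standard 0·log 0 = 0
convention). This matters because the three probability estimates have
different denominators (L, L−1, L−2): carrying ε through unobserved bins
would leave an O(1/L²) residue (~10⁻³ at L = 40) in the score, turning the
smoothing constant into a systematic artifact. Under the zero convention ε
is purely a numerical guard: features computed at ε ∈ {1e−6, 1e−8, 1e−10}
agree to far better than 1e−4, and a homopolymer scores exactly 0 on every
MI feature. Log base 2 (bits) by default; the choice is immaterial after
min–max normalisation and is exposed as a parameter.

The canonical 55-column layout is `[PSFMI 34 | SSFMI 20 | MFE 1]`:
triple-MI bins in lexicographic multiset order, then pair-MI bins, then
raw symbol frequencies `N_x/L` (A, C, G, U for the sequence; "(", ".", ")"
for the structure), then — structure block only — the base-pair count (the
number of "(" symbols; G–U wobbles are already pairs in the folded input,
so they are counted). Feature names encode structure symbols as L/D/R
(left bracket, dot, right bracket) to keep TSV headers shell-safe.

Base frequencies are reported raw (`N_x/L`), not ε-smoothed; the two
differ by < 4ε/L. Whether pair lookups inside the conditional-MI term
should be positional rather than unordered is not determinable from the
feature counts alone; unordered lookups are used throughout, consistent
with the window-binning rule.

## Folding backends

Structures can be supplied (Vienna/RNAfold-dialect files, energy parsed
from the final parenthesised token) or computed:

- `rnafold` shells out to ViennaRNA's `RNAfold` for thermodynamic MFE
  folding — use this to reproduce literature-style results;
- `nussinov` (default in tests and simulation) is a weighted Nussinov
  dynamic program maximising total pair weight G–C = 3, A–U = 2, G–U = 1
  subject to nesting and a hairpin loop of ≥ `min_loop` (default 3, the
  standard steric constraint) unpaired bases. It reports −(total weight)
  as a pseudo-MFE so that, as with real thermodynamics, more stable
  hairpins score more negative. Traceback prefers the smallest pairing
  partner index at each interval, making the structure deterministic.
  Exhaustive enumeration over all nested structures confirms optimality
  for short sequences in the tests.

The Nussinov fallback is deliberately simple: it has no stacking energies
or loop penalties, and it pairs random sequences far more aggressively
than a thermodynamic model would. This compresses the MFE gap between
real hairpins and shuffled controls, so MFE is a weaker feature under the
fallback than it is with `RNAfold`.

## Normalisation and classifier

Each feature column is mapped linearly to (−1, 1) from its training-set
min/max (`y = 2(x−min)/(max−min) − 1`); constant columns map to 0 and
out-of-range test values are *not* clipped, keeping the map linear.
Normalisation is refitted inside every cross-validation round on the
training rows only (no leakage); a whole-dataset scaling mode is available
for reproducing MATLAB `mapminmax`-style pipelines where scaling preceded
evaluation.

Classification is an SVM (libsvm via scikit-learn's `SVC`). The default
operating point is the RBF kernel with C = 65536 and γ = 10⁻⁴; a grid
search over a log-2 grid (C ∈ 2⁻⁵…2¹⁷, γ ∈ 2⁻¹⁷…2³ by default) under
seeded stratified 10-fold CV is provided, with ties resolved to the
smaller C, then the smaller γ, so the selection is deterministic. Class
weighting (`balanced`) is off by default and available for imbalanced
designs.

## Evaluation

From aggregated confusion counts: SE, SP, PR, F1, ACC and MCC. Ratios
with a zero denominator are reported as 0 and flagged, so leave-one-out
rounds with a missing class aggregate cleanly. ROC/AUC uses the trapezoid
rule with midrank tie handling (equivalently the normalised Mann–Whitney
U, asserted in tests); AUPR is the step integral of the precision–recall
curve. The jackknife aggregates counts over its n rounds and pools the
held-out decision scores for the curves; an alternative per-round
averaging was considered and rejected since single-sample rounds have no
defined per-round metrics. Stratified folds are used for k-fold so
imbalanced runs keep positives in every fold; `k = n` reduces exactly to
the jackknife.

Information gain ranks features by `IG = H(y) − Σ_b (n_b/n)·H(y|bin b)`
in bits, with equal-width 10-bin discretisation by default and quantile
bins optional (quantile bins make IG invariant under monotone feature
transforms). Scores can be max-normalised so the top feature prints 1.0;
raw bits are the default.

## Synthetic benchmark

The generator emulates the two classes of the hairpin-classification
problem without any external data:

- **Positives**: a random 5′ arm of `stem_fraction·L` nt (default 0.4 of
  the target length, so ~80% of the molecule is stem — the geometry of a
  typical pre-miRNA, which is nearly all stem with a small terminal
  loop), a terminal loop of at least 4 nt filling the remaining length,
  and a 3′ arm reverse-complementary to the 5′ arm with G–U wobbles at
  rate 0.1 per pair and single-base bulges at rate 0.05 per position.
  Bulge insertions are compensated by trimming outer stem pairs so every
  record lands exactly in the configured length range (default 60–120 nt,
  the span of real precursors).
- **Negatives**: dinucleotide-preserving shuffles of the positives, via a
  random Eulerian walk on the dinucleotide graph. This is the principled
  pseudo-hairpin stand-in: mono- and di-nucleotide composition is
  conserved *exactly*, so the sequence-MI block is nearly information-free
  by construction and the classifier must exploit structure — mirroring
  why coding-region pseudo hairpins are the field's hard negatives. An
  i.i.d. GC-matched mode is available as an easier alternative.

All randomness flows from one integer seed through named substreams
(`numpy` `default_rng([seed, salt])`), so benchmarks are bit-reproducible.

What the generator does **not** emulate: real miRBase sequence statistics
beyond composition and hairpin geometry, genomic context, paralog
redundancy, or the coding-region origin of real pseudo hairpins. Passing
the end-to-end tests therefore shows that the pipeline detects a designed
structural signal at realistic sizes and imbalance ratios — not that it
attains any particular accuracy on curated biological benchmarks, which
require the external databases and a thermodynamic folder.

## Problem sizes

The evaluation protocols refit the full pipeline per round, so the shipped
benchmarks are sized for interactive runs: 50+50 records for the balanced
jackknife (100 SVM fits), 20:176 for the imbalanced 5-fold design (the
~1:8.8 ratio regime), folding-oracle checks at L ≤ 12 where exhaustive
enumeration is feasible, and 100 random sequences of 40–120 nt for the
dual-route extractor comparison.

## Known limitations

- The pseudo-MFE scale of the Nussinov fallback is pair-weight units, not
  kcal/mol; mixing backends within one feature table would make the MFE
  column incoherent (the extractor uses one backend per run).
- Pointwise MI features are not bounded or variance-stabilised; the SVM's
  min–max normalisation absorbs scale but not heavy tails.
- The 3-tuple MI role assignment (canonical ascending order) is one of
  several defensible conventions; it is fixed and documented rather than
  symmetrised.
- Jackknife on datasets whose classes are indistinguishable exhibits the
  usual leave-one-out anti-correlation artifact (accuracy below chance),
  which is a property of the protocol, not a defect of the metrics.
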