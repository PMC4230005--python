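# Methods

## Residue scoring

The 20×9 property matrix **X** (20 amino acids × 9 physicochemical
properties; shipped as `adld/data/amino_acid_properties.csv`) is reduced
to one real number per residue:

1. **Standardize** each property column to a z-score.  The sample
   standard deviation (divisor m − 1 = 19) is used; this choice is pinned
   by a calibration test — it is the variant that reproduces the
   published 4-decimal score table, and the correlation-matrix spectrum
   is unaffected by it either way.
2. **Correlate**: the 9×9 Pearson correlation matrix **R** of the
   property columns (scale-invariant, so raw and standardized columns
   give the same **R**).
3. **Eigendecompose** **R**.  Eigenvalues are sorted descending; each
   eigenvector is sign-normalized so its largest-magnitude component is
   positive, which makes the decomposition fully deterministic (exact
   eigenvalue ties — never the case for the packaged table, whose
   spectrum is 3.2237, 1.9132, 1.4048, 1.1876, 0.4959, 0.4467, 0.1992,
   0.1218, 0.0071 — would be ordered by eigenvector sign pattern).
4. **Retain** the smallest t whose accumulated contribution rate
   ACR_t = Σ_{k≤t} λ_k / Σλ reaches 85%.  For the packaged table t = 4
   (ACR₄ = 0.8588).
5. **Score**: TotalScore_i = Σ_{k=1..t} (x*ᵢ · a_k) · CR_k, i.e. the
   CR-weighted sum of the residue's scores on the retained components.

The 20 scores are pairwise distinct (at full precision and at 4 dp) and
sum to zero, being linear combinations of zero-mean z-scores.  Scores are
carried at full float precision everywhere; 4-dp rounding is applied only
in serialized reports.  The table's "Tyrosine/Threonine" naming is
metadata only — rows are keyed strictly by one-letter symbol, and the T
row carries threonine's 119.105 Da, the Y row tyrosine's 181.176 Da.

The scoring is not a general-purpose PCA API: no user matrices, no
alternative property sets, no scaling options.  Its output is only
meaningful for the packaged table.

## Diagram construction

For an ordered pair (longer sequence first; equal lengths are ordered
lexicographically by id for reproducibility), coordinate (i, j), 1-based,
is an alignment point when

- |i − j| ≤ w, with w = ξ if N₁ − N₂ ≤ ξ else N₁ − N₂,
- j ≤ N₂, and
- |tᵢ − tⱼ| ≤ ε.

Only the 2w + 1 diagonals of the band are ever materialized.  The shorter
sequence is conceptually padded to length N₁, but padded positions never
generate points: literal zero-padding could spuriously match real scores
whenever ε > 0, and with ε = 0 the two readings coincide because no
residue's total score is 0.  Score comparison is exact floating-point
arithmetic; ε = 0 therefore means "identical residue", which is safe
because both sides draw from the same 20-value table.

Maximal runs of consecutive points (unit diagonal steps, no gap
tolerance) with length ≥ δ become similar fragments, scanned offset 0
first, then +1, +2, …, then −1, −2, … and left-to-right within a track.
Negative offsets o = j − i lie below the main diagonal: a fragment at
offset −k is a suffix realigned after a k-residue insertion in the longer
sequence.  Main-diagonal points not covered by any main-diagonal fragment
are the free points; off-diagonal stray points are discarded.  With δ = 1
every point lands in a fragment and the reduction is the identity.

Defaults: ε = 0, δ = 3, ξ = 10.  ξ = 10 is the conventional floor for the
band threshold; published diagrams of β-globin pairs use 12 and 16, and
no published rule selects it, so it is always an explicit user parameter
(`adld.reproduction.xi_sweep` quantifies sensitivity to it).  δ should
grow with sequence length (e.g. 5 for >1100-residue spike proteins) to
suppress chance runs.

## Distances

SD(pair) = Σ fragment lengths (all tracks) + free-point count.  The
matching matrix d fills the lower triangle, including the diagonal:
d_ii is computed by a genuine self-comparison, so internal repeats add
by-path fragments and d_ii can exceed N.  The distance is
s_ij = 1 − min(1, d_ij/d_ii): zero for identical sequences, one when no
structure is retained, clamped so highly self-repetitive partners cannot
push it negative.  Normalizing by the row's d_ii is asymmetric by
construction and only the lower triangle is defined; a symmetric variant
(denominator min(d_ii, d_jj)) is available behind the off-by-default
`symmetric_norm` flag as a deliberate departure from the canonical
definition.  Matrices serialize as labelled CSV (lower triangle, 4 dp by
default) and as symmetrized lower-triangular PHYLIP for downstream tools.

## Trees

Neighbor joining (via scikit-bio) on the symmetrized distance matrix,
negative branch lengths clamped to zero with a log note, Newick output.
This is a convenience exporter: NJ consistency is tested on closed-form
3-leaf and additive 4-leaf metrics, but no claim is made of reproducing
any particular published tree node-for-node (the published trees came
from an external GUI program with unstated settings).

## Synthetic data

`adld.synthetic` draws sequences uniformly over the 20-letter alphabet
from an explicitly threaded seeded generator and applies ordered edit
recipes (substitute / insert / delete, 1-based positions, substitutions
guaranteed to change the residue).  It emulates exactly the geometric
events the diagram is designed to detect — block insertions shifting
runs onto by-path tracks, substitutions punching gaps — and nothing
else: no substitution-rate matrices, no indel length distributions, no
compositional bias.  Tests passing on these pairs therefore validate the
diagram geometry and the distance bookkeeping, not biological realism.

## Numerical and testing choices

- The banded implementation is checked for exact equality of point sets,
  fragments and free points against a dense brute-force re-evaluation on
  hundreds of seeded random pairs of length ≤ 60 — sizes chosen to keep
  the dense oracle cheap while exercising every branch (band clipping,
  unequal lengths, all parameter ranges).
- Printed 4-dp reference values are asserted by rounding, not tolerance,
  so a half-ulp drift at the 5th decimal fails the test.
- Degenerate inputs fail loudly and specifically: constant property
  columns name the property; a sequence whose self-comparison retains
  nothing (shorter than δ) names the sequence; unknown residues (B, Z,
  X, U, gaps) raise with 1-based position by default, with an opt-in
  drop policy that warns — dropping shifts every downstream coordinate,
  which is why it is not the default.

## Known limitations

- Two benchmark reproductions (β-globin and mitochondrial ND5 sets)
  require user-supplied GenBank FASTA; the package never downloads
  sequences, so those tests report exactly what is missing until the
  files are provided under `tests/data/user/`.
- ε > 0 groups residues by score proximity on an essentially arbitrary
  1-D scale; small ε values near the minimum score gap (0.0178, between
  F and H) change behaviour discontinuously.
- The distance is not a metric (asymmetric normalization, no triangle
  inequality) and carries no statistical significance model for run
  lengths.
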