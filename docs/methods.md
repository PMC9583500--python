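# Methods

## The decomposition

`csss` models the measured level of protein *i* in each cell as a reference
(steady-state) level modulated multiplicatively by a small number of
unbalanced processes:

```
ln(X_i(cell) + offset) = G_i0 λ_0(cell) + Σ_{α≥1} G_iα λ_α(cell)
```

The columns of `G` are orthonormal patterns over the marker panel; `λ` are
per-cell amplitudes. We absorb the conventional minus sign inside the
exponential into the stored λ, so reconstruction is a plain sum and all
up/down-regulation logic reads off the sign of the product `G_iα·λ_α(cell)`.

**Fitting.** The log matrix `C = ln(X + offset)` (cells × markers) is
factored through the eigendecomposition of the small symmetric
`markers × markers` matrix `CᵀC`; amplitudes are the projections `Λ = C G`.
This is algebraically identical to the full SVD of `C` (tested to 1e−8
against a direct SVD) but costs O(n·m²) time and O(n·m) memory, so panels
of 10⁵–10⁶ cells are routine. The route is uncentered on purpose: the top
singular direction *is* the reference state, it is not removed as a mean.

**Rank and ordering.** An *m*-marker panel yields at most *m − 1* constraint
processes plus the reference. The numerical rank uses a relative floor of
1e−12 applied to the eigenvalues of `CᵀC` (the quantities actually
diagonalized; a floor on the singular scale would mistake eigensolver noise,
which is of order √eps there, for signal). Processes are ordered strictly by
decreasing singular value; ties (tolerance 1e−10 relative) keep the
eigensolver's column order. Sign ambiguity is fixed deterministically: each
`G` column is flipped so its largest-magnitude entry is positive, with λ
flipped to match, making barcodes reproducible across platforms.

**Reference state and deviations.** The reference intensity is
`exp(G_i0 λ_0(cell)) − offset`, clipped at zero — computed per cell, since
the α = 0 amplitude varies with the cell (for a population of identical
cells it reproduces the input exactly). The deviation attributable to
process α is the rank-one matrix `λ_α ⊗ G_α` on the log scale.

**Offset.** FACS intensities can be zero after compensation, and the model
needs a logarithm; `offset` (default 1.0 intensity unit) is added before the
log and recorded in every artifact. Negative post-compensation FCS values
are clipped to zero at read time and the count is logged. Whether to rescale
intensities before the log is exposed to the caller (pass transformed
values); the default is raw intensities.

## Tail thresholds

A process is *active* in a cell only if the cell's amplitude lies in a tail
of the pooled amplitude distribution. Thresholds are always computed on the
pooled population (all conditions together) so that condition comparisons
use one common ruler; per-condition thresholds would confound abundance
changes with threshold drift.

* **quantile** — cuts at the `tail_fraction` and `1 − tail_fraction`
  empirical quantiles (default 0.05 per side). Deterministic, auditable,
  but activates a fixed fraction regardless of how many cells actually
  carry the process.
* **knee** (default) — emulates reading the tails off the sorted-amplitude
  sigmoid plot. On each half of the sorted curve (normalized to the unit
  square) the max-distance-to-chord point on the convex side locates the
  bend where the central bulk gives way to the tail; the cut is then placed
  at the point of maximum discrete curvature beyond the bend — the middle
  of the largest value gap in the tail segment. The refinement matters: the
  raw max-distance point sits where the curve's slope equals the chord's,
  which for a Gaussian bulk is ≈2.4σ *inside* the bulk and would mark ~1% of
  quiescent cells active per side — fatal when estimating fold changes of
  subpopulations at the 0.3% scale. With the gap refinement, a separated
  carrier mode falls wholly on the active side and a pure Gaussian bulk
  yields almost no active cells.

Degenerate halves (near-linear curve, normalized max distance ≤ 1e−3) fall
back to the quantile cut with a warning, as does any knee solution whose
central interval would retain fewer than half the cells. A constant
amplitude column gets both cuts at that constant: no cell is active
(inequalities are strict). Activity is two-sided by default — lower-tail
cells are "active, negative sense" — with one-sided modes available.

## Barcodes and subpopulations

A cell's barcode is the signed ternary vector of its activity calls
(`signed` mode, default) or its absolute value (`binary` mode). Signed is
the default because process direction carries the biology — a Her2-induced
and a Her2-repressed cell should not merge into one subpopulation; binary
mode reproduces presentations that only distinguish active from inactive.

Subpopulations are exact barcode groups. The table keeps every barcode
(fractions per condition sum to 1, counts to that condition's cell number)
and flags as **dominant** those at ≥ `abundance_floor` (default 1%) in at
least one condition — the `any_condition` scope, so a treatment-emergent
subpopulation undetectable at baseline is still flagged. The all-zero
barcode (no active process) is retained in the table but never flagged
dominant and is labelled `0`; letters a, b, c … name the signature-bearing
barcodes in descending pooled abundance, ties broken lexicographically.

## Differential abundance

Fold changes are ratios of per-condition fractions. When the control
fraction is below the detection floor (default `1/n_cells(control)`, i.e.
one observed cell), the subpopulation is flagged *emergent* and the fold
change is reported as the conservative bound `treated_fraction /
detection_floor` — never infinity. Each barcode gets a two-sided
two-proportion z-test; Benjamini–Hochberg q-values are reported alongside
raw p-values. When per-replicate fraction tables are supplied (several
flasks/experiments per condition), a two-sample t-test on replicate
fractions replaces the z-test, matching replicated experimental designs.
Fold changes can be computed on pooled fractions or on replicate means;
both are exposed.

## Process networks

A process's subnetwork contains the markers with `|G_iα| ≥ g_cut`; node
weight is the raw `G` entry (no rescaling) and node direction is the sign
of the mean `G_iα λ_α(cell)` over a chosen cell subset (positively active
cells, negatively active cells, or all — directions flip exactly when the
subset flips). There is no principled universal cut for "significant"
participation; the default `1.96/√m` (≈ twice the flat-pattern magnitude)
is a heuristic and the realized cut is always logged. Interaction edges are
imported from a pre-downloaded two-column pair list and filtered to the node
set; no live database queries.

## Synthetic generator

The generator runs the model forward:
`ln X_i = ln(baseline_i) + Σ_α G_iα λ_α + ε`, with i.i.d. Gaussian noise ε
(default σ = 0.05) on the log scale — multiplicative noise, matching FACS
behavior. Subpopulations are defined by signed barcodes over the planted
processes with per-condition mixing fractions; active amplitudes are drawn
as `sign·A + N(0, 0.1A)` (default A = 3.0), inactive processes get a small
jitter (σ = 0.1) so sorted-amplitude curves have a realistic sigmoid shape.
Subpopulation sizes are allocated by largest-remainder rounding of the
stated fractions — planted fractions are realized exactly, so recovered
fold changes are not blurred by multinomial sampling noise — and cell order
is then shuffled with the seeded generator; the same seed gives
bit-identical output.

Two generator design points are load-bearing and deliberate:

1. **Balance.** The uncentered route returns the planted patterns unmixed
   only when the planted amplitudes have (pooled) zero means and zero cross
   moments; otherwise mean activity leaks into the reference direction and
   correlated processes rotate into each other. The default radiotherapy
   scenario is therefore amplitude-balanced — each process carries equal
   pooled positive and negative mass, and two-process subpopulations come
   in sign-paired twins of equal pooled size — while preserving the
   dynamics of interest (0.3% → 21% ≈ 70-fold expansion, emergence from 0
   to 1.5%, contraction 9.9% → 4.9%, exactly 8 dominant subpopulations).
2. **Orthogonality to the baseline.** Planted weight patterns are
   orthogonalized against the log-baseline direction, because fitted
   constraint patterns are orthogonal to the reference pattern by
   construction; planting them otherwise makes the two parameterizations
   incomparable by an irreducible rotation.

What a green recovery test therefore establishes: the pipeline recovers
planted patterns (|cosine| ≥ 0.95), subpopulation fractions (±2 pp) and a
70-fold expansion (±10%) *in this balanced, well-separated regime*
(amplitude 3.0 ≈ 30× the inactive jitter). It does not establish behavior
under heavy-tailed instrument noise, spillover, autofluorescence, strongly
unbalanced process activity, or amplitudes comparable to the jitter — in
that last regime the active and inactive amplitude distributions overlap
and no threshold rule can separate them.

## Numerical choices and degenerate inputs

* Natural log throughout; offset > 0 required, checked.
* Rank-deficient inputs (e.g. a constant marker column, or identical cells)
  reduce the process count with a warning rather than erroring.
* `n_cells ≥ n_markers` is required (the covariance route needs it).
* Permuting cells permutes amplitudes only; duplicating all cells scales
  importance by √2 and leaves patterns unchanged (up to sign) — both
  tested.
* Scaling all intensities by a constant changes only the reference term in
  the offset → 0 limit when deviation patterns are orthogonal to both the
  log-baseline and the all-ones marker directions; with measurement noise
  the constraint terms move at second order (~1e−5 for σ = 0.02).

## Known limitations

* Compensation, gating and stromal/immune exclusion are assumed done
  upstream; the FCS reader is minimal (list mode, float/double/uniform
  integer widths) and read-only.
* Thresholding assumes the pooled amplitude distribution is
  bulk-plus-tails; a process active in >50% of cells would defeat the
  central-interval invariant (the quantile fallback then applies).
* The two-proportion z-test treats cells as independent draws; cells from
  the same flask are correlated, so when replicate structure exists the
  replicate t-test mode should be preferred.
* Bulk-sample surprisal analysis (per-tissue amplitudes) and thermodynamic
  quantities beyond the decomposition are out of scope.
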