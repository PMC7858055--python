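# Methods

## Replication-mode inference from GC skew

The windowed skew is (G − C)/(G + C) with 1 kb windows at 1 kb steps; the
final window wraps around the circular coordinate origin, windows with no G
or C score 0, and non-ACGT letters count as neither G nor C. The cumulative
curve is the running sum of window skews.

The classifier rests on one geometric fact: the cumulative skew of a
circular sequence is the sum of a linear trend (slope = whole-replicon mean
skew) and a periodic residual. A replicon whose leading strand spans the
entire circle — the unidirectional case — puts its whole signal into the
trend; a bidirectional replicon has zero net skew and puts its signal into
the residual, a V-shaped curve whose minimum marks *ori* and maximum marks
*ter*. The classifier therefore detrends, smooths the residual with a
circular moving average (half-width 25 windows, wide enough to suppress
gene-scale skew structure), and compares the residual range against the
absolute net skew:

* trend dominates → `unidirectional` (ori/ter localized on the raw curve);
* residual dominates and the extrema are 0.35–0.65 of the circle apart →
  `bidirectional`;
* extrema ≤ 0.10 of the circle apart → `unidirectional`;
* combined amplitude (residual range + |net skew|, divided by the number of
  windows) below 0.01 → `unpredictable`, as is any separation that falls in
  neither band.

Working with the detrended residual rather than the raw cumulative curve
matters numerically: the raw curve of a net-skewed circular replicon has its
extrema pinned at the coordinate wrap regardless of where *ori* lies, and
circular smoothing across the wrap distorts the extrema by about the
smoothing width, which at 0.5 Mb is enough to push the plain
extremum-separation rule out of its own decision band.

The amplitude floor of 0.01 is set midway (on a log scale) between the
random-walk noise floor of skewless sequences (≈0.005 at 0.5–2 Mb) and the
weakest signal the classifier is expected to resolve (planted per-window
skew a = 0.04, which yields measured amplitude a/2 = 0.02 for bidirectional
replicons, since the residual accumulates over only half the circle).
Extremum ties break toward the smallest coordinate. All thresholds are
parameters of `SkewParams`; the defaults are this package's
operationalization of what is, in the field, usually a visual call.

Limitations: a unidirectional replicon has (in this model) uniform skew, so
its *ori* cannot be localized from skew alone — only the mode is meaningful;
the reported ori/ter for unidirectional calls are the raw-curve extrema and
carry window-scale noise.

## Marker-frequency analysis

Model: in steady-state exponential growth with doubling time τ, a locus
replicated at time t(x) after the population-wide earliest initiation has
relative copy number n(x) = 2^(−t(x)/τ). Log₂ read depth is therefore
linear in replication time, falling by C/τ from *ori* to *ter*.

Pipeline and numerical choices:

* **Binning**: mean depth per 1 kb bin; the final partial bin averages over
  its actual width.
* **Correction**: per-bin factor = stationary-phase bin / stationary
  replicon mean; exponential bins are divided by it. Bins with zero
  stationary coverage are masked, not divided. The stationary sample
  estimates the multiplicative bias field (library, mappability) shared by
  both phases; correction cancels it exactly in expectation but adds the
  stationary sample's Poisson noise (√2 inflation at equal depth).
* **Outlier masking**: a bin is removed when its distance from the median
  of its 50 circular neighbors (25 per side, masked bins excluded) exceeds
  2 × their interquartile range, strictly — so perfectly flat neighborhoods
  (IQR 0) mask nothing. The rule is iterated to a fixpoint, which makes the
  operation idempotent; on profiles whose only contamination is planted
  spikes the fixpoint is reached after one round.
* **Gradient fits**: three circular models on log₂ of unmasked positive
  bins — flat; one-slope (value declining linearly with clockwise distance
  from a breakpoint *ori*); two-slope (a "tent": peak p at *ori*, trough q
  at *ter*, linear along both arcs). Breakpoints are scanned on a coarse
  grid (~n/64) and refined locally; given breakpoints, the linear
  coefficients are closed-form least squares. The tent is symmetric under
  swapping (ori, p) ↔ (ter, q); fits are canonicalized so the peak is
  *ori*. Selection is BIC-style, m·ln(SSE/m) + k·ln m with k = 1/3/4
  parameters, i.e. one degree of freedom per extra breakpoint. If an
  external *ori* is supplied the breakpoint is constrained to ±10 kb of it.
  Profiles with >50 % masked bins are rejected; stationary-phase profiles
  return `flat` with a warning.
* **Synchrony**: region coverage is the mean of unmasked bins within ±5 kb
  of a site; R_ori = ori1/ori2, R_dif = dif1/dif2. Termination synchrony is
  called when |R_dif − 1| ≤ 0.15 and R_ori > 1.15; initiation synchrony
  when |R_ori − 1| ≤ 0.15 and R_dif < 0.85; otherwise indeterminate. The
  5 kb half-width and 0.15 tolerance are this package's defaults; reported
  point ratios in the literature rarely state a window.

Caveat on unidirectional replicons: *ter* sits only ~20 kb from *ori*, so a
symmetric window centred on *ori* straddles both the earliest- and the
latest-replicating DNA. This biases R_ori upward (away from 1) — harmless
for termination-synchrony calls, which only require R_ori > 1, but it means
R_ori for a unidirectional chromid overshoots the point-value expectation
2^((C₁−C₂)/τ). Similarly, the one-slope fit cannot place *ter* more
precisely than "adjacent to *ori*": the terminal gap is below the gradient
resolution, and `ter_est` is reported as the bin preceding `ori_est`.

## ori and dif site search

The *dif* scan counts mismatches of the 28-bp reference (and its reverse
complement) at every circular offset — an exhaustive, deterministic
replacement for a permissive BLASTN search, with the coverage leniency
mapped to a default budget of 8 mismatches. Structural filters: outside
annotated CDS (skipped with a warning when no annotation is given), an
inverted-repeat arm of ≥7 bp with ≤2 mismatches, and a XerD half-site
(right 11-mer of the reference) matching with ≤1 mismatch. Candidates are
ranked by mismatch count, then distance to an expected terminus. The
shipped default reference is a **synthetic** canonical-architecture site
(XerC arm / 6 bp spacer / conserved E. coli XerD box, with the XerC arm an
imperfect inverted repeat of the XerD arm); real analyses should supply the
reference *dif* sequences appropriate to their taxa.

The *ori* search slides a 500 bp window (step = window/5) scoring DnaA
boxes (TTATCCACA, ≤1 mismatch, either strand) and GATC sites; windows with
≥3 boxes and ≥8 GATC qualify, overlapping qualifying windows merge into
their best window, and ranking follows distance to a skew-predicted *ori*
when available, else (boxes, GATC) descending with coordinate tie-breaks.

## Parsimony on the species tree

Sankoff dynamic programming with unit costs over the state alphabet
{uni, bi}; multifurcations sum over children natively; tips without a state
(e.g. unpredictable skew calls) contribute zero cost to every assignment —
but only when the trait table was built through `map_modes_to_tree`;
directly constructed trees treat a stateless tip as an error. A root
constraint restricts the root's cost vector to one state. A top-down pass
recovers, per internal node, the set of states attained in at least one
optimal labelling, and the edges on which some optimal labelling changes
state. Unconstrained minima equal the best constrained minimum, match Fitch
counts on binary trees, and are invariant to rerooting — all cross-checked
against exhaustive enumeration in the test suite.

## Strand bias

Genes are assigned to the replichore containing their midpoint (the
literature rarely states a rule for boundary-spanning genes); midpoints
within 1 kb of *ori* or *ter* are excluded as boundary genes. On the right
replichore (clockwise fork, *ori*→*ter* in coordinate direction) the
leading strand is the plus strand; on the left replichore the minus strand;
a unidirectional replicon is a single right replichore. Ratios with zero
lagging genes are reported as undefined rather than infinite.

## Synthetic data: what it does and does not emulate

* **Sequences**: bases i.i.d. per position with P(G) − P(C) =
  ±a·GC, sign set by the local leading strand (default GC 0.45, a = 0.08 —
  within the range of real proteobacterial skews). Real genomes add
  gene-scale skew structure, repeats, and horizontally acquired islands;
  i.i.d. sequences therefore bound the classifier's noise floor from below.
* **Coverage**: the exponential-population age structure is collapsed into
  the first-moment expectation 2^(−t/τ) rather than simulating single
  cells; Poisson sampling supplies noise of the right scale. The bias
  field is lognormal per 1 kb bin (σ = 0.1) and shared between phases,
  exactly the situation stationary-phase correction is designed for; real
  bias fields also have GC-dependent and long-range structure. Depth is
  normalized so that the mean over **all replicons jointly** equals the
  requested depth — one sequencing run has one scale — which is what makes
  cross-replicon ori/dif ratios meaningful.
* **Timing**: under termination synchrony a replicon with period C_r
  initiates C_max − C_r after the slowest, so all termini finish together;
  under initiation synchrony all start together. A unidirectional replicon
  is modelled with a single effective fork and its *ter* placed 20 kb
  counterclockwise of *ori* (terminus adjacent to origin, as observed for
  real unidirectional chromids); the short terminal gap extrapolates the
  fork linearly past C.
* **Genes**: midpoints uniform, lognormal lengths (median 900 bp, σ = 0.3),
  strand leading with the configured probability; overlaps are not
  prevented. **Trees**: random joins with one planted monophyletic
  bidirectional clade.

Everything is deterministic under its seed. Passing tests on these
generators demonstrate correctness of the estimators under the stated
model, not robustness to mapper artifacts, repeat-driven coverage
pathologies, or skew signals confounded with horizontally transferred DNA.

## Problem sizes used in the checks

Self-tests run replicons of 0.3–3 Mb, coverage grids over C/τ ∈
{0.5, 1, 2} at 50–200× depth with 10 seeds per cell, skew grids over
0.5–2 Mb with 20 seeds per cell, and 200 random ≤8-tip trees against
exhaustive enumeration; the headline-reproduction script uses a 3 Mb main
chromosome plus 0.8 Mb chromid at 200× over 10 seeds. These sizes put every
statistic comfortably past its convergence scale while keeping a full run
in the low minutes on one CPU.
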