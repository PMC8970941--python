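# Methods

## Scoring model

The framework evaluates a change-point detector by *where* its
detections land relative to ground truth, on a scale that is invariant
to series length and target spacing.

**Segmentation.** A series of length *N* with targets
tCP₁ < … < tCPₙ is tiled into *n* scoring segments with interior
boundaries at floored midpoints mᵢ = ⌊(tCPᵢ + tCPᵢ₊₁)/2⌋; segment *i*
is the inclusive range `[mᵢ₋₁ + 1, mᵢ]` with m₀ = 0 and mₙ = N. This
is the unique tiling in which segments are disjoint, every index
belongs to exactly one segment, each segment holds exactly one target,
and lengths sum to *N*. Flooring odd midpoint sums gives deterministic
integer boundaries; the at-most-one-sample asymmetry it introduces is
negligible after normalization. All public coordinates are 1-based
inclusive.

**Normalized error distance.** A detection at *e* in segment
`[a, b]` with target *c* scores `NED = (c − e)/(c − a)` when `e ≤ c`
and `(e − c)/(b − c)` when `e > c`, so NED ∈ [0, 1] with 1 meaning
"at the far boundary". The signed variant (negative before the target,
positive after) supports distribution reports on `[−1, 1]`. Targets on
a segment boundary make a denominator vanish and are rejected as
degenerate (the generators never produce them); a detection exactly on
the target scores 0 regardless of side.

**Classification.** Per segment, the detection nearest the target
scores it (ties break to the smaller position); the rest are counted
*redundant* and carry no distance. Within the hit radius `hd` the
segment is a *hit* (contribution 0); otherwise an *error*
(contribution NED); no detection is a *miss* (contribution 1, placed
at +1 on the signed axis — a convention, since a miss has no side; it
is stated in reports). `MWED` is the mean contribution over segments
and `MWTD = 1 − MWED` exactly.

A frequency-weighted formulation (summing frequency × NED over the
distinct NED values) reproduces the same mean; it is retained only for
the binned distribution report, where each bin's WED mass is its
frequency times |bin centre|. The default 201 bins over `[−1, 1]` are
odd-count so one bin is centred exactly at 0 and hits carry no mass;
the total mass converges to the mean |signed NED| at rate one bin
width.

**Rates.** Hit/miss/error counts divide by the number of scored
segments by default, so the three rates sum to 1 exactly. An
alternative `total_ecps` denominator (scoring detections plus
redundant ones) is provided for detector-centric reporting; under it
the rates need not sum to 1.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| hit radius `hd` | `max(1, round(0.005·segment length))` | samples | scale-free: a fixed absolute radius would grade long-segment runs more leniently; configurable absolutely |
| distribution bins | 201 over [−1, 1] | — | odd count centres a bin at 0 (hits weightless) |
| scan `alpha` | 0.01 | — | two-sided significance of the best split; controls false alarms per window |
| `min_seg` | 16 | samples | smallest half-sample for a two-sample statistic |
| descent `min_len` | 16 | samples | bracket length at which the search stops |
| SSA `lag` / `base_len` / `test_len` | 32 / 128 / 64 | samples | lag-embedding dimension and reference/test stretch lengths |
| SSA `threshold` | 0.55 | score fraction | calibrated by simulation: false-alarm rate 1.5% on 200 pure N(0,1) windows of length 4096 (0.52 → 6.5%, 0.50 → 13.5%); the 5% design bound is met with margin |

## Detectors

The five baselines are standard, documented variants, deliberately
simple; none is claimed optimal.

* **t / ks** — exhaustive scans: evaluate the two-sample Welch-*t*
  (via cumulative sums, O(1) per split) or Kolmogorov–Smirnov
  statistic (via one global stable argsort, O(L) per split, with tie
  groups handled exactly) at every candidate split, return the argmax
  if its p-value beats `alpha`. The KS scan decimates candidates on
  windows longer than 512 samples (`jump = L // 512`) to bound cost;
  windows up to 512 are always scanned exhaustively. Ties in the
  argmax break to the smaller split.
* **bst / tst** — bracket-descent searches over the split axis that
  keep the best statistic seen and shrink the bracket by ½ (binary,
  probing the halves' midpoints) or ⅔ (ternary, probing the third
  points) per two evaluations, giving O(log L) statistic evaluations.
  The descent assumes an effectively unimodal statistic profile; on a
  sharply peaked off-centre profile the binary variant can discard the
  peak's bracket and localize poorly (the best-seen probe is still
  returned). This is an accepted limitation of the reconstruction —
  the evaluation framework, not the detectors, is the point.
* **ssa** — singular-spectrum change score: the `base_len` samples
  before a candidate boundary are lag-embedded and the left-singular
  subspace capturing 90% of their energy extracted; the score is the
  fraction of the following `test_len` samples' lag-vector energy
  outside that subspace. Base and test are centred on the base mean,
  making the score invariant to constant offsets. The sweep stops at
  the first threshold crossing and refines to the score argmax over
  the next `test_len` boundaries, ties to the right — on a plateau
  (zero-variance base saturates the score at 1) the change sits at the
  plateau's right edge.

Detectors that find no change return "none"; by default the harness
counts the segment as a miss. An `endpoint_fallback` option emits the
window start instead (some pipelines pin undetected windows to an
endpoint), but it is off by default because such detections are
indistinguishable from genuine far-off errors and inflate NED ≈ 1
error mass.

## Window harnesses

Fixed (FSW) and random (RSW) slide windows share one advance rule:
after a detection at global position *q* the next window starts at
*q* + 1; otherwise the window advances by its own length (stride
configurable). This rule terminates, visits every sample, and makes
RSW with `l_min = l_max = n` coincide exactly with FSW at `n_fsw = n`.
RSW draws each window length uniformly from `[l_min, l_max]` with a
generator seeded per run, so runs are bit-reproducible. Trailing
windows shorter than the detector's minimum are skipped and logged.
Per-window computing times are summed into the run's `compute_time`
and normalized across detectors (NST = share of total time); timing is
reported but flagged hardware-dependent and never asserted on.

## Synthetic protocols

Three seeded protocols emulate common benchmarking designs:

* **exp1** — single change point: N(0, 1) for the first *m* samples,
  N(V, 1) after, with N a random power of two in 2¹⁰–2¹⁵, V uniform in
  [1.0, 3.7], and *m* uniform in `[16, N − 16]` (the margin keeps both
  regimes above the detectors' minimum half-sample; an unconstrained
  draw could place the target where no two-sample statistic exists).
  20 groups × 100 samples, one parameter draw per group.
* **exp2** — 15–30 Gaussian segments per sample; segment length a
  power of two in 2¹²–2¹⁵ (a uniform-integer mode is available), mean
  uniform in [1.0, 0.1·n_seg], variance uniform in [1.0, 2.0·n_seg],
  drawn per segment with consecutive parameter pairs forced distinct;
  paired with an RSW config. The window bounds default to
  `[2⁹, 2¹²]` — below the typical segment length, so most windows see
  at most one boundary.
* **exp3** — as exp2 with exactly 30 segments, paired with the FSW
  sweep `n_fsw = 2⁶ … 2¹⁵`.

The second parameter of the Gaussian blocks is treated as a
*variance* throughout. A `noiseless` mode replaces each block by its
constant mean (consecutive means forced distinct) for exact,
hand-checkable harness diagnostics.

What the generators emulate — and what they do not: blocks are i.i.d.
Gaussian with abrupt mean/variance changes. Real physiological or
epidemiological series add autocorrelation, trends, heavy tails and
gradual drifts; passing tests here demonstrate correct scoring
arithmetic and qualitative detector behaviour (effect-size response,
window-length trade-off), not detector performance on real signals.

## Numerical choices and degenerate inputs

* Zero-variance window halves give an infinite *t* statistic when the
  means differ (p-value 0) and 0 otherwise, so constant windows never
  fire and clean steps always do.
* KS p-values use the asymptotic two-sample Kolmogorov distribution.
* Welch degrees of freedom fall back to `n₁ + n₂ − 2` when both
  variances vanish.
* Empty scored sets, all-zero timing maps, out-of-range MWED, windows
  shorter than a detector's minimum, and annotation violations
  (unsorted, duplicate, or boundary-touching targets) raise
  `ValueError` with a named cause; too-short windows inside a harness
  sweep are skipped and logged instead, since they are a normal end
  effect.

## Problem sizes in the test suite

The suite exercises the framework at deliberately moderate scale —
e.g. 100 single-change samples of length 2¹⁰ per effect size for the
recovery checks, one noiseless 30-segment sample of ~2·10⁴ points for
the window sweep, windows up to length 512 for brute-force oracle
comparisons, and lengths up to 2¹⁵ for the evaluation-count fits.
These sizes are the package's own test design; the library itself has
no size limits beyond memory.

## Known limitations

* The binary/ternary descents trade localization for evaluation
  count; they are faithful to their O(log L) design, not to any
  specific prior implementation, and published results obtained with
  other implementations are not expected to be numerically
  reproducible here.
* The miss-at-+1 convention loads the rightmost distribution bin with
  miss mass; distribution plots of high-miss runs should read that bin
  together with the miss rate.
* The SSA detector cannot place a change inside its first `base_len`
  samples of a window; the harnesses mitigate this by re-windowing
  after each detection.
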