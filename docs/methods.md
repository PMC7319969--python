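# Methods

`rjcnv` detects copy-number variation (CNV) from windowed sequencing read
depths with a fully Bayesian segmentation model sampled by reversible-jump
MCMC.  This note describes the model, the inference machinery, the
synthetic-data generator, and the numerical and design choices behind
them, in enough detail to audit or extend the package.

## Signal construction

Per-base depths (samtools-depth dialect, 1-based positions) are summed
over non-overlapping windows (default 100 bp; the final window of a
chromosome may be shorter and is kept).  Two corrections follow:

* **Indefinable bases.** `R_CorrSize,i = R_Raw,i x W / (W - n_N,i)`,
  where `W` is the window's own size and `n_N,i` its count of N bases.
  Windows with more than half N bases, or zero raw depth, are excluded
  from every downstream step.
* **GC content.** A locally weighted quadratic regression of
  `R_CorrSize` on GC fraction (tricube weights, span 0.75) is fitted on
  retained windows with GC in [0.20, 0.80]; each in-range window is
  rescaled by (mean fitting-set depth)/(fitted depth at its GC).
  Windows with extreme GC (or a non-positive fitted value) are left
  unadjusted.  The smoother is evaluated on a grid of at most 201 GC
  values and interpolated, the standard way of keeping LOESS linear in
  the number of windows.  We wrote the local-quadratic smoother
  ourselves because the statsmodels `lowess` is locally linear only; a
  noiseless quadratic depth-GC relationship is reproduced exactly
  (tested), which a degree-1 smoother cannot do.

The read-depth signal (RDS) is `D_i = ln R_CorrGC,i` for a single sample
and `D_i = ln(R_CorrGC,i(case)/R_CorrGC,i(control))` for a case/control
pair (exclusion masks are unioned; natural logarithms throughout — the
base only rescales all location hyperparameters).

## Model

Windows are grouped into `M` regions by breakpoint indicators
`B = [b_0..b_I]` (`b_0 = b_I = 1`); each region carries one of `K` states
(single sample: absolute CN 1..5, normal = 2; paired: loss/normal/gain).
The unnormalized posterior is `p(B) p(C|B) p(D|B,C)` with

* `p(B) = λ^(M-1) (1-λ)^(I-M)` — i.i.d. Bernoulli breakpoints;
* `p(C|B)` — the first region's state is drawn from Dirichlet-multinomial
  weights `W0`; each later region's state is drawn from a reduced
  (K-1)-category Dirichlet-multinomial with concentrations
  `w0k/(1-w0k')` shared across all regions whose predecessor has state
  `k'`.  Integrating the weights out leaves a Pólya-urn product over
  gamma functions that depends on the sequence only through its
  transition counts.  Because each urn's concentrations sum to 1, the
  closed form normalizes exactly over neighbour-distinct sequences
  (property-tested by enumeration, and checked term-by-term against the
  sequential urn predictive).
* `p(D|B,C)` — within a region the RDSs are i.i.d. normal with conjugate
  normal–inverse-gamma priors on (mean, variance) specific to the
  region's state; the marginal per region is closed-form and is
  validated against 2-D numerical quadrature and, for single windows,
  against the location-scale Student-t predictive.

All probability arithmetic is in log space via `math.lgamma`; region
sums of `D` and `D²` come from prefix sums, so every region term is
O(1).

## Empirical hyperparameters

With `m̂ = median(D)` and `ŝ² = (1.4826 MAD)²`:

| parameter | default | meaning |
|---|---|---|
| `μ0k` | `m̂ + ln(k/2)` (single); `m̂ + [ln ½, 0, ln 1.5]` (paired) | expected RDS per state; depth proportional to copy number, one extra copy on a diploid = ×1.5 |
| `κ` | `(4 ŝ / gap_min)²`, floored at 1 | prior precision of a region mean around `μ0k`, expressed in pseudo-windows |
| `α` | 2 | inverse-gamma shape (fat-tailed, finite mean) |
| `β` | `ŝ²(α-1)` | sets `E[σ²] = ŝ²` |
| `W0` | (0.05, 0.80, 0.05, 0.05, 0.05) / (0.05, 0.90, 0.05) | prior state weights, normal-dominated |
| `λ` | `max((M_init-1)/(I-1), 1/I)` | breakpoint rate, estimated from the initialization's breakpoint density |

The `κ` choice deserves emphasis.  The NIG marginal's mean-mismatch
penalty saturates at `κ (x̄-μ0)²/(2σ²)` as the region grows, so with a
loose prior (κ≈1) adjacent copy-number states become practically
interchangeable for long regions — we measured order-of-magnitude FPR
inflation.  Tying the prior sd of a region mean, `ŝ/√κ`, to a quarter of
the smallest gap between adjacent state means makes states identifiable
at any region length while letting small regions borrow strength.  Every
constant is overridable through `RunConfig.hp_overrides` / `--config`.

## Inference

Each sweep refreshes all region states from their joint conditional
P(C|D,B) — enumerated exactly over the `K(K-1)^(M-1)` neighbour-distinct
sequences when that count is at most 200,000 and `M` is within the
configured region limit (10), otherwise by a per-region Gibbs pass with
O(1) incremental prior deltas — and then attempts one boundary move:
merge, split, trifid (split into three) or a ±1-window boundary shift,
with probabilities (1/3, 1/6, 1/6, 1/3).  The default state refresh is
the maximizing combination (mode-seeking, matching the procedure's
specification); `state_update_mode="sample"` draws exactly from the
conditional and is the mode under which the whole sampler is validated
against brute-force enumeration of every (B, C) pair on small instances.

Acceptance probabilities are Metropolis–Hastings ratios on the discrete
state space: kernel ratio times reverse/forward proposal probability,
with every uniform choice (breakpoint, boundary, region, state-keep
side, new-state draw) accounted for; the derivations are spelled out in
`rjcnv/sampler.py`.  One subtlety: a double merge (the kept state
collides with the adjacent region, which is then absorbed) is reachable
through two distinct forward paths, so its forward probability carries a
factor 2; its reverse is the trifid.  Getting this factor wrong is
detectable by the enumeration oracle, which is exactly how the test
suite pins it.

**Initialization.**  A cubic smoothing spline (penalty chosen by
generalized cross-validation; tracks longer than 6,000 windows are
reduced to 8-window block means first) is fitted to the RDSs, and
breakpoints are placed where the fitted curve crosses the 5th/95th
percentile of its own fitted values.  Two augmentations proved
necessary at low coverage: (1) a block-mean scan (widths 10/25/50
windows, two phases each, robust |z| > 3.5) seeds candidate events
shorter than the spline's GCV bandwidth, which the smoother suppresses
entirely and which the boundary moves alone would rediscover only
through a rare well-placed trifid; (2) every candidate breakpoint is
snapped to the best local two-segment changepoint within ±100 windows,
because detector-derived boundaries are only bandwidth- or
block-accurate while the ±1-window boundary walk covers ground slowly.
Region labels are biased by scan sign and threshold side; a conflict
with the neighbour-distinct constraint is resolved by redrawing.
The z threshold 3.5 makes the expected number of false seeds per
~20,000 scanned blocks of order ten; false seeds are cheap (the sampler
merges them away), missed weak events are not.

**Sections.**  The genome is cut into 0.5 Mb sections (never spanning
chromosomes); hyperparameters and the initialization are genome-wide,
but sections are sampled independently, each with an RNG stream derived
from (master seed, section index) so results are identical under any
execution order.  Sampling runs past a 5,000-iteration burn-in and stops
once two consecutive 1,000-iteration checks produce identical
BF-thresholded window calls (cap 100,000 iterations; non-convergence is
flagged, not fatal).

**Calling.**  For window `i` and abnormal state `k`, the Bayes factor is
the post-burn-in count ratio times `w02/w0k`; a window is called
abnormal if its maximum BF strictly exceeds 20 (ties break toward the
state nearest normal, then the lowest label; a BF of exactly 20 is
normal).  Runs of equal-state retained windows merge into regions,
breaking at excluded-window gaps; equal-state regions abutting across
section borders are merged, since sections are an inference artifact.
Region coordinates are window-grid resolution; the method does not
refine breakpoints below the window size.

## Synthetic data

The generator reproduces a chr20-scale benchmark design: on a 63 Mb
diploid genome, 20 deletion pieces (CN 1) and 20 duplication pieces
(CN 3/4/5 uniform), two of each size in {1, 2.5, 5, 10, 25, 50, 100,
250, 500, 1000} kb per type — 7,774,000 bp, 12.3% of the genome — placed
uniformly at random on the window grid, non-overlapping, with at least
one normal window between pieces.  The desk-scale variant divides the
genome by ten (6.3 Mb) and keeps the scaled sizes of at least 2.5 kb
({2.5, 5, 10, 25, 50, 100} kb, two per type; 770,000 bp, 12.2%).

Depth emission is window-level.  The default noise model places
single-end reads (70 bp) as a Poisson process whose rate tracks the
local copy number; each read adds its overlap length to every window it
touches.  This reproduces what matters about piled aligned reads at a
given coverage: window-sum variance of order read_length × mean (ln-sd
≈ 0.62 at the 2.2× preset vs ≈ 0.16 at 22×), a small point mass at
exactly zero depth, and short-range correlation across window borders.
A pure per-base Poisson option (`noise="poisson"`, variance = mean)
exists as the idealized emission the hierarchical model assumes; under
it low coverage is barely harder than high coverage, which contradicts
the published coverage effect, so the read-process model is the
default.  An optional multiplicative GC bias (with synthetic smooth GC
fractions) exercises the LOESS correction path.

What the generator does **not** emulate: mappability and
reference-error artifacts, shared case/control platform biases (our
paired samples are independent read processes, which makes the
log-ratio *noisier* than real pairs that share systematic biases),
PCR-duplicate structure, and within-read base-quality variation.
Passing the scaled benchmarks therefore demonstrates correct inference
under the model's own assumptions plus realistic counting noise — not
robustness to alignment pathology.

## Problem sizes used in the shipped checks

The acceptance tests run the scaled design with 4 replicates
(single-sample, 2.2× analogue), 3 replicates (paired) and 4 replicates
(22× analogue, matched seeds), and the posterior-enumeration oracle on
20 instances of up to 8 windows; `scripts/acceptance.py` recomputes the
high-coverage accuracy from 5 fresh replicates.  These sizes keep the
full suite inside a routine CI run while leaving the Monte-Carlo error
of each reported mean well below the comparison tolerances.

## Known limitations

* At the 2.2× analogue, 2.5 kb events sit at ≈3.3σ (gains) on the
  regional mean, so their posterior support is genuinely marginal:
  detection rates below 100% at low coverage are the correct answer,
  not a sampler failure (they recover fully at 22×).
* Region-edge windows inherit the posterior's boundary uncertainty
  (several windows at 2.2×) through the cumulative-count Bayes factors,
  so base-level recall on a design whose pieces are at most 100 kb runs
  one-to-two points below what the same edge error produces on
  megabase-scale pieces.
* The mode-seeking default state update is not a draw from the
  conditional and breaks detailed balance by design; use sample mode
  for posterior summaries you intend to interpret as probabilities.
* Zero-depth windows are excluded, so homozygous deletions (CN 0)
  are visible only through flanking CN 1 calls and exclusion gaps.
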