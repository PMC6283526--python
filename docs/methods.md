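# Methods

## Scope and data model

cetsakit processes protein-level quantification tables from 10-plex
isobaric-labeling CETSA experiments. Three designs share one in-memory
vocabulary: a `ChannelMap` assigns the ten reporter channels a temperature
(melt: 37–64 °C in 3 °C steps), a concentration (ITDR), or a time point
(ITTR), plus treatment/replicate labels and the reference channel (always
the lowest x). Fold changes are channel abundance divided by the reference
abundance, so the reference entry is exactly 1 by construction. Missing
channels are carried as NaN and propagate through every stage; a curve
needs ≥8 of 10 usable points to be fitted (a 4-parameter model wants
comfortable residual degrees of freedom) and pairwise curve distances
require ≥8 shared points, consistent with the fitting floor.

## The LL.4 model and its fitter

All curve fitting uses the four-parameter log-logistic model
`f(x) = c + (d−c)/(1 + exp(b·(ln x − ln e)))` with the natural logarithm, so
`e` is directly the melting temperature (°C), inflection dose (µM) or
inflection time (min). Inversion is closed-form
(`x = e·exp(ln((d−y)/(y−c))/b)`), defined for y strictly inside (c, d).

The fitter is a projected Levenberg–Marquardt iteration, batched over
thousands of curves at once (stacked numpy arrays, batched 4×4 normal-
equation solves). Internally it optimizes (b, c, d, ln e). Choices that
matter:

* **Initialization** (deterministic ladder): c₀ = min(y), d₀ = max(y),
  e₀ from linear interpolation of the first crossing of (c₀+d₀)/2, and
  b₀ ∈ {+1, +3, −1, −3}; the start with the smallest residual sum of
  squares wins, ties to the first. No random restarts anywhere.
* **Bounds**: c, d ∈ [−0.5, 3·max(y)] (fold-change data is scale-bounded
  near 1), e ∈ [min(x)/10, 10·max(x)], |b| ≤ 50. Bounds are enforced by
  projecting trial steps.
* **Stopping**: relative step < 1e-10, relative SSR gain < 1e-10, damping
  exhausted, or 2000 iterations. Noiseless parameter recovery on the
  10-point melt grid is accurate to ~1e-11 per parameter.
* **R²** is 1 − SS_res/SS_tot about the observed mean; constant data
  (SS_tot = 0) returns R² = 0 and a degenerate-but-converged fit with
  d ≈ c. Fewer than 5 usable points returns a failed fit, not an
  exception.

Zero doses/times (buffer-only, t = 0 channels) are mapped to a pseudo-dose
one ladder step below the lowest nonzero x (lowest x divided by the largest
successive ratio of the ladder) for log-axis fitting and AUC.

## Normalization

**Melt.** Per run: per-temperature medians over *all* quantified proteins
(not a curated "typical melting curves" subset) are fitted with LL.4; the
normalization factor per channel is `scaling · fitted/raw` with
`scaling = 1/fitted[37 °C]`. After application the per-temperature medians
lie exactly on the scaled fitted sigmoid and the 37 °C median is exactly 1.
If the median fit fails or is degenerate (R² < 0.5 — e.g. a run with no
melting trend), identity factors are returned and the run is flagged rather
than silently rescaled. Normalizing an already-normalized run reproduces
factors within ~1e-15 of 1 on clean data.

**ITDR/ITTR.** Channel-wise median-to-1: each channel is scaled so its
median fold change across proteins is exactly 1 (the reference channel is
already 1). The published description ("adjusting the median fold change to
be 1.0") does not say whether the rescaling is channel-wise or one global
constant; channel-wise is the default because it makes a null protein flat
at 1 — the geometry the baseline band presumes — and a `global` mode is
available as a config switch. A single-protein run is degenerately forced
to all-1, which is documented behavior, not an error.

## Baseline band and hit criteria

The band pools the fold changes of all proteins (and both technical
replicates) at the `n_low = 3` lowest dose groups and takes
`median ± 2.5·MAD`, MAD scaled by the normal-consistency constant 1.4826
(both configurable). Fold changes at the reference channel are excluded
from the pool by default: they are 1 by construction (a value divided by
itself) and carry no information about technical variance; including them
would deflate the MAD by mixing in a point mass at zero deviation. With
lognormal ratio noise σ the band spans ≈ ±2.5σ and ~1.2 % of genuine
baseline points fall outside it (2·Φ(−2.5)), which the tests verify by
Monte Carlo.

The criteria chain per replicate: any point outside the band; a ≥30 %
effect beyond the band edge at one of the `n_high = 3` highest doses
(multiplicative by default, FC ≥ 1.3·upper or FC ≤ lower/1.3 — the
published wording is ambiguous between multiplicative and additive, so an
additive ±0.3 mode is configurable); fit R² > 0.8; ≥3 PSMs. The four
criteria are evaluated independently (the band exit need not be at the same
dose as the 30 % effect). When both direction branches fire on a
non-monotone curve, the direction with the larger |ln FC| wins and the call
is flagged `ambiguous_direction`.

**Replicates.** A consensus hit must pass the full chain in every technical
replicate with the same direction; proteins present in a single replicate
are called per replicate but never promoted. The consensus MDT is computed
from a pooled LL.4 fit of all replicates' points (20 points for a
duplicate design) intersected with the band edge — a lower-variance
estimator than averaging two per-replicate crossings — with the geometric
mean of per-replicate MDTs as fallback when the pooled fit has no crossing
in range. MDTs are clipped to [lowest nonzero dose, highest dose]; a curve
already beyond the edge at the lowest dose is flagged `saturated`, a
zero-width band (MAD = 0) falls back to `median·(1±0.01)` and is flagged.

The AUC summary is the trapezoidal mean of (FC − 1) over the log10 dose
axis (flat-at-1 ⇒ 0), exported per protein together with mean R² and MDT
for the AUC-vs-R² overview plot data.

The 37 °C abundance control flags proteins whose treated/control abundance
ratio deviates more than 10 % (configurable) — a CETSA signal for such a
protein confounds stability with expression; zero/missing control values
are flagged `unassessable`. Note that a 10 % cut is only a ~2σ threshold
when each measurement has a 5 % CV, so a few percent of null proteins are
expected to be flagged; the tests assert agreement with that normal-theory
rate.

## EDS ranking

For each complete-subset protein of a 2 control + 2 treatment melt design:
pairwise Euclidean distance between melting curves in 10-space with
pairwise deletion of missing points (≥8 shared required);
`ΣED(inter-treatment)` over all 4 control×treatment pairs (cross-replicate
pairs included); `ΣED(inter-replicate)` over the 2 within-condition pairs;
`EDS = ΣED_it / (K·ΣED_ir)` with K = 10 by default. K only rescales and
never changes the ranking (the formula's purpose), so it is exposed as
`eds_denominator_constant`. Ranking: infinite EDS first (identical
replicates, nonzero shift; ordered by inter-treatment sum), finite scores
descending, the 0/0 case (four identical curves) near the bottom, proteins
without a complete 2+2 design last; protein id is the final tie-break so
the order is permutation-stable. The plot book renders one PDF page per
complete-subset protein in this order, with replicate points, fitted
control/treatment curves and per-run peptide/PSM annotations.

## Synthetic experiments

The generator emulates the measurement chain far enough to validate every
stage, with all randomness drawn from a mandatory seed (identical configs
give byte-identical tables):

* **Melting**: logistic soluble fraction in linear temperature,
  `plateau + (1−plateau)/(1+exp(slope·(T−tm)))`, with per-protein
  Tm ~ N(52, 4) °C (52 °C being the median melting temperature of a
  human-cell soluble proteome), slope ~ U(0.4, 1.2) /°C and residual
  plateau ~ U(0, 0.3).
* **Binding**: single-site occupancy `dose/(dose+K_d)` shifting Tm by up to
  `max_tm_shift` (default 4 °C) at saturation; ITTR occupancy rises as
  `1 − exp(−t·ln2/halftime)` at saturating dose.
* **Measurement**: base abundance × soluble fraction × multiplicative
  lognormal noise (σ = 0.08 default; reporter ratios are ratio-scale).
  Melt runs draw noise for every channel; isothermal designs draw it on
  the response ratio, leaving the reference abundance exact. Per-channel
  missingness and PSM/peptide evidence counts (1 + Poisson(6)) complete
  the tables.
* **Designs**: 10-point melts 37–64 °C in duplicate control + duplicate
  treatment; 10-dose 4-fold ITDR ladders topping at 25 mM in technical
  duplicate at a 52 °C isotherm; 10 time points for ITTR. An optional
  37 °C no-heat control table lets a configurable fraction of non-binders
  change expression (lognormal(0, 0.15)) to exercise the abundance
  control.

**Spike-in design.** Binder labels go only to proteins for which the
programmed effect is observable: ≥3 PSMs, and (ITDR) an apparent
dose-response plateau ≥1.5 given the protein's latent K_d — drawn
log-uniform over 0.4–400 µM, i.e. doses 2–7 of the ladder, since an EC50
above the seventh dose cannot be bracketed by the top-three-dose effect
rule — or (melt) Tm inside [tm_mean−1.5σ, tm_mean+1σ] so a shift is visible
within the sampled window. This mirrors how a validation spike-in is
designed inside an assay's dynamic range, and matches the published
observation that a single-isotherm ITDR misses proteins melting far from
the chosen temperature.

**Deliberate model mismatch.** The melt generator works in linear
temperature while the analysis fits log-temperature LL.4, so melt tests are
not circular; over 37–64 °C the approximation recovers Tm to ~0.1 °C
noiselessly. Setting `melt_in_log_temperature=True` makes generated curves
exactly LL.4-representable (residuals < 1e-9), which the tests use as a
strict parameter-recovery oracle. What the simulations do **not** model:
peptide-level rollup, co-isolation interference, TMT channel cross-talk,
abundance-dependent noise, and batch effects between MS runs — so passing
tests demonstrate correctness of the processing chain under the stated
noise model, not robustness to every artifact of real instrument data.

## Validation results and known limitations

Problem sizes for the proteome-scale checks: 5000 proteins × 2 technical
replicates per screen, 20 independent seeds for the null control, 200
spiked binders for recovery, and a 500-protein duplicate melt design for
EDS — matching the scale at which the acceptance checks specify them.

* The 20-seed null screen yields zero consensus hits in every seed: the
  dual-replicate rule makes chance passage of all four criteria in both
  replicates (same direction) vanishingly rare.
* Spike-in sensitivity is 0.88–0.94 across seeds with zero false
  positives and Spearman(MDT, K_d) ≥ 0.91. Sensitivity is bounded by an
  interaction of the criteria themselves: with σ = 0.08 the band edge sits
  near 1.20, so the 30 %-beyond-band rule demands FC ≥ 1.57 while binders
  with plateaus of 1.5–1.6 are admitted by design; those marginal binders
  pass only with favorable noise in *both* replicates, and the R² > 0.8
  requirement doubles the jeopardy. A screen aiming at such weak effectors
  would need lower reporter noise or more replicates, not looser
  thresholds.
* In the duplicate melt design, 16–20 of 20 binders (seed-dependent)
  exceed the 95th percentile of the non-binder EDS distribution. The
  stragglers have shallow melting slopes and plateaus near 0.3, giving a
  +3 °C shift a Euclidean signature (~0.4) inside the null tail — a real
  limitation of distance-based ranking for marginal melters, and the
  reason hit confirmation belongs to the dose-response arm.
* All outputs are deterministic: repeated runs on identical configs and
  inputs are bit-identical (PDF metadata is written without timestamps),
  and every output directory carries a manifest of config and input
  hashes.
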