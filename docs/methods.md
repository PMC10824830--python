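# Methods

## Signal model and pipeline

The pipeline treats each dyad as two seated interactants whose torso motion
is informative mainly along the **proximity axis** — the line between them.
Processing per dyad (and per analysis segment) is fixed in this order:

1. **Torso centroid.** Unweighted per-frame mean of the interactant's
   available back markers (up to four: upper/lower × left/right). Identifier
   markers never enter the analysis.
2. **Projection.** The axis is the unit vector between the two time-mean
   centroids, estimated once per segment, not per frame: the geometry is
   quasi-static, and a per-frame axis would leak the partner's motion into
   one's own projection. Orientation is *approach-positive for both sides*
   (the sign flips for the second interactant). This convention is what makes
   the downstream correlation signs readable: positive = symmetric
   (mirror-like, both approach/retreat together), negative = asymmetric
   (one approaches while the other retreats). A shared-world-axis projection
   would invert the reading for one side.
3. **Differentiation.** First differences, mm/frame. The correlation
   statistic is scale-invariant, so mm/frame is never converted to mm/s.
4. **Low-pass filter.** Causal single-pole recursion
   y[t] = y[t−1] + α(s[t] − y[t−1]) with α = Δt/(RC+Δt), RC = 1/(2πf_c),
   f_c = 10 Hz by default (α ≈ 0.3437 at 120 fps). The filter is single-pass
   on purpose — a forward–backward pass would be a different, zero-phase
   two-pole filter. Initialization y[0] = s[0] avoids a startup-transient
   bias; a decaying transient of relative weight (1−α)^t remains, which is
   why a noiseless echoed dyad correlates to 1 within ~10⁻³ rather than
   exactly.

## Correlation and pooling

The per-lag statistic is the **uncentered** product-moment coefficient
r = Σab / √(Σa²Σb²). Speeds fluctuate around zero, so centering is
unnecessary by construction; an optional centering flag exists to quantify
the difference on data with offsets. Delayed correlations (default grid: 0
plus 100–1500 ms in 100 ms steps, exact frame counts at 120 fps, rounded to
the nearest frame otherwise) hold the storyteller's series fixed, shift the
child's, and trim non-overlapping ends, so the pair count at lag L is
m = n − |L|. Zero-energy slices make r undefined at that lag; the lag is
flagged missing and excluded from pooling rather than fabricated.

Pooling maps each dyad's rᵢ to xᵢ = atanh(rᵢ) and averages **unweighted**
across dyads; the standard error is 1/√(Σmᵢ). The se formula strictly assumes
similar mᵢ across dyads (equal-length recordings); an inverse-variance
weighted mean is available behind a flag for sensitivity analysis.
Correlations numerically at ±1 (possible on tiny noiseless segments) are
clamped to ±(1−10⁻¹²) with a warning so pooling never produces infinities.

Confidence bands multiply the pooled se by the two-sided normal quantile at
the Bonferroni-corrected level α/k (defaults α = 0.001, k = 41, corrected
p ≈ 2.4×10⁻⁵) and back-transform endpoint-wise through tanh. k is an explicit
parameter, never derived from the grid length: the comparison count and the
grid are conceptually distinct (a symmetric ± grid would double the lags but
not the reading). Contrasts are differences in Fisher space with standard
errors in quadrature; the result is a *comparative* level of coordination.
The within-dyad climax contrast defaults to post − pre ("the change created
by the climax"); a direction switch exists. Between-group contrasts subtract
the baseline group's climax-contrast curve (baselines: the 3-year-old group
for age, the PII condition for condition), with the two groups pooled over
the other factor first.

## Calibration caveat: serial correlation

The 1/√m standard error treats the m sample pairs as independent. That holds
for white-noise speed signals but **not** after low-pass filtering or for
smooth (autocorrelated) base motion: serial correlation inflates Var(r)
beyond 1/m, making the band anticonservative. The null-calibration study
therefore feeds white-noise speed pairs directly into the correlation and
pooling stages — the regime where the method's own assumption holds — and
confirms the family-wise rate stays at its nominal level there. On
realistically smooth, filtered signals an occasional spurious flag at an
uncoupled lag is expected (and observed in the analysis runs); surrogate-pair
or permutation nulls would fix this but are outside the pipeline's scope.

A related, benign effect: filtering *raises* the measured correlation at the
coupling lag above the unfiltered closed form ρ = gσ_s/√(g²σ_s²+σ_ε²) when
the base motion is smoother than the coupling noise, because the filter
removes proportionally more noise than signal. The parameter-recovery study
therefore scores peak *location and sign*, not magnitude.

## The synthetic generator

The generator emulates the kind of session the pipeline analyses: two
interactants seated
1.2 m apart facing each other along x, four back markers each (fixed offsets
averaging to zero, so the centroid recovers the torso path exactly), 120 fps,
~5-minute sessions with a climax partway through, and 0.5 mm marker jitter
(reflecting an optical system's sub-millimetre resolution floor, not a
measured noise level).

* Storyteller speed: zero-mean stationary AR(1), default sd 1 mm/frame
  (~12 cm/s — gentle seated sway) and smoothness φ = 0.9 (smooth,
  torso-scale motion). No quantitative description of real torso speed
  spectra was available, so these are declared package defaults, reported
  with every analysis, not estimates of any dataset.
* Child speed: c[t] = Σ_k g_k·s[t−L_k] + ε[t], with separate coupling sets
  before and after the climax frame. Positive gain ⇒ symmetric coordination,
  negative ⇒ asymmetric, by the orientation contract. Default: a single
  g = 0.1 coupling at 500 ms, post-climax only, with ε sd 1 mm/frame —
  producing aggregated R values of the few-hundredths-to-tenths order typical
  of spontaneous-coordination studies.
* Coupling acts on **speeds**, because the statistic does. Positions are
  leaky integrals (drift coefficient 0.999 per frame, ~8 s time constant) so
  seated posture stays bounded; the resulting stationary postural sway is
  ~0.1 m sd. The leak perturbs speed recovery by ≤0.001·position per frame,
  which is negligible at the analysis scale.
* Determinism: one RNG stream per dyad, seeded base_seed + index; study-level
  drivers derive per-dyad seeds through `SeedSequence`. Regenerating a corpus
  from the same seed is byte-identical.

What the generator does *not* emulate: gesture and facial expressiveness,
biomechanical posture constraints, occlusion patterns of real capture
volumes, or heterogeneous dyad-level coupling strengths. Passing tests
therefore demonstrate the pipeline's arithmetic and inferential behavior
under its stated assumptions, not ecological validity on real recordings.

## Problem sizes and numerical choices

Simulation studies use one-minute sessions at 120 fps (7200 frames) and
groups of 10–50 dyads with 50–200 replicates — sizes at which the Monte-Carlo
error of the reported rates is far below the decision thresholds, chosen as
the package's standard validation scale. Tie-breaks: peak finding reports the
first lag of a plateau; the climax frame is floor(t_climax·fps), with the
boundary frame opening the post segment; gap filling interpolates only
interior runs (a run touching either end has no anchor and stays missing).
Dyads with more than 10% missing samples after filling are excluded with a
logged, machine-readable reason — an artifact QC policy, not a claim about
any particular study's criterion.

## Known limitations

* The se ≈ 1/√Σm band is exact only for serially independent pairs (see the
  calibration caveat); treat flags on strongly autocorrelated data as
  descriptive unless checked against surrogate nulls.
* The uncentered statistic is offset-sensitive; it is correct for speeds,
  not for general signals (the centering flag exists for diagnosis).
* Pre/post segments are trimmed independently; correlations never span the
  climax boundary, so a few lag-lengths of data near the boundary contribute
  to only one segment.
* C3D and proprietary capture formats are out of scope; the long-format CSV
  dialect is the single interchange format.
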