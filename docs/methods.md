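# Methods

`zebranvu` quantifies neurovascular-unit phenotypes in larval zebrafish from
three data streams: tracked free-swimming trajectories in half-darkened
12-well plates, single-plane fluorescence time series of spontaneous neuronal
calcium activity, and two-channel 3-D lightsheet stacks of the optic tectum.
All group comparisons follow a 2x2 factorial design — osmolyte (20 mM
mannitol or glucose, 4–9 dpf) crossed with the nitric-oxide donor SNP
(0.1 mM, 8–9 dpf).  This note records the models, the tunable parameters and
the numerical choices; nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Behavioural endpoints

### Zones, segmentation, artefact filter

The well is a disc (default radius 11 mm, a 12-well-plate well) split by a
diameter divider; a point is *dark* when its signed distance along the
divider normal is positive, and points exactly on the divider count as light
(a deterministic tie-break on a measure-zero set).  A trajectory is split
into maximal runs of constant zone.  Single-frame zone flickers produced as
a larva skims the divider are removed by discarding segments whose *point
count* falls strictly below the 1st percentile (linear-interpolation
definition) of the per-recording segment-size distribution.  Three choices
here were genuinely open and are configurable:

* segment "length" = sample count, not arc length — the artefacts being
  removed are single-frame flickers, which sample count targets directly;
* the percentile is computed per recording, not pooled across a cohort, so
  one larva's endpoints never depend on who else was analysed;
* light/dark **transitions are counted on the unfiltered label sequence**
  (a transition into a zone is a behavioural event even if the resulting
  visit was brief); the filter only gates the geometric features.

Strict `<` comparison at the threshold means a uniform-length input loses
nothing, and re-applying the filter at the same threshold value is a no-op.

### Speed classes and time budgets

Inter-frame speeds (Euclidean displacement over Δt) are classed with the
tracker's bands, implemented as half-open intervals [0, 3.3), [3.3, 6.4),
[6.4, ∞) mm/s (inactive / low / high).  The printed band edges leave
(6.3, 6.4) unassigned — a rounding artefact of the tracker's display — and
the half-open convention is the unique exhaustive, order-preserving
completion at the stated precision.  Budgets are computed in 1-min bins:
per bin, % of time in light and, within each zone, % of *zone* time per
speed class (so activity measures are not confounded by light preference);
bins are then averaged with equal weight, excluding from a zone's average
any bin with no time in that zone.  15-min block summaries average the bins
inside each block.  An interval inherits the zone of its starting point.

### Geometric path features

For every kept segment the package fits the minimum-area enclosing ellipse
and derives

* eccentricity ε = √(1 − (b/a)²) — 0 for a circle, 1 for a line;
* MPDE — mean distance of the segment's points to the ellipse centre (mm);
* MPDC — mean distance of the segment's points to the well centre (mm),
  the thigmotaxis readout.

Per-larva, per-zone endpoints are unweighted means over kept segments.
Zones a larva never visited carry missing values, not zeros.

**Ellipse solver.**  Khachiyan's dual coordinate-ascent with Todd–Yıldırım
away steps, run on the convex-hull vertices only (the enclosing ellipse
depends on no interior point; hull reduction makes thousand-point segments
cheap).  Points are centred and scaled to unit extent first — without this
the lifted 3x3 system is badly conditioned for segments far from the origin.
The 3x3 inverse is maintained by Sherman–Morrison rank-1 updates with a
periodic refresh against round-off drift.  Because first-order ascent can
zigzag for ~10⁵ iterations when the optimal support has five active points,
once the dual gap falls below 10⁻⁵ a damped Newton solve of the KKT
conditions (Mᵢ = d+1 on the support, using ∂Mᵢ/∂uⱼ = −(qᵢᵀX⁻¹qⱼ)²) finishes
to the target tolerance (default 10⁻⁷, iteration cap 10⁵; non-convergence
raises).  After convergence the shape matrix is rescaled so the farthest
point sits exactly on the boundary: containment is then guaranteed, at an
area cost bounded by the dual gap.  Degenerate inputs (fewer than 3 distinct
points, or collinear) return a flagged segment fit with a = half the largest
pairwise extent, b = 0, and ε defined as 1.

## Calcium transients

F₀ is a low percentile (default 20th) of the raw trace, either global or as
a rolling window (default 30 s) when the baseline drifts; ΔF/F₀ = (F−F₀)/F₀.

Detection is matched-template filtering.  The ΔF/F₀ series is detrended
with a running 20th-percentile baseline (20 s window, re-centred), then
correlated with a causal exponential template of time constant τ = 2 s (the
indicator's decay), normalised so a clean transient of amplitude A scores A
at its onset.  Pooling the whole decay instead of the single peak sample
roughly doubles the effective SNR, which is what makes events at ~5x the
noise sd reliably detectable.  Local maxima of the score above the
threshold, with prominence at least 0.4x the threshold (suppressing shoulder
echoes on decay tails), are events; detected templates are then peeled off,
the baseline re-estimated from the cleaned trace, and detection repeated
(2 refinement rounds) — this removes the bias neighbouring transients exert
on a rolling baseline.  The threshold defaults to 3x a robust noise sd with
a floor of 0.01 ΔF/F₀; the noise sd is 1.4826·MAD of the first-differenced
series divided by √2, which stays clean even when transients occupy a large
fraction of the trace (a plain MAD of the detrended series does not).
Events within 2 s merge, keeping the larger — two true events closer than
that are not resolvable at this bandwidth and are deliberately reported as
one, so a frequency estimate at the default separation is slightly censored
at high rates; the rate-recovery checks tighten the separation to 0.5 s
where an uncensored estimate is wanted.  Transient frequency is
60·count/duration (events/min).  Because the baseline is percentile-based
and the threshold noise-scaled, the detected count is invariant to affine
gain/offset changes of the raw fluorescence.

## Image quantification

Stacks are (channel, z, y, x) voxel arrays with physical voxel size attached
(default 0.6 x 0.6 x 1.0 µm, the lightsheet acquisition geometry).
Quantities:

* **Maximum-intensity projection** over z.
* **Vessel mask**: threshold of the MIP (Otsu by default, fixed threshold as
  an override; the realised threshold is always logged) with specks below
  50 px removed.  On a Gaussian-profile ridge Otsu lands below the half
  maximum, so its mask is somewhat wider than the FWHM tube — a property of
  the estimator, not an error; a fixed half-maximum threshold reproduces the
  FWHM mask.
* **Vascular length**: topological skeleton of the 2-D mask; length = Σ over
  adjacent skeleton-pixel pairs of 1 (axial) or √2 (diagonal) pixel steps,
  times the pixel size.  Length is measured on the projection, matching how
  the per-animal endpoint normalises projected reporter intensity.
* **Vessel-normalised intensity**: total signal-channel intensity inside the
  mask divided by vascular length (a.u./µm) — serves both the endothelial
  reporter and NO-indicator endpoints, and is invariant to any signal
  outside the mask.
* **Tissue-ROI mean**: mean voxel intensity over a fixed 3-D box given in
  config (no automatic tectum detection) — serves the glial/channel
  immunostain endpoints.
* **Mural nuclei**: 3-D threshold (Otsu or fixed) inside the ROI, connected
  components at 26-connectivity, discard components below 4 µm³, count.
  Otsu thresholding makes the count invariant to detector gain.

## Synthetic data

The generators are pure functions of their parameter objects (seed
included) and return full ground truth, so every downstream stage is tested
by parameter recovery.  They emulate the *statistical structure* the
analysis assumes — not larval biomechanics: no beat-and-glide kinematics,
no acclimatisation dynamics, no photon-physics in the stacks.  Passing
tests therefore demonstrate correctness of the measurement chain, not
performance on real recordings.

**Trajectories** are correlated random walks at dt = 0.1 s for 3600 s (the
1-h assay): a three-state continuous-time Markov chain (inactive/low/high;
default dwell structure gives roughly 70/20/10% occupancy) drives step
length with per-state speeds 1.0, 4.8, 9.0 mm/s (each inside its class
band); heading evolves by wrapped-normal turns (variance 1/κ, κ = 4) plus a
thigmotactic drift toward the wall (wall_attraction, rad/s scaled by
(r/R)²); the wall reflects specularly.  Divider crossings are accepted with
side-dependent probabilities — into dark with (1−p_light)/crossing_bias,
into light with min(1, p_light·crossing_bias) — so that, by flux balance
across the symmetric halves, the long-run light occupancy approximates
p_light (default 0.8, the control preference), and crossing_bias = ∞ pins
the larva to its starting side.  Treatment presets encode only effect
directions: glucose lowers p_light to 0.6, doubles the activation rates out
of inactivity and raises wall_attraction to 3; both SNP co-treatment arms
equal control (full rescue).  The magnitudes are arbitrary package defaults
chosen once for clear direction recovery at n = 40/group; the package makes
no claim to reproduce real effect sizes.  Cohorts derive per-larva seeds as
base_seed + index.

**Calcium traces**: F(t) = baseline + slow sinusoidal drift (period fixed to
duration/3) + Σ events of amplitude·baseline·exp(−(t−tₖ)/τ) + Gaussian
noise; event times homogeneous Poisson.  Defaults: 5 Hz sampling, 300 s,
baseline 100 a.u., τ = 2 s, rate 0.05 /s (3/min), amplitude 0.3 ΔF/F₀,
noise 1 a.u.

**Stacks** (default 40 x 120 x 160 voxels at 1.0 x 0.6 x 0.6 µm): vessels
are tubes with Gaussian radial profile (σ = radius/2) rendered from 3-D
centrelines via a sampled distance transform; the ground-truth mask is the
projected FWHM isocontour and the ground-truth length the polyline arc
length.  The green channel carries the same tube profile at `green_level`.
Nuclei are isotropic Gaussian blobs (σ = 1.5 µm) placed on the vessels at
least 5σ apart — at that spacing the inter-blob intensity saddle stays
below any sensible threshold, so separate nuclei cannot merge into one
component.  `red_vessel_level = 0` emulates a nuclear-only red reporter
line (the mural-cell counting experiment images different transgenics than
the NO-reactivity one, so the red channel's composition is a parameter).

## Group statistics

Per endpoint: Shapiro–Wilk normality per design cell (reported and warned
on, never acted on — no automatic nonparametric fallback), two-way ANOVA
with interaction using type-II sums of squares (on the balanced designs used
throughout, types I/II/III coincide; type II degrades most gracefully under
mild imbalance), and pooled-variance pairwise t-tests with Sidak adjustment
p_adj = 1 − (1 − p)^m.  The default family is the four contrasts the study
design draws: mannitol vs glucose, glucose vs glucose+SNP, mannitol vs
mannitol+SNP, mannitol vs glucose+SNP; the fully crossed six-pair family is
available.  Significance bands follow the standard asterisk convention
(0.05 / 0.01 / 0.001 / 0.0001).  Note that under a full-rescue design the
glucose effect appears in the interaction term and the mannitol-vs-glucose
contrast, not in the osmolyte main effect (which averages treated and
rescued arms).

Statistical calibration (type-I error of the interaction test, power at
large effects) is checked by simulation with normal per-larva endpoint
draws at n = 12/cell — the ANOVA's own null model; these simulations
exercise the statistics module, independently of the behaviour generator.

## Problem sizes and determinism

All randomness flows through integer seeds (`numpy.random.default_rng`);
hypothesis profiles are derandomised.  The suite's simulation sizes are:
200 one-hour larvae plus a single 10-h run for light-occupancy recovery;
40 larvae/group for direction recovery; 40 seeded traces for
detection scoring and 200 for rate recovery; 1000 null ANOVA datasets for
the type-I check; 12 larvae/arm at 600 s recordings for the end-to-end
chain.  These sizes put Monte-Carlo error comfortably inside the asserted
bands while keeping the whole suite in minutes on one CPU.

## Known limitations

* The trajectory model's occupancy approaches `p_light` only in the long
  run; over 1 h the realised cohort mean sits 2–3 percentage points below
  the asymptote (initial placement on the light side does not fully offset
  finite-time mixing), which is why recovery is asserted against a long-run
  simulation of the same model rather than against the nominal parameter.
* Transient detection censors event pairs closer than the merge separation;
  at 3/min this is a ~5–8% undercount at the 2 s default.
* Skeleton length on a digital grid is direction-dependent at the few-%
  level (√2 diagonal steps); rotation robustness is bounded at 8%, not
  exact.
* The statistics module assumes one observation per larva (no repeated
  measures, no mixed models).
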