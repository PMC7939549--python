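# Methods

This note documents the models, parameter choices and numerical decisions
behind `lamindyn`, and what the synthetic-data tests do and do not show
about real microscopy data.

## Image quantification

**Segmentation.** Nuclei are found on the lamin channel by a global Otsu
threshold, hole filling (a bright peripheral rim around a dimmer interior
thresholds as a ring; filling recovers the full disk), a minimum-size filter
(default 64 px), and a watershed split of touching objects seeded at local
maxima of the Euclidean distance transform. Huang's fuzzy-entropy threshold
is reserved for intranuclear structure detection, where the bright puncta
sit on the nucleoplasmic background; it is implemented in
`imagequant.threshold_huang` (256-bin histogram, class memberships
`u = 1/(1+|x−μ_class|/C)`, Shannon fuzziness minimized).

**Region partition.** The nucleoplasm is the nucleus eroded by the rim
width with a Euclidean disk footprint (rim in pixels rounded to the nearest
integer, at least 1); the periphery is the set difference, so the two
regions are disjoint and tile the nucleus exactly. The rim defaults to
0.8 μm — the one rim value the assay family defines (the structure-analysis
exclusion rim) — and is configurable, since the erosion depth used by
interactive plugins is rarely recorded.

**Projection statistics.** The nucleoplasmic intensity is the median over
nucleoplasm pixels of the z-minimum projection; the peripheral intensity is
the 75th percentile over periphery pixels of the z-maximum projection.
Projection first, statistic second: the order matters and is fixed here.
The min/max pairing makes the nucleoplasm read-out robust against
out-of-focus peripheral signal bleeding inward and the periphery read-out
robust against the rim being thinner than the erosion band. Single planes
serve as both projections. The ratio is invariant under global intensity
scaling; no background subtraction is applied by default.

**Time-series normalization.** Ratio series are normalized to an anchor
frame. The automatic anchor is the last index before the first point that
exceeds the running baseline mean by 2 baseline SDs (the multiple is
configurable); this operationalizes "the moment preceding a significant
increase" when the onset is not annotated.

**Cell-cycle staging.** Integrated DNA-stain density per nucleus is summed
over the nucleus footprint (all z-planes for stacks). Gates
`(g1_low, g1_high, sg2_high)` assign G1 to `[g1_low, g1_high)` and S-G2 to
`[g1_high, sg2_high]`; everything else is unassigned. Gates are
user-supplied (typically the antimode and the right tail of the bimodal
histogram) — no automatic mixture fit is attempted.

**Structure detection.** Candidates come from a Huang threshold of the
z-average projection restricted to each nucleus; 4-connected components are
kept if their area is within 0.0001–5 μm² and their centroid (nearest
pixel) lies farther than 0.8 μm from the nucleus boundary by the exact
Euclidean distance transform. Inclusion is centroid-based: a particle
overlapping the rim but centred inside it counts. Zero particles is a valid
result.

## Continuous photobleaching

The published analyses of this assay delegate the trace decomposition to a
separate algorithm; here the operational definition is a constrained
two-exponential mixture, `I(t)/I0 = f·e^{−k_fast t} + (1−f)·e^{−k_slow t}`,
with the fast amplitude reported as the immobile fraction — immobile
molecules in the confocal spot bleach at the illumination rate, while the
mobile pool turns over with the unbleached nucleoplasmic reservoir and
decays slowly. The fit:

- normalizes to an initial-intensity estimate (mean of the first ~0.5% of
  samples) but frees an overall amplitude in `[0.2, 5]`, so normalization
  error does not bias `f`;
- parameterizes `k_fast = r·k_slow` with `r ≥ 5` (configurable), which
  prevents component-label swapping;
- seeds `k_fast`/`k_slow` from early/late log-slopes and the amplitude
  split from the extrapolated slow-component intercept, then runs 5
  jittered restarts of trust-region least squares;
- decimates traces to ≤ 6,000 points (from the native ~60,000 at 1 kHz ×
  60 s) for speed;
- reports `f = 0` when the fitted fast component decays by less than 5%
  over the whole measurement — an undecayed "fast" component is
  operationally mobile, and the mixture is otherwise unidentifiable on a
  near-constant trace.

Synthetic traces use an initial intensity of 1, so the noise SD is relative
(SNR 50 ⇔ `noise_sd = 0.02`). Measured recovery on those conditions:
single-trace error within ±0.05 and cohort bias below 0.02 across immobile
fractions 0.1–0.7.

## FCS

The correlation model is the triplet-3D form (one dark state, two diffusing
species by default):

    G(t) = [1 + Σ_j T_j(e^{−t/τ_trip,j} − 1)]
           · Σ_i ρ_i [1+(t/τ_D,i)^{a_i}]^{−1} [1+(t/τ_D,i)^{a_i}/k²]^{−1/2}
           + G_∞

Fixed by default at the calibrated instrument values `k = 7.92`,
`V_eff = 0.267 fl`, `a_i = 1`, one triplet state, two species — all
overridable. Derived quantities use `w0 = (V_eff/(π^{3/2}k))^{1/3}` with
1 fl ≡ 1 μm³ (0.267 fl → w0 ≈ 0.182 μm) and `D_i = w0²/(4τ_D,i)`, which
holds to machine precision by construction. The fit is least squares in G
(not log G), weighted by per-lag SDs when available, with diffusion times
on a log scale, multi-start initialization spread around the curve's
half-decay lag, and species reported fast-first. Triplet lifetimes are
fitted freely by default (bounded below the half-decay lag). The software
correlator computes `G(τ) = ⟨δI δI_τ⟩/⟨I⟩²` for all integer lags by FFT
(unbiased normalization) and averages within quasi-logarithmic bins, the
software analogue of a multi-tau correlator.

The Stokes–Einstein prediction treats complexes as spheres of equal
density: `D ∝ M^{−1/3}`, so `predicted_d_ratio(m_a, m_b) = (m_b/m_a)^{1/3}`.
For 175 kDa vs 100 kDa this is 0.830.

## Telomere trajectories

Tracks are 50 points over 20.5 min (Δt = total time/(n−1) ≈ 25.1 s).
Whole-nucleus drift and rotation are removed by closed-form least-squares
rigid registration (SVD/Kabsch) of each frame's telomere constellation onto
frame 0, using telomeres visible in both frames; frames with fewer than
three usable points are left uncorrected and flagged. Registration comes
first, then the complete-track filter (all 50 points; no interpolation),
then summaries. With ~40 telomeres per nucleus the rigid fit absorbs a
negligible share of genuine per-telomere motion (6 parameters against 120
coordinates); hull volumes of drift-contaminated simulations are recovered
to better than 10% in the median.

Hull volumes use the convex hull of all track points, returning 0 for
degenerate (point/collinear/coplanar) tracks rather than erroring. MSD is
the time-averaged estimator over all ordered pairs at each lag multiple.
Population curves report the per-lag mean and the 15th–85th percentile band
(the central 70% of the population); box summaries follow the Tukey rule.

## Statistics

Proportions are arcsin(√p)-transformed, ratios log-transformed, before
parametric tests. Two-group designs report Cohen's d with pooled SD (on
the transformed scale for t tests; on raw values for Mann-Whitney, matching
how effect sizes are usually quoted next to rank tests). ANOVA uses Tukey
HSD post-hoc (statsmodels); Kruskal-Wallis uses Dunn's rank-based z tests
with tie correction and Bonferroni adjustment (implemented here);
repeated-measures two-way ANOVA delegates to statsmodels AnovaRM. All
implemented tests are calibration-checked by simulation: null rejection
rates at α = 0.05 fall within [0.035, 0.065] over 2,000 replicates.

## Synthetic data: what it does and does not emulate

The generators produce: disk nuclei with a uniform bright rim and dimmer
interior plus Gaussian read noise; lognormal 2C/4C DNA content (CV 6%,
typical of fixed-cell DNA histograms); two-exponential CP traces;
triplet-3D FCS curves with lag-proportional noise; and free
(Gaussian-step), confined (specular reflection at a sphere) or anomalous
(fractional-Gaussian increments, Hurst α/2, sampled exactly by Cholesky at
these track lengths) trajectories with shared rigid nucleus motion and
localization noise added last. Defaults follow the assay conditions: 1 kHz
× 60 s traces, 50 time points over 20.5 min, 40 telomeres per nucleus
(dozens of trackable spots in a mouse fibroblast nucleus), telomere
D ≈ 5×10⁻⁴ μm²/s.

Deliberately not modelled: optical point-spread functions, photon shot
statistics of the detection path, chromatic misalignment, intensity
gradients, segmentation-confounding cell shapes, or photophysics beyond a
single dark state. Passing recovery tests therefore demonstrates that the
estimators are unbiased and correctly implemented under their stated
models — not that they are robust to every imaging artifact of real data;
the configurable noise and geometry parameters exist so users can probe
sensitivity.

## Problem sizes

The regression suite runs population checks at sizes chosen to make the
statistical tolerances meaningful while staying quick on one CPU: 50 nuclei
for N/P recovery, 200 + 120 CP traces, 100 random tracks for the hull
oracle, 200-track MSD ensembles, and 2,000 replicates for test calibration.
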