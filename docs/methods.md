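# Methods

This note records the scientific conventions behind `ribbonquant`: what
each stage computes, which choices were genuinely open, how they were
resolved, and what the synthetic-data tests do and do not establish.

## Coordinate and unit conventions

Arrays are ordered `(z, y, x)`; the physical position of voxel index
`i` is `(i + 0.5) × voxel_size`. Default geometries follow the
acquisitions the pipeline was built for: confocal voxels of
0.2 × 0.08 × 0.08 μm (z, y, x), 2D-STED pixels of 15 nm, GCaMP
time-lapse sampling of 0.78 s. All outputs are in μm, μm², μm³, s, mV
and arbitrary fluorescence units.

## 2D-STED cluster segmentation

Per channel: Gaussian blur (σ = 1 px, reflective boundary) →
maximum-entropy threshold → distance-transform watershed → size filter
(strictly more than 50 px) → moment-matched ellipse fit.

* **Maximum-entropy threshold.** The Kapur–Sahoo–Wong criterion over a
  256-equal-width-bin histogram spanning [min, max]; candidate
  thresholds are interior bin edges; foreground is strictly above the
  threshold ("dark" background convention). The implementation is
  vectorised over cumulative sums and is verified in the tests against
  a direct per-bin enumeration of the objective.
* **Area.** Reported area is the calibrated mask area
  (pixel count × pixel area), not the fitted-ellipse area; the ellipse
  axes and orientation (from second-order image moments, equal-area /
  equal-moment convention) are retained as shape descriptors.
* **Pairing.** One pair per cropped frame; if several objects survive
  the size filter in a channel the largest objects are paired
  (largest-to-largest) — multi-object frames are rare in 1 × 1 μm crops.
* **Correlation.** Spearman rank correlation with two-sided p plus an
  ordinary least-squares regression of Ca_v1.3 area on CtBP2 area with
  95% confidence intervals on slope and intercept.

A caveat found during development: on *strictly noise-free* frames the
entire background collapses into a single histogram bin and the Kapur
arg-max becomes unstable between frames, which perturbs the recovered
area ranking (true-vs-recovered Spearman ≈ 0.92). With any realistic
read noise (the generator default) the threshold stabilises and the
ranking is preserved at Spearman ≥ 0.99.

## 3D surface reconstruction

The commercial surface algorithm is re-expressed through four documented
conventions (no claim of numerical parity):

| parameter | meaning here | default profiles |
|---|---|---|
| surface detail | σ of pre-threshold Gaussian smoothing | 0.048 μm (ribbon-wt), 0.150 (psd-wt), 0.140 (ribbon-ko), 0.163 (psd-ko) |
| max sphere diameter | background scale; background = Gaussian blur with σ = diameter/2 | 0.280 / 0.520 / 0.250 / 0.611 μm |
| split distance | minimum physical separation of watershed seeds | 0.150 / 0.150 / 0.350 / 0.350 μm |
| quality | per-object peak background-subtracted intensity; objects below threshold dropped | "auto" for ribbons, off for PSDs |

No split distance is published for PSD reconstructions; the profile
reuses the ribbon split distance of the matching condition. The quality
filter is stated for ribbon reconstructions only, so PSD profiles leave
it off.

Pipeline: local background subtraction (clipped at 0) → smoothing at
the surface-detail grain → threshold → 26-connected components →
watershed seeded by maxima of the physical-unit Euclidean distance
transform (EDT) → per-object extent refinement → quality filter →
measurement of volume and integrated intensity on the *raw* stack.

Numerical choices that matter:

* **Threshold modes.** The default auto threshold is the same Kapur
  criterion as in 2D. On sparse stacks whose few bright voxels dominate
  the histogram range, maximum entropy places the threshold mid-signal
  and discards dim puncta; the `"noise"` mode (median + 6 × 1.4826 × MAD
  of the smoothed subtracted stack) is the recommended alternative for
  such data and is what the recovery tests use. An explicit numeric
  threshold is always accepted.
* **Seeding.** The EDT is lightly smoothed (σ = 1 voxel) before peak
  finding; the discrete EDT otherwise has flat plateaus that seed one
  watershed basin per plateau voxel. Components whose maxima were all
  suppressed by a neighbour's seed are retained as their own objects so
  the labels always partition the mask.
* **Extent.** By default each object is delimited at half of its peak
  smoothed intensity (FWHM convention). A global threshold deep in the
  Gaussian tails otherwise inflates the apparent object — by ~0.5 μm in
  z for a 0.15 μm punctum under a 0.25 μm axial PSF — which would
  erode the 0.5 μm engagement rule. `extent="threshold"` restores plain
  above-threshold masks.
* **Quality "auto".** 6 × 1.4826 × MAD of the raw stack: an object's
  background-subtracted peak must clearly exceed what raw noise can
  produce. On noise-free stacks MAD is 0 and the filter is inert.

## Engagement classification

Surface-to-surface distance between voxelised objects is the minimum
physical distance between boundary-voxel centers; intersecting or
26-adjacent sets are at distance 0. This differs from a sub-voxel mesh
distance by at most one voxel diagonal (≈ 0.23 μm at the default
anisotropy); the synthetic world places its engaged/floating gaps with
margins wider than that. A ribbon is synaptic iff its nearest-PSD
distance is strictly below the 0.5 μm cutoff. The number of IHCs used
for normalisation is an explicit input (cells are counted manually in
this preparation; no algorithm is defined for it).

## Trace analysis

* **ΔF−F₀.** F₀ is the 10th percentile of the trace (default) or the
  mean of the first k samples; the mode and value are logged in the
  trace metadata. The percentile choice assumes transients occupy a
  minority of samples.
* **Peak frequency.** The corrected trace is smoothed (Gaussian,
  σ = 1.5 samples) and local maxima with prominence ≥ 5 × 1.4826 × MAD
  of the smoothed trace are counted; frequency = count / duration in
  minutes. The 4×MAD-without-smoothing variant admitted tens of false
  peaks per 10-min trace at transient SNR 5 and was rejected. Exact
  count recovery is reliable for SNR ≳ 8; at SNR = 5 with 0.78 s
  sampling and ~2 s decay the transient peak (≈5σ) overlaps the noise
  extreme-value range (≈4σ over 770 samples), so occasional missed or
  spurious peaks are expected at that boundary — a sampling limit, not
  an implementation artefact. Two transients closer than about one
  sampling interval merge into one peak.
* **Voltage events.** Events are maximal runs above the −35 mV
  threshold, with 2 mV hysteresis so noise chatter during the slow
  repolarisation does not split one spike into several events. For the
  AUC each event window is extended outward until the voltage returns
  to baseline (median of sub-threshold samples by default), and
  ∫(V − baseline) dt is integrated trapezoidally, in mV·s. Published
  AUC values for this preparation carry no units and are not
  reproduction targets; the mV·s convention here is self-consistent.

## Optogenetic schedules

Schedules are exact integer microseconds; onsets strictly increase,
pulses never overlap, and every pulse ends within the session. oSparse
places pulses at k/rate from t = 0; oBurst places one
5-pulse 50 Hz burst at the start of every 1 s epoch (phase-locked to
session start; a phase offset is available). For any equal session
length the two paradigms deliver identical pulse counts and on-times —
18,000 pulses and 90 s on-time per hour at the defaults.

## Statistics

Mann–Whitney U uses full enumeration of all C(n₁+n₂, n₁) assignments
whenever min(n₁, n₂) ≤ 8 (midranks, so ties are handled exactly);
larger samples use the normal approximation with tie and continuity
corrections. Welch's and paired t-tests, Shapiro–Wilk (3 ≤ n ≤ 5000),
one-way ANOVA, and two-way ANOVA with type-II sums of squares (a
conventional default for unbalanced layouts) are delegated to
scipy/statsmodels. Post-hoc menus: Šídák (p' = 1 − (1−p)^m),
Holm-Šídák (step-down, enforced monotone), rank-based Dunn with tie
correction and Šídák family bound, and a Dunnett-T3-style option
implemented as pairwise Welch tests under the Šídák bound — the
studentised-maximum-modulus critical values are approximated by that
bound, which is conservative. Reports carry medians + IQR and
means ± SEM per group.

## The synthetic world

The generator emulates, with ground truth recorded in a JSON manifest:

* **Confocal stacks** (default 32 × 128 × 128 voxels ≈ 6.4 × 10.2 ×
  10.2 μm): 20 ribbon/PSD pairs with log-normal radii (medians 0.15 and
  0.20 μm, σ_log 0.25) and intensities (median 2000 a.u. over
  background 50), rendered as Gaussian spots (σ = radius/2), convolved
  with a confocal-like PSF (σ = 0.08, 0.08, 0.25 μm), with Poisson shot
  noise and Gaussian read noise (σ = 5). A chosen fraction of pairs is
  placed with surface gaps of 0.05–0.25 μm (engaged), the rest at
  1.0–1.8 μm (floating); both bands clear the 0.5 μm rule by more than
  the voxelisation error, and the manifest's engaged flags come from
  the generator's own voxel-level distance audit, not the intended
  placement. Placement is rejection sampling with 0.6 μm within-channel
  and 1.3 μm non-partner cross-channel separation; failure after 10⁴
  attempts raises. The radius/intensity distributions are declared, not
  fitted — no real-data distributions are published for them.
* **STED frame pairs**: true areas from a Gaussian copula with latent
  Pearson correlation 2·sin(πρ/6), giving population Spearman exactly ρ,
  log-normal marginals (median 0.03 μm², σ_log 0.4); blobs rendered as
  soft-edged discs of the true area.
* **GCaMP traces**: baseline + linear drift + instant-rise,
  exponential-decay transients (τ = 2 s) + Gaussian noise at 0.78 s
  sampling.
* **Voltage traces**: resting potential with double-exponential spikes
  (2 ms rise, 10 ms decay) whose analytic integral is recorded, plus
  Gaussian noise, at 10 kHz.

What a green test establishes: the pipeline recovers counts, positions,
classes, areas, peak times and doses from data whose generative model it
does not see, under the stated noise. What it does not establish:
robustness to optical artefacts the generator omits (spectral
bleed-through, depth-dependent aberrations, STED depletion physics,
drift), to non-spherical object morphology, or numerical parity with
the commercial reconstruction tool.

## Known limitations

* Surface distances are voxel-level, not sub-voxel mesh distances.
* The Kapur auto threshold is biased on sparse high-dynamic-range 3D
  stacks (use `"noise"` or an explicit value there).
* Event detection near the AP threshold depends on the 2 mV hysteresis
  under heavy noise; count monotonicity in the threshold is guaranteed
  only for clean traces.
* The Dunnett-T3 critical values are Šídák-approximated (conservative).
* One ribbon may be assigned the PSD of a neighbouring synapse if it is
  genuinely closer (nearest-neighbour semantics; no bipartite matching).
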