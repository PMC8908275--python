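# Methods

## Signal model and ADC estimation

All fitting assumes mono-exponential diffusion decay,
`S(b) = S0 · exp(−b · ADC)`, so `ln S` is linear in b. The two-point
estimator `ADC = ln(S_low/S_high)/(b_high − b_low)` is the closed form of
the ordinary-least-squares fit of `ln S` on b restricted to two b-values;
`fit_adc_loglinear` implements the general OLS for ≥ 2 b-values and reduces
to the two-point formula exactly when given two. The default pair is
(170, 1100) s·mm⁻²: a nonzero low b avoids perfusion (IVIM) contamination
of the decay rate, and 1100 s·mm⁻² provides diffusion sensitivity while
remaining clinically achievable. IVIM, kurtosis, and noise-floor
corrections are out of scope.

Degenerate voxels are handled by marking, never by repair: any nonpositive
signal among the selected volumes makes the voxel's ADC NaN (clamping
would fabricate a diffusivity), and negative fitted ADCs are retained
(flooring at zero would bias the in-mask median and SD that the
delineation thresholds are built from). Repeated acquisitions at one
b-value are arithmetically averaged before fitting, mirroring scanner
magnitude averaging; geometric averaging was rejected because it is
undefined at zero-signal voxels.

## Delineation

The tool formalizes "viable tumour = bright at high b AND low ADC":

1. **Statistics inside the manual mask only.** The rough operator mask
   defines the sampling region for both thresholds, which adapts them to
   the individual image — necessary because MR intensities are arbitrary
   and vary across scanners and sessions.
2. **Dual thresholds.** The DWI threshold is Otsu's maximizer of
   between-class variance over a 256-bin equal-width histogram of the
   in-mask high-b intensities; the ADC threshold is
   `median + k·SD` (default k = 0.5, sample SD with n−1). Comparisons are
   inclusive (`S ≥ t`, `ADC ≤ t`) so that a zero-spread region keeps its
   median voxels rather than vanishing.
3. **Intersection, largest component, expansion.** The raw VTV is the
   voxel-wise AND of both masks within the manual mask. The largest 3D
   connected component is kept (default 26-neighbourhood; 6 available),
   then grown to the fixed point of one-ring dilation within the
   *eligibility* mask — the voxels satisfying both thresholds anywhere in
   the volume. Thresholds stay **frozen** at their manual-mask estimates
   during growth; re-estimating per iteration would let the region define
   its own criterion and was rejected as circular.

Numerical conventions worth stating:

- **Otsu candidates are interior bin edges**; the split `{v < t} / {v ≥ t}`
  coincides exactly with a histogram-bin partition, and the between-class
  variance `w0·w1·(μ0−μ1)²` uses the exact class means of the sample (via
  a value-weighted histogram), not bin-center approximations. Ties take
  the smallest threshold. A collection with zero range raises a
  degenerate-histogram error: no separation exists.
- **Component ties** (equal largest sizes) resolve to the component whose
  first voxel comes earliest in array scan order — deterministic under
  any labelling backend.
- **Empty raw VTV is an error, not an empty result**, carrying both
  thresholds: an empty delineation always warrants operator review.
- 26-connectivity is the default because thin oblique rims on 5 mm slices
  visually read as "one region" only when diagonal contact counts.
- All inputs must share one voxel grid (spacing/origin within 10⁻³ mm,
  direction cosines within 10⁻⁴ — header-rounding tolerance); the tool
  never resamples. Mask files holding label values other than 0/1 are
  coerced to boolean with a logged warning.
- A `slice_restricted_expansion` option confines growth to slices touched
  by the manual mask, for comparison against slice-limited manual
  contours; it is off by default.

The median VTV ADC — the reported biomarker — is taken over finite ADC
voxels in the final VTV, with the even-count median defined as the mean of
the central order statistics.

## Repeatability statistics

Percentiles use linear interpolation between closest ranks (sorted-sample
position `1 + p(n−1)`), the convention echoed in every JSON summary. The
nonparametric Bland–Altman summary reports the median difference as bias
and the 15.9% / 84.2% percentiles as 68.3% limits of agreement; on large
`N(0, σ)` samples these converge to ±σ (the exact Gaussian quantiles at
those fractions are −0.9986σ and +1.0027σ, within the 2% calibration
tolerance the tests use). The 84.2% figure (rather than the conventional
84.1%) is deliberate and configurable.

The test–retest uncertainty symmetrizes the pooled differences
(`{+d} ∪ {−d}`, median exactly 0 by construction) and reports ±u with u =
half the 15.9–84.2 inter-percentile range; u is invariant under sign
flips of any subset of differences and converges to σ for Gaussian
differences. Pearson correlation uses a Fisher-z interval
`tanh(arctanh r ± z_α/√(n−3))`; a bootstrap CI was the alternative and
Fisher-z was chosen as the closed-form standard. Significance of a
longitudinal change is the strict comparison `|Δ| > u`.

## Phantom generator

The generator emulates a pelvic DWI protocol: 64×64×24 grid at
1.82 × 1.82 mm² in-plane and 5.0 mm slice pitch (4.6 mm slice + 0.4 mm
gap — the gap is folded into z-spacing because delineation operates on
the stored lattice, not on continuous anatomy), b = {0, 170, 1100}
s·mm⁻². Compartments are ellipsoids/boxes placed in millimetres and
rasterized with painter's rule (later compartments overwrite earlier).
Noise is Rician — `|S + n1 + i·n2|` with independent `N(0, σ)` components
— since magnitude MR data are Rician; a Gaussian option exists for
analytic checks. SNR is quoted as background S0 / σ at b = 0.

The canonical tumour phantom is background (ADC 1.4×10⁻³ mm²·s⁻¹,
S0 600), a viable rim (ADC 0.9×10⁻³, S0 1000 — jointly bright-at-high-b
and low-ADC), and a necrotic core (ADC 2.2×10⁻³, S0 900) overwriting the
rim's interior. These are fixture defaults chosen inside the
physiological order of magnitude (10⁻³ mm²·s⁻¹), not measurements of any
real tissue. What the phantom does **not** emulate: EPI distortion, eddy
currents, intra-volume motion blur, perfusion signal, partial-volume
mixing at compartment boundaries (compartments are piecewise-constant),
and spatially correlated noise. Passing tests therefore demonstrate
correctness of the algorithmic chain and its noise robustness under the
stated model — not clinical performance on patient scans, where manual
masks, anatomy, and artefacts are far less forgiving.

Test–retest pairs are two independent-noise realizations of the same
anatomy, optionally with an integer-voxel rigid shift (bounded by a
jitter parameter in mm) of the second acquisition to emulate bulk
motion/peristalsis between back-to-back scans.

## Simulated repeatability study

`sadt.experiments` binds the pipeline into the study design the tool
serves: per subject, each session is acquired as a test–retest pair; the
session-level ADC is the mean of the two medians; u pools the
test–retest differences of all sessions (baseline and follow-up
together). The validation experiment imposes a known rim-ADC increase of
3u (u taken from baseline) and asks whether each subject's measured
session change clears u.

Problem sizes were chosen to keep the full validation suite around ten
seconds on one CPU while leaving clear statistical margins: 20 phantom
seeds for delineation recovery, 30 subjects for the repeatability study,
10⁵ samples for the Gaussian-calibration checks, 200/100 randomized
trials for the oracle-equivalence checks.

One property of the 3u-change experiment deserves honesty: with
session-mean noise around 0.7u per subject, an imposed 3u change sits
about 2.8 SD above the significance threshold, so over 30 subjects a
small fraction of random streams will produce one subject just below u —
the per-subject difference distribution also has slightly heavier tails
than Gaussian, because a delineation can change its voxel set discretely
when the Otsu threshold moves across a histogram bin. This is exactly the
regime where nonparametric statistics are preferable to mean ± 1.96 SD,
and it is the reason the uncertainty is estimated from percentiles here.

## Known limitations

- The manual mask must be drawn on the DWI grid; no registration or
  resampling from other sequences is provided.
- Otsu thresholding assumes a bimodal in-mask intensity histogram; a
  manual mask covering only homogeneous tissue yields a threshold that
  splits texture noise (and a perfectly uniform region is an error).
- The ADC threshold `median + 0.5·SD` presumes the manual mask contains a
  majority of non-necrotic tumour; a mask dominated by necrosis shifts
  the median upward and admits necrotic voxels.
- Expansion can leak into any connected structure that satisfies both
  frozen thresholds (e.g. adjacent bright low-ADC tissue); the manual
  mask and, where needed, `slice_restricted_expansion` are the guards.
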