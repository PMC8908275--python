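# sadt — semi-automatic viable-tumour-volume delineation from DWI

Quantitative diffusion-weighted MRI (DWI) is increasingly used to monitor
tumour response during radiotherapy: the apparent diffusion coefficient
(ADC) rises as cellularity drops under treatment. The measurement, however,
depends heavily on *where* it is taken. This package implements a
semi-automatic delineation tool (SADT) that extracts the **viable tumour
volume (VTV)** — tumour tissue excluding necrosis — from a rough manual
mask, so that median-ADC measurements become reproducible across observers
and repeated scans. It targets physicists and image analysts working with
rectal/pelvic DWI, but nothing in the method is organ-specific.

## The method

**ADC mapping.** Under the mono-exponential model `S(b) = S0·exp(−b·ADC)`,
log-signal is linear in the diffusion weighting b, so voxel-wise

```
ADC = ln(S_low / S_high) / (b_high − b_low)
```

with the default pair b = (170, 1100) s·mm⁻²: the nonzero low b suppresses
perfusion (IVIM) effects, the high b gives diffusion sensitivity. A general
log-linear least-squares fit over any ≥ 2 b-values is also provided.

**Delineation.** Inside the operator's rough manual mask, two thresholds
are estimated:

1. an Otsu threshold on the b = 1100 s·mm⁻² intensities → the *DWI mask*
   of bright (high-cellularity) voxels, `S ≥ t_Otsu`;
2. `t_ADC = median(ADC) + 0.5·SD(ADC)` over the in-mask voxels → the *ADC
   mask* of diffusion-restricted voxels, `ADC ≤ t_ADC`. The low-ADC
   criterion rejects necrosis and T2 shine-through.

Their intersection inside the manual mask is the raw VTV; post-processing
keeps the largest 3D connected component and then lets it expand beyond
the manual mask into connected voxels that still satisfy both (frozen)
thresholds, repairing an over-tight manual mask.

**Repeatability statistics.** Median VTV ADC values from paired
delineations are compared with nonparametric Bland–Altman statistics
(bias = median difference; 68.3% limits of agreement = 15.9% and 84.2%
percentiles, the order-statistic analogue of ±1 SD) and Pearson r with a
Fisher-z CI. Test–retest differences, symmetrized to ±d, yield an
uncertainty estimate ±u (half the inter-percentile range); a longitudinal
ADC change is significant when |Δ| > u.

**Phantom.** Because the workflow needs ground truth to validate against,
a synthetic DWI phantom generator paints tissue compartments (background,
bright low-ADC viable rim, high-ADC necrotic core) on the acquisition grid
(1.82 × 1.82 mm² in-plane, 5 mm slice pitch), applies mono-exponential
decay and Rician magnitude noise, and emits back-to-back test–retest
acquisitions.

## Worked example

Generate a noisy phantom (SNR 30 at b = 0 in background), build a generous
manual mask from the truth labels, and delineate:

```bash
sadt phantom --seed 7 --noise-sigma 20 --out-dir phantom/
# manual mask: tumour labels dilated by 3 voxels (any rough mask works)
python - <<'EOF'
import nibabel as nib, numpy as np
from scipy import ndimage
img = nib.load("phantom/truth_labels.nii.gz")
manual = ndimage.binary_dilation(np.asarray(img.dataobj) >= 2, iterations=3)
nib.save(nib.Nifti1Image(manual.astype(np.uint8), img.affine), "manual.nii.gz")
EOF
sadt delineate --dwi phantom/dwi.nii.gz --bvals phantom/dwi.bval \
    --manual-mask manual.nii.gz --out-dir out/
```

which logs

```
INFO:sadt.cli:VTV: 2264 voxels, 37496.4 mm^3, median ADC 0.0008964 mm^2/s
```

and writes `out/report.json` containing (abridged):

```json
{
  "thresholds": {
    "dwi": {"value": 195.93, "units": "signal"},
    "adc": {"value": 0.00147, "value_1e-3_mm^2/s": 1.470, "units": "mm^2/s"}
  },
  "median_adc": {"value": 0.000896, "value_1e-3_mm^2/s": 0.896, "units": "mm^2/s"},
  "vtv_volume": {"value": 37496.37, "units": "mm^3"},
  "stage_voxel_counts": {"manual": 6544, "dwi_mask": 2297, "adc_mask": 67368,
                         "raw_vtv": 2264, "final_vtv": 2264}
}
```

Reading: the Otsu threshold (195.9) isolates the bright rim from the 6544
in-mask voxels; the ADC threshold (1.470 × 10⁻³ mm²·s⁻¹) removes the
necrotic core; the final VTV of 2264 voxels recovers the simulated viable
rim (generating ADC 0.9 × 10⁻³) with a median ADC of 0.896 × 10⁻³ mm²·s⁻¹
— a 0.4% error at this noise level. `sadt stats bland-altman` and
`sadt stats uncertainty` then summarize paired measurements from CSV.

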