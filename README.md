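# cacforge

Threshold-free coronary artery calcium (CAC) quantification and
cardiovascular risk categorization for CT attenuation-correction (CTAC)
scans, with a synthetic phantom generator for end-to-end validation.

## The problem

CTAC scans are acquired in every cardiac PET/CT or SPECT/CT session, but
they are thick-slice (5 mm), low-resolution and not ECG-synchronized:
cardiac motion and partial-volume averaging smear calcified plaque so
that lesions fall partly or wholly below the 130 HU threshold on which
clinical Agatston scoring depends. Scoring calcium directly from CTAC
would spare patients a dedicated calcium-scoring CT (CSCT), but the
threshold-based procedure breaks down there.

`cacforge` implements a quantification chain that does not rely on the
130 HU threshold:

1. **Region of interest.** Volumes are resampled to a 1.0 mm in-plane /
   1.5 mm slice grid; a small 3-D residual CNN segments the heart and a
   2-D residual classifier selects axial slices containing visible CAC.
2. **Decomposition.** A CycleGAN trained on *unpaired* slices translates
   between the "CAC" and "noCAC" domains. The removing generator
   predicts a nonnegative **CAC-map** M(x) and subtracts it:
   the calcium-free counterpart is x − M(x), so the identity
   x = (x − M(x)) + M(x) holds exactly and M ≥ 0 by construction.
3. **Scoring.** The CAC area is where the map exceeds a small floor;
   lesion intensities are read from the *original* image at those
   voxels (sub-130 HU values count). The score is the **pseudomass**
   (uncalibrated mass): Σ lesion HU × voxel volume, in HU·mm³.
4. **Risk.** Pseudomass maps onto the five clinical risk categories
   (I: 0, II: 1–10, III: 11–100, IV: 101–400, V: > 400 Agatston) through
   a calibrated logarithm,
   `vis = α·log_β(γ·mass) − δ` for mass > 0 (and 0 at mass 0), rounded
   half-up and clamped to 1–5. Published rest/stress parameter presets
   (α=3.1, β=9.0, γ=1.1, δ=1.6 rest; α=3.5, β=9.0, γ=1.0, δ=1.5 stress)
   are shipped for forward evaluation; `calibrate()` refits α and δ for
   any other pseudomass scale.
5. **Evaluation.** Interscan reproducibility ΔR = |a−b| / (½(a+b)),
   Bland–Altman limits of agreement with half-normal regression
   (limits b ± 1.96·√(π/2)·a·√mean), patient-level detection metrics,
   and Cohen's linearly weighted kappa with an asymptotic 95% CI.

Classical threshold-based scoring (130 HU connected components,
Agatston weights 1–4) is implemented alongside as the reference path.

Because real patient scans cannot ship with a package, `cacforge`
includes a seeded phantom generator: ellipsoidal hearts in a schematic
thorax, ellipsoidal calcific lesions (≥ 150 HU) on near-surface
positions, and a CTAC degradation chain (anisotropic motion blur, 5 mm
slice averaging, noise) that reproduces the sub-threshold-lesion regime.
Every phantom carries exact voxel-level ground truth.

## Worked example

```python
import numpy as np
from cacforge import phantom, pipeline, scoring

case = phantom.generate_case(seed=7, n_lesions=3)
prep = pipeline.prepare_case(case)

# clinical threshold scoring of the thin-slice reference volume
ref = pipeline.score_reference(prep, pipeline.RunConfig())
print(f"CSCT pseudomass {ref.pseudomass:.0f} HU*mm^3, Agatston {ref.agatston:.1f}")
print("risk category:", scoring.categorize_agatston(ref.agatston).roman)

# continuous risk score with the published rest preset
vis = scoring.vis_auto(9.0 / 1.1, scoring.REST_PARAMS)
print(f"vis_auto at mass 9/1.1: {vis:.2f}")
```

prints

```
CSCT pseudomass 38440 HU*mm^3, Agatston 256.0
risk category: IV
vis_auto at mass 9/1.1: 1.50
```

— three lesions worth ~256 Agatston put the phantom in risk category
IV (101–400), and the risk formula evaluates to exactly 1.5 at the mass
where its logarithm equals one.

The same chain runs from the shell:

```bash
cacforge phantoms --n-cases 10 --seed 1 --out phantoms/
cacforge train-roi --out models/ --seed 1
cacforge train-decomp --out models/decomp.npz --seed 1
cacforge demo --seed 20 --out demo_report.json
```

## Layout

- `src/cacforge/volume.py` — CT volume container, NIfTI/MetaImage I/O, resampling
- `src/cacforge/phantom.py` — synthetic cases with voxel-level calcium truth
- `src/cacforge/nn/` — minimal numpy autodiff (conv2d/conv3d, Adam)
- `src/cacforge/roi.py` — heart segmentation, CAC slice classification
- `src/cacforge/decomposition.py` — CycleGAN decomposition / CAC-maps
- `src/cacforge/scoring.py` — lesions, pseudomass, Agatston, risk categories
- `src/cacforge/evalstats.py` — ΔR, Bland–Altman, detection metrics, κ_LW
- `src/cacforge/pipeline.py` — orchestration, demo, recovery experiments
- `docs/methods.md` — model and design notes

Voxel convention: arrays are indexed (z, y, x) with spacing stored as
(dx, dy, dz); world coordinate of voxel (k, j, i) is
origin + (i·dx, j·dy, k·dz), 0-based.
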