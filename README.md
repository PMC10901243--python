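# fiberpol

Mueller-matrix polarimetry of fibrous samples: a simulated
dual-rotating-retarder imaging polarimeter, Lu–Chipman polar
decomposition, and axial statistics of the fast-axis orientation that
separate **intrinsic birefringence** from **form birefringence**.

## The problem

Aligned biological fibers (collagen, myofibrils, silk) are linearly
birefringent for two distinct physical reasons. The ordered molecular
lattice inside a positively birefringent fiber produces *intrinsic*
birefringence whose fast axis is **perpendicular** to the fiber long axis;
anisotropic scattering by the aligned cylinders produces *form*
birefringence whose fast axis is **parallel** to it. A bulk measurement of
linear retardance couples the two, so the retardance magnitude alone cannot
say which source dominates — but the *statistical distribution* of the
per-pixel fast axis can: a fiber carrying both effects shows a
cross-perpendicular **bimodal** distribution, and the relative height of
the two peaks tracks the balance of the two sources.

`fiberpol` is for researchers in tissue polarimetry who want a tested,
fully synthetic desk-scale version of that analysis: every stage from the
camera frames to the bimodal summary is simulated, reconstructed and
verified against ground truth.

## The method

1. **Acquisition.** A polarizer + quarter-wave plate pair generates the
   probe state; a second pair analyzes it. Both plates rotate synchronously
   over 30 frames (6°/frame and 30°/frame). The per-pixel Mueller matrix
   `M` is recovered from the 30 intensities by rank-checked least squares
   (equivalent to the classical Fourier-coefficient inversion on this even
   sampling). Air (empty sample) reconstruction quantifies calibration
   error as `max |m_ij − δ_ij|`.
2. **Decomposition.** `M = M_Δ · M_R · M_D` (Lu–Chipman). From the factors:
   fast-axis orientation `θ = ½·atan2(r₂, r₁)` via the retardance vector of
   `M_R`; linear retardance `δ`; depolarization power
   `Δ = 1 − |tr(m_Δ)|/3`; and directly from the elements the diattenuation
   azimuth `α_P = ½·atan2(m31, m21)` and the birefringence azimuth
   `α_q = ½·atan2(m42, −m43)`.
3. **Orientation statistics.** The per-pixel `θ` map is binned into a
   180°-periodic frequency-distribution histogram (FDH, default 1° bins).
   Circular peak detection, FWHM width `β` per peak, and classification:
   the fiber axis is `α_P` peak + 90°; the `θ` peak nearer the fiber axis
   is the form-birefringence peak `θ_c`, the other is the intrinsic peak
   `θ_b`, and `γ = peak(θ_b) / (peak(θ_b) + peak(θ_c))` is the intrinsic
   share.
4. **Phantoms.** Synthetic Mueller images of glass fiber (form only),
   air-dried tendon (intrinsic only) and silk-like birefringent cylinders,
   where each pixel draws its fast axis from a two-component mixture with
   intrinsic weight `w` — the generative twin of `γ`. Layer-stacking,
   silk-thickness and muscle-stretching sweeps reproduce the qualitative
   trends of those experiments with exact ground truth.

## Worked example

Silk-like phantom with fiber axis 20° and intrinsic share `w = 0.6`, run
through the complete simulated pipeline:

```python
import numpy as np
from fiberpol import (
    silk_spec, generate_phantom, simulate_stack, reconstruct_mueller,
    decompose_image, build_fdh, find_peaks, classify_peaks,
)

image, truth = generate_phantom(
    [silk_spec(fiber_axis=20.0, mixture_w=0.6)], shape=(128, 128), seed=42
)
stack = simulate_stack(image, noise_sd=0.002, seed=42)   # 30 camera frames
mueller = reconstruct_mueller(stack)                     # per-pixel M
maps = decompose_image(mueller)                          # theta, alphaP, ...
summary = classify_peaks(
    find_peaks(build_fdh(maps.theta)), build_fdh(maps.alphaP)
)
for key, value in summary.to_dict().items():
    print(f"{key:>15}: {value if value is None else round(float(value), 4)}")
```

prints

```
    theta_b_deg: 109.5
    theta_c_deg: 20.5
         peak_b: 0.0314
         peak_c: 0.0212
     beta_b_deg: 17.9588
     beta_c_deg: 16.5012
          gamma: 0.5974
 fiber_axis_deg: 20.5
       modality: 2.0
```

The fiber axis (20°) is recovered from the `α_P` peak to within a bin; the
two `θ` peaks sit on and perpendicular to it (20.5° / 109.5°); and the
intrinsic share `γ = 0.597` recovers the generated mixture weight 0.6.

The same pipeline is available from the shell:

```bash
fiberpol phantom --preset silk --fiber-axis 20 --seed 42 --out m.tif
fiberpol acquire --mueller m.tif --noise-sd 0.002 --seed 42 --out stack.tif
fiberpol reconstruct --stack stack.tif --out m.tif
fiberpol decompose --mueller m.tif --out maps.h5
fiberpol report --maps maps.h5 --out summary.json
```

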