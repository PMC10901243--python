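# Methods

## Conventions

All angles are degrees. Axial quantities (fast axes, transmission axes,
fiber orientations) live on [0°, 180°), measured counterclockwise from the
horizontal image x-axis. Stokes vectors are (I, Q, U, V) with Q > 0 for
horizontal linear polarization; with this convention a quarter-wave
retarder at fast axis θ has fourth row (0, sin 2θ, −cos 2θ, 0), which fixes
every sign in the pipeline. Mueller elements are named m11..m44 (1-based)
in all user-facing output; storage is 0-based. Whether the camera frame is
mirrored relative to any particular instrument is unknowable from the
analysis alone; the convention here is internally consistent and applied
identically to generator, analyzer, phantoms and reported maps.

## Acquisition model

The simulated instrument is a dual-rotating quarter-wave-plate polarimeter:
fixed polarizer P1 (0°) + rotating QWP R1 on the generator side, rotating
QWP R2 + fixed polarizer P2 (0°) on the analyzer side. The default
protocol takes 30 frames with R1 stepping 6°/frame and R2 30°/frame (a 1:5
ratio). Frame k records, per pixel,

    I_k = a_k · M · s_k,

with s_k the generator Stokes vector and a_k the analyzer row. Stacking
the outer products a_k ⊗ s_k gives a 30×16 design matrix of rank 16
(asserted at run time); reconstruction is the per-pixel least-squares
solution via the pseudoinverse. On an evenly stepped protocol this is
algebraically identical to the classical Fourier-coefficient inversion,
but simpler to state and rank-checkable; a rank-deficient protocol raises
an error reporting the computed rank. A noise-free simulate→reconstruct
round trip recovers arbitrary physical Mueller images to < 1e−9 per
element.

Noise model: zero-mean multiplicative Gaussian on each intensity
(`I → I·(1+ε)`, ε ~ N(0, noise_sd)), clipped at zero. This captures
gain/flicker-type camera noise; Poisson shot noise is not modeled.
Raw-frame registration is unnecessary because simulated frames are
co-registered by construction.

Calibration is quantified, not compensated: the air (identity-sample)
acquisition is reconstructed and `max |m_ij − δ_ij|` over pixels and
elements is reported. A noise-amplification fact worth recording: the
30-frame QWP protocol has worst-element noise gain ≈ 2.3 (least squares)
and ≈ 2.0 (the weighted/ML variant), so at 0.2% relative intensity noise
the *maximum* per-element error over 10⁴ pixels × 16 elements concentrates
around 0.015–0.020 — the extreme-value factor (~4.3σ) dominates. Per-pixel
air error at that noise level is therefore ~2× the 0.01 figure often
quoted for spatially aggregated calibration residuals; the package reports
the per-pixel maximum, the stricter statistic.

## Polar decomposition

`lu_chipman` factors the m11-normalized matrix as M = M_Δ·M_R·M_D:

* M_D from the first-row diattenuation vector,
  `m_D = √(1−D²)·I + (1−√(1−D²))·D̂D̂ᵀ`;
* M′ = M·M_D⁻¹; m_Δ is the symmetric square-root factor of m′m′ᵀ
  (computed from the eigenvalues of m′m′ᵀ, sign from det m′), with the
  polarizance vector (P − mD)/(1−D²);
* m_R = m_Δ⁻¹·m′, re-orthogonalized by nearest-rotation (SVD) projection
  when the numerical defect exceeds 1e−9.

Factors multiply back to the input to < 1e−8; on 1000 random
depolarizer·retarder·diattenuator products the generation parameters
(θ, δ, Δ, D) are recovered to 1e−6.

Derived parameters:

* θ = ½·atan2(r₂, r₁) from the retardance vector
  r_i ∝ Σ ε_ijk m_R(j,k). The normalization of r cancels in the ratio, so
  the occasionally garbled printed forms of this normalization are moot.
  Orientation is undefined when sin(total retardance) ≈ 0 (retardance 0 or
  180°): such pixels are masked, not propagated.
* δ = arccos(√((m_R11+m_R22)² + (m_R21−m_R12)²) − 1), clamped within 1e−9.
* Δ = 1 − |tr(m_Δ)|/3 over the 3×3 submatrix. (The equivalent 4×4 form is
  1 − |tr(M_Δ)−1|/3; a matrix-inverse reading of the same symbols would
  leave [0,1] and is rejected.)
* α_P = ½·atan2(m31, m21) — first-*column* elements, verified against the
  Stokes-product azimuth of a diattenuator acting on unpolarized light.
* α_q = ½·atan2(m42, −m43); equals θ exactly for any pure linear retarder.

All half-angle ratios use atan2 and reduce mod 180°, avoiding quadrant
ambiguity. `decompose_image` applies the factorization in batch (vectorized
eigendecomposition) and returns six maps plus a uint8 mask with reason
bits (θ undefined, α_P/α_q below floor, degenerate diattenuator, singular
depolarizer). The element-magnitude floors for α_P/α_q default to 1e−6·m11
and are configurable — no published threshold policy exists for these, so
the floors are explicit and reported in artifact headers.

### Why θ is robust and α_q is not

A *diagonal* depolarizer rescales m42 and m43 by the same coefficient and
cannot rotate α_q; the instability appears when depolarization couples the
linear (U) and circular (V) Stokes components — an off-diagonal element in
m_Δ — or when diattenuation mixes into row 4. Polar decomposition strips
both effects before reading the fast axis, which is why θ stays exact where
α_q drifts; additionally, strong depolarization shrinks |{m42, m43}| toward
zero so that element noise inflates the α_q spread while α_P (backed by a
large |m21|) stays stable. Both mechanisms are asserted by Monte Carlo
tests.

## Orientation statistics

FDHs use 1° bins by default (no binning convention is standard in the
literature; sub-degree β resolution comes from interpolation, below).
Masked pixels are dropped before binning; bin masses sum to 1.

* **Peaks**: circular local maxima found on a tripled copy of the mass
  array, requiring prominence ≥ 0.1× the maximum bin mass, greedily
  selected by density with pairwise axial separation ≥ 20°, at most 4
  returned. A flat histogram yields modality 0.
* **β (FWHM)**: from the peak bin, walk circularly in both directions to
  the first crossings of half the peak mass with linear interpolation
  between bins; β is the angular span between crossings. Undefined (NaN)
  if no crossing occurs within 90° on a side.
* **peak()** is read as the probability *mass of the peak's bin* (not an
  integrated area). With equal angular spread in the two mixture
  components the bin-mass ratio equals the component-weight ratio, which
  is what makes γ an unbiased estimate of the generative weight; an
  area-under-peak reading would behave identically in that regime but is
  not implemented.
* **Classification**: fiber axis = α_P peak + 90°. With two θ peaks, the
  nearer to the fiber axis is θ_c (form), the other θ_b (intrinsic), and
  γ = peak(θ_b)/(peak(θ_b)+peak(θ_c)). A lone θ peak is assigned by a 45°
  threshold (γ = 0 or 1). Classification is *refused*, with a modality
  report, when α_P is not unimodal, when θ has more than two peaks (the
  serial-parallel multi-petal case), or on an exact 45° tie — the tie has
  measure zero and no principled resolution.
* Optional circular moving-average smoothing (3-bin window) exists behind
  a flag and is off everywhere, including all acceptance checks.

## Phantom generator

Each pixel of a layer is `depolarizer_diag(d) @ retarder(δ, axis) @
diattenuator(D, fiber+90°)` — the polar-decomposition factor order, so
noise-free single-layer phantoms decompose exactly. The retarder axis is
drawn per pixel:

| kind | axis draw | magnitude |
|---|---|---|
| nonbirefringent_cylinder | fiber + N(0, σ) | δ_form |
| pure_birefringent | fiber + 90° + N(0, σ) | δ_intrinsic |
| birefringent_cylinder | ⊥ fiber w.p. w, ∥ fiber w.p. 1−w, + N(0, σ) | δ_intrinsic / δ_form |

The two-component mixture is a phenomenological stand-in for the physical
coupling of lattice birefringence and cylinder scattering inside one
fiber: the measurable evidence for that coupling is histogram-level, and
the mixture reproduces every histogram-level phenomenon (cross-
perpendicular bimodality, γ trends, multi-petal stacking patterns) with
exact ground truth. It does *not* model radiative transfer, Mie/T-matrix
cylinder scattering, wavelength dispersion, or real tissue texture, so
passing tests demonstrate correctness of the *analysis* under the stated
statistical model, not of any photon-transport claim. Refractive indices
of real samples do not map onto δ_form/δ_intrinsic here; the magnitudes
are free parameters.

Defaults (chosen once as the package's study conditions):

* glass fiber: δ_form 20°, D 0.1, depol (0.95, 0.95, 0.90), σ 3° — stiff,
  deliberately ordered fibers justify the small angular spread;
* air-dried tendon: δ_intrinsic 45°, D 0.02, depol (1, 1, 1), σ 5° — D is
  kept nonzero-but-negligible, mirroring the residual scattering that in
  practice keeps the α_P reference measurable;
* silk: δ_form = δ_intrinsic = 30°, D 0.1, depol (0.90, 0.90, 0.85),
  σ 8°, w 0.6 — σ chosen so β ≈ 2.355σ falls in the 12–27° range typical
  of reported peak widths, and w > ½ because the intrinsic peak dominates
  thin silk.

Sweeps:

* **Layer series** (counts 2, 4, 6, 8, 10): layer L uses depol
  coefficients d^L (each pass depolarizes further) and
  w_L = w₁·ρ^(L−1), ρ = 0.85 (multiple scattering progressively buries
  the intrinsic signal). Both schedules are recorded in the truth object.
* **Stretch series** (NS, CS1, CS2, LS1, LS2): w = 0.5 + k·0.15 for
  k = 0, −1, −2, +1, +2 — transverse stretching strengthens form
  birefringence, longitudinal strengthens intrinsic.
* **Crossed layers**: two layers with an overlap strip (three vertical
  regions). For equal-retardance non-birefringent layers the overlap
  fast axis is the angular bisector of the two layer orientations — exact
  for pure retarders, within a degree once diattenuation and
  depolarization are added.

## Problem sizes and numerical choices

Default phantom size is 128×128 (16 384 pixels), at which γ̂ has standard
error ≈ 0.015 — comfortably inside the ±0.05 recovery band; distributional
property tests use 10⁵ direct angle draws. The batch decomposition of a
128×128 image takes well under a second. Composition is associative to
1e−12; decomposition round trips hold to 1e−8; the acquisition round trip
to 1e−9. Degenerate inputs (ideal polarizers, rank-deficient depolarizers)
are flagged/refused rather than approximated.

## Known limitations

* Forward (transmission) geometry only; no backscattering.
* No Cloude/eigenvalue physicality filtering — the pipeline consumes its
  own simulated matrices, and element-bound checks suffice for those.
* No mixture-model (e.g. von Mises) fitting: peaks are histogram bins, by
  design, so results are directly comparable with histogram-based reports.
* The absolute scale of the air-calibration error depends on the assumed
  camera noise; see the acquisition section for the noise-gain analysis.
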