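# Methods

## Scope and model

`hospect` studies projection-space scatter correction for quantitative
¹⁶⁶Ho SPECT on a digital Jaszczak-style phantom. The chain is: voxel
phantom → attenuated, PSF-blurred line-integral projection → parametric
four-window spectral synthesis with Poisson noise → DEW/TEW correction →
OSEM reconstruction → CRC/CNR scoring and sigmoid summary → LDD
compartment dosimetry and paired statistics. Everything is deterministic
given one integer seed.

## Phantom

A water cylinder (inner ⌀ 206 mm, inner height 186 mm, 7 mm PMMA wall)
carries the six-sphere fillable insert (inner ⌀ 9.9/12.4/15.4/19.8/24.8/
31.3 mm, 2 mm walls). Default loading: 29 MBq in the 31.53 ml of sphere
volume and 312 MBq in the 6200 ml background (341 MBq total, an 18:1
concentration ratio). The sphere centers sit on a 55 mm ring in the
mid-height transverse plane; the axial placement is not dictated by the
physical phantom, mid-height is this package's choice. Voxelization is by
voxel-center membership — simple, unambiguous, and convergent: analytic
and voxelized region volumes agree within 2% at ≤ 1 mm voxels (tested).
Attenuation maps assign water to all liquid regions and PMMA to walls,
log-log interpolated from embedded standard mass-attenuation tables
(50–150 keV); water at 80.6 keV gives μ ≈ 0.184 cm⁻¹. ¹⁶⁶Ho decay
(half-life 26.8 h) is applied per projection at its start time on a
contiguous schedule; at 30 s per view the within-view decay is < 0.03%
and is neglected.

## Acquisition simulator

The simulator is **parametric, not a transport code**. The published
analyses depend only on window-integrated spectral quantities, so each
window is described by (a) component fractions and (b) a total rate
relative to the main window, with the spatial pattern of each component
derived from the primary (unscattered photopeak) projection:

* photopeak-associated scatter: primary ⊗ Gaussian of 2× the system FWHM;
* high-energy downscatter: primary ⊗ Gaussian of 10× FWHM, 25% of it
  replaced by a flat field (the 1.38 MeV gamma penetrates all septa, so
  its imprint is nearly uniform);
* bremsstrahlung: the same very broad Gaussian;
* within W2, 35% of the photopeak component is treated as
  phantom-scattered (medium blur) rather than primary — the main window's
  own scatter that a downscatter window cannot see.

Default fractions are the packaged decomposition (W2: 48.3/48.7/0.0/3.0%,
W4: 0.0/96.9/0.0/3.1%, rows normalized to exact unit sum). The relative
window rates (W1 0.40, W3 0.26, W4 0.50 of W2) are anchored on two
physical constraints: the high-energy content of W4 equals that of W2
(the equal-area argument behind DEW's `k = 1`), and the side-window sum
sits slightly below W2's total scatter content, so TEW mildly
undercorrects. Counting noise is independent Poisson per pixel and per
component; realized per-component counts are recorded as tallies and sum
exactly to the stored window counts.

The system PSF is linear in distance (FWHM = 4 mm + 0.55 mm/cm), a
generic medium-energy-collimator resolution model; at the default 30 cm
orbit the FWHM is 20.5 mm. Detector sensitivity defaults to 100 counts/s
per MBq before attenuation (~10⁶ main-window counts per 30 s view of the
341 MBq phantom).

What the generator does **not** emulate: collimator hole patterns and
septal-penetration streaks, energy-resolution blurring of individual
photons, dead time (the 341 MBq loading is chosen to stay below the
~400 MBq dead-time regime in the first place), patient anatomy, and any
vendor-specific reconstruction behavior. Passing tests therefore
demonstrate the *relative* behavior of the correction methods under a
controlled, physically plausible spectrum — not absolute equivalence with
any particular camera.

## Scatter correction

DEW: `W2 − k·W4`, `k = 1` by default (stored as a float for sensitivity
studies). TEW: trapezoid estimate `(W1/w1 + W3/w3)·w2/2`; with the
nominal 6/12/6 keV widths the factors are exactly 1 and the operator is
bit-identical to direct `W2 − (W1+W3)` subtraction (the exact keV widths
6.004/12.09/5.998 may be passed explicitly). Negative pixels are clamped
to zero by default because the multiplicative EM update requires
non-negative data; a no-clamp mode exists for analysis. Correction is
applied before reconstruction.

## Reconstruction

The projector rotates the volume into the detector frame and sums along
rays, with per-ray attenuation factors (half-voxel self-attenuation for
the emitting voxel) and optional per-depth Gaussian blur. Rotation is a
bilinear *push* (source voxels scatter onto destination neighbors,
weights summing to 1), so projection totals are conserved exactly and the
back-projector — bilinear sampling, the exact transpose — makes the pair
adjoint to floating-point precision (tested at 1e-6, measured ~1e-16).

OSEM: subsets assigned round-robin over the orbit, processed in greedy
maximal-angular-spacing order; uniform positive initialization inside the
inscribed cylindrical FOV; ε = 1e-12 in the forward-projection ratio;
voxels with zero subset sensitivity stay zero. `n_subsets` must divide
`n_projections`; desk-scale runs therefore use 64 projections with the
protocol's 8 subsets (the clinical 120/8 is the full-scale default). The
Butterworth filter (gain `1/√(1+(f/fc)^{2n})` on radial frequency) is a
visualization step; CRC/CNR and dose are computed on unfiltered volumes
by default, with a switch (`filter_before_metrics`) for sensitivity
studies.

## Image quality metrics

Sphere VOIs are the labeled interiors eroded by a margin to avoid
partial-volume border voxels — 1 voxel when voxels are ≤ 2 mm, else 0 (at
4 mm the smallest spheres would not survive erosion). The background VOI
is a 25 mm-radius cylinder about the phantom axis in the sphere plane,
40 mm tall (height is a package choice; only the radius is prescribed by
the protocol). CNR uses the sample (n−1) standard deviation. The CRC
sigmoid fixes the plateau `a = 1`, bounds `b > 0`, `c > 0`,
`d ∈ [0, 1]`, initial `(1, 2, 0)`, solved by trust-region least squares.
FWHM of profiles is measured by linear interpolation of the half-maximum
crossings after baseline subtraction; the CRC x-axis uses the PSF model
evaluated at the orbit radius.

## Dosimetry and statistics

LDD dose: `D_v = A·(n_v/Σn)·κ/m_v`, i.e. the reconstructed volume is
normalized to the administered activity (relative normalization — no
absolute camera calibration is claimed). κ defaults to 15.87 J/GBq of
locally deposited ¹⁶⁶Ho energy after complete decay; density 1.0 g/ml for
phantom water (1.06 g/ml option for liver). Compartment criteria: mean
tumor and NTL dose, tumor fraction ≥ 150 Gy, NTL fraction in the
half-open [0, 50) Gy window; all mass-weighted. Planning inverts the
tumor dose-per-GBq linearly and flags (never silently caps) lung doses
above 30 Gy single / 50 Gy cumulative. The paired t-test is computed from
the textbook formula with the two-sided p from the t distribution
(n−1 df), significance read at 0.05.

Patient-cohort dose tables are not reproducible on a desk (no patient
data by design); the package instead verifies the *consistency* of the
paired DEW-vs-TEW comparison: over ≥ 10 independent simulated phantom
acquisitions the tumor-dose difference keeps one sign and is detected by
the paired test.

## Problem sizes and numerical choices

Default study scale: 64³ voxels at 4 mm isotropic, 64 projections × 30 s,
full 341 MBq loading — chosen so a complete four-arm comparison runs in
minutes on one core; the dose-replicate study uses 24 projections and 5
OSEM iterations per replicate. Grids much below 64³ at 4 mm cannot host
the 10×-FWHM downscatter kernel and are rejected with a configuration
error. All randomness flows from one `numpy` generator seeded by the
user; draws occur window by window (W1→W4) and component by component in
a fixed order, so acquisitions are bit-reproducible.

## Known limitations

* The spectral decomposition is configuration, not physics: changing the
  per-window fractions or rates changes every downstream conclusion.
* The projector is parallel-beam; no fan/cone geometry, no resolution
  recovery in the system matrix beyond an optional Gaussian.
* CRC at 4 mm voxels on the smallest (9.9 mm) sphere rests on a handful
  of voxels and is correspondingly coarse.
* Absolute CRC/CNR/dose values are simulator-specific; only orderings and
  paired contrasts between correction methods are meaningful.
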