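# Methods

This note records the models implemented in `fpmkit`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the numerical
conventions that tests rely on.

## Imaging model

A thin sample of complex transmittance `t(x,y)` illuminated by a plane wave
with direction cosines `(α, β)` produces the exit wave `t·exp[ik(αx+βy)]`.
After the objective, the camera records

    I_i = |iFT[ T(u − α_i/λ, v − β_i/λ) · P(u,v) ]|²,

where `T` is the sample spectrum and `P` the pupil over the coherent transfer
function (CTF) disc of radius `NA_obj/λ`. Frequencies are in cycles/µm
everywhere; the radian convention never crosses a module boundary. Sign
convention: an LED displaced toward +x illuminates with `α < 0`, shifting the
captured passband toward +u. Refraction by slide and coverglass is ignored
when LED positions are converted to angles.

The simulator renders the camera image by cropping the passband window from a
centred high-resolution spectrum (band-limited resampling at an integer
downsampling ratio), multiplying by the pupil and inverse transforming.
Passband centres snap to the nearest frequency pixel; sub-pixel LED
positioning is out of scope. Optional noise is Poisson shot noise with a
photon budget plus Gaussian read noise, both off by default and requiring an
explicit seed.

**Defocus is a pupil factor.** For a thin sample displaced axially the exit
wave propagates to the objective's focal plane *after* transmission, so the
angular-spectrum factor `H(u,v)` multiplies the pupil, not the shifted object
spectrum. The simulator therefore injects defocus (and any other aberration)
as a complex pupil; this is what makes refocusing by initial pupil
modification an exact inverse at small illumination NA.

## Reconstruction

Sequential Gauss–Newton amplitude replacement: per frame the modelled
passband field is formed, its amplitude is replaced by √I keeping the phase,
and the Fourier mismatch ΔF drives

    O_win += conj(P)·|P| / (|P|max·(|P|² + δ_obj)) · ΔF
    P     += conj(O_win)·|O_win| / (|O|max·(|O|² + δ_pupil·|O|max²)) · ΔF,

the second update only with embedded pupil function recovery (EPRY) enabled;
the CTF support and a 1.1 amplitude cap are re-imposed after every pupil
update. Defaults: `δ_obj = 1e-3` (pupil magnitudes are order one) and
`δ_pupil = 1e-8` *relative to |O|max²* — object-spectrum magnitudes scale
with the grid, so an absolute pupil regulariser would be meaningless. The
pupil step saturates below ~1e-8; larger values over-damp the slow transfer
of defocus from the object estimate into the pupil (the object/pupil defocus
near-ambiguity), which on feature-rich objects needs on the order of 150
sweeps to resolve. Frames are visited centre-out by illumination NA, the
stopping rule is a relative misfit change below 1e-4, and three consecutive
misfit increases abort with a diagnostic. No global phase is anchored;
comparisons against ground truth use SSIM on amplitudes or an NRMSE minimised
over a global phase and ±2 px shifts.

The initial spectrum is the band-limited upsampled square root of the most
on-axis frame (zero phase), confined to the synthetic-NA disc so the
recovered spectrum never carries energy outside it.

Reported aberrations use Noll-normalised Zernike polynomials over the pupil
disc — defocus is `Z(2,0) = √3(2ρ²−1)` — fitted by least squares to the
unwrapped pupil phase.

## Digital refocusing

Post-reconstruction refocusing (PRR) multiplies the field spectrum by the
angular-spectrum kernel; evanescent components are zeroed by default (a real
exponential decay is available). `propagate(field, z)` moves the virtual
focal plane by +z toward the detector and a feature at axial position z0 is
sharpest in the plane tagged z0. A second kernel with phase delay *linear* in
radial frequency is provided; a radially linear delay admits more than one
normalisation, and the form implemented here,
`exp(i2πz/λ)·exp(−iπ(z/λ)·√((λu)²+(λv)²))`, is the normative one because it
is dimensionless, radially linear, and delays low-to-intermediate angles more
than the angular-spectrum kernel while delaying grazing angles less (more at
λρ ≈ 0.3, less at λρ ≈ 0.95).
Whether the constant on-axis factor belongs in the kernel is cosmetic for
intensity rendering.

Initial pupil modification (IPM) multiplies the pupil by the angular-spectrum
phase for −z and re-runs the whole reconstruction. Costs are tracked by FFT
operation counters (`n·log2 n` per transform): one PRR plane costs two
transforms of the high-resolution grid, one IPM plane costs two to four
transforms of the low-resolution grid per frame per iteration — a ratio of
several hundred in the configurations used here.

Two physical limits shape the PRR/IPM comparison. The angular-parallax error
`z·NA_illu` must stay below the resolution `λ/NA_syn` for the two routes to
agree, so the equivalence experiments use the inner 3×3 LEDs. And with EPRY
enabled the reconstruction "autofocuses": the recovered object lands near the
maximum-contrast plane with the residual defocus absorbed between object and
pupil, which is why refocusing experiments measure the refocus distance from
an SSIM-vs-z scan rather than assuming it.

## Blood-film phantom

The generator emulates a thin Giemsa-stained smear in the proportions of real
films: cells of radius 3–4 µm with a dark rim (45% absorption in air, 10% in
oil), a weaker interior absorption, a biconcave optical-path profile and
granular absorbing stain mottle (0.25 µm grain, 20% peak); ring-stage
parasites are a 1.2 µm absorbing chromatin spot plus a fainter cytoplasmic
ring at 0.9 µm radius, placed at per-parasite axial offsets within ±1.5 µm of
the membrane plane; sub-threshold debris (few-pixel specks and ~5 µm² blobs)
is planted outside cells to exercise the size filters. Layers at distinct z
are collapsed into one exit field by propagate-and-multiply composition, and
the focal series used by the rendering pipeline is band-limited to the
synthetic NA with a raised-cosine taper, as a reconstructed field would be.

Choices a reader should know about, made because the alternative leaves the
ground truth unobservable rather than merely harder:

- the parasite is purely absorbing — a phase-bearing dot acts as a lens and
  displaces its own best-focus plane off its geometric layer, severing the
  link between truth z and any observable focus (stained chromatin is
  strongly absorbing at 632 nm, so this is also the physical choice);
- the cell optical path peaks at 0.04 µm (~0.4 rad) — stronger phase domes
  generate caustics inside the focal range that drown the parasite cues;
- cells are placed with ≥3 µm clearance, as in the counting zone of a
  well-made film — defocused masks inflate footprints by the blur width and
  tighter packing merges them.

What the phantom does **not** emulate: partial coherence, LED spectral width,
reconstruction artefacts from noisy or miscalibrated data, parasite species/
stage morphology, white cells and platelets, or staining variability.
Passing the pipeline tests therefore demonstrates the geometry and focus
logic of the method, not clinical sensitivity.

## EDoF pipeline

Air recipe: the RBC mask ORs a Sobel/Otsu edge map of the unwrapped phase
(quality-guided 2D unwrapping) with local-mean adaptive thresholding of the
amplitude (block ≈ 2 cell diameters), removes objects under 50 px,
reflection-pads and fills holes; a closing-based twin mask supplies a
boundary ridge whose removal cuts thin bridges between clumped cells (the
ridge is eroded as deeply as the closing is wide, otherwise a closed-over
bridge survives); components under 12 µm² (~half a cell footprint) are
dropped. Oil recipe: solid masks binarised from amplitude and
median-deviation phase are intersected with a Sobel edge mask before filling
and filtering. The mask is computed on the sharpest plane by default;
computing per-plane masks and unioning them before cleaning (available as
`mask_planes="all"`) inflates every footprint by the defocus blur width,
which merges neighbours and defeats the area filters — measured, and the
reason for the default.

Candidate parasites are dark objects inside the rim-eroded footprint
(erosion 1.0 µm), found per plane by the darkest class of a 3-class
multi-Otsu threshold (2-class Otsu lumps much of the textured interior into
"dark"), opened with a 2 px disc to detach rim remnants, kept when their
equivalent diameter exceeds 80% of the 1 µm floor ("significantly smaller"
objects are dropped; thresholded regions of a true 1 µm object measure below
its geometric footprint) and stays below a 3 µm ceiling (cell-scale blobs are
not parasites), and when their Michelson contrast against the remaining
interior exceeds 0.18 — between the mottle's ~0.15 and stained chromatin's
~0.4. Detections are merged across planes by 1 µm centroid proximity,
anchored at the highest-contrast appearance.

Plane selection (air) follows the contour-length rule: the plane whose
Canny-traced object perimeter (contour pixels × pitch × π/4) is closest to
the 4 µm perimeter of a typical ring-stage parasite. The object is segmented
at a threshold anchored 70% of the way from the intracellular background to
the candidate's darkest value *over the whole series*; per-plane adaptive
thresholds track the defocus blur and erase the z-dependence of the measured
perimeter on coherent data. Ties go to the plane nearest the membrane plane;
a candidate with no contour anywhere falls back to the membrane plane,
flagged. The oil variant maximises Michelson contrast between a 0.6 µm disc
at the candidate and a 0.9–1.6 µm surround annulus.

The consistency check resets assignments whose z lies farther than the full
film thickness from the median of trusted (non-fallback) assignments:
parasites legitimately span ±thickness/2 about the film centre and a
small-sample median can sit off-centre by as much again, so only distances
beyond the full thickness are physically impossible.

The composite takes the sharpest-membrane plane as base and replaces each
assigned cell's interior (footprint minus a 0.6 µm membrane rim) verbatim
with its selected plane, blending only a 1 px feather band; the per-pixel
plane index is recorded.

## Focal-series planning and sharpness

A 3 µm film at NA_syn 0.88 needs at least twelve planes (step below the
synthesised DoF); the test series uses 13 planes from −1.5 to +1.5 µm at
0.25 µm so the stated parasite range is fully covered.

Sharpness ranking follows the Sobel-then-variance recipe on 3×3
median-filtered amplitudes. A documented limitation: on smooth coherent
amplitude images the *total* gradient grows with defocus (edge fringing plus
phase-contrast conversion), so on the blood phantom the ranked "sharpest"
plane sits off the membrane plane. On granular absorbing scenes the metric
is exact, which is why chromatic focal shifts are calibrated on a textured
reference patch (`make_texture_patch`): the shift is a property of the
optics, not of the scene, so a reference-region calibration applies across
the field of view. `color_edof` accepts the calibrated per-channel offsets,
windows each channel's series to the film thickness about its own focus, and
merges the channel-wise composites after 0.1–99.9 percentile normalisation
(the merge normalisation is a package choice). Channel wavelengths default
to 632/525/470 nm.

## Numerical conventions and degenerate inputs

- FFTs are numpy's; spectra are handled in centred layout with explicit
  shifts; all transforms route through counters for cost accounting.
- Amplitude replacement guards the zero-field case
  (`guard = 1e-12·max|ψ| + 1e-300`); an all-zero passband skips the pupil
  update. Degenerate histograms fall back from multi-Otsu to Otsu.
- Morphology uses 8-connectivity; coordinates are 0-based and pixel-centred.
- SSIM uses an 11 px Gaussian window (σ 1.5), C1=(0.01L)², C2=(0.03L)²,
  C3=C2/2; the luminance-omitted variant drops the luminance factor and keeps
  C2 unchanged.
- A kernel at z = 0 is identically 1, including over the evanescent domain.
- Empty LED sets, non-positive lengths, mismatched grids, duplicate or
  unsorted focal plans, and missing noise seeds raise immediately.

## Known limitations

- The sharpness recipe's defocus bias on smooth coherent scenes (above).
- Plane-selection accuracy is validated to ±1 focal step on the phantom;
  coherent ringing makes sub-step claims meaningless.
- The layered-object composition is a thin-film stand-in for physically
  thick samples; multiple scattering between layers is not modelled, in
  keeping with the thin-sample regime the toolkit targets
  (`ou_thickness_limit` quantifies where that regime ends).
- IPM is exact only because simulated aberrations live in the pupil; with
  real miscalibrated data both refocusing routes degrade, and the package
  measures their decline rather than assuming it.
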