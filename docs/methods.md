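# Methods

This note documents the models behind `ra224spect`: what is simulated, how
the reconstruction and scoring work, which parameters matter, and what the
synthetic setup can and cannot show about real scanner data.

## 1. Decay chain and energy windows

²²⁴Ra decays in six steps to stable ²⁰⁸Pb, emitting four α particles; the
photons usable for imaging come from ²¹²Pb (x rays at 70–90 keV, γ at
239 keV). The bundled emission library (`data/ra224_emissions.csv`,
ICRP-107 derived) contains the 20 photon lines with energy ≥ 40 keV and
probability ≥ 0.5 % per ²²⁴Ra decay. Window summaries computed from this
library are therefore slightly below values computed from the complete
library: for 216–264 keV the bundled lines give ΣP = 47.4 % (vs ~48 % with
sub-cutoff lines), and for 64–96 keV 37.2 % (vs ~43 %). The
probability-weighted mean energy in 216–264 keV is 239.17 keV in either
case. This discrepancy is documented rather than patched; the exact line
set behind the tabulated 43/48 % is not recoverable.

Energy windows are fractional: a window at center E₀ with width fraction f
spans E₀(1 ± f/2). The two acquisition sets are

| window | lower scatter | emission | upper scatter | AC energy |
|---|---|---|---|---|
| x-ray, 80 keV (40 %, 20 % scatter) | 48–64 | 64–96 | 96–112 | 77.4 |
| γ, 240 keV (20 %, 5 % scatter) | 204–216 | 216–264 | 264–276 | 239 |

Window membership is inclusive on both bounds (239 and 241 keV both belong
to 216–264). The triple-energy-window (TEW) scatter estimate is the
standard trapezoid: S = (C_lo/w_lo + C_up/w_up) · w_main/2.

**Steady-state dose.** D = (C/λ)·E·k/ρ converts a steady activity
concentration into the cumulative absorbed dose, assuming every decay's
energy is deposited locally with no daughter relocalization. The bundled
chain energies count α energy only (²²⁴Ra full chain 26.56 MeV, ²¹²Pb
sub-chain 7.81 MeV, branch-averaged over the ²¹²Bi split), so doses are
mild underestimates (≈ 6–11 % below values that include β/conversion-
electron energy); the function is documented as a ±15 % bookkeeping
approximation.

## 2. Phantom model

The NEMA IEC body phantom is used without the lung insert: six hot spheres
(⌀ 10, 13, 17, 22, 28, 37 mm) on a 114.4-mm circle in one transaxial
plane, cold water background. Printed sphere volumes (0.52 … 26.52 mL,
total 47.82 mL) are (π/6)d³ truncated — not rounded — to 0.01 mL;
`printed_sphere_volumes` reproduces the vendor sheet exactly, including
the total, only under truncation.

The hull cross-section is a 70-mm-tall, 300-mm-wide rectangle capped by
two half-ellipses (semi-axes 150 × 80 mm; total height 230 mm), axial
length 180 mm — standard phantom dimensions chosen here because the
originals are not stated. Voxelization uses voxel-center membership by
default; with subsampling (s³ ≥ 8 points per voxel) partial-volume
averaging permits spacings coarser than the smallest sphere radius. The
attenuation map is analytic: μ of water inside the hull (0.184 /cm at the
80-keV AC energy, 0.127 /cm at 240 keV), zero outside.

The background VOI erodes the hull by a hull margin (Euclidean distance
transform) and removes every sphere dilated by a sphere margin. With the
study margins (40.2 mm spheres / 26.8 mm hull) the implemented hull yields
≈ 2.7 L on the 4.8-mm grid — close to the 2.8 L of the physical setup but
dependent on the assumed hull, so tests assert a 2.0–3.5 L range rather
than the point value.

## 3. Acquisition simulation

**Primary component.** A parallel-beam projector over n views spanning
360°: the volume is rotated about the axial axis per view (bilinear
resampling stored as a sparse operator; columns are normalized so every
in-grid voxel projects exactly its content, and the operator's transpose
is the exact adjoint used in reconstruction), attenuated along the exit
path with exp(−∫μ dl), blurred in the detector plane by a depth-dependent
Gaussian σ(d) = σ₀ + slope·d, and scaled by sensitivity × t_view. A
circular orbit (radius 250 mm) replaces the scanner's body-contour orbit:
orbit shape is scanner-specific and immaterial to the scoring method under
test.

**Scatter component.** The measured regime — 94–97 % of window counts are
collimator-generated secondaries of the 2,615-keV ²⁰⁸Tl line — is
emulated parametrically, not transported: per view, scatter carries
(1/pf − 1) times the primary counts (pf = primary fraction), distributed
as a mixture of the primary projection convolved with a broad Gaussian
(FWHM 120 mm) and a spatially uniform floor (floor fraction 0.5, also
feeding counts outside the body outline, as collimator scatter does).
Fixed fractions of the window scatter are routed into the flanking TEW
windows; all three windows are sampled as independent Poisson counts from
a mandatory seed.

**Preset systems.** The four collimator/window models are calibrated at
the acquisition-count level on the default phantom:

| preset | primary fraction | sensitivity (counts/kBq·s/view) | PSF σ₀, slope (mm, mm/mm) | TEW side fractions |
|---|---|---|---|---|
| ME80 | 0.04 | 0.3361 | 2.0, 0.035 | 0.344 each |
| HE80 | 0.06 | 0.2816 | 2.5, 0.050 | 0.351 each |
| ME240 | 0.03 | 0.1592 | 2.0, 0.035 | 0.2345 each |
| HE240 | 0.03 | 0.0890 | 2.5, 0.050 | 0.229 each |

Primary fractions follow the Monte-Carlo window decomposition of the
measured spectra (4 %/6 % at 80 keV for ME/HE; 3 % at 240 keV).
Sensitivities solve the measured count relations simultaneously: ME
collects 1.79× the HE counts, 240-keV windows 1.16× the 80-keV counts, a
30-min ME240 acquisition at 90 kBq/mL lands at ≈ 9 megacounts (inside the
measured 4.6–10 Mc span), and the largest sphere's maximum-voxel count
rate at 2.4-mm voxels falls inside the measured 3.6–10.2 counts/h per
kBq/mL. TEW side fractions are set so the TEW estimate reproduces the
*measured* window-level scatter ratios (66 % at 80 keV; 91 %/89 % at
240 keV) — deliberately underestimating the true simulated 94–97 %
scatter, as the physical TEW estimate does.

The per-view spatial structure of real collimator scatter is unknowable
from acquisition-level totals; kernel width, floor fraction and side
fractions are acknowledged free calibration knobs and are fixed at the
values above.

## 4. Reconstruction

Attenuated OSEM: multiplicative EM updates over angle-interleaved view
subsets (subset k holds views ≡ k mod S; subsets are processed in
bit-reversed order), forward model = the attenuated projector without PSF
(no resolution recovery, and no vendor-equivalence claim). Views are
weighted 1/n_views so a consistent reconstruction distributes the total
detected (scatter-model-corrected) counts over the volume; voxel values
are in counts. Initialization is a uniform positive image on the μ-map
support. Reconstructions are deterministic.

**Scatter correction** is additive inside the forward model: the TEW
estimate, computed pixelwise from side-window data prefiltered with the
kernel paired to the postfilter (9→9, 12→16, 16→20 mm), clamped at zero,
is added to the projected estimate. Whether the vendor applies TEW by
pre-subtraction or in the forward model is not public; the additive form
preserves Poisson statistics and non-negativity.

**Update ladder.** 24 levels from 5 to 900 total updates. Factorization
into (iterations, subsets) prefers iterations: the smallest subset count
(∈ {1…6}, dividing both the update count and n_views) with ≤ 30
iterations; above the cap, the largest allowed divisor (60 → 30×2,
900 → 150×6). The 30-iteration cap is what makes 60 updates factor as
30 × 2 rather than 60 × 1.

**Postfilter.** Isotropic Gaussian, σ = FWHM/2.355, boundary-renormalized
to preserve the volume total within 0.1 %.

## 5. VOI analysis and SSR

Sphere VOIs are spheric voxel sets (voxel center within d/2) placed on the
voxel grid within a 20-mm search radius of the nominal position by
maximizing the enclosed total intensity — candidate totals are exact
direct sums, so the search equals a brute-force oracle bit for bit. Ties
break toward the nominal center, then lexicographically. The placement
counts as a local maximum only if the maximizer is interior to the search
ball (at least one voxel step from its boundary) and strictly improves on
the nominal total; otherwise the nominal position is kept and the sphere
is flagged. The boundary/improvement test is a committed interpretation;
the original analysis does not state its local-maximum test.

The background peak is the largest mean of an equal-diameter spheric
kernel over all positions whose full kernel fits inside the background
mask (binary erosion), computed as a convolution. SSR = sphere VOI mean /
volume-matched background peak; it is scale-invariant, and SSR < 1 means
the sphere is not defined above the scatter-noise floor. Maximum-voxel
values are normalized as max/(concentration × duration) to counts/h per
kBq/mL.

## 6. Optimization and comparison

Per sphere, SSR vs updates is smoothed with a 3-element floating average
(endpoints average the two available values), normalized to its own
maximum, and the curves are summed with equal sphere weights, omitting
spheres whose smoothed curve has no interior local maximum (first argmax
at either end). The optimum is the argmax of this sum; ties resolve to the
fewest updates. Image-domain placement flags are recorded per
reconstruction (the dashed-segment information) but do not gate curve
inclusion — the omission clause is applied at curve level, the reading most
consistent with the aggregation procedure; both signals are reported.

Two aggregate quantities are deliberately distinct: the *combined
normalized SSR* (above) locates the optimum but is scale-free — its
maximum is bounded by the number of included spheres — so protocols are
*compared* on the sum of the raw smoothed per-sphere SSRs at each
protocol's optimum (`aggregate_ssr` in `ranking.csv`), which carries the
scatter-correction effect. Alternative sphere weightings are config hooks
only; equal weights are the committed default.

The grid runner executes every (ladder level × {AC, SC+AC} × postfilter)
cell per acquisition — 144 per acquisition, 1,296 for the default
nine-acquisition study (four systems at 90 and 30 kBq/mL plus the
3-s/view ME240 scan at 20 kBq/mL, count-equivalent to 2 kBq/mL) — with a
dry-run mode for enumeration. AC reconstructions are shared across the
three postfilter levels (they differ only in postfiltering); SC cells are
reconstructed per filter because the scatter prefilter is paired to the
postfilter. Cells are keyed by a content hash of acquisition, settings and
profile, cached as CSV, and round-tripped through their CSV representation
so cached and fresh runs are bit-identical; pipelines are therefore
idempotent and resumable, and all randomness derives from the config seed
via per-stage hashing.

## 7. Problem sizes

The full study scale (256-class matrix, 2.40-mm voxels, 60 views, 24
ladder levels) is supported but expensive; the package's working profiles
are smaller, chosen so the simulated phantom still covers the full hull:

- **desk profile** (default `GridConfig`): 64×64×40 voxels at 4.8 mm,
  24 views — simulator calibration and unit tests;
- **reduced study profile** (directional tests): 44×44×28 voxels at
  7.0 mm (8-point subsampled voxelization), 24 views, 30 kBq/mL, 12-mm
  postfilter, nine-level ladder (5–240) log-spaced like the full ladder,
  five seeds;
- **native-resolution check**: 128×128×36 voxels at 2.40 mm with an
  axially cropped (70-mm) hull, 24 × 75-s views, for the maximum-voxel
  count-rate calibration.

Count levels are set by sensitivity × activity × time and are independent
of the grid, so acquisition-level calibrations hold at any profile; voxel-
level quantities (maximum-voxel rates) are only compared to measured
values at the native 2.40-mm spacing.

## 8. What the synthetic data do and do not show

The generator reproduces the *statistical regime* of the measurement — a
3–6 % primary fraction on a dominant, spatially broad scatter background,
Poisson counting noise, the measured count ratios between collimators and
windows, and TEW side-window ratios — so it exercises exactly the failure
mode the scoring method must survive. It does not reproduce: energy-
resolved transport (pair production, septal penetration, backscatter
compartments), the true spatial autocorrelation of collimator scatter,
the noncircular orbit, vendor reconstruction internals (resolution
recovery, regularization), CT-based μ-maps, or detector imperfections.
Passing directional tests (scatter correction raises SSR everywhere;
optima shift to fewer updates with SC; the ME240+SC protocol ranks first)
therefore show that the *analysis chain* reacts to these physics the way
the real study observed — not that the simulator predicts absolute scanner
performance. Per-sphere absolute SSR values at desk profiles are
resolution-limited and not comparable to measured ones.

## 9. Numerical choices

- Rotation operators are cached per (grid, angle); their transpose is the
  exact adjoint, which makes MLEM count preservation testable to 0.5 %.
- OSEM guards divisions with ε = 1e-12 and clamps images at zero; voxels
  with zero subset sensitivity stay zero.
- The attenuation line integral assigns the emitting voxel half its own
  path length.
- `background_peak` uses an FFT convolution; an SSR is declared undefined
  when the peak is below 1e-9 of the volume maximum (guarding FFT residue
  around an exact zero).
- Degenerate inputs raise typed errors (invalid spec, degenerate mask or
  geometry, unfactorizable update counts, inconsistent grids) rather than
  returning sentinel values.
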