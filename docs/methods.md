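# Methods

`myolam` quantifies myocardial orthotropy — the three orthogonal structural
axes of ventricular tissue: the myocyte long-axis **m**, the sheet in-plane
direction **s** and the laminar (sheetlet) normal **n** — from 3D image
volumes, and compares three independent ways of measuring it. Everything is
exercised on synthetic laminar phantoms whose true **m**, **s**, **n** fields
are known analytically, so each stage can be validated end to end.

## The three measurements

**Structure tensor (ST).** For a high-resolution contrast-enhanced
structural volume (bright sheetlet-interstices, dark laminae), intensity
gradients are computed with a 3- or 5-point central-difference template
(derivative template width, `dtw`), applied by FFT convolution after mirror
padding. The per-voxel outer product T = ∇I ∇Iᵀ is then carried down a
resolution pyramid: at each level every tensor component is smoothed
separably with a normalized binomial kernel ((1,2,1)/4 for smoothing
template width `stw`=3, (1,4,6,4,1)/16 for `stw`=5) and decimated by 2,
doubling the voxel spacing. Two levels take 50 μm data to the 200 μm grid of
a typical diffusion acquisition. Because intensity varies most strongly
*across* the laminae, the eigenvector of the **largest** eigenvalue is the
putative sheet normal (written v3 to parallel the diffusion convention) and
the smallest-eigenvalue eigenvector is the putative myocyte direction (v1).
Kernel-support bookkeeping shows a `dtw`=3/`stw`=3 configuration with two
doublings draws on an effective 9-voxel-wide template per axis at native
spacing (3 ⊛ 3 ⊛ zero-upsampled 3).

**Diffusion tensor (DTI).** Diffusion weighting follows
b = γ²δ²(Δ − δ/3)|g|² with γ the proton gyromagnetic ratio. Note a common
notational slip in the literature: the value "42 MHz/T" is γ/2π; the
formula needs angular units, so the package uses γ = 2π·42.58×10⁶
rad s⁻¹ T⁻¹. The tensor is fitted per voxel by linear least squares on
ln(S_k/S0) = −b_k g_kᵀ D g_k — the standard log-linear reconstruction,
exact on noiseless monoexponential data (a weighted or nonlinear variant is
used only as a cross-check in the tests). The eigenvector of the largest
eigenvalue (e1) is the putative myocyte direction and the smallest (e3) the
putative sheet normal — the *reverse* pairing of the structure tensor.
Negative eigenvalues from noisy fits are clamped to zero with a per-voxel
flag. The diagnostic √(2DΔ) gives the one-dimensional RMS displacement a
diffusion measurement probes: ~7 μm for free water at Δ = 11.5 ms, small
against the ~80–120 μm laminar repeat, which bounds how directly such an
acquisition can sense laminar structure.

**FLASH-isosurface (FI).** The structural volume is upsampled 4× by
tricubic B-spline interpolation (50 → 12.5 μm; "cubic regression
interpolation" is read as the tricubic spline, the standard volumetric
cubic scheme), an isosurface is extracted at an intensity between the
lamina and interstice levels (marching cubes; face normals oriented toward
the brighter side via the local intensity gradient), and the mesh is
partitioned into 200 μm boxes aligned with the DTI/ST grid, anchored at the
grid origin. Per box, the axial mean normal n^FI is the principal
eigenvector of the area-weighted scatter matrix Σ wᵢ nᵢnᵢᵀ — arithmetic
averaging is ill-defined for sign-ambiguous normals, so an axial
(scatter-matrix) mean is used; whether the original procedure
area-weighted its average is not recorded, and area weighting is the
natural choice for a surface integral. Boxes containing branching or
multiple laminar orientations are rejected by the concentration parameter K
of a von Mises–Fisher distribution fitted to the sign-aligned normals,
using the closed-form 3D approximation K̂ = R̄(3 − R̄²)/(1 − R̄²) (R̄ the
mean resultant length). The keep rule is inclusive, K ≥ 7.0, with a minimum
of 10 faces per box; R̄ = 1 is capped at a large sentinel and flagged.
Tests verify the estimator against the maximum-likelihood solution of
coth κ − 1/κ = R̄ on samples drawn from a vMF distribution; the closed form
carries a few-percent bias at moderate κ, which is irrelevant at the 7.0
accept/reject boundary.

## Cardiac frame and angles

A cylindrical frame is built from a user-supplied long-axis point and
direction (the original workflow registered a model geometry with external
tools; supplying the axis directly removes that dependency without changing
any measurement definition). Off-axis, the local basis is radial r
(normalized rejection of the voxel offset from the axis), longitudinal l
(the axis), and circumferential c = l × r (right-handed). Four projected
angles are defined for axial vectors and folded into (−90°, +90°]:

| angle | formula | 0° | 90° |
|---|---|---|---|
| helix α′ | atan2(v·l, v·c) | circumferential | longitudinal |
| myocyte transverse α″ | atan2(v·r, v·c) | circumferential | radial |
| sheet elevation β′ | atan2(v·l, v·r) | radial | longitudinal |
| sheet transverse β″ | atan2(v·c, v·r) | radial | circumferential |

These are the *apparent* (projected) sheet angles; the absolute sheet angle
is deliberately not computed. A textual ambiguity exists in the source
literature over whether sheet transverse angles project onto the long-axis
or short-axis plane; the package implements the explicit per-angle
definitions above. Projections that are degenerate (v orthogonal to the
projection plane) are flagged NaN, as are on-axis voxels. ROIs are cuboids
in frame coordinates (angular sector × transmural span × longitudinal
span), with normalized transmural depth (0 = endocardium) attached;
`standard_rois` provides the four equatorial sectors (lateral, anterior,
septal, posterior).

## Comparison statistics

Deviations between axial vectors are |cos⁻¹|a·b|| ∈ [0°, 90°]; differences
between folded angles use the period-180 circular distance
min(|x−y|, 180−|x−y|). Summaries report median, MAD, IQR
(linear-interpolation quantiles), mean and SD (n−1); flagged voxels are
excluded pairwise (complete-case). Deviation histograms are quadrant rose
binnings over [0°, 90°] with a right-closed last bin. Transmural profiles
bin by normalized depth and use the period-180 angle-doubling trick for the
per-bin circular mean and circular SD (the literature does not state
whether its profile SDs were circular; circular is the self-consistent
choice for folded angles). Eigenvalue-ratio (sorting-confidence)
distributions report 100·λ_small/λ_large for the assignment-relevant pair —
laminar pair λ2/λ3 for DTI but λ1/λ2 for ST, since the two modalities place
the laminar normal at opposite ends of the spectrum.

## Synthetic phantoms

The **slab** phantom stacks laminae with a single fixed normal: intensity
is a periodic raised-cosine profile of position·n̂ (smooth, so gradients
are well-defined at 50 μm voxels; a binary profile would alias), with the
bright interstice bump occupying a configurable fraction of each period
(default 0.4) and the repeat defaulting to 120 μm — the top of the
biological 80–120 μm range, chosen because it is the largest value that is
both realistic and comfortably resolvable at 50 μm voxels (a 100 μm repeat
sits exactly at the Nyquist limit, where an axis-aligned pattern has
vanishing central differences). Contrast is a free parameter (the
underlying intensity distributions are not quantified in the literature);
defaults are background 20, contrast 80, i.e. dark laminae at 20 and bright
interstices up to 100. Structural noise is additive Gaussian (high-SNR
magnitude images are approximately Gaussian); diffusion signals get Rician
noise (magnitude of a complex Gaussian), the correct model for magnitude
MR.

The **annulus** phantom is a cylindrical wall whose myocyte direction
follows a linear transmural helix rule from +60° (endocardium) to −60°
(epicardium) by default — the classical ~120° span — with the sheet normal
tilted out of the short-axis plane by a configurable elevation rule
(default 0°). The laminar intensity pattern is periodic in radius
(concentric laminae): for a nonzero elevation rule no scalar phase field
has gradients along the prescribed normal everywhere, so the intensity
pattern corresponds to the zero-elevation geometry while the ground-truth
n still follows the rule. Coordinates are 0-based voxel indices, positions
at voxel centers, units μm, frame handedness circumferential =
longitudinal × radial.

Gradient schemes are the classical dual-gradient 6-direction set and an
icosahedral 12-direction set, each with one leading b0; δ = 3.6 ms,
Δ = 11.5 ms, b defaulting to 1000 s/mm². Default simulated tensor
eigenvalues are (1.7, 1.0, 0.7)×10⁻³ mm²/s, representative of fixed
myocardium.

What the phantoms do *not* emulate: laminar branching and the two-population
laminar architecture, transmural variation in contrast uptake, partial
voluming at tissue boundaries, k-space artifacts, eddy currents,
multi-compartment (non-monoexponential) diffusion, and fixation shrinkage.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not the field's systematic disagreements on
real tissue — on these ideal phantoms all three methods agree with the
truth to well under a degree, whereas real-data comparisons show
method-dependent biases precisely because tissue violates these
assumptions.

## Tissue mask

Tissue is dark in contrast-enhanced images, so the mask keeps intensities
≤ 20% of a robust reference (the 99.5th percentile, so hot voxels cannot
shift the threshold; the reference intensity for the "≤20%" rule is
otherwise unspecified). Morphological clean-up is slice-wise in 2D (slicing
along z): clean → bridge → fill → open → thicken. clean/bridge/fill are
512-entry lookup-table operations over the 3×3 neighbourhood (clean drops
foreground pixels with no 8-neighbour; bridge sets a background pixel whose
foreground ring neighbours form ≥ 2 mutually unconnected groups; fill sets
a background pixel with all eight neighbours foreground); open uses a 3×3
structuring element; thicken adds one ring of background pixels per
iteration (default 1), each adjacent to exactly one component, and is
constructed never to merge previously unconnected components. The bridge
and thicken neighbourhood rules are not standardized anywhere; the truth
tables above are this package's documented choice and are tested
exhaustively against an independent oracle. Boundary feathering (replacing
non-tissue intensities within 2 voxels of the mask boundary with the
nearest tissue intensity) is available to suppress spurious tissue/border
gradients before ST analysis.

## Numerical choices

- Convolution boundaries: whole-sample mirror padding everywhere (FFT path
  pads explicitly; direct path uses the equivalent mirror mode). FFT and
  direct convolution agree to 1e-8 relative.
- Decimation keeps even-index samples starting at 0, aligning the pyramid
  with the 200 μm grid deterministically.
- Eigenvectors are sign-fixed so the largest-magnitude component is
  positive (ties broken by the first such component); eigenvalue ties keep
  solver order. All eigen-decompositions use the symmetric solver.
- Degenerate inputs are flagged, not raised: zero-denominator eigenvalue
  ratios, on-axis voxels, degenerate projections, isotropic fits, empty
  masks and empty ROI selections all produce NaN/flag outputs.
- The upsampler evaluates the spline at refined voxel centers
  ((i + 0.5)/factor − 0.5 in input index units), so refined grids tile the
  same physical extent.

## Problem sizes

Unit and property tests run on 16³–48³ phantoms; the end-to-end recovery
checks use a 48³ slab (ST pyramid to 12³ at 200 μm; FI on the 4× upsampled
192³ volume), sizes at which every stage's behaviour is already
asymptotic. The full pipeline on a 64×64×128 phantom — the native grid of
a 200 μm whole-heart acquisition — completes in well under five minutes on
one CPU.

## Known limitations

- Registration-based frame fitting is out of scope; the long axis is a
  config input.
- The exact boundary-smoothing procedure referenced by the original ST
  workflow is not reproduced; nearest-tissue feathering is a documented
  approximation.
- No anisotropic voxel support; no HARDI or multi-compartment diffusion;
  no prolate-spheroidal frame.
- Gradients are computed on raw intensities (no intensity normalization).
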