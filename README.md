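# myolam

Quantification of myocardial orthotropy from 3D imaging.

Ventricular myocardium is orthotropic: at every point there is a myocyte
long-axis **m**, a sheet in-plane direction **s**, and a laminar (sheetlet)
normal **n**. Sheetlets are stacks of cardiomyocytes ~4–6 cells
(~80–120 μm) thick separated by cleavage planes, and the myocyte axis
rotates smoothly by ~120° in helix angle from endocardium to epicardium.
Three imaging-based estimators of this triad are implemented and compared:

- **ST** — 3D structure-tensor analysis of a high-resolution
  contrast-enhanced structural volume (50 μm voxels): gradients from 3- or
  5-point derivative templates, per-voxel T = ∇I ∇Iᵀ, binomial low-pass
  pyramid with resolution doubling down to the 200 μm diffusion grid,
  eigenanalysis. The largest-eigenvalue eigenvector (v3) is the putative
  sheet normal.
- **DTI** — monoexponential diffusion-tensor reconstruction from
  diffusion-weighted stacks, b = γ²δ²(Δ − δ/3)|g|², log-linear
  least-squares fit, eigenvalues sorted descending with e1 the putative
  myocyte direction and e3 the putative sheet normal.
- **FI** — direct laminar-normal measurement: 4× tricubic upsampling,
  marching-cubes isosurface between lamina and interstice intensities,
  area-weighted axial mean of face normals per 200 μm box, and rejection of
  boxes with a von Mises–Fisher concentration K < 7.0.

A cylindrical cardiac frame provides the four projected angles (helix α′,
myocyte transverse α″, sheet elevation β′, sheet transverse β″), and a
statistics layer computes axial deviation angles |cos⁻¹|a·b|| ∈ [0°, 90°],
median ± MAD / median ± IQR summaries, quadrant rose histograms,
eigenvalue-ratio (sorting-confidence) distributions and transmural
profiles. Because no real acquisition ships with the package, a synthetic
module generates laminar slab and helical-annulus phantoms with exact
ground-truth **m**, **s**, **n** fields, plus Rician-noise
diffusion-weighted signals from prescribed tensor fields — every stage is
testable against known truth. See `docs/methods.md` for the full model
description.

Intended users: researchers in cardiac microstructure imaging and
image-analysis methodology who need a reference implementation of these
estimators or a controlled test bed for orientation-recovery pipelines.

## Worked example

Run the full pipeline on a noisy 32³ slab phantom (50 μm voxels, laminar
repeat 120 μm, sheet normal along +z, Gaussian structural noise σ=2 on an
80-unit contrast, Rician DWI noise σ=10 on S0=1000):

```python
from myolam import pipeline
from myolam.synthetic import PhantomSpec

cfg = pipeline.RunConfig()
cfg.phantom = PhantomSpec(shape=(32, 32, 32), noise_sigma=2.0)
cfg.dwi_noise_sigma = 10.0
cfg.seed = 7
report = pipeline.run_pipeline(cfg)
print(report["st_v3_vs_truth"]["median"], report["dti_e3_vs_truth"]["median"])
```

Selected output (degrees, per 200 μm voxel / box):

```
st_v3_vs_truth    median 0.26   mad 0.10    (n=512)
dti_e3_vs_truth   median 2.56   mad 1.23    (n=512)
fi_vs_truth       median 0.13   mad 0.06    (n=512 boxes, all kept, K >= 7)
st_v3_vs_fi       median 0.29   mad 0.10
dti_e3_vs_fi      median 2.57   mad 1.21
```

Reading: the structure tensor and the isosurface method recover the true
laminar normal to a fraction of a degree at this noise level, and agree
with each other equally well; the diffusion estimate carries a few degrees
of noise-driven scatter because its laminar eigenvalues (1.0 vs
0.7 ×10⁻³ mm²/s) are closer together than the structure tensor's. On a
noiseless phantom all three medians are 0.0°.

The same run is available from the shell:

```
myolam run demo.yaml --out results/
```

with `demo.yaml` holding the `RunConfig` fields; subcommands `simulate`,
`st`, `dti`, `mask`, `fi`, `angles` and `compare` expose the individual
stages on NIfTI/bvec/bval inputs.

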