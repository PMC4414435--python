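"""End-to-end orchestration: phantom → ST → DTI → FI → comparison stats.

A :class:`RunConfig` (deserializable from YAML) fully determines a run; the
single global seed is expanded per stage by a fixed counter offset so each
stage's random stream is reproducible in isolation.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import dti, fi, io, mask, stats, stensor, synthetic
from .core import ValidityError
from .synthetic import PhantomSpec

log = logging.getLogger("myolam")

# per-stage offsets added to the global seed (kept below 2**31 overall)
STAGE_SEEDS = {"phantom": 1, "dwi": 2}


@dataclass
class RunConfig:
    """Serializable configuration of a full synthetic pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    slab_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    st_config: stensor.STConfig = field(default_factory=stensor.STConfig)
    n_dir: int = 6
    b_value: float = 1000.0
    dti_eigvals: tuple[float, float, float] = (1.7e-3, 1.0e-3, 0.7e-3)
    dwi_noise_sigma: float = 0.0
    S0: float = 1000.0
    mask_fraction: float = 0.20
    fi_upsample: int = 4
    fi_threshold: float | None = None  # default: midway between lamina/interstice
    k_threshold: float = fi.K_THRESHOLD
    min_faces: int = fi.MIN_FACES
    box_um: float = 200.0
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        raw = io.load_yaml(path)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        errors = []
        if "phantom" in raw:
            try:
                raw["phantom"] = PhantomSpec(**{
                    k: tuple(v) if k == "shape" else v
                    for k, v in raw["phantom"].items()})
            except TypeError as exc:
                errors.append(f"phantom: {exc}")
        if "st_config" in raw:
            try:
                raw["st_config"] = stensor.STConfig(**raw["st_config"])
            except (TypeError, ValidityError) as exc:
                errors.append(f"st_config: {exc}")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            errors.append(f"unknown fields: {sorted(unknown)}")
        if errors:
            raise ValidityError("invalid configuration: " + "; ".join(errors))
        for key in ("slab_normal", "dti_eigvals"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic comparison and return the stats report.

    Stages: laminar phantom generation, structure-tensor pyramid down to the
    200 μm grid, DWI simulation + log-linear tensor fit on the same grid,
    tissue masking, FLASH-isosurface laminar normals, and the deviation
    statistics comparing v3^ST, e3^DTI and n^FI against each other and
    against the known ground truth. When ``output_dir`` is set, volumes,
    tables and a JSON report/manifest are written there.
    """
    t_start = time.perf_counter()
    spec = config.phantom
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, timings[stage])

    # ------------------------------------------------------------- phantom
    t0 = time.perf_counter()
    spec_run = PhantomSpec(**{**asdict(spec), "seed": config.seed + STAGE_SEEDS["phantom"]})
    if spec_run.geometry == "slab":
        volume, truth = synthetic.make_slab_phantom(spec_run, config.slab_normal)
    else:
        volume, truth = synthetic.make_annulus_phantom(spec_run)
    tick("phantom", t0)

    # ------------------------------------------------------------ ST stage
    t0 = time.perf_counter()
    st_field = stensor.st_pyramid(volume, config.st_config)
    st_result = stensor.st_eigenanalysis(st_field)
    st_vecs = stensor.st_vectors(st_result)
    tick("st", t0)

    # ----------------------------------------------------------- DTI stage
    t0 = time.perf_counter()
    factor = 2 ** config.st_config.n_levels
    coarse = synthetic.GroundTruth(
        m=truth.m[::factor, ::factor, ::factor],
        s=truth.s[::factor, ::factor, ::factor],
        n=truth.n[::factor, ::factor, ::factor],
    )
    tensors = synthetic.make_tensor_field(coarse, config.dti_eigvals,
                                          spacing=spec.spacing * factor)
    scheme = synthetic.standard_scheme(config.n_dir, config.b_value)
    dwi = synthetic.simulate_dwi(tensors, scheme, S0=config.S0,
                                 noise_sigma=config.dwi_noise_sigma,
                                 seed=config.seed + STAGE_SEEDS["dwi"])
    dti_result = dti.fit_tensor(dwi, scheme)
    dti_vecs = dti.dti_vectors(dti_result)
    tick("dti", t0)

    # ---------------------------------------------------------- mask stage
    t0 = time.perf_counter()
    tissue = mask.build_tissue_mask(volume, fraction=config.mask_fraction)
    tick("mask", t0)

    # ------------------------------------------------------------ FI stage
    t0 = time.perf_counter()
    up = fi.upsample(volume, config.fi_upsample)
    threshold = config.fi_threshold
    if threshold is None:
        threshold = spec.background + 0.5 * spec.contrast
    mesh = fi.isosurface(up, threshold)
    summaries = fi.box_axial_normal(mesh, box_um=config.box_um,
                                    k_threshold=config.k_threshold,
                                    min_faces=config.min_faces)
    kept = fi.filter_boxes(summaries, config.k_threshold, config.min_faces)
    tick("fi", t0)

    # --------------------------------------------------------- comparisons
    t0 = time.perf_counter()
    n_true_coarse = coarse.n
    report: dict = {"seed": config.seed, "timings_s": timings}

    dev_st_truth = stats.axial_angle(st_vecs["v3"], n_true_coarse)
    dev_dti_truth = stats.axial_angle(dti_vecs["e3"], n_true_coarse)
    dev_st_dti = stats.axial_angle(st_vecs["v3"], dti_vecs["e3"])
    report["st_v3_vs_truth"] = stats.summarize(dev_st_truth)
    report["dti_e3_vs_truth"] = stats.summarize(dev_dti_truth)
    report["st_v3_vs_dti_e3"] = stats.summarize(dev_st_dti)

    # per-box FI comparisons against truth and the gridded ST/DTI fields
    fi_devs_truth, fi_devs_st, fi_devs_dti = [], [], []
    box_shape = st_result.eigvals.shape[:3]
    box_vox = config.box_um / spec.spacing  # native voxels per box
    for s in kept:
        bi = s.box_index
        gi = tuple(int(b) for b in bi)
        if not all(0 <= gi[a] < box_shape[a] for a in range(3)):
            continue
        n_t = truth.n[int(bi[0] * box_vox), int(bi[1] * box_vox), int(bi[2] * box_vox)]
        fi_devs_truth.append(stats.axial_angle(s.n_fi, n_t))
        fi_devs_st.append(stats.axial_angle(s.n_fi, st_vecs["v3"][gi]))
        fi_devs_dti.append(stats.axial_angle(s.n_fi, dti_vecs["e3"][gi]))
    report["fi_boxes_total"] = len(summaries)
    report["fi_boxes_kept"] = len(kept)
    report["fi_vs_truth"] = stats.summarize(fi_devs_truth)
    report["st_v3_vs_fi"] = stats.summarize(fi_devs_st)
    report["dti_e3_vs_fi"] = stats.summarize(fi_devs_dti)

    report["st_laminar_confidence"] = stats.eigen_confidence_distribution(
        st_result, "st", "laminar")["summary"]
    report["dti_laminar_confidence"] = stats.eigen_confidence_distribution(
        dti_result, "dti", "laminar")["summary"]
    report["mask_tissue_fraction"] = float(tissue.mask.mean())
    report["total_s"] = round(time.perf_counter() - t_start, 3)
    tick("stats", t0)

    # -------------------------------------------------------------- output
    if config.output_dir:
        outdir = config.output_dir
        os.makedirs(outdir, exist_ok=True)
        io.save_volume(os.path.join(outdir, "phantom.nii.gz"), volume)
        io.save_vector_field(os.path.join(outdir, "truth_n.nii.gz"), truth.n,
                             spec.spacing)
        io.save_tensor_field(os.path.join(outdir, "st_tensor.nii.gz"), st_field)
        io.save_vector_field(os.path.join(outdir, "st_v3.nii.gz"), st_vecs["v3"],
                             st_field.spacing)
        io.save_bvec_bval(os.path.join(outdir, "scheme"), scheme.directions,
                          scheme.bvals)
        io.save_yaml(os.path.join(outdir, "config.yaml"), _yamlable(config.to_dict()))
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items() if not callable(v)}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
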