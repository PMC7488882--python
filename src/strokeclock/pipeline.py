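"""End-to-end orchestration: simulate -> maps -> voi -> ratios -> evaluate.

Each stage reads and writes files under one run directory, so stages are
individually re-runnable and a full run is reproducible from its config and
seed alone.  The final manifest lists every artifact with a SHA-256
checksum; identical configs produce byte-identical manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cohort import build_cohort_table
from .evaluation import evaluate_cohort
from .lesion_voi import SegmentationConfig, VoiPair, build_voi_pair
from .phantom import (BRISTOL, GLASGOW, OXFORD, AcquisitionParams, PhantomSpec,
                      TissueParams, default_onset_sampler, make_cohort,
                      simulate_diffusion, simulate_echo_series, simulate_flair,
                      subcohort_onset_sampler)
from .qmaps import DiffusionSet, EchoSeries, compute_quant_maps

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "stage_simulate", "stage_maps", "stage_voi", "stage_ratios",
           "stage_evaluate", "ACQUISITION_PRESETS"]

ACQUISITION_PRESETS: dict[str, AcquisitionParams] = {
    "bristol": BRISTOL,
    "glasgow": GLASGOW,
    "oxford": OXFORD,
}

SAMPLERS = {"full": default_onset_sampler, "subcohort": subcohort_onset_sampler}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """One reproducible run: cohort, acquisition, segmentation, evaluation."""

    out_dir: Path
    n: int = 35
    seed: int = 0
    acquisition: str = "bristol"
    sampler: str = "full"
    include_flair: bool | None = None  # None: follow the acquisition preset
    t2_method: str = "loglin"
    window_min: float = 270.0
    strict_boundary: bool = False
    subcohort_metrics: bool = False
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.window_min <= 0:
            raise ValueError("window_min must be > 0")
        if self.acquisition not in ACQUISITION_PRESETS:
            raise ValueError(f"unknown acquisition preset {self.acquisition!r}")
        if self.sampler not in SAMPLERS:
            raise ValueError(f"unknown onset sampler {self.sampler!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.include_flair and not self.acquisition_params.has_flair:
            raise ValueError(f"preset {self.acquisition!r} has no FLAIR settings")

    @property
    def acquisition_params(self) -> AcquisitionParams:
        return ACQUISITION_PRESETS[self.acquisition]

    @property
    def flair_enabled(self) -> bool:
        if self.include_flair is None:
            return self.acquisition_params.has_flair
        return self.include_flair

    @classmethod
    def from_yaml(cls, path: Path | str, out_dir: Path | str | None = None) -> "RunConfig":
        raw = io.read_yaml(path)
        return cls.from_dict(raw, out_dir=out_dir)

    @classmethod
    def from_dict(cls, raw: dict, out_dir: Path | str | None = None) -> "RunConfig":
        raw = dict(raw)
        if out_dir is not None:
            raw["out_dir"] = out_dir
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            ph = dict(raw["phantom"])
            for comp in ("tissue", "csf", "lesion"):
                if comp in ph and isinstance(ph[comp], dict):
                    ph[comp] = TissueParams(**ph[comp])
            for key in ("shape", "lesion_center_vox", "lesion_semiaxes_vox"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            raw["phantom"] = PhantomSpec(**ph)
        if "segmentation" in raw and isinstance(raw["segmentation"], dict):
            raw["segmentation"] = SegmentationConfig(**raw["segmentation"])
        return cls(**raw)


def _patient_dirs(out_dir: Path) -> list[Path]:
    return sorted((out_dir / "patients").iterdir())


def stage_simulate(cfg: RunConfig) -> None:
    """Generate the cohort and write every signal volume and truth mask."""
    spec = replace(cfg.phantom, seed=cfg.seed)
    patients, skeleton = make_cohort(
        n=cfg.n, spec=spec, onset_sampler=SAMPLERS[cfg.sampler],
        seed=cfg.seed, acquisition=cfg.acquisition_params)
    vx = spec.voxel_size_mm
    for pid, patient in zip(skeleton["patient_id"], patients):
        pdir = cfg.out_dir / "patients" / pid
        rng = np.random.default_rng(patient.spec.seed)
        params = cfg.acquisition_params
        echoes = simulate_echo_series(patient, params, rng=rng)
        diff = simulate_diffusion(patient, params, rng=rng)
        io.save_nifti(echoes.volumes, pdir / "signals" / "echo.nii.gz", vx)
        io.save_nifti(np.concatenate([diff.s0[None], diff.dwis]),
                      pdir / "signals" / "dwi.nii.gz", vx)
        meta = {
            "echo_times_ms": list(params.echo_times),
            "b_s_per_mm2": diff.b,
            "directions": diff.directions.tolist(),
            "voxel_size_mm": vx,
            "onset_minutes": float(patient.onset_minutes),
        }
        if cfg.flair_enabled:
            flair = simulate_flair(patient, params, rng=rng)
            io.save_nifti(flair, pdir / "signals" / "flair.nii.gz", vx)
            meta["flair"] = {"TI_ms": params.flair_TI, "TR_ms": params.flair_TR,
                             "TE_ms": params.flair_TE}
        io.write_json(meta, pdir / "signals" / "acquisition.json")
        io.save_nifti(patient.lesion_mask, pdir / "truth" / "lesion.nii.gz", vx)
        io.save_nifti(patient.brain_mask, pdir / "truth" / "brain.nii.gz", vx)
    skeleton.to_csv(cfg.out_dir / "cohort.csv", index=False)


def stage_maps(cfg: RunConfig) -> None:
    """Compute the quantitative map set for every patient from its signals."""
    for pdir in _patient_dirs(cfg.out_dir):
        meta = io.read_json(pdir / "signals" / "acquisition.json")
        vx = float(meta["voxel_size_mm"])
        echoes = EchoSeries(
            volumes=io.load_nifti(pdir / "signals" / "echo.nii.gz", series=True),
            echo_times=tuple(meta["echo_times_ms"]))
        dwi_stack = io.load_nifti(pdir / "signals" / "dwi.nii.gz", series=True)
        diff = DiffusionSet(s0=dwi_stack[0], dwis=dwi_stack[1:],
                            b=float(meta["b_s_per_mm2"]),
                            directions=np.asarray(meta["directions"]))
        flair_path = pdir / "signals" / "flair.nii.gz"
        flair = io.load_nifti(flair_path) if flair_path.exists() else None
        maps = compute_quant_maps(echoes, diff, flair=flair,
                                  t2_method=cfg.t2_method, voxel_size_mm=vx)
        for name in ("adc", "dwi", "t2w", "t2", "s0_fit", "residual", "valid"):
            io.save_nifti(getattr(maps, name), pdir / "maps" / f"{name}.nii.gz", vx)
        if maps.flair is not None:
            io.save_nifti(maps.flair, pdir / "maps" / "flair.nii.gz", vx)
        io.write_json({"units": {"adc": "um^2/ms", "t2": "ms",
                                 "dwi": "a.u.", "t2w": "a.u.", "flair": "a.u."},
                       "t2_method": cfg.t2_method, "voxel_size_mm": vx},
                      pdir / "maps" / "maps.json")


def stage_voi(cfg: RunConfig) -> None:
    """Segment the ischemic VOI and build the mirrored reference per patient."""
    for pdir in _patient_dirs(cfg.out_dir):
        vx = float(io.read_json(pdir / "maps" / "maps.json")["voxel_size_mm"])
        adc = io.load_nifti(pdir / "maps" / "adc.nii.gz")
        t2 = io.load_nifti(pdir / "maps" / "t2.nii.gz")
        valid = io.load_nifti(pdir / "maps" / "valid.nii.gz").astype(bool)
        brain = io.load_nifti(pdir / "truth" / "brain.nii.gz").astype(bool)
        voi = build_voi_pair(adc, t2, brain, cfg.segmentation,
                             voxel_volume_ml=vx**3 / 1000.0, valid=valid)
        io.save_nifti(voi.ischemic, pdir / "voi" / "ischemic.nii.gz", vx)
        io.save_nifti(voi.reference, pdir / "voi" / "reference.nii.gz", vx)
        io.write_json({"lesion_volume_ml": voi.lesion_volume_ml,
                       "nonischemic_median_adc": voi.nonischemic_median,
                       "nonischemic_hwhm_adc": voi.nonischemic_hwhm},
                      pdir / "voi" / "report.json")


def stage_ratios(cfg: RunConfig) -> None:
    """Compute per-patient intensity ratios and write the cohort table."""
    skeleton = pd.read_csv(cfg.out_dir / "cohort.csv")
    ids, onsets, map_sets, vois = [], [], [], []
    for pid, onset in zip(skeleton["patient_id"], skeleton["onset_min"]):
        pdir = cfg.out_dir / "patients" / pid
        report = io.read_json(pdir / "voi" / "report.json")
        vx = float(io.read_json(pdir / "maps" / "maps.json")["voxel_size_mm"])
        maps = _load_map_set(pdir, vx)
        voi = VoiPair(
            ischemic=io.load_nifti(pdir / "voi" / "ischemic.nii.gz").astype(bool),
            reference=io.load_nifti(pdir / "voi" / "reference.nii.gz").astype(bool),
            nonischemic_median=float(report["nonischemic_median_adc"]),
            nonischemic_hwhm=float(report["nonischemic_hwhm_adc"]),
            lesion_volume_ml=float(report["lesion_volume_ml"]))
        ids.append(pid)
        onsets.append(float(onset))
        map_sets.append(maps)
        vois.append(voi)
    table = build_cohort_table(ids, onsets, map_sets, vois,
                               window_min=cfg.window_min,
                               strict_boundary=cfg.strict_boundary)
    table.to_csv(cfg.out_dir / "ratios.csv", index=False)


def _load_map_set(pdir: Path, vx: float):
    from .qmaps import QuantMapSet

    flair_path = pdir / "maps" / "flair.nii.gz"
    return QuantMapSet(
        adc=io.load_nifti(pdir / "maps" / "adc.nii.gz"),
        dwi=io.load_nifti(pdir / "maps" / "dwi.nii.gz"),
        t2w=io.load_nifti(pdir / "maps" / "t2w.nii.gz"),
        t2=io.load_nifti(pdir / "maps" / "t2.nii.gz"),
        s0_fit=io.load_nifti(pdir / "maps" / "s0_fit.nii.gz"),
        residual=io.load_nifti(pdir / "maps" / "residual.nii.gz"),
        valid=io.load_nifti(pdir / "maps" / "valid.nii.gz").astype(bool),
        flair=io.load_nifti(flair_path) if flair_path.exists() else None,
        voxel_size_mm=vx)


def stage_evaluate(cfg: RunConfig) -> dict:
    """Run the statistical evaluation over the cohort table."""
    table = pd.read_csv(cfg.out_dir / "ratios.csv")
    results = evaluate_cohort(table, window_min=cfg.window_min,
                              subcohort_metrics=cfg.subcohort_metrics)
    io.write_json(results, cfg.out_dir / "evaluation.json")
    return results


STAGES = (("simulate", stage_simulate), ("maps", stage_maps),
          ("voi", stage_voi), ("ratios", stage_ratios),
          ("evaluate", stage_evaluate))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and write the artifact manifest.

    Returns the manifest dict.  A failing stage raises PipelineError naming
    the stage; artifacts written before the failure are kept.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        try:
            fn(cfg)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
    manifest = {"seed": cfg.seed, "n": cfg.n, "acquisition": cfg.acquisition,
                "files": []}
    skip = {cfg.out_dir / "manifest.json"}
    for path in sorted(cfg.out_dir.rglob("*")):
        if path.is_file() and path not in skip:
            manifest["files"].append({
                "path": str(path.relative_to(cfg.out_dir)),
                "sha256": io.sha256_of(path)})
    io.write_json(manifest, cfg.out_dir / "manifest.json")
    return manifest
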