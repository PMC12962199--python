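"""End-to-end orchestration: register -> average -> segment -> map -> solve.

``calc_shim`` runs the full chain on an echo series and writes the
plain-text shim configuration plus a JSON report; ``adjust_shim`` reads a
configuration back.  Everything is driven by a validated
:class:`PipelineConfig` and a single seed, so a (config, seed) pair is
fully deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import io as lsio
from .errors import LungshimError
from .evaluate import BssfpParams, mask_stats
from .fieldmap import FieldMap, fieldmap_from_series
from .geometry import Geometry2D
from .phantom import EchoSeries, PhantomParams, make_phantom, simulate_echo_series
from .preprocess import RegistrationSettings, align_and_average
from .segmentation import LungMask, SegmentationSettings, segment_lungs
from .shim import (
    ShimSolution,
    build_basis,
    predict_residual,
    read_shim_config,
    solve_shim,
    write_shim_config,
)

logger = logging.getLogger("lungshim")


class AcquisitionConfig(BaseModel):
    """TR-shifted multi-echo protocol defaults (microseconds)."""

    te1_us: float = Field(570.0, gt=0)
    delta_t_us: float = Field(100.0, gt=0)
    n_echoes: int = Field(4, ge=2)
    n_reps: int = Field(3, ge=1)
    snr: float = Field(20.0, gt=0)
    motion_amplitude_px: float = Field(3.0, ge=0)


class FieldmapSettings(BaseModel):
    magnitude_weighting: bool = False


class ShimSettings(BaseModel):
    order: int = Field(2, ge=0, le=2)


class EvaluateSettings(BaseModel):
    bins: int = Field(50, ge=1)
    bssfp: BssfpParams = BssfpParams()


class PipelineConfig(BaseModel):
    """Full configuration of the shimming pipeline."""

    acquisition: AcquisitionConfig = AcquisitionConfig()
    phantom: PhantomParams = PhantomParams()
    registration: RegistrationSettings = RegistrationSettings()
    segmentation: SegmentationSettings = SegmentationSettings()
    fieldmap: FieldmapSettings = FieldmapSettings()
    shim: ShimSettings = ShimSettings()
    evaluate: EvaluateSettings = EvaluateSettings()
    seed: int = 0
    skip_registration: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.model_validate(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class CalcShimResult:
    solution: ShimSolution
    fieldmap: FieldMap
    residual: FieldMap
    mask: LungMask
    report: dict


def simulate(config: PipelineConfig):
    """Generate a phantom and its echo series from the config and seed."""
    truth, geometry = make_phantom(config.phantom, seed=config.seed)
    acq = config.acquisition
    series = simulate_echo_series(
        truth,
        geometry,
        te1=acq.te1_us,
        delta_t=acq.delta_t_us,
        n_echoes=acq.n_echoes,
        n_reps=acq.n_reps,
        snr=acq.snr,
        motion_amplitude=acq.motion_amplitude_px,
        seed=config.seed + 1,
    )
    return truth, geometry, series


def calc_shim(
    series: EchoSeries,
    config: PipelineConfig,
    outdir=None,
    external_mask: np.ndarray | None = None,
) -> CalcShimResult:
    """Run register -> average -> segment -> field-map -> solve -> write.

    ``external_mask`` bypasses the built-in segmenter (e.g. a mask from a
    learned model).  When ``outdir`` is given, the shim configuration file,
    field/residual maps and a JSON report are written there; stage failures
    propagate with the stage name while earlier outputs are preserved.
    """
    t0 = time.perf_counter()
    stages: dict[str, float] = {}
    current_stage = "init"
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        nonlocal current_stage
        logger.info("stage %s", name)
        current_stage = name
        stages[name] = time.perf_counter()

    try:
        _stage("preprocess")
        if config.skip_registration:
            averaged = EchoSeries(
                data=series.data.mean(axis=0, keepdims=True),
                te_list=series.te_list.copy(),
                delta_t=series.delta_t,
                geometry=series.geometry,
            )
        else:
            averaged = align_and_average(series, config.registration)
        stages["preprocess"] = time.perf_counter() - stages["preprocess"]

        _stage("segmentation")
        if external_mask is not None:
            m = np.asarray(external_mask) > 0.5
            from scipy import ndimage as _ndi

            _, count = _ndi.label(m)
            mask = LungMask(mask=m, component_count=int(count), geometry=series.geometry)
        else:
            mask = segment_lungs(
                np.abs(averaged.data[0, 0]), config.segmentation, series.geometry
            )
        stages["segmentation"] = time.perf_counter() - stages["segmentation"]

        _stage("fieldmap")
        fmap = fieldmap_from_series(
            averaged, weights_from_magnitude=config.fieldmap.magnitude_weighting
        )
        stages["fieldmap"] = time.perf_counter() - stages["fieldmap"]

        _stage("shim")
        basis = build_basis(series.geometry, order=config.shim.order)
        solution = solve_shim(fmap, mask.mask, basis)
        residual = predict_residual(fmap, solution, basis)
        stages["shim"] = time.perf_counter() - stages["shim"]

        _stage("evaluate")
        pre = mask_stats(fmap, mask, bins=config.evaluate.bins)
        post = mask_stats(residual, mask, bins=config.evaluate.bins)
        stages["evaluate"] = time.perf_counter() - stages["evaluate"]
    except LungshimError as exc:
        raise type(exc)(f"stage {current_stage} failed: {exc}") from exc

    report = {
        "coefficients": solution.coefficients.tolist(),
        "f0_offset_hz": solution.f0_offset_hz,
        "n_mask_voxels": solution.n_voxels,
        "condition_number": solution.condition_number,
        "residual_ss_hz2": solution.residual_ss,
        "unshimmed_ss_hz2": solution.unshimmed_ss,
        "pre_shim": pre.to_dict(),
        "post_shim": post.to_dict(),
        "stage_seconds": stages,
        "total_seconds": time.perf_counter() - t0,
        "config": config.model_dump(mode="json"),
    }

    if outdir is not None:
        write_shim_config(outdir / "shim_config.txt", solution, series.geometry)
        lsio.write_fieldmap(fmap, series.geometry, outdir, prefix="fieldmap")
        lsio.write_fieldmap(residual, series.geometry, outdir, prefix="residual")
        lsio.write_map(
            mask.mask.astype(float), series.geometry, outdir / "lung_mask.nii"
        )
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    logger.info("calc_shim done in %.2f s", report["total_seconds"])
    return CalcShimResult(
        solution=solution, fieldmap=fmap, residual=residual, mask=mask, report=report
    )


def adjust_shim(config_path) -> ShimSolution:
    """Read a shim configuration file and return the stored solution."""
    return read_shim_config(config_path)
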