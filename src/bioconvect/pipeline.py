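"""Config-driven orchestration of generation and analysis stages.

A run config (YAML or a plain dict) names the stages to execute and their
parameter blocks; stages run in the canonical order

    simulate → render → spectrum / density / motility / piv → theory

with artifacts handed from stage to stage and written to standard formats
(trajectory CSV, multi-page TIFF + JSON sidecar, metric records as JSON).
A single global seed is expanded into per-stage seeds by a fixed counter
scheme, and a manifest with parameter hashes, seeds and headline metrics
(λ, ω, ton, v, τc, D, R, w) makes any run reproducible and comparable.

Internally all lengths are µm, times s, intensities counts; the config
boundary accepts mm and SI via explicitly suffixed field names.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import continuum_model as cm
from . import densitometry as dens
from . import flowfield as ff
from . import motility as mot
from . import pattern_spectrum as spec
from . import synthetic_data as synth
from .core import ImageStack, ParameterError, TrajectorySet

__all__ = ["RunConfig", "run_pipeline", "validate_against_theory"]

STAGE_ORDER = ["simulate", "render", "spectrum", "density", "motility", "piv", "theory"]
GEOMETRIES = ("3d_topview", "quasi2d_sideview")
#: per-stage seed: (global_seed * SEED_STRIDE + stage index) mod 2**31
SEED_STRIDE = 100003


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * SEED_STRIDE + STAGE_ORDER.index(stage)) % (2**31)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    geometry: str
    output_dir: Path
    stages: dict[str, dict]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - {"seed", "geometry", "output_dir", "stages"}
        if unknown:
            raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
        for req in ("seed", "stages"):
            if req not in raw:
                raise ParameterError(f"config missing required field '{req}'")
        geometry = raw.get("geometry", "quasi2d_sideview")
        if geometry not in GEOMETRIES:
            raise ParameterError(f"geometry must be one of {GEOMETRIES}")
        stages = raw["stages"]
        bad = set(stages) - set(STAGE_ORDER)
        if bad:
            raise ParameterError(f"unknown stage(s): {sorted(bad)}")
        cfg = cls(
            seed=int(raw["seed"]),
            geometry=geometry,
            output_dir=Path(raw.get("output_dir", "bioconvect_out")),
            stages={k: dict(v or {}) for k, v in stages.items()},
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        """Pre-run validation: referenced input paths must exist."""
        for name, block in self.stages.items():
            for key, val in block.items():
                if key.startswith("input_") and key.endswith("_path"):
                    if not Path(val).exists():
                        raise ParameterError(
                            f"stage '{name}': input path {val!r} does not exist"
                        )


def _hash_params(block: dict) -> str:
    return hashlib.sha256(
        json.dumps(block, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _motility_params(block: dict) -> synth.MotilityParams:
    keys = (
        "speed_um_s",
        "tumble_rate_per_s",
        "rot_diffusion_rad2_s",
        "reorientation_time_s",
        "sediment_speed_um_s",
        "cell_radius_um",
    )
    return synth.MotilityParams(**{k: block[k] for k in keys if k in block})


def _suspension_params(block: dict) -> cm.SuspensionParams:
    keys = (
        "volume_fraction",
        "density_contrast",
        "kinematic_viscosity_m2_s",
        "cell_diffusion_um2_s",
        "cell_speed_um_s",
        "depth_mm",
        "reorientation_time_s",
        "gravity_m_s2",
        "cell_volume_um3",
        "mean_density_per_ml",
    )
    return cm.SuspensionParams(**{k: block[k] for k in keys if k in block})


def validate_against_theory(
    stats: mot.MotilityStats,
    p: cm.SuspensionParams,
    rc_reference: Optional[float] = None,
    compute_rc: bool = False,
) -> dict:
    """Stability verdict from measured motility and suspension parameters.

    The diffusion constant and RMS speed measured by the motility pipeline
    are injected into the suspension parameters; the verdict compares the
    Rayleigh number against the critical value — computed by the linear
    solver when B is known and ``compute_rc`` is set, or taken from
    ``rc_reference``. With neither available the verdict is
    ``indeterminate``.
    """
    p = cm.SuspensionParams(
        volume_fraction=p.volume_fraction,
        density_contrast=p.density_contrast,
        kinematic_viscosity_m2_s=p.kinematic_viscosity_m2_s,
        cell_diffusion_um2_s=stats.diffusion_um2_s,
        cell_speed_um_s=stats.rms_speed_um_s,
        depth_mm=p.depth_mm,
        reorientation_time_s=p.reorientation_time_s,
        gravity_m_s2=p.gravity_m_s2,
        cell_volume_um3=p.cell_volume_um3,
        mean_density_per_ml=p.mean_density_per_ml,
    )
    nums = cm.compute_dimensionless_numbers(p)
    result: dict[str, Any] = {"numbers": nums.as_dict(), "rc": None}
    if nums.rayleigh == 0:
        result["verdict"] = "stable"
        return result
    if compute_rc and p.reorientation_time_s is not None:
        rc, _ = cm.critical_rayleigh(p, n_q=8, n_grid=64, rtol=1e-2)
        result["rc"] = rc
    elif rc_reference is not None:
        result["rc"] = rc_reference
    else:
        result["verdict"] = "indeterminate"
        return result
    result["verdict"] = "unstable" if nums.rayleigh > result["rc"] else "stable"
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    Returns the manifest dict; artifacts and ``manifest.json`` are written
    under ``cfg.output_dir``. The manifest contains no timestamps, so two
    runs with the same config and seed produce identical manifests.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "geometry": cfg.geometry,
        "stages": {},
        "metrics": {},
    }
    traj: Optional[TrajectorySet] = None
    stack: Optional[ImageStack] = None

    for name in STAGE_ORDER:
        if name not in cfg.stages:
            continue
        block = cfg.stages[name]
        seed = stage_seed(cfg.seed, name)
        record: dict[str, Any] = {"params_hash": _hash_params(block), "seed": seed}

        if name == "simulate":
            mp = _motility_params(block)
            domain = (
                synth.DomainSpec(**block["domain"]) if "domain" in block else None
            )
            kind = block.get("kind", "run_and_tumble")
            common = dict(
                n_cells=int(block.get("n_cells", 100)),
                duration_s=float(block.get("duration_s", 30.0)),
                dt_s=float(block.get("dt_s", 1.0 / 30.0)),
                seed=seed,
            )
            if kind == "run_and_tumble":
                traj = synth.simulate_run_and_tumble(mp, domain, **common)
            elif kind == "gyrotactic":
                traj = synth.simulate_gyrotactic_swimmers(mp, domain, None, **common)
            else:
                raise ParameterError(f"unknown simulate kind {kind!r}")
            traj.to_csv(out / "trajectories.csv")
            record["output"] = "trajectories.csv"

        elif name == "render":
            if "input_trajectories_path" in block:
                traj_in = TrajectorySet.from_csv(
                    block["input_trajectories_path"],
                    frame_interval_s=float(block.get("frame_interval_s", 1.0 / 30.0)),
                )
            else:
                traj_in = traj
            if traj_in is None:
                raise ParameterError("render stage has no trajectories to rasterize")
            rp_keys = (
                "incident_intensity",
                "attenuation_per_cell",
                "psf_sigma_um",
                "noise_model",
                "noise_sigma",
                "pixel_size_um",
                "bit_depth",
            )
            rp = synth.RenderParams(**{k: block[k] for k in rp_keys if k in block})
            domain = synth.DomainSpec(**block["domain"])
            stack = synth.render_transmission_stack(traj_in, rp, domain, seed=seed)
            stack.to_tiff(out / "stack.tiff")
            record["output"] = "stack.tiff"

        elif name == "spectrum":
            stack_in = _resolve_stack(block, stack)
            mode = block.get(
                "mode",
                "column_1d" if cfg.geometry == "quasi2d_sideview" else "azimuthal_2d",
            )
            ps = spec.windowed_power_spectrum(stack_in, mode=mode)
            metrics = spec.characterize_dynamics(ps)
            pd_frame = metrics.smax_series
            np.savetxt(
                out / "smax.csv",
                pd_frame,
                delimiter=",",
                header="time_s,smax",
                comments="",
            )
            np.savetxt(
                out / "spectrum.csv",
                np.column_stack([ps.q_per_mm, ps.s_qt.mean(axis=0)]),
                delimiter=",",
                header="q_per_mm,s_mean",
                comments="",
            )
            manifest["metrics"].update(metrics.as_dict())
            record["output"] = ["smax.csv", "spectrum.csv"]

        elif name == "density":
            stack_in = _resolve_stack(block, stack)
            maps = [
                dens.relative_density_map(f, frame_index=i)
                for i, f in enumerate(stack_in.frames)
            ]
            profile = dens.vertical_profile(maps, stack_in.pixel_size_um)
            profile.to_csv(out / "profile.csv", index=False)
            length, r2 = dens.fit_sedimentation_length(profile)
            manifest["metrics"]["sedimentation_length_um"] = length
            manifest["metrics"]["sedimentation_fit_r2"] = r2
            record["output"] = "profile.csv"

        elif name == "motility":
            if "input_trajectories_path" in block:
                traj_in = TrajectorySet.from_csv(
                    block["input_trajectories_path"],
                    frame_interval_s=float(block.get("frame_interval_s", 1.0 / 30.0)),
                )
            else:
                traj_in = traj
            if traj_in is None:
                raise ParameterError("motility stage has no trajectories")
            lags, cv = mot.velocity_autocorrelation(
                traj_in, max_lag_s=block.get("max_lag_s")
            )
            stats = mot.fit_motility(lags, cv, n_tracks=traj_in.n_tracks)
            np.savetxt(
                out / "vacf.csv",
                np.column_stack([lags, cv]),
                delimiter=",",
                header="lag_s,cv_um2_s2",
                comments="",
            )
            manifest["metrics"].update(
                {
                    "v_um_s": stats.rms_speed_um_s,
                    "tau_c_s": stats.correlation_time_s,
                    "diffusion_um2_s": stats.diffusion_um2_s,
                }
            )
            record["output"] = "vacf.csv"
            manifest["_motility_stats"] = stats  # handed to the theory stage

        elif name == "piv":
            stack_in = _resolve_stack(block, stack)
            if stack_in.n_frames < 2:
                raise ParameterError("piv stage needs at least two frames")
            fld = ff.piv_flow_field(
                stack_in.frames[0],
                stack_in.frames[1],
                stack_in.pixel_size_um,
                stack_in.frame_interval_s,
            )
            fld.to_dataframe().to_csv(out / "flowfield.csv", index=False)
            manifest["metrics"]["max_cell_flow_um_s"] = float(
                np.hypot(fld.vx_um_s, fld.vz_um_s).max()
            )
            record["output"] = "flowfield.csv"

        elif name == "theory":
            p = _suspension_params(block)
            stats = manifest.pop("_motility_stats", None)
            if stats is not None:
                verdict = validate_against_theory(
                    stats, p, rc_reference=block.get("rc_reference")
                )
            else:
                nums = cm.compute_dimensionless_numbers(p)
                verdict = {"numbers": nums.as_dict(), "verdict": "indeterminate", "rc": None}
            manifest["metrics"]["rayleigh"] = verdict["numbers"]["rayleigh"]
            manifest["metrics"]["scaled_speed"] = verdict["numbers"]["scaled_speed"]
            manifest["metrics"]["stability_verdict"] = verdict["verdict"]
            (out / "theory.json").write_text(
                json.dumps(
                    {k: v for k, v in verdict.items()},
                    indent=1,
                    default=lambda o: None if (isinstance(o, float) and math.isnan(o)) else str(o),
                )
            )
            record["output"] = "theory.json"

        manifest["stages"][name] = record

    manifest.pop("_motility_stats", None)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _resolve_stack(block: dict, stack: Optional[ImageStack]) -> ImageStack:
    if "input_stack_path" in block:
        return ImageStack.from_tiff(block["input_stack_path"])
    if stack is None:
        raise ParameterError("stage has no image stack input")
    return stack
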