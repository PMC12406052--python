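"""Scenario configuration and end-to-end orchestration.

One YAML file drives the whole chain: phantom -> paradigm/handlers ->
sampling -> acquisition engine -> frame-wise reconstruction -> GLM
evaluation.  Every random draw derives from the single run seed, and the
manifest written next to the outputs (config hash, seed, versions, stage
timings) makes a rerun bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import evaluate_series
from .dynamics import (
    BoldHandler,
    BoldSpec,
    HandlerChain,
    block_paradigm,
    hemodynamic_signal,
)
from .engine import NoiseSpec, SequenceParams, phantom_energy, run_acquisition
from .mrd import read_mrd
from .phantom import (
    DEFAULT_TISSUES,
    TissueParams,
    contrast_volume,
    define_roi,
    make_coil_profiles,
    make_synthetic_phantom,
)
from .recon import adjoint_recon, frames_from_mrd, reconstruct_series
from .sampling import SamplingPattern, epi_3d, read_trajectory, stack_of_spirals

__all__ = ["ScenarioConfig", "derive_timing", "run_scenario", "load_config", "preset_path"]


@dataclass
class ScenarioConfig:
    """Flat, explicit description of one simulated experiment."""

    phantom: dict = field(default_factory=lambda: {"shape": [32, 32, 32], "voxel_size": [3.0, 3.0, 3.0]})
    paradigm: dict = field(default_factory=lambda: {"on_s": 20.0, "off_s": 20.0})
    sequence: dict = field(default_factory=lambda: {"TR_shot_ms": 50.0, "TE_ms": 25.0, "FA_deg": 12.0, "Tobs_ms": 25.0})
    trajectory: dict = field(default_factory=lambda: {"kind": "epi"})
    engine: dict = field(default_factory=lambda: {"kind": "basic", "snr_in": 1000.0, "L": 1})
    bold: dict = field(default_factory=lambda: {"delta_r2s": -1.0})
    roi: dict = field(default_factory=lambda: {"center_mm": [0.0, -24.0, 0.0], "semi_axes_mm": [18.0, 18.0, 18.0], "gm_threshold": 0.5})
    recon: dict = field(default_factory=lambda: {"method": "adjoint", "strategy": "cold", "mu": "auto", "wavelet": "sym8", "max_iter": 50, "tol": 1e-5})
    analysis: dict = field(default_factory=lambda: {"p": 0.001})
    run: dict = field(default_factory=lambda: {"length_s": 120.0, "seed": 0})

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown scenario section: {key}")
            getattr(cfg, key).update(val)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh) or {})


def preset_path(name: str) -> Path:
    """Path of a packaged scenario preset (e.g. 'tiny_epi')."""
    return Path(__file__).parent / "configs" / f"{name}.yaml"


def derive_timing(config: ScenarioConfig, n_shots_per_frame: int) -> dict:
    """Shot budget and volume timing implied by the run length.

    n_shots_total = floor(run_length / TR_shot); TR_vol = N_s * TR_shot;
    n_frames = floor(n_shots_total / N_s) (the remainder is dropped).
    """
    TR_shot_s = config.sequence["TR_shot_ms"] * 1e-3
    n_total = int(math.floor(config.run["length_s"] / TR_shot_s + 1e-9))
    if n_shots_per_frame > n_total:
        raise ValueError("run too short to acquire even one volume")
    n_frames = n_total // n_shots_per_frame
    return {
        "n_shots_total": n_total,
        "n_frames": n_frames,
        "TR_vol_s": n_shots_per_frame * TR_shot_s,
        "dropped_shots": n_total - n_frames * n_shots_per_frame,
    }


def _build_patterns(config: ScenarioConfig, shape, n_frames_cap=None):
    traj = dict(config.trajectory)
    kind = traj.pop("kind", "epi")
    Tobs = config.sequence["Tobs_ms"]
    seed = config.run.get("seed", 0)
    if kind == "epi":
        shots = epi_3d(shape, Tobs)
        n_s = len(shots)
        timing = derive_timing(config, n_s)
        n_frames = timing["n_frames"] if n_frames_cap is None else min(timing["n_frames"], n_frames_cap)
        patterns = [
            SamplingPattern(
                shots=epi_3d(shape, Tobs), grid_shape=shape, frame_index=t
            )
            for t in range(n_frames)
        ]
    elif kind == "stack_of_spirals":
        params = dict(
            nz=shape[2],
            center_frac=traj.get("center_frac", 0.1),
            AF=traj.get("AF", 4.0),
            dynamic=traj.get("dynamic", False),
            grid_shape=shape,
            n_samples=traj.get("n_samples", 3000),
            n_turns=traj.get("n_turns", 14.0),
            Tobs=Tobs,
        )
        first = stack_of_spirals(frame_index=0, seed=seed, **params)
        timing = derive_timing(config, first.n_shots)
        n_frames = timing["n_frames"] if n_frames_cap is None else min(timing["n_frames"], n_frames_cap)
        patterns = [first] + [
            stack_of_spirals(frame_index=t, seed=seed, **params)
            for t in range(1, n_frames)
        ]
    elif kind == "import":
        pattern = read_trajectory(traj["path"])
        timing = derive_timing(config, pattern.n_shots)
        n_frames = timing["n_frames"] if n_frames_cap is None else min(timing["n_frames"], n_frames_cap)
        patterns = [
            SamplingPattern(shots=pattern.shots, grid_shape=pattern.grid_shape, frame_index=t)
            for t in range(n_frames)
        ]
    else:
        raise ValueError(f"unknown trajectory kind: {kind}")
    return patterns, timing


def run_scenario(config: ScenarioConfig, out_dir: str, seed: int | None = None) -> dict:
    """Execute the full chain and write mrd + NIfTI + report + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.run["seed"] = int(seed)
    seed = int(config.run.get("seed", 0))
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "version": __version__,
        "numpy": np.__version__,
        "stages": {},
        "completed": [],
    }
    t_wall = time.perf_counter

    def stage_done(name, t0):
        manifest["stages"][name] = round(t_wall() - t0, 3)
        manifest["completed"].append(name)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        # ---- phantom --------------------------------------------------
        t0 = t_wall()
        ph_cfg = config.phantom
        tissues = tuple(
            TissueParams(**t) for t in ph_cfg.get("tissues", [])
        ) or DEFAULT_TISSUES
        phantom = make_synthetic_phantom(
            shape=tuple(ph_cfg["shape"]),
            voxel_size=tuple(ph_cfg.get("voxel_size", [3.0, 3.0, 3.0])),
            seed=seed,
            tissues=tissues,
        )
        seq = SequenceParams(
            TR_shot=config.sequence["TR_shot_ms"],
            TE=config.sequence["TE_ms"],
            FA=config.sequence["FA_deg"],
            Tobs=config.sequence["Tobs_ms"],
        )
        contrast = contrast_volume(phantom, seq.TR_shot, seq.TE, seq.FA)
        roi = define_roi(
            phantom,
            center_mm=tuple(config.roi["center_mm"]),
            semi_axes_mm=tuple(config.roi["semi_axes_mm"]),
            gm_threshold=config.roi.get("gm_threshold", 0.5),
        )
        coils = make_coil_profiles(phantom, L=config.engine.get("L", 1))
        stage_done("phantom", t0)

        # ---- dynamics -------------------------------------------------
        t0 = t_wall()
        paradigm = block_paradigm(
            config.paradigm["on_s"], config.paradigm["off_s"], config.run["length_s"]
        )
        signal = hemodynamic_signal(paradigm, seq.TR_shot)
        bold = BoldSpec(
            delta_r2s=config.bold.get("delta_r2s", -1.0), TE=seq.TE, roi=roi
        )
        chain = HandlerChain(handlers=(BoldHandler(bold, signal),))
        stage_done("dynamics", t0)

        # ---- sampling + acquisition ----------------------------------
        t0 = t_wall()
        patterns, timing = _build_patterns(config, phantom.shape)
        manifest["timing"] = timing
        snr = config.engine.get("snr_in", None)
        noise = None
        if snr is not None and not (isinstance(snr, float) and math.isinf(snr)):
            noise = NoiseSpec(
                snr_in=float(snr),
                energy=phantom_energy(contrast, mask=phantom.head_mask()),
                covariance=coils.covariance,
                seed=seed,
            )
        mrd_path = str(out / "run.mrd")
        run_acquisition(
            phantom,
            chain,
            patterns,
            sequence=seq,
            out=mrd_path,
            engine=config.engine.get("kind", "basic"),
            noise=noise,
            coils=coils,
            n_jobs=config.engine.get("n_jobs", 1),
        )
        stage_done("acquisition", t0)

        # ---- reconstruction ------------------------------------------
        t0 = t_wall()
        run = read_mrd(mrd_path)
        frames = frames_from_mrd(run)
        method = config.recon.get("method", "adjoint")
        if method == "adjoint":
            volumes = np.stack([adjoint_recon(f, coils) for f in frames])
            diagnostics = []
        elif method == "cs":
            series = reconstruct_series(
                frames,
                strategy=config.recon.get("strategy", "cold"),
                problem_template={
                    "coils": coils,
                    "mu": config.recon.get("mu", "auto"),
                    "wavelet": config.recon.get("wavelet", "sym8"),
                    "max_iter": config.recon.get("max_iter", 50),
                    "tol": config.recon.get("tol", 1e-5),
                },
            )
            volumes = series.volumes
            diagnostics = series.diagnostics
        else:
            raise ValueError(f"unknown recon method: {method}")
        mag = np.abs(volumes)
        _save_nifti(mag.transpose(1, 2, 3, 0), phantom.affine, out / "series.nii.gz")
        stage_done("reconstruction", t0)

        # ---- analysis -------------------------------------------------
        t0 = t_wall()
        frame_times = np.array([run.frame_time_s(t) for t in range(run.n_frames)])
        report = evaluate_series(
            mag,
            paradigm,
            frame_times,
            roi,
            reference=contrast,
            p=config.analysis.get("p", 0.001),
            TR_shot=seq.TR_shot,
        )
        report_d = report.to_dict()
        report_d["timing"] = timing
        report_d["recon_iterations"] = [d["iterations"] for d in diagnostics]
        report_d["mu_per_frame"] = [d["mu"] for d in diagnostics]
        with open(out / "report.json", "w") as fh:
            json.dump(report_d, fh, indent=2, sort_keys=True)
        stage_done("analysis", t0)
        return report_d
    except Exception as exc:
        manifest["error"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise


def _save_nifti(arr, affine, path):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))
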