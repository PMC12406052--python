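"""k-space sampling patterns: 3D EPI, in-out spirals, stack-of-spirals.

A Shot is one readout: an ordered list of k-space locations with
echo-centred timestamps (t = 0 at the echo, spanning the Tobs window).
Coordinates are dimensionless, per-axis in [-0.5, 0.5) (cycles per voxel).
Patterns group the shots of one volume/frame.  A hardware audit converts
normalised coordinates to physical gradient and slew-rate demands, and
trajectories round-trip through a small binary container or a CSV dialect
so externally optimised readouts can be imported.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Shot",
    "SamplingPattern",
    "HardwareSpec",
    "epi_3d",
    "spiral_inout",
    "stack_of_spirals",
    "gradients_and_slew",
    "write_trajectory",
    "read_trajectory",
]

GAMMA_KHZ_PER_MT = 42.576  # gyromagnetic ratio of 1H


@dataclass
class Shot:
    """One readout: ordered k-space samples with echo-centred times (ms)."""

    samples: np.ndarray  # (N, 3) in [-0.5, 0.5)
    times: np.ndarray  # (N,), ms, uniform spacing, 0 at the echo
    shot_index: int = 0
    kz_plane: int | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.times) != len(self.samples):
            raise ValueError("times and samples must have the same length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be strictly increasing with constant spacing")
        if np.any(self.samples < -0.5) or np.any(self.samples >= 0.5):
            raise ValueError("k-space coordinates must lie in [-0.5, 0.5)")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def dwell(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class SamplingPattern:
    """All shots of one k-space volume (frame)."""

    shots: list
    grid_shape: tuple[int, int, int]
    frame_index: int = 0

    def __post_init__(self):
        if len(self.shots) < 1:
            raise ValueError("a sampling pattern needs at least one shot")
        n = self.shots[0].n_samples
        if any(s.n_samples != n for s in self.shots):
            raise ValueError("all shots in a pattern must share the sample count")

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    def all_samples(self) -> np.ndarray:
        return np.concatenate([s.samples for s in self.shots], axis=0)


@dataclass(frozen=True)
class HardwareSpec:
    """Gradient system limits and geometry for the constraint audit."""

    Gmax: float = 40.0  # mT/m
    Smax: float = 180.0  # T/m/s
    gamma: float = GAMMA_KHZ_PER_MT  # kHz/mT
    dwell: float = 0.01  # ms
    fov: tuple[float, float, float] = (192.0, 192.0, 192.0)  # mm

    def __post_init__(self):
        if min(self.Gmax, self.Smax, self.gamma, self.dwell, *self.fov) <= 0:
            raise ValueError("all hardware parameters must be strictly positive")


def _readout_times(n: int, Tobs: float) -> np.ndarray:
    """Uniform echo-centred times spanning the Tobs window."""
    return np.linspace(-Tobs / 2, Tobs / 2, n)


def epi_3d(grid_shape: tuple[int, int, int], Tobs: float) -> list[Shot]:
    """Plane-per-shot 3D EPI: one fully sampled (kx, ky) plane per kz.

    Within a plane the readout rasters over ky lines with alternating kx
    direction; the ky = 0 line falls at the middle of the window, i.e. near
    the echo.  The union over shots is exactly the Cartesian grid.
    """
    nx, ny, nz = (int(n) for n in grid_shape)
    if min(nx, ny, nz) < 2:
        raise ValueError("grid must be at least 2 voxels per axis")
    kx = (np.arange(nx) - nx // 2) / nx
    ky = (np.arange(ny) - ny // 2) / ny
    kz = (np.arange(nz) - nz // 2) / nz
    times = _readout_times(nx * ny, Tobs)
    shots = []
    for iz in range(nz):
        pts = np.empty((ny * nx, 3))
        for line, iy in enumerate(range(ny)):
            xs = kx if line % 2 == 0 else kx[::-1]
            pts[line * nx : (line + 1) * nx, 0] = xs
            pts[line * nx : (line + 1) * nx, 1] = ky[iy]
        pts[:, 2] = kz[iz]
        shots.append(Shot(samples=pts, times=times.copy(), shot_index=iz, kz_plane=iz))
    return shots


def spiral_inout(
    n_samples: int,
    n_turns: float = 14.0,
    grid_shape: tuple[int, int, int] | None = None,
    Tobs: float = 30.0,
    kmax: float = 0.4999,
) -> Shot:
    """Archimedean in-out spiral in the (kx, ky) plane.

    The second half spirals outward from the k-space centre; the first half
    is its point-reflection traversed inward, so the readout passes through
    k = 0 exactly at the echo (t = 0).  With n_samples even, times run at a
    constant dwell with t[n_samples//2] = 0.
    """
    if n_samples % 2 != 0:
        raise ValueError("n_samples must be even for an in-out readout")
    half = n_samples // 2
    j = np.arange(half + 1, dtype=np.float64)  # 0 .. half
    radius = kmax * j / half
    theta = 2 * np.pi * n_turns * j / half
    out = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    inward = -out[1 : half + 1][::-1]
    pts2d = np.concatenate([inward, out[:half]], axis=0)  # out[0] = centre at index half
    pts = np.zeros((n_samples, 3))
    pts[:, :2] = pts2d
    dt = Tobs / n_samples
    times = (np.arange(n_samples) - half) * dt
    return Shot(samples=pts, times=times)


def stack_of_spirals(
    nz: int,
    center_frac: float = 0.1,
    AF: float = 4.0,
    dynamic: bool = False,
    frame_index: int = 0,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    n_samples: int = 3000,
    n_turns: float = 14.0,
    Tobs: float = 30.0,
) -> SamplingPattern:
    """Variable-density stack of in-out spirals along kz.

    ``round(center_frac * nz)`` central planes (always including kz = 0) are
    acquired in every frame; the outer planes are subsampled by the
    acceleration factor AF: a fixed stride subset when static ("scan and
    repeat"), or a fresh seeded uniform draw without replacement per frame
    when dynamic.
    """
    import warnings

    if nz < 1 or not 0 <= center_frac <= 1 or AF < 1:
        raise ValueError("invalid stack-of-spirals parameters")
    kz = (np.arange(nz) - nz // 2) / nz
    order = np.argsort(np.abs(kz), kind="stable")  # centre-out plane ranking
    n_center = int(np.floor(center_frac * nz + 0.5))
    center_planes = np.sort(order[:n_center])
    outer_planes = np.sort(order[n_center:])
    n_outer = len(outer_planes)
    if n_outer == 0:
        chosen_outer = np.array([], dtype=int)
    else:
        n_pick = int(np.ceil(n_outer / AF))
        if AF > n_outer:
            warnings.warn("AF exceeds the number of outer planes; only the centre is acquired")
            chosen_outer = np.array([], dtype=int)
        elif dynamic:
            rng = np.random.default_rng([seed, frame_index])
            chosen_outer = np.sort(rng.choice(outer_planes, size=n_pick, replace=False))
        else:
            stride = outer_planes[:: max(1, int(round(n_outer / n_pick)))][:n_pick]
            chosen_outer = stride
    planes = np.sort(np.concatenate([center_planes, chosen_outer]).astype(int))
    base = spiral_inout(n_samples=n_samples, n_turns=n_turns, Tobs=Tobs)
    shots = []
    for s, iz in enumerate(planes):
        pts = base.samples.copy()
        pts[:, 2] = kz[iz]
        shots.append(Shot(samples=pts, times=base.times.copy(), shot_index=s, kz_plane=int(iz)))
    return SamplingPattern(shots=shots, grid_shape=tuple(int(n) for n in grid_shape), frame_index=frame_index)


def gradients_and_slew(
    shot: Shot, hw: HardwareSpec, grid_shape: tuple[int, int, int]
) -> dict:
    """Finite-difference gradient (mT/m) and slew (T/m/s) audit of a shot.

    Normalised coordinates are converted to physical spatial frequencies
    via the voxel size (fov / matrix); G = dk/dt / gamma.
    """
    if shot.n_samples < 3:
        raise ValueError("need at least 3 samples to audit gradients and slew")
    if hw.fov is None or hw.dwell is None:
        raise ValueError("hardware spec must define fov and dwell")
    vox_m = np.asarray(hw.fov, dtype=np.float64) * 1e-3 / np.asarray(grid_shape)
    k_phys = shot.samples / vox_m  # cycles/m
    dt_s = shot.dwell * 1e-3
    gamma_hz_per_mt = hw.gamma * 1e3
    grad = np.diff(k_phys, axis=0) / dt_s / gamma_hz_per_mt  # mT/m
    slew = np.diff(grad, axis=0) / dt_s * 1e-3  # (mT/m)/s -> T/m/s
    gmag = np.linalg.norm(grad, axis=1)
    smag = np.linalg.norm(slew, axis=1)
    return {
        "gradient": gmag,
        "slew": smag,
        "g_max": float(gmag.max()),
        "s_max": float(smag.max()),
        "ok": bool(gmag.max() <= hw.Gmax and smag.max() <= hw.Smax),
    }


# ---------------------------------------------------------------------------
# Trajectory exchange
# ---------------------------------------------------------------------------

_TRAJ_VERSION = 1


def write_trajectory(pattern: SamplingPattern, path: str):
    """Lossless binary container (zip of float64 arrays + JSON header).

    A ``.csv`` extension selects the plain-text dialect instead: one row per
    sample, columns shot, t, kx, ky, kz.
    """
    if str(path).endswith(".csv"):
        _write_trajectory_csv(pattern, path)
        return
    header = {
        "version": _TRAJ_VERSION,
        "grid_shape": list(pattern.grid_shape),
        "frame_index": pattern.frame_index,
        "n_shots": pattern.n_shots,
        "samples_per_shot": pattern.shots[0].n_samples,
        "kz_planes": [s.kz_plane for s in pattern.shots],
    }
    samples = np.stack([s.samples for s in pattern.shots])
    times = np.stack([s.times for s in pattern.shots])
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header))
        for name, arr in (("samples", samples), ("times", times)):
            buf = io.BytesIO()
            np.save(buf, arr.astype(np.float64))
            zf.writestr(name + ".npy", buf.getvalue())


def _write_trajectory_csv(pattern: SamplingPattern, path: str):
    with open(path, "w") as fh:
        fh.write("# grid_shape=%d,%d,%d\n" % pattern.grid_shape)
        fh.write("shot,t,kx,ky,kz\n")
        for s in pattern.shots:
            for t, (kx, ky, kz) in zip(s.times, s.samples):
                fh.write(
                    f"{s.shot_index},{float(t)!r},{float(kx)!r},{float(ky)!r},{float(kz)!r}\n"
                )


def read_trajectory(path: str) -> SamplingPattern:
    if str(path).endswith(".csv"):
        return _read_trajectory_csv(path)
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            samples = np.load(io.BytesIO(zf.read("samples.npy")))
            times = np.load(io.BytesIO(zf.read("times.npy")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
    if samples.ndim != 3 or samples.shape[0] == 0:
        raise ValueError("trajectory file contains no shots")
    shots = [
        Shot(
            samples=samples[i],
            times=times[i],
            shot_index=i,
            kz_plane=header["kz_planes"][i],
        )
        for i in range(samples.shape[0])
    ]
    return SamplingPattern(
        shots=shots,
        grid_shape=tuple(header["grid_shape"]),
        frame_index=header.get("frame_index", 0),
    )


def _read_trajectory_csv(path: str) -> SamplingPattern:
    import csv

    grid_shape = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "grid_shape=" in line:
                    grid_shape = tuple(int(v) for v in line.split("=")[1].split(","))
                continue
            if line.startswith("shot,"):
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise ValueError(f"malformed trajectory CSV at line {lineno}: {line!r}")
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError("trajectory CSV contains no samples")
    if grid_shape is None:
        raise ValueError("trajectory CSV is missing the grid_shape header line")
    arr = np.asarray(rows)
    shots = []
    for si in np.unique(arr[:, 0]).astype(int):
        sub = arr[arr[:, 0] == si]
        shots.append(Shot(samples=sub[:, 2:5], times=sub[:, 1], shot_index=int(si)))
    return SamplingPattern(shots=shots, grid_shape=grid_shape)
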