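"""Anatomical ground truth: tissue maps, GRE contrast, coils, activation ROI.

The digital phantom is a three-tissue (WM/GM/CSF) fuzzy segmentation on a
regular voxel grid.  Each tissue carries constant MR parameters (proton
density rho, T1, T2*), and the steady-state spoiled GRE signal equation
turns them into a per-tissue contrast at the echo time.  A built-in
generator produces a brain-like phantom from three nested smoothed
ellipsoidal shells, so no external data are needed; NIfTI fraction maps
can be imported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TissueParams",
    "Phantom",
    "ContrastVolume",
    "CoilProfile",
    "RoiMask",
    "DEFAULT_TISSUES",
    "gre_contrast",
    "make_synthetic_phantom",
    "contrast_volume",
    "make_coil_profiles",
    "define_roi",
    "save_phantom_nifti",
    "load_phantom_nifti",
]


@dataclass(frozen=True)
class TissueParams:
    """Constant MR parameters of one tissue class.

    rho is the proton density (arbitrary units), T1 and T2s are the
    longitudinal and effective transverse relaxation times in ms.
    """

    name: str
    rho: float
    T1: float
    T2s: float

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError(f"{self.name}: rho must be >= 0")
        if self.T1 <= 0 or self.T2s <= 0:
            raise ValueError(f"{self.name}: relaxation times must be > 0")


# 7T-like defaults for the three cortical tissue classes.
DEFAULT_TISSUES = (
    TissueParams("WM", rho=0.77, T1=1330.0, T2s=26.0),
    TissueParams("GM", rho=0.86, T1=2000.0, T2s=33.0),
    TissueParams("CSF", rho=1.00, T1=4000.0, T2s=100.0),
)


@dataclass
class Phantom:
    """Fractional tissue maps w_i on a common grid, with voxel geometry."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tissues: tuple[TissueParams, ...]
    fractions: np.ndarray  # (n_tissues, *shape), each in [0, 1]
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.fractions.shape != (len(self.tissues),) + self.shape:
            raise ValueError("fraction fields must share the phantom shape")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValueError("tissue fractions must lie in [0, 1]")
        if np.any(self.fractions.sum(axis=0) > 1 + 1e-9):
            raise ValueError("tissue fractions must sum to at most 1 per voxel")
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            aff[:3, 3] = -np.asarray(self.shape) / 2 * np.asarray(self.voxel_size)
            self.affine = aff

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def tissue_index(self, name: str) -> int:
        for i, t in enumerate(self.tissues):
            if t.name == name:
                return i
        raise KeyError(name)

    def head_mask(self, threshold: float = 0.05) -> np.ndarray:
        """Voxels with a non-negligible total tissue fraction."""
        return self.fractions.sum(axis=0) > threshold


@dataclass
class ContrastVolume:
    """Voxel-wise steady-state contrast mu(r) at the reference time tref."""

    values: np.ndarray
    tref: float  # ms


@dataclass
class CoilProfile:
    """Receiver sensitivities S_l(r) and the coil noise covariance."""

    maps: np.ndarray  # (L, *shape), complex
    covariance: np.ndarray  # (L, L) Hermitian PSD

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        self.covariance = np.asarray(self.covariance, dtype=np.complex128)
        L = self.maps.shape[0]
        if self.covariance.shape != (L, L):
            raise ValueError("covariance must be L x L")
        if not np.allclose(self.covariance, self.covariance.conj().T, atol=1e-10):
            raise ValueError("covariance must be Hermitian")
        evals = np.linalg.eigvalsh(self.covariance)
        if np.min(evals) < -1e-10 * max(1.0, np.max(np.abs(evals))):
            raise ValueError("covariance must be positive semi-definite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass
class RoiMask:
    """Boolean activation region; the spatial ground truth for detection."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_active == 0:
            raise ValueError("ROI is empty")

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())


def gre_contrast(tissue: TissueParams, TR: float, TE: float, FA: float) -> float:
    """Steady-state spoiled-GRE signal of one tissue.

    mu = rho sin(a) (1 - E1) / (1 - cos(a) E1) * exp(-TE/T2*),
    with E1 = exp(-TR/T1); TR, TE in ms, FA in degrees.
    """
    if TR <= 0 or TE < 0:
        raise ValueError("TR must be > 0 and TE >= 0")
    if not 0 <= FA <= 90:
        raise ValueError("flip angle must lie in [0, 90] degrees")
    a = np.deg2rad(FA)
    e1 = np.exp(-TR / tissue.T1)
    return float(
        tissue.rho
        * np.sin(a)
        * (1 - e1)
        / (1 - np.cos(a) * e1)
        * np.exp(-TE / tissue.T2s)
    )


def _ellipsoid(shape, semi_axes, center=None) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    if center is None:
        center = [n / 2 - 0.5 for n in shape]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi_axes))
    return q <= 1.0


def make_synthetic_phantom(
    shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
    tissues: tuple[TissueParams, ...] = DEFAULT_TISSUES,
    smooth_vox: float = 1.0,
) -> Phantom:
    """Three nested smoothed ellipsoidal shells: CSF / GM / WM (out to in).

    Fuzzy boundaries come from Gaussian smoothing (``smooth_vox`` voxels) of
    the binary shells, renormalised so fractions stay in [0,1] and sum to at
    most 1.  Deterministic given (shape, seed); the seed only jitters the
    shell axes slightly so distinct phantoms can be drawn.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 16 for n in shape):
        raise ValueError("phantom grid must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.02 * rng.standard_normal(3)
    base = np.asarray(shape, dtype=np.float64) / 2.0
    outer = _ellipsoid(shape, base * 0.90 * jitter)
    mid = _ellipsoid(shape, base * 0.74 * jitter)
    inner = _ellipsoid(shape, base * 0.52 * jitter)
    shells = np.stack(
        [
            (inner).astype(np.float64),  # WM core
            (mid & ~inner).astype(np.float64),  # GM shell
            (outer & ~mid).astype(np.float64),  # CSF rim
        ]
    )
    order = [t.name for t in tissues]
    by_name = {"WM": shells[0], "GM": shells[1], "CSF": shells[2]}
    frac = np.stack([gaussian_filter(by_name[n], smooth_vox) for n in order])
    total = frac.sum(axis=0)
    over = total > 1.0
    if np.any(over):
        frac[:, over] /= total[over]
    np.clip(frac, 0.0, 1.0, out=frac)
    return Phantom(shape=shape, voxel_size=tuple(voxel_size), tissues=tuple(tissues), fractions=frac)


def contrast_volume(phantom: Phantom, TR: float, TE: float, FA: float) -> ContrastVolume:
    """Voxel-wise contrast: sum_i w_i(r) mu_i at tref = TE."""
    vol = np.zeros(phantom.shape, dtype=np.float64)
    for i, tissue in enumerate(phantom.tissues):
        vol += phantom.fractions[i] * gre_contrast(tissue, TR, TE, FA)
    return ContrastVolume(values=vol, tref=TE)


def make_coil_profiles(
    phantom: Phantom, L: int = 1, covariance: np.ndarray | None = None
) -> CoilProfile:
    """Analytic ring-of-receivers sensitivity model.

    L coils sit at equi-angular positions on a ring around the volume in the
    x-y plane; each magnitude profile is a broad Gaussian peaking towards its
    coil, with a smooth linear phase.  L = 1 returns the uniform profile 1.
    """
    if L < 1:
        raise ValueError("need at least one coil")
    shape = phantom.shape
    if covariance is None:
        covariance = np.eye(L)
    if L == 1:
        return CoilProfile(maps=np.ones((1,) + shape), covariance=covariance)
    nx, ny, nz = shape
    x, y = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij"
    )
    maps = np.empty((L,) + shape, dtype=np.complex128)
    radius = 1.4
    for l in range(L):
        ang = 2 * np.pi * l / L
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        mag = np.exp(-d2 / (2 * 1.0**2))
        phase = np.exp(1j * 0.8 * (np.cos(ang) * x + np.sin(ang) * y))
        maps[l] = (mag * phase)[:, :, None] * np.ones((1, 1, nz))
    # keep the root-sum-of-squares well away from zero inside the head
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss.max()
    return CoilProfile(maps=maps, covariance=covariance)


def define_roi(
    phantom: Phantom,
    center_mm: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
    gm_threshold: float = 0.5,
) -> RoiMask:
    """Activation ROI: gray-matter fraction >= threshold inside an ellipsoid.

    The ellipsoid is given in mm relative to the volume centre.
    """
    vs = np.asarray(phantom.voxel_size)
    center_vox = np.asarray(phantom.shape) / 2 - 0.5 + np.asarray(center_mm) / vs
    semi_vox = np.asarray(semi_axes_mm) / vs
    ell = _ellipsoid(phantom.shape, semi_vox, center=center_vox)
    gm = phantom.fractions[phantom.tissue_index("GM")]
    mask = ell & (gm >= gm_threshold)
    if not mask.any():
        raise ValueError("ROI is empty: the ellipsoid does not intersect GM at this threshold")
    return RoiMask(mask=mask)


def save_phantom_nifti(phantom: Phantom, prefix: str) -> list[str]:
    """One float32 NIfTI per tissue fraction map; returns the file names."""
    import nibabel as nib

    paths = []
    for i, tissue in enumerate(phantom.tissues):
        img = nib.Nifti1Image(phantom.fractions[i].astype(np.float32), phantom.affine)
        path = f"{prefix}_{tissue.name}.nii.gz"
        nib.save(img, path)
        paths.append(path)
    return paths


def load_phantom_nifti(
    paths: list[str],
    tissues: tuple[TissueParams, ...],
    voxel_size: tuple[float, float, float] | None = None,
) -> Phantom:
    import nibabel as nib

    imgs = [nib.load(p) for p in paths]
    frac = np.stack([np.asanyarray(img.dataobj, dtype=np.float64) for img in imgs])
    aff = imgs[0].affine
    if voxel_size is None:
        voxel_size = tuple(np.abs(np.diag(aff)[:3]))
    return Phantom(
        shape=frac.shape[1:],
        voxel_size=voxel_size,
        tissues=tuple(tissues),
        fractions=np.clip(frac, 0, 1),
        affine=aff,
    )
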