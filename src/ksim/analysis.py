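"""Score a reconstructed series against the ground truth.

Voxel-wise ordinary-least-squares GLM with a task regressor (paradigm
convolved with the same HRF used in simulation, sampled at the frame
timestamps) and a constant; one-sided Student-t detection at an
uncorrected threshold; confusion metrics, precision/recall curve and its
AUC, balanced accuracy; image quality (PSNR/SSIM) and temporal SNR.
Precision/recall is preferred over ROC because active voxels are rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import Paradigm, hemodynamic_signal
from .phantom import ContrastVolume, RoiMask

__all__ = [
    "DesignMatrix",
    "StatMap",
    "StatReport",
    "make_design_matrix",
    "glm_tstats",
    "threshold_map",
    "confusion_metrics",
    "pr_curve_auc",
    "image_metrics",
    "tsnr",
    "evaluate_series",
]


@dataclass
class DesignMatrix:
    """Named regressor columns; the task column is first."""

    matrix: np.ndarray  # (T, k)
    names: tuple[str, ...]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def T(self) -> int:
        return self.matrix.shape[0]


@dataclass
class StatMap:
    """Voxel-wise Student-t statistics for the task contrast."""

    tvalues: np.ndarray
    dof: int
    degenerate: np.ndarray = None  # zero-variance voxels, excluded from curves
    beta_task: np.ndarray = None
    beta_const: np.ndarray = None

    def __post_init__(self):
        if self.dof <= 0:
            raise ValueError("residual degrees of freedom must be positive")
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.tvalues, dtype=bool)


@dataclass
class StatReport:
    """All detection and quality metrics of one reconstruction run."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    bacc: float
    auc: float
    pr_curve: tuple = ()
    tsnr_roi: float = float("nan")
    tsnr_roi_raw: float = float("nan")
    psnr: float = float("nan")
    ssim: float = float("nan")
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return str(v)
            return v

        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": clean(self.precision), "recall": clean(self.recall),
            "bacc": clean(self.bacc), "auc": clean(self.auc),
            "tsnr_roi": clean(self.tsnr_roi), "tsnr_roi_raw": clean(self.tsnr_roi_raw),
            "psnr": clean(self.psnr), "ssim": clean(self.ssim),
            **{k: clean(v) for k, v in self.extras.items()},
        }


def make_design_matrix(
    paradigm: Paradigm, frame_times_s: np.ndarray, TR_shot: float = 50.0
) -> DesignMatrix:
    """Task (paradigm * HRF at the frame timestamps) plus a constant."""
    sig = hemodynamic_signal(paradigm, TR_shot)
    task = np.interp(frame_times_s, sig.times, sig.values)
    X = np.stack([task, np.ones_like(task)], axis=1)
    return DesignMatrix(matrix=X, names=("task", "constant"))


def glm_tstats(series: np.ndarray, design: DesignMatrix) -> StatMap:
    """Voxel-wise OLS; t for the one-sided positivity of the task effect.

    ``series`` is (T, *spatial) magnitude data.  Voxels with zero residual
    variance get t = 0 and a degeneracy flag.
    """
    X = design.matrix
    T, k = X.shape
    if series.shape[0] != T:
        raise ValueError("series length does not match the design")
    if T < k + 1:
        raise ValueError("need more frames than regressors")
    spatial = series.shape[1:]
    Y = series.reshape(T, -1).astype(np.float64)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # (k, V)
    resid = Y - X @ beta
    dof = T - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[0, 0])
    # voxels whose temporal scatter is indistinguishable from zero — in
    # particular below the single-precision quantisation of the raw-data
    # container — carry no temporal information; they get t = 0 and a flag
    level = np.abs(Y).mean(axis=0)
    scale = level + level.mean()
    degenerate = Y.std(axis=0) <= np.maximum(1e-5 * scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[0] / np.where(se > 0, se, 1.0), np.where(beta[0] > 0, np.inf, 0.0))
        t = np.where(degenerate, 0.0, t)
    return StatMap(
        tvalues=t.reshape(spatial),
        dof=int(dof),
        degenerate=degenerate.reshape(spatial),
        beta_task=beta[0].reshape(spatial),
        beta_const=beta[-1].reshape(spatial),
    )


def threshold_map(stat: StatMap, p: float = 0.001) -> np.ndarray:
    """One-sided detection mask: t above the Student quantile at level p."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    thr = stats.t.ppf(1 - p, stat.dof)
    return stat.tvalues > thr


def confusion_metrics(detection: np.ndarray, truth: RoiMask | np.ndarray) -> dict:
    """Confusion counts, precision, recall and balanced accuracy."""
    t = truth.mask if isinstance(truth, RoiMask) else np.asarray(truth, dtype=bool)
    d = np.asarray(detection, dtype=bool)
    if d.shape != t.shape:
        raise ValueError("detection and truth masks must share the shape")
    tp = int((d & t).sum())
    fp = int((d & ~t).sum())
    fn = int((~d & t).sum())
    tn = int((~d & ~t).sum())
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    tnr = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "precision": precision, "precision_defined": precision_defined,
        "recall": recall,
        "bacc": 0.5 * (recall + tnr),
    }


def pr_curve_auc(
    stat: StatMap | np.ndarray, truth: RoiMask | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall over all score thresholds; AUC by trapezoid in recall.

    Degenerate voxels are excluded.  The recall = 0 endpoint duplicates the
    highest-threshold precision.  Returns (recall, precision, auc).
    """
    if isinstance(stat, StatMap):
        scores = stat.tvalues[~stat.degenerate].ravel()
        t = (truth.mask if isinstance(truth, RoiMask) else truth)[~stat.degenerate].ravel()
    else:
        scores = np.asarray(stat).ravel()
        t = (truth.mask if isinstance(truth, RoiMask) else np.asarray(truth)).ravel()
    t = t.astype(bool)
    if not t.any():
        raise ValueError("ground-truth mask is empty")
    order = np.argsort(-scores, kind="stable")
    labels = t[order]
    # group ties: cut only where the score changes
    s_sorted = scores[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cum_tp = np.cumsum(labels)
    idx = np.concatenate([distinct, [len(labels) - 1]])
    tp = cum_tp[idx].astype(np.float64)
    n_pred = idx + 1.0
    precision = tp / n_pred
    recall = tp / t.sum()
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(precision, recall))
    return recall, precision, auc


def image_metrics(recon: np.ndarray, reference: ContrastVolume | np.ndarray) -> dict:
    """PSNR (peak = max |reference|) and SSIM on magnitude images."""
    from skimage.metrics import structural_similarity

    ref = reference.values if isinstance(reference, ContrastVolume) else np.asarray(reference)
    ref = np.abs(ref).astype(np.float64)
    img = np.abs(np.asarray(recon)).astype(np.float64)
    if img.shape != ref.shape:
        raise ValueError("reconstruction and reference must share the shape")
    peak = ref.max()
    if peak <= 0:
        raise ValueError("reference image is identically zero")
    mse = float(np.mean((img - ref) ** 2))
    psnr = float("inf") if mse == 0 else float(10 * np.log10(peak**2 / mse))
    ssim = float(structural_similarity(img, ref, data_range=peak))
    return {"psnr": psnr, "ssim": ssim}


def tsnr(
    series: np.ndarray,
    roi: RoiMask | np.ndarray,
    design: DesignMatrix | None = None,
) -> dict:
    """Temporal SNR averaged over the ROI.

    Voxel-wise temporal mean over temporal standard deviation.  When a
    design is given, the fitted task component is removed first so evoked
    activity does not inflate the "noise" (the raw-series value is also
    returned).  Zero-variance voxels are flagged (infinite tSNR) and
    excluded from the average when any finite voxel exists.
    """
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    T = series.shape[0]
    if T < 2:
        raise ValueError("need at least two frames for tSNR")
    Y = series.reshape(T, -1)[:, mask.ravel()].astype(np.float64)

    def _avg(yy):
        m = yy.mean(axis=0)
        s = yy.std(axis=0, ddof=1)
        finite = s > 0
        if not finite.any():
            return float("inf"), int((~finite).sum())
        return float(np.mean(m[finite] / s[finite])), int((~finite).sum())

    raw, n_flag_raw = _avg(Y)
    if design is None:
        return {"tsnr": raw, "tsnr_raw": raw, "n_zero_variance": n_flag_raw}
    X = design.matrix
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    task_cols = [i for i, n in enumerate(design.names) if n == "task"]
    detrended = Y - X[:, task_cols] @ beta[task_cols]
    det, n_flag = _avg(detrended)
    return {"tsnr": det, "tsnr_raw": raw, "n_zero_variance": n_flag}


def evaluate_series(
    series_mag: np.ndarray,
    paradigm: Paradigm,
    frame_times_s: np.ndarray,
    truth_roi: RoiMask,
    reference: ContrastVolume | np.ndarray | None = None,
    p: float = 0.001,
    TR_shot: float = 50.0,
) -> StatReport:
    """Full statistical evaluation of a reconstructed magnitude series."""
    design = make_design_matrix(paradigm, frame_times_s, TR_shot)
    stat = glm_tstats(series_mag, design)
    detection = threshold_map(stat, p)
    conf = confusion_metrics(detection, truth_roi)
    recall_c, precision_c, auc = pr_curve_auc(stat, truth_roi)
    ts = tsnr(series_mag, truth_roi, design)
    report = StatReport(
        tp=conf["tp"], fp=conf["fp"], tn=conf["tn"], fn=conf["fn"],
        precision=conf["precision"], recall=conf["recall"], bacc=conf["bacc"],
        auc=auc, pr_curve=(recall_c, precision_c),
        tsnr_roi=ts["tsnr"], tsnr_roi_raw=ts["tsnr_raw"],
    )
    if reference is not None:
        im = image_metrics(series_mag.mean(axis=0), reference)
        report.psnr = im["psnr"]
        report.ssim = im["ssim"]
    report.extras["p_threshold"] = p
    report.extras["dof"] = stat.dof
    return report
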