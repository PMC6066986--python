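"""Offline quality control and GLM validation.

Desk-scale counterpart of the offline analysis around the engine: motion
artifact flagging (translations over 3 mm or rotations over 0.02 rad),
SPM-style high-pass filtering via discrete-cosine basis regression (cutoff
456 s for SVM sessions, 152 s for ROI sessions — twice the longest gap
between repetitions of the same stimulus), and a voxelwise ordinary-least-
squares GLM that checks planted effects are recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .design import Condition, Method, RunSchedule
from .phantom import _block_regressors

TRANSLATION_THRESH_MM = 3.0
ROTATION_THRESH_RAD = 0.02

HIGHPASS_CUTOFF_S = {Method.SVM: 456.0, Method.ROI: 152.0}


def detect_artifacts(
    motion: np.ndarray,
    trans_thresh_mm: float = TRANSLATION_THRESH_MM,
    rot_thresh_rad: float = ROTATION_THRESH_RAD,
    mode: str = "absolute",
) -> np.ndarray:
    """Flag volumes whose motion exceeds the thresholds (strictly).

    ``motion`` is (n_volumes, 6): three translations in mm, three rotations
    in radians. ``mode`` "absolute" tests the parameters themselves;
    "delta" tests frame-to-frame differences (first frame vs zero).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or not np.all(np.isfinite(motion)):
        raise ValueError("motion must be a finite (n_volumes, 6) array")
    if trans_thresh_mm <= 0 or rot_thresh_rad <= 0:
        raise ValueError("thresholds must be positive")
    if mode == "delta":
        motion = np.diff(motion, axis=0, prepend=np.zeros((1, 6)))
    elif mode != "absolute":
        raise ValueError("mode must be 'absolute' or 'delta'")
    trans_bad = np.any(np.abs(motion[:, :3]) > trans_thresh_mm, axis=1)
    rot_bad = np.any(np.abs(motion[:, 3:]) > rot_thresh_rad, axis=1)
    return trans_bad | rot_bad


def dct_basis(n_volumes: int, cutoff_s: float, tr_s: float) -> np.ndarray:
    """Discrete-cosine drift basis (SPM convention), columns k = 1..K with
    K = floor(2 * n * tr / cutoff); empty (n, 0) when the cutoff removes
    nothing."""
    n = int(n_volumes)
    order = int(np.floor(2.0 * n * tr_s / cutoff_s))
    t = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def highpass(signal: np.ndarray, cutoff_s: float, tr_s: float) -> np.ndarray:
    """Regress discrete-cosine drift components out of a series (time last
    axis); frequencies below 1/cutoff are removed and the mean is preserved."""
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n < 2:
        raise ValueError("series must contain at least 2 volumes")
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff_s must exceed 2 * tr_s")
    X = dct_basis(n, cutoff_s, tr_s)
    if X.shape[1] == 0:
        return signal.copy()
    flat = signal.reshape(-1, n)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    out = flat - (X @ beta).T
    return out.reshape(signal.shape)


@dataclass
class GlmDesign:
    """Design matrix for the voxelwise GLM, with named columns."""

    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            bad = self._dependent_columns()
            raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")

    def _dependent_columns(self) -> list[str]:
        bad, kept = [], []
        for j in range(self.X.shape[1]):
            trial = self.X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) < len(kept) + 1:
                bad.append(self.names[j])
            else:
                kept.append(j)
        return bad

    def column(self, name: str) -> int:
        return self.names.index(name)


def build_glm_design(
    schedule: RunSchedule,
    cutoff_s: Optional[float] = None,
    motion: Optional[np.ndarray] = None,
    artifact_flags: Optional[np.ndarray] = None,
) -> GlmDesign:
    """Condition regressors (HRF-convolved boxcars) + intercept + DCT drift
    basis + demeaned motion covariates + one indicator column per flagged
    volume; all over the run's non-dummy volumes."""
    n = schedule.n_volumes
    if cutoff_s is None:
        cutoff_s = HIGHPASS_CUTOFF_S[schedule.method]
    regs = _block_regressors(schedule)[:, schedule.n_dummy :]
    cols, names = [], []
    for cond in (Condition.TENDERNESS, Condition.ANGUISH):
        r = np.zeros(n)
        for b, block in enumerate(schedule.blocks):
            if block.condition == cond:
                r += regs[b]
        cols.append(r)
        names.append(cond.value)
    cols.append(np.ones(n))
    names.append("intercept")
    dct = dct_basis(n, cutoff_s, schedule.tr_s)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"dct_{k + 1}")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n:
            raise ValueError("motion covariates must have one row per non-dummy volume")
        for j in range(6):
            cols.append(motion[:, j] - motion[:, j].mean())
            names.append(f"motion_{j}")
    if artifact_flags is not None:
        for v in np.flatnonzero(np.asarray(artifact_flags, dtype=bool)):
            ind = np.zeros(n)
            ind[v] = 1.0
            cols.append(ind)
            names.append(f"artifact_{v}")
    return GlmDesign(np.column_stack(cols), names)


@dataclass
class GlmResult:
    betas: np.ndarray  # (*grid, n_regressors)
    t_maps: dict[str, np.ndarray]  # contrast name -> 3D t map
    contrast_estimates: dict[str, np.ndarray]
    residual_variance: np.ndarray  # 3D
    design: GlmDesign

    def psc_beta(self, condition: Condition | str) -> np.ndarray:
        """Condition amplitude as a PSC fraction: beta_condition / beta_intercept."""
        c = self.design.column(Condition(condition).value)
        i = self.design.column("intercept")
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.betas[..., c] / self.betas[..., i]


DEFAULT_CONTRASTS = {
    "tenderness": {Condition.TENDERNESS.value: 1.0},
    "anguish": {Condition.ANGUISH.value: 1.0},
    "tenderness-anguish": {Condition.TENDERNESS.value: 1.0, Condition.ANGUISH.value: -1.0},
    "anguish-tenderness": {Condition.TENDERNESS.value: -1.0, Condition.ANGUISH.value: 1.0},
}


def fit_glm(
    volumes: np.ndarray,
    design: GlmDesign,
    contrasts: Optional[dict[str, dict[str, float]]] = None,
) -> GlmResult:
    """Voxelwise OLS: betas and contrast t-statistics.

    ``volumes`` is (x, y, z, t) with dummies stripped; t must match the
    design. t = c'b / sqrt(sigma2 * c'(X'X)^-1 c) with sigma2 from the
    residuals at n - p degrees of freedom.
    """
    X = design.X
    n, p = X.shape
    if volumes.shape[-1] != n:
        raise ValueError("volumes and design must cover the same number of volumes")
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    grid = volumes.shape[:3]
    Y = volumes.reshape(-1, n).T  # (n, n_vox)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # (p, n_vox)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof

    t_maps, est_maps = {}, {}
    for name, weights in contrasts.items():
        c = np.zeros(p)
        for col, wgt in weights.items():
            c[design.column(col)] = wgt
        est = c @ beta
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(var)
        t_maps[name] = t.reshape(grid)
        est_maps[name] = est.reshape(grid)

    return GlmResult(
        betas=beta.T.reshape(*grid, p),
        t_maps=t_maps,
        contrast_estimates=est_maps,
        residual_variance=sigma2.reshape(grid),
        design=design,
    )


def qc_report(
    motion: np.ndarray,
    schedule: RunSchedule,
    cutoff_s: Optional[float] = None,
    mode: str = "absolute",
) -> dict:
    """Summary of the QC stage for one run, serializable as JSON."""
    flags = detect_artifacts(motion, mode=mode)
    if cutoff_s is None:
        cutoff_s = HIGHPASS_CUTOFF_S[schedule.method]
    return {
        "run_index": schedule.run_index,
        "method": schedule.method.value,
        "n_volumes": int(motion.shape[0]),
        "n_flagged": int(flags.sum()),
        "flagged_volumes": [int(v) for v in np.flatnonzero(flags)],
        "translation_threshold_mm": TRANSLATION_THRESH_MM,
        "rotation_threshold_rad": ROTATION_THRESH_RAD,
        "artifact_mode": mode,
        "highpass_cutoff_s": float(cutoff_s),
    }


def write_qc_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
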