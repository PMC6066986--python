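"""ROI-method neurofeedback: training-run voxel mapping and per-volume
percent-signal-change feedback against a sigmoid-weighted neutral baseline.

The training run maps, inside each a-priori anatomical ROI, the 10% of
voxels most activated by the target emotion versus the preceding neutral
blocks. During feedback runs the signal is the PSC of the current volume's
mean over those selected voxels relative to a weighted mean of the previous
neutral block:

    f = (ROI_curr - m) / m,    m = sum_k sig(k) * ROI_k / sum_k sig(k)

where ``ROI_k`` is the selected-voxel mean of the k-th baseline volume and
``sig(k) = 1 / (1 + exp(-(k - B/2)))`` down-weights early baseline volumes
still contaminated by the previous block's hemodynamic decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .design import Condition, EMOTIONS

DEFAULT_FRACTION = 0.10


def sigmoid_weights(n_baseline: int) -> np.ndarray:
    """sig(k) = 1/(1+exp(-(k - B/2))) for k = 1..B."""
    if n_baseline < 1:
        raise ValueError("baseline must contain at least one volume")
    k = np.arange(1, n_baseline + 1, dtype=float)
    return 1.0 / (1.0 + np.exp(-(k - n_baseline / 2.0)))


@dataclass(frozen=True)
class RoiDefinition:
    """An anatomical ROI tied to the emotion it is the feedback target for."""

    name: str
    mask: np.ndarray  # 3D boolean
    target_condition: Condition

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "target_condition", Condition(self.target_condition))
        if not mask.any():
            raise ValueError("ROI mask is empty")
        if self.target_condition not in EMOTIONS:
            raise ValueError("target_condition must be an emotion")


@dataclass
class TrainedRoiModel:
    """Selected top-fraction voxel set of an ROI plus its source statistic map."""

    roi: RoiDefinition
    selected_voxels: np.ndarray  # linear indices into the flattened grid
    fraction: float
    stat_map: np.ndarray  # 3D, NaN outside mask / at excluded voxels

    def roi_mean(self, volume: np.ndarray) -> float:
        """Mean signal over the selected voxels of one 3D volume."""
        return float(np.mean(volume.ravel()[self.selected_voxels]))


class BaselineBuffer:
    """Selected-voxel means of the current neutral block, in arrival order.

    Reset at every neutral-block onset; queried during the following emotion
    block via :meth:`weighted_mean`.
    """

    def __init__(self) -> None:
        self.roi_means: list[float] = []

    @property
    def B(self) -> int:
        return len(self.roi_means)

    def reset(self) -> None:
        self.roi_means = []

    def append(self, roi_mean: float) -> None:
        self.roi_means.append(float(roi_mean))

    @property
    def weights(self) -> np.ndarray:
        return sigmoid_weights(self.B)

    def weighted_mean(self) -> float:
        return weighted_baseline_mean(self)


def update_baseline(
    buffer: BaselineBuffer,
    volume: np.ndarray,
    model: TrainedRoiModel,
    condition: Condition | str = Condition.NEUTRAL,
) -> BaselineBuffer:
    """Append the current volume's selected-voxel mean to the baseline buffer.

    Only valid during a neutral block (the baseline condition).
    """
    if Condition(condition) != Condition.NEUTRAL:
        raise ValueError("baseline updates are only valid during neutral blocks")
    buffer.append(model.roi_mean(volume))
    return buffer


def weighted_baseline_mean(buffer: BaselineBuffer) -> float:
    """m = sum_k sig(k) * ROI_k / sum_k sig(k)."""
    if buffer.B < 1:
        raise ValueError("no baseline established (empty buffer)")
    w = sigmoid_weights(buffer.B)
    x = np.asarray(buffer.roi_means)
    wn = w / np.sum(w)  # normalize first: B = 1 returns the value exactly
    return float(np.sum(wn * x))


def compute_psc_feedback(curr_roi_mean: float, buffer: BaselineBuffer) -> float:
    """Dimensionless PSC of the current volume against the weighted baseline."""
    m = weighted_baseline_mean(buffer)
    if m == 0:
        raise ZeroDivisionError("weighted baseline mean is zero; PSC undefined")
    return (float(curr_roi_mean) - m) / m


# ---------------------------------------------------------------------------
# training-run mapping


def _contiguous_blocks(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """(label, start, stop) for each maximal run of equal labels."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start, i))
            start = i
    return out


def compute_activation_stat(
    training_volumes: np.ndarray,
    labels: Sequence[str],
    roi: RoiDefinition,
) -> np.ndarray:
    """Per-voxel activation statistic inside the ROI mask.

    For each target-emotion block: (block mean - preceding-neutral mean) /
    preceding-neutral mean, per voxel; averaged over the run's target blocks.
    ``training_volumes`` is (x, y, z, t) with dummies already stripped;
    ``labels`` are the shifted per-volume condition labels.

    Voxels whose preceding-neutral mean is zero in any block are excluded
    (NaN) with a warning. Returns a 3D map, NaN outside the mask.
    """
    if training_volumes.shape[-1] != len(labels):
        raise ValueError("labels must match the number of volumes")
    target = roi.target_condition.value
    blocks = _contiguous_blocks(list(labels))
    flat = training_volumes.reshape(-1, training_volumes.shape[-1])
    roi_idx = np.flatnonzero(roi.mask.ravel())

    per_block = []
    for j, (lab, start, stop) in enumerate(blocks):
        if lab != target:
            continue
        # the immediately preceding neutral run of volumes
        prev = None
        for lab2, s2, e2 in reversed(blocks[:j]):
            if lab2 == Condition.NEUTRAL.value:
                prev = (s2, e2)
                break
            if lab2 in (e.value for e in EMOTIONS):
                break
        if prev is None:
            raise ValueError("target block without a preceding neutral block")
        block_mean = flat[roi_idx, start:stop].mean(axis=1)
        neut_mean = flat[roi_idx, prev[0] : prev[1]].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_block.append((block_mean - neut_mean) / neut_mean)
        if np.any(neut_mean == 0):
            warnings.warn(
                f"{int(np.sum(neut_mean == 0))} ROI voxels with zero neutral mean excluded",
                RuntimeWarning,
                stacklevel=2,
            )
    if not per_block:
        raise ValueError(f"no {target} blocks in the training labels")

    stat_roi = np.mean(np.stack(per_block), axis=0)
    stat = np.full(roi.mask.shape, np.nan)
    stat.ravel()[roi_idx] = stat_roi
    return stat


def select_top_voxels(
    stat_map: np.ndarray,
    mask: np.ndarray,
    fraction: float = DEFAULT_FRACTION,
) -> np.ndarray:
    """Linear indices of the ceil(fraction * |mask|) most active voxels.

    "Most active" means largest positive statistic; ties break toward the
    lowest linear voxel index, NaN statistics sort last. The result is
    returned sorted by voxel index.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("mask is empty")
    n_sel = int(np.ceil(fraction * idx.size))
    stats = stat_map.ravel()[idx]
    keys = np.where(np.isnan(stats), -np.inf, stats)
    # stable sort on index (already ascending), then stable sort descending on
    # statistic -> ties resolved by ascending linear index
    order = np.argsort(-keys, kind="stable")
    return np.sort(idx[order[:n_sel]])


def train_roi_model(
    training_volumes: np.ndarray,
    labels: Sequence[str],
    roi: RoiDefinition,
    fraction: float = DEFAULT_FRACTION,
) -> TrainedRoiModel:
    """Map the most active voxels of an ROI from the training run."""
    stat = compute_activation_stat(training_volumes, labels, roi)
    selected = select_top_voxels(stat, roi.mask, fraction)
    return TrainedRoiModel(roi, selected, fraction, stat)


# ---------------------------------------------------------------------------
# serialization


def save_roi_model(model: TrainedRoiModel, out_dir: str | Path) -> None:
    """Selected voxels as a NIfTI mask + YAML sidecar; stat map as NIfTI."""
    import nibabel as nib

    from .phantom import _affine

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel_mask = np.zeros(model.roi.mask.shape, dtype=np.uint8)
    sel_mask.ravel()[model.selected_voxels] = 1
    nib.Nifti1Image(sel_mask, _affine()).to_filename(
        str(out / f"{model.roi.name}_selected.nii")
    )
    nib.Nifti1Image(model.stat_map.astype(np.float32), _affine()).to_filename(
        str(out / f"{model.roi.name}_stat.nii")
    )
    finite = model.stat_map[np.isfinite(model.stat_map)]
    sidecar = {
        "roi_name": model.roi.name,
        "target_condition": model.roi.target_condition.value,
        "fraction": model.fraction,
        "n_selected": int(model.selected_voxels.size),
        "stat_summary": {
            "max": float(finite.max()),
            "mean": float(finite.mean()),
        },
    }
    with open(out / f"{model.roi.name}_model.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
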