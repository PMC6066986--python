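"""SVM-method neurofeedback: multivoxel pattern decoding of tenderness
versus anguish with cumulative retraining across runs.

Each emotion-block volume is converted to a feature vector of per-voxel PSC
relative to the previous neutral block, restricted to a feature-selection
mask. A soft-margin linear SVM separates tenderness from anguish patterns;
the feedback signal is the signed projection x.w + b onto the hyperplane
normal, re-oriented so that larger values always mean stronger engagement of
the current block's target emotion. At every run boundary the model is
refitted on all examples observed so far (cumulative training).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from sklearn.svm import SVC

from .design import Condition
from .roi import sigmoid_weights

DEFAULT_C = 1.0
#: numeric class codes; tenderness sits on the positive side of the hyperplane
CLASS_CODES = {Condition.TENDERNESS: 1, Condition.ANGUISH: -1}


def extract_features(
    volume: np.ndarray,
    feature_mask: np.ndarray,
    neutral_baseline: np.ndarray,
) -> np.ndarray:
    """Per-voxel PSC of a volume relative to the previous neutral block.

    ``neutral_baseline`` holds per-voxel (sigmoid-)weighted means of the
    previous neutral block over the masked voxels, in mask order.
    """
    mask = np.asarray(feature_mask, dtype=bool)
    vals = volume.ravel()[np.flatnonzero(mask.ravel())]
    base = np.asarray(neutral_baseline, dtype=float)
    if base.shape != vals.shape:
        raise ValueError("baseline length must equal the number of mask voxels")
    if np.any(base == 0):
        raise ZeroDivisionError("zero baseline voxel; PSC undefined")
    return (vals - base) / base


def neutral_block_baseline(
    neutral_volumes: Sequence[np.ndarray], feature_mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Sigmoid-weighted per-voxel mean over a neutral block's volumes.

    ``neutral_volumes`` are 3D volumes when ``feature_mask`` is given, or
    already-masked 1D vectors when it is None.
    """
    if len(neutral_volumes) < 1:
        raise ValueError("no baseline established (no neutral volumes)")
    if feature_mask is not None:
        mask_idx = np.flatnonzero(np.asarray(feature_mask, dtype=bool).ravel())
        stack = np.stack([np.asarray(v).ravel()[mask_idx] for v in neutral_volumes])
    else:
        stack = np.stack([np.asarray(v, dtype=float) for v in neutral_volumes])
    w = sigmoid_weights(stack.shape[0])
    return (w[:, None] * stack).sum(axis=0) / w.sum()


@dataclass
class TrainingStore:
    """Append-only store of labeled emotion-block feature vectors."""

    X: list[np.ndarray] = field(default_factory=list)
    y: list[int] = field(default_factory=list)  # CLASS_CODES values
    run_index: list[int] = field(default_factory=list)
    volume_index: list[int] = field(default_factory=list)

    def add(self, x: np.ndarray, label: Condition | str, run_index: int, volume_index: int) -> None:
        label = Condition(label)
        if label not in CLASS_CODES:
            raise ValueError("training labels must be tenderness or anguish")
        self.X.append(np.asarray(x, dtype=float))
        self.y.append(CLASS_CODES[label])
        self.run_index.append(int(run_index))
        self.volume_index.append(int(volume_index))

    def extend(self, other: "TrainingStore") -> None:
        self.X.extend(other.X)
        self.y.extend(other.y)
        self.run_index.extend(other.run_index)
        self.volume_index.extend(other.volume_index)

    def __len__(self) -> int:
        return len(self.y)

    def digest(self) -> str:
        h = hashlib.sha256()
        for x, y in zip(self.X, self.y):
            h.update(np.asarray(x).tobytes())
            h.update(bytes([y & 0xFF]))
        return h.hexdigest()[:16]


@dataclass
class SvmModel:
    """Linear hyperplane (w, b) with tenderness on the positive side."""

    w: np.ndarray
    b: float
    C: float = DEFAULT_C
    class_orientation: str = "tenderness_positive"
    store_digest: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if np.linalg.norm(self.w) == 0:
            raise ValueError("degenerate hyperplane (zero normal vector)")


def train(store: TrainingStore, C: float = DEFAULT_C) -> SvmModel:
    """Fit a soft-margin linear SVM on all stored examples.

    Deterministic for a fixed store: the quadratic program is solved to a
    tight tolerance with no stochastic components.
    """
    if len(store) == 0 or len(set(store.y)) < 2:
        raise ValueError("training requires examples of both classes")
    X = np.stack(store.X)
    y = np.asarray(store.y)
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(X, y)
    # sklearn orders classes ascending (-1, +1), so coef_ points toward +1
    # (tenderness), matching the declared orientation
    return SvmModel(
        w=clf.coef_.ravel().copy(),
        b=float(clf.intercept_[0]),
        C=C,
        store_digest=store.digest(),
    )


def retrain_cumulative(
    model: SvmModel, store: TrainingStore, new_run_examples: TrainingStore
) -> SvmModel:
    """Extend the store with a finished run's examples and refit from scratch.

    Cumulative training is batch semantics: the returned model equals
    ``train`` on the concatenated store exactly.
    """
    store.extend(new_run_examples)
    return train(store, C=model.C)


def project(model: SvmModel, x: np.ndarray) -> float:
    """Signed hyperplane projection x.w + b."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != model.w.shape:
        raise ValueError(f"feature dimension {x.size} != model dimension {model.w.size}")
    return float(x @ model.w + model.b)


def decode_feedback(model: SvmModel, x: np.ndarray, current_condition: Condition | str) -> float:
    """Projection re-oriented toward the current block's target emotion.

    Tenderness blocks reward positive projections, anguish blocks negative
    ones, so the returned value always grows with engagement of the target.
    """
    cond = Condition(current_condition)
    if cond not in CLASS_CODES:
        raise ValueError("feedback is only defined during emotion blocks")
    p = project(model, x)
    return p if cond == Condition.TENDERNESS else -p


def predict(model: SvmModel, x: np.ndarray) -> Condition:
    """Decoded class of a feature vector (ties go to tenderness)."""
    return Condition.TENDERNESS if project(model, x) >= 0 else Condition.ANGUISH


# ---------------------------------------------------------------------------
# serialization


def save_svm_model(
    model: SvmModel, feature_mask: np.ndarray, out_dir: str | Path, name: str = "svm"
) -> None:
    """w as a NIfTI map over the feature mask + YAML sidecar."""
    import nibabel as nib

    from .phantom import _affine

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w_map = np.zeros(np.asarray(feature_mask).shape, dtype=np.float32)
    w_map.ravel()[np.flatnonzero(np.asarray(feature_mask, dtype=bool).ravel())] = model.w
    nib.Nifti1Image(w_map, _affine()).to_filename(str(out / f"{name}_weights.nii"))
    sidecar = {
        "b": float(model.b),
        "C": float(model.C),
        "class_orientation": model.class_orientation,
        "training_store_digest": model.store_digest,
    }
    with open(out / f"{name}_model.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
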