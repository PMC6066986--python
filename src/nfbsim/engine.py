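"""Closed-loop feedback engine: stream volumes one per TR, dispatch to the
active method, map feedback to color saturation, log everything.

The engine discards the leading dummy volumes, updates baselines during
neutral blocks, and during emotion blocks emits one feedback sample per
volume (every TR = 2 s). Feedback is mapped to the saturation of the virtual
environment's hue — orange for tenderness, purple for anguish, baseline
tones for neutral — by a clipped linear ramp reaching full saturation at
``f_max``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import phantom as ph
from .design import (
    Condition,
    DEFAULT_N_DUMMY,
    DEFAULT_SHIFT_VOLUMES,
    DEFAULT_TR_S,
    Method,
    RunSchedule,
    SessionDesign,
    block_index_per_volume,
    label_volumes,
)
from .roi import BaselineBuffer, TrainedRoiModel, compute_psc_feedback, train_roi_model
from .roi import RoiDefinition
from .svm import (
    SvmModel,
    TrainingStore,
    decode_feedback,
    extract_features,
    neutral_block_baseline,
    project,
    retrain_cumulative,
    train,
)

HUE_BY_CONDITION = {
    Condition.TENDERNESS: "orange",
    Condition.ANGUISH: "purple",
    Condition.NEUTRAL: "baseline",
}

DEFAULT_F_MAX_ROI = 0.02  # 2% PSC maps to full saturation


@dataclass(frozen=True)
class EngineConfig:
    method: Method
    tr_s: float = DEFAULT_TR_S
    n_dummy: int = DEFAULT_N_DUMMY
    shift_volumes: int = DEFAULT_SHIFT_VOLUMES
    f_max: Optional[float] = None  # None -> method default
    n_levels: Optional[int] = None  # None -> continuous saturation
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        if self.f_max is not None and self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if self.n_levels is not None and self.n_levels < 2:
            raise ValueError("n_levels must be >= 2 when set")


@dataclass(frozen=True)
class FeedbackSample:
    run_index: int
    volume_index: int  # non-dummy volume index within the run
    time_s: float
    block_id: int
    condition: Condition
    raw_feedback: float
    saturation: float
    hue_target: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")


@dataclass
class FeedbackLog:
    samples: list[FeedbackSample] = field(default_factory=list)
    config_digest: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": [s.run_index for s in self.samples],
                "volume": [s.volume_index for s in self.samples],
                "time_s": [s.time_s for s in self.samples],
                "block": [s.block_id for s in self.samples],
                "condition": [s.condition.value for s in self.samples],
                "raw_feedback": [s.raw_feedback for s in self.samples],
                "saturation": [s.saturation for s in self.samples],
                "hue_target": [s.hue_target for s in self.samples],
            }
        )

    def write_tsv(self, path: str | Path, method: Method | None = None) -> None:
        df = self.to_dataframe()
        if method is not None:
            df.insert(5, "method", Method(method).value)
        df.to_csv(path, sep="\t", index=False)


def config_digest(config: EngineConfig) -> str:
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def map_feedback_to_saturation(
    raw: float, f_max: float, n_levels: Optional[int] = None
) -> float:
    """clip(raw / f_max, 0, 1), optionally quantized to ``n_levels`` steps."""
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    s = float(np.clip(raw / f_max, 0.0, 1.0))
    if n_levels is not None:
        if n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        s = round(s * (n_levels - 1)) / (n_levels - 1)
    return s


RoiModels = dict[Condition, TrainedRoiModel]


@dataclass
class SvmBundle:
    """Trained SVM hyperplane plus the mask and store it operates on."""

    model: Optional[SvmModel]
    feature_mask: np.ndarray
    store: TrainingStore = field(default_factory=TrainingStore)
    f_max: Optional[float] = None


class _RunStreamer:
    """Per-run state machine fed one 3D volume per TR.

    During neutral blocks it accumulates baselines (per-ROI means and the
    SVM per-voxel buffer); during emotion blocks it computes raw feedback
    with the active method, maps it to saturation, and (for SVM) collects
    labeled features for cumulative retraining.
    """

    def __init__(
        self,
        schedule: RunSchedule,
        config: EngineConfig,
        roi_models: Optional[RoiModels] = None,
        svm_bundle: Optional[SvmBundle] = None,
    ) -> None:
        self.schedule = schedule
        self.config = config
        self.roi_models = roi_models
        self.svm = svm_bundle
        self.block_ids = block_index_per_volume(schedule, config.shift_volumes)
        self.samples: list[FeedbackSample] = []
        self.run_store = TrainingStore()
        self._prev_block: Optional[int] = None
        self._roi_buffers: dict[Condition, BaselineBuffer] = {}
        if roi_models is not None:
            self._roi_buffers = {c: BaselineBuffer() for c in roi_models}
        self._svm_neutral_vols: list[np.ndarray] = []
        self._svm_baseline: Optional[np.ndarray] = None

        if config.method == Method.ROI and roi_models is None:
            raise ValueError("ROI method requires trained ROI models")
        if config.method == Method.SVM and svm_bundle is None:
            raise ValueError("SVM method requires a feature mask / model bundle")

    def _enter_block(self, block_id: int, cond: Condition) -> None:
        if cond == Condition.NEUTRAL:
            for buf in self._roi_buffers.values():
                buf.reset()
            self._svm_neutral_vols = []
        else:
            if self.svm is not None and self._svm_neutral_vols:
                # vectors are already masked; weight them directly
                self._svm_baseline = neutral_block_baseline(self._svm_neutral_vols)

    def step(self, volume: np.ndarray, acq_index: int) -> Optional[FeedbackSample]:
        """Process the ``acq_index``-th acquired volume (dummies included)."""
        cfg = self.config
        if acq_index < self.schedule.n_dummy:
            return None
        i = acq_index - self.schedule.n_dummy
        block_id = self.block_ids[i]
        if block_id is None:  # shifted before run start
            return None
        cond = self.schedule.blocks[block_id].condition
        if block_id != self._prev_block:
            self._enter_block(block_id, cond)
            self._prev_block = block_id

        if cond == Condition.NEUTRAL:
            for c, model in (self.roi_models or {}).items():
                self._roi_buffers[c].append(model.roi_mean(volume))
            if self.svm is not None:
                mask_idx = np.flatnonzero(
                    np.asarray(self.svm.feature_mask, dtype=bool).ravel()
                )
                self._svm_neutral_vols.append(volume.ravel()[mask_idx].copy())
            return None

        # emotion block: one sample per volume
        if cfg.method == Method.ROI:
            model = self.roi_models[cond]
            raw = compute_psc_feedback(model.roi_mean(volume), self._roi_buffers[cond])
            f_max = cfg.f_max if cfg.f_max is not None else DEFAULT_F_MAX_ROI
        else:
            if self._svm_baseline is None:
                raise RuntimeError("emotion block before any neutral baseline")
            x = extract_features(volume, self.svm.feature_mask, self._svm_baseline)
            self.run_store.add(x, cond, self.schedule.run_index, i)
            if self.svm.model is None:  # training run: collect only
                return None
            raw = decode_feedback(self.svm.model, x, cond)
            f_max = cfg.f_max if cfg.f_max is not None else self.svm.f_max
            if f_max is None:
                raise ValueError("SVM f_max not set; train the model first")

        sat = map_feedback_to_saturation(raw, f_max, cfg.n_levels)
        sample = FeedbackSample(
            run_index=self.schedule.run_index,
            volume_index=i,
            time_s=i * self.schedule.tr_s,
            block_id=block_id,
            condition=cond,
            raw_feedback=raw,
            saturation=sat,
            hue_target=HUE_BY_CONDITION[cond],
        )
        self.samples.append(sample)
        return sample


def run_session(
    volumes: np.ndarray,
    schedule: RunSchedule,
    config: EngineConfig,
    roi_models: Optional[RoiModels] = None,
    svm_bundle: Optional[SvmBundle] = None,
) -> tuple[list[FeedbackSample], TrainingStore]:
    """Stream one run's volumes (dummies included) through the engine.

    Returns the run's feedback samples and, for the SVM method, the labeled
    features collected for cumulative retraining.
    """
    if roi_models is not None:
        for model in roi_models.values():
            if model.roi.mask.shape != volumes.shape[:3]:
                raise ValueError("ROI mask grid does not match the volumes")
    if svm_bundle is not None and np.asarray(svm_bundle.feature_mask).shape != volumes.shape[:3]:
        raise ValueError("feature mask grid does not match the volumes")
    streamer = _RunStreamer(schedule, config, roi_models, svm_bundle)
    for v in range(volumes.shape[-1]):
        streamer.step(volumes[..., v], v)
    return streamer.samples, streamer.run_store


def default_svm_f_max(model: SvmModel, store: TrainingStore) -> float:
    """Twice the median |projection| over the training examples."""
    projections = [abs(project(model, x)) for x in store.X]
    return 2.0 * float(np.median(projections))


def train_from_run(
    volumes: np.ndarray,
    schedule: RunSchedule,
    config: EngineConfig,
    rois: Optional[dict[Condition, RoiDefinition]] = None,
    feature_mask: Optional[np.ndarray] = None,
    fraction: float = 0.10,
    C: float = 1.0,
) -> Union[RoiModels, SvmBundle]:
    """Fit the feedback model(s) from the training run.

    ROI method: maps each target ROI's most active voxel decile.
    SVM method: collects PSC features from the run and fits the initial
    hyperplane; sets the feedback scale ``f_max``.
    """
    labels = label_volumes(schedule, config.shift_volumes)
    nfb = volumes[..., schedule.n_dummy :]
    if config.method == Method.ROI:
        if rois is None:
            raise ValueError("ROI training requires ROI definitions")
        return {
            cond: train_roi_model(nfb, labels, roi, fraction)
            for cond, roi in rois.items()
        }
    if feature_mask is None:
        raise ValueError("SVM training requires a feature mask")
    bundle = SvmBundle(model=None, feature_mask=np.asarray(feature_mask, dtype=bool))
    _, store = run_session(volumes, schedule, config, svm_bundle=bundle)
    model = train(store, C=C)
    bundle.model = model
    bundle.store = store
    bundle.f_max = default_svm_f_max(model, store)
    return bundle


def run_nfb_session(
    session: ph.SyntheticSession,
    config: EngineConfig,
    rois: Optional[dict[Condition, RoiDefinition]] = None,
    feature_mask: Optional[np.ndarray] = None,
) -> tuple[FeedbackLog, Union[RoiModels, SvmBundle]]:
    """Full protocol: train on run 1, then stream runs 2-4 with feedback.

    For the SVM method the model is refitted at every run boundary on all
    examples observed so far (cumulative training).
    """
    if rois is None and config.method == Method.ROI:
        rois = default_rois(session.roi_masks)
    if feature_mask is None and config.method == Method.SVM:
        feature_mask = session.roi_masks["feature_mask"]

    training = session.runs[0]
    models = train_from_run(
        training.volumes, training.schedule, config, rois=rois, feature_mask=feature_mask
    )
    log = FeedbackLog(config_digest=config_digest(config))
    for run in session.runs[1:]:
        if config.method == Method.ROI:
            samples, _ = run_session(run.volumes, run.schedule, config, roi_models=models)
        else:
            samples, run_store = run_session(run.volumes, run.schedule, config, svm_bundle=models)
            models.model = retrain_cumulative(models.model, models.store, run_store)
        log.samples.extend(samples)
    return log, models


def default_rois(masks: dict[str, np.ndarray]) -> dict[Condition, RoiDefinition]:
    """Septo-hypothalamic ROI targets tenderness; right amygdala, anguish."""
    return {
        Condition.TENDERNESS: RoiDefinition(
            "septo_hypothalamic", masks["septo_hypothalamic"], Condition.TENDERNESS
        ),
        Condition.ANGUISH: RoiDefinition(
            "right_amygdala", masks["right_amygdala"], Condition.ANGUISH
        ),
    }


# ---------------------------------------------------------------------------
# closed loop


def simulate_closed_loop(
    design: SessionDesign,
    phantom_config: ph.PhantomConfig,
    responder_gain: float,
    config: EngineConfig,
    seed: Optional[int] = None,
) -> tuple[ph.SyntheticSession, FeedbackLog]:
    """Closed-loop simulation: feedback modulates the next block's effect.

    The training run is generated open loop and used to fit the models. In
    runs 2-4, the planted effect amplitude of each emotion block is scaled by
    ``1 + responder_gain * (mean saturation of the previous same-emotion
    block in the run)``, emulating a participant who up-regulates in
    proportion to the feedback received. ``responder_gain = 0`` reproduces
    the open-loop session and log exactly.
    """
    if responder_gain < 0:
        raise ValueError("responder_gain must be >= 0")
    if seed is not None:
        phantom_config = replace(phantom_config, seed=seed)

    seeds = ph._session_seeds(phantom_config, len(design.runs))
    masks = ph.default_masks(phantom_config.grid_dims)

    # run 1: open loop, then train
    training_vols = ph._assemble_run(design.runs[0], phantom_config, seeds[0])
    runs = [_make_run_data(training_vols, design.runs[0], phantom_config)]
    models = train_from_run(
        training_vols,
        design.runs[0],
        config,
        rois=default_rois(masks) if config.method == Method.ROI else None,
        feature_mask=masks["feature_mask"] if config.method == Method.SVM else None,
    )

    log = FeedbackLog(config_digest=config_digest(config))
    for schedule, run_seed in zip(design.runs[1:], seeds[1:]):
        vols, samples, run_store = _closed_loop_run(
            schedule, phantom_config, run_seed, responder_gain, config, models
        )
        runs.append(_make_run_data(vols, schedule, phantom_config))
        if config.method == Method.SVM:
            models.model = retrain_cumulative(models.model, models.store, run_store)
        log.samples.extend(samples)

    session = ph.SyntheticSession(runs, masks, phantom_config, design)
    return session, log


def _make_run_data(
    volumes: np.ndarray, schedule: RunSchedule, config: ph.PhantomConfig
) -> ph.RunData:
    n_total = schedule.n_dummy + schedule.n_volumes
    if config.motion_trace is not None:
        motion = np.asarray(config.motion_trace)[:n_total]
    else:
        motion = ph.synthesize_motion(n_total, seed=config.seed + schedule.run_index)
    return ph.RunData(volumes, schedule, motion)


def _closed_loop_run(
    schedule: RunSchedule,
    phantom_config: ph.PhantomConfig,
    run_seed: np.random.SeedSequence,
    gain: float,
    config: EngineConfig,
    models: Union[RoiModels, SvmBundle],
) -> tuple[np.ndarray, list[FeedbackSample], TrainingStore]:
    """Generate one run volume-by-volume while feeding the engine.

    The per-block amplitude multiplier is fixed when acquisition enters the
    block; the block's HRF-convolved contribution is causal, so past volumes
    are unaffected.
    """
    noise, drift = ph._run_noise_and_drift(phantom_config, schedule, run_seed)
    regressors = ph._block_regressors(schedule)
    n_total = schedule.n_dummy + schedule.n_volumes
    n_vox = phantom_config.n_voxels
    base = phantom_config.baseline_intensity

    psc_acc = np.zeros((n_vox, n_total))
    entered: set[int] = set()
    # samples of each emotion block, for the responder update
    block_sats: dict[int, list[float]] = {}
    last_block_of: dict[Condition, int] = {}
    multipliers = np.ones(len(schedule.blocks))

    if config.method == Method.ROI:
        streamer = _RunStreamer(schedule, config, roi_models=models)
    else:
        streamer = _RunStreamer(schedule, config, svm_bundle=models)

    vols = np.empty((n_vox, n_total))
    for v in range(n_total):
        t = (v - schedule.n_dummy) * schedule.tr_s  # acquisition time, unshifted
        blk = schedule.block_at_time(t)
        if blk is not None and blk not in entered:
            entered.add(blk)
            cond = schedule.blocks[blk].condition
            if cond != Condition.NEUTRAL:
                prev = last_block_of.get(cond)
                if prev is not None and block_sats.get(prev):
                    multipliers[blk] = 1.0 + gain * float(np.mean(block_sats[prev]))
                last_block_of[cond] = blk
                block_sats[blk] = []
                for eff in phantom_config.planted_effects:
                    if eff.condition == cond:
                        psc_acc[eff.voxels] += (
                            eff.psc_amplitude * multipliers[blk] * regressors[blk]
                        )[None, :]

        col = base * (1.0 + psc_acc[:, v])
        col = col + drift[v]
        col = col + noise[:, v]
        vols[:, v] = col
        sample = streamer.step(col.reshape(phantom_config.grid_dims), v)
        if sample is not None and sample.block_id in block_sats:
            block_sats[sample.block_id].append(sample.saturation)

    return (
        vols.reshape(*phantom_config.grid_dims, n_total),
        streamer.samples,
        streamer.run_store,
    )
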