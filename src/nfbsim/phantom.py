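"""Synthetic block-design BOLD sessions with known ground truth.

The phantom stands in for the scanner: each voxel's time series is

    baseline * (1 + sum_c psc_c(v) * [boxcar_c (*) HRF](t)) + drift + AR(1) noise

where ``psc_c(v)`` is the planted percent-signal-change amplitude of
condition ``c`` at voxel ``v``, the hemodynamic response function (HRF) is
the canonical double-gamma, drift is a linear ramp plus a slow sinusoid, and
the noise is Gaussian AR(1). Generation is a pure function of the design and
the configuration (seed included), so every downstream stage can be tested
against exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import signal as sp_signal
from scipy import stats

from .design import Condition, RunSchedule, SessionDesign

DEFAULT_GRID = (16, 16, 10)
#: fine temporal grid for HRF convolution (s)
CONV_DT = 0.1
#: isotropic voxel size used for the NIfTI affine (mm)
VOXEL_SIZE_MM = 3.75


def double_gamma_hrf(
    t: np.ndarray | float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    normalize: bool = True,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t`` (s).

    Difference of two gamma densities (peak near 5 s, undershoot near 15 s,
    back to ~0 by 32 s), scaled to unit peak when ``normalize`` is True.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    h = np.where(t < 0, 0.0, h)
    if normalize:
        grid = np.arange(0, 32, CONV_DT)
        ref = stats.gamma.pdf(grid, peak_delay / peak_disp, scale=peak_disp) - (
            undershoot_ratio
            * stats.gamma.pdf(grid, undershoot_delay / undershoot_disp, scale=undershoot_disp)
        )
        h = h / ref.max()
    return h


@dataclass(frozen=True)
class PlantedEffect:
    """A voxel set responding to one condition with a given PSC amplitude."""

    voxels: np.ndarray  # linear voxel indices into the flattened grid
    condition: Condition
    psc_amplitude: float  # fraction, e.g. 0.02 for 2%

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=np.int64))
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.psc_amplitude < 0:
            raise ValueError("psc_amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to synthesize a session, seed included."""

    grid_dims: tuple[int, int, int] = DEFAULT_GRID
    baseline_intensity: float = 1000.0
    noise_sd: float = 20.0
    ar1_coef: float = 0.3
    drift_amplitude_per_run: float = 10.0
    drift_period_s: float = 300.0  # below the high-pass cutoff frequencies
    planted_effects: tuple[PlantedEffect, ...] = ()
    motion_trace: Optional[np.ndarray] = None  # (total volumes, 6) or None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        n_vox = int(np.prod(self.grid_dims))
        seen: dict[tuple[int, str], int] = {}
        for eff in self.planted_effects:
            if eff.voxels.size and (eff.voxels.min() < 0 or eff.voxels.max() >= n_vox):
                raise ValueError("planted voxel indices outside the grid")
            for v in eff.voxels:
                key = (int(v), eff.condition.value)
                if key in seen:
                    raise ValueError(
                        f"voxel {v} has contradictory effect definitions for {eff.condition.value}"
                    )
                seen[key] = 1

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))


@dataclass
class RunData:
    """One run's synthetic volumes (dummies included) plus provenance."""

    volumes: np.ndarray  # (x, y, z, n_dummy + n_volumes)
    schedule: RunSchedule
    motion: np.ndarray  # (n_dummy + n_volumes, 6): 3 translations mm, 3 rotations rad

    @property
    def nfb_volumes(self) -> np.ndarray:
        """Volumes with the leading dummies stripped."""
        return self.volumes[..., self.schedule.n_dummy :]


@dataclass
class SyntheticSession:
    runs: list[RunData]
    roi_masks: dict[str, np.ndarray]
    ground_truth: PhantomConfig
    design: SessionDesign


# ---------------------------------------------------------------------------
# default geometry: named masks on the 16 x 16 x 10 grid


def default_masks(grid_dims: tuple[int, int, int] = DEFAULT_GRID) -> dict[str, np.ndarray]:
    """Named binary masks: two target ROIs and the SVM feature mask.

    The septo-hypothalamic ROI (tenderness target) is a 1,000-voxel box, the
    right amygdala ROI (anguish target) a smaller box, and the feature mask
    covers most of the grid while excluding a strip that stands in for
    sensorimotor/visuospatial cortex.
    """
    nx, ny, nz = grid_dims
    septo = np.zeros(grid_dims, dtype=bool)
    septo[0 : min(10, nx), 0 : min(10, ny), :] = True
    amygdala = np.zeros(grid_dims, dtype=bool)
    amygdala[min(10, nx - 1) : nx, 0 : min(8, ny), :] = True
    feature = np.ones(grid_dims, dtype=bool)
    feature[:, max(0, ny - 3) :, :] = False  # excluded sensorimotor/visuospatial strip
    return {
        "septo_hypothalamic": septo,
        "right_amygdala": amygdala,
        "feature_mask": feature,
    }


def roi_phantom_config(
    seed: int = 0,
    psc_amplitude: float = 0.02,
    active_fraction: float = 0.10,
    noise_sd: float = 20.0,
    grid_dims: tuple[int, int, int] = DEFAULT_GRID,
    **kwargs,
) -> PhantomConfig:
    """Phantom for the ROI method: a random ``active_fraction`` of each target
    ROI responds to its target condition at ``psc_amplitude``."""
    masks = default_masks(grid_dims)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    effects = []
    for name, cond in (
        ("septo_hypothalamic", Condition.TENDERNESS),
        ("right_amygdala", Condition.ANGUISH),
    ):
        idx = np.flatnonzero(masks[name].ravel())
        n_active = int(np.ceil(active_fraction * idx.size))
        chosen = np.sort(rng.choice(idx, size=n_active, replace=False))
        effects.append(PlantedEffect(chosen, cond, psc_amplitude))
    return PhantomConfig(
        grid_dims=grid_dims,
        noise_sd=noise_sd,
        planted_effects=tuple(effects),
        seed=seed,
        **kwargs,
    )


def svm_phantom_config(
    seed: int = 0,
    psc_amplitude: float = 0.02,
    n_voxels_per_set: int = 60,
    noise_sd: float = 20.0,
    grid_dims: tuple[int, int, int] = DEFAULT_GRID,
    **kwargs,
) -> PhantomConfig:
    """Phantom for the SVM method: two disjoint voxel sets inside the feature
    mask, one responding to tenderness and one to anguish, so the two
    conditions have opposite-signed discriminative patterns."""
    masks = default_masks(grid_dims)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    idx = np.flatnonzero(masks["feature_mask"].ravel())
    chosen = rng.choice(idx, size=2 * n_voxels_per_set, replace=False)
    set_t = np.sort(chosen[:n_voxels_per_set])
    set_a = np.sort(chosen[n_voxels_per_set:])
    effects = (
        PlantedEffect(set_t, Condition.TENDERNESS, psc_amplitude),
        PlantedEffect(set_a, Condition.ANGUISH, psc_amplitude),
    )
    return PhantomConfig(
        grid_dims=grid_dims,
        noise_sd=noise_sd,
        planted_effects=effects,
        seed=seed,
        **kwargs,
    )


def synthesize_motion(
    n_volumes: int,
    seed: int = 0,
    step_sd_mm: float = 0.02,
    step_sd_rad: float = 0.0002,
    spikes: Sequence[tuple[int, float, float]] = (),
) -> np.ndarray:
    """Slow random-walk motion trace (n_volumes, 6) with optional spikes.

    ``spikes`` is a list of (volume index, translation mm, rotation rad)
    added on top of the walk, to exercise artifact detection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    steps = np.concatenate(
        [
            rng.normal(0, step_sd_mm, size=(n_volumes, 3)),
            rng.normal(0, step_sd_rad, size=(n_volumes, 3)),
        ],
        axis=1,
    )
    trace = np.cumsum(steps, axis=0)
    for vol, trans, rot in spikes:
        trace[vol, 0] += trans
        trace[vol, 3] += rot
    return trace


# ---------------------------------------------------------------------------
# generation


def _block_regressors(schedule: RunSchedule) -> np.ndarray:
    """Unit-amplitude HRF-convolved boxcar per block, sampled at volume times.

    Returns (n_blocks, n_dummy + n_volumes); dummy volumes precede time 0 and
    see no stimulus, so their regressor values are 0.
    """
    tr = schedule.tr_s
    total_s = schedule.total_duration_s
    fine_t = np.arange(0.0, total_s + 32.0, CONV_DT)
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, CONV_DT))
    vol_times = (np.arange(-schedule.n_dummy, schedule.n_volumes)) * tr

    out = np.zeros((len(schedule.blocks), schedule.n_dummy + schedule.n_volumes))
    onsets = schedule.onsets_s
    for b, (onset, block) in enumerate(zip(onsets, schedule.blocks)):
        box = ((fine_t >= onset) & (fine_t < onset + block.duration_s)).astype(float)
        # scale to unit steady state so a long block's plateau equals the
        # planted PSC amplitude exactly
        conv = np.convolve(box, hrf)[: fine_t.size] / hrf.sum()
        vals = np.interp(vol_times, fine_t, conv, left=0.0, right=conv[-1])
        out[b] = vals
    return out


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, phi: float) -> np.ndarray:
    """Stationary Gaussian AR(1): x_t = phi * x_{t-1} + eps, sd(eps) = sd."""
    n_vox, n_t = shape
    eps = rng.normal(0.0, sd, size=(n_vox, n_t))
    if phi == 0.0:
        return eps
    # seed each series from the stationary distribution so variance is flat in t
    x0 = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi), size=n_vox)
    zi = (phi * x0)[:, None]
    out, _ = sp_signal.lfilter([1.0], [1.0, -phi], eps, axis=1, zi=zi)
    return out


def _drift(config: PhantomConfig, n_total: int, tr_s: float) -> np.ndarray:
    """Linear ramp plus slow sinusoid, shared by all voxels (n_total,)."""
    amp = config.drift_amplitude_per_run
    if amp == 0:
        return np.zeros(n_total)
    t = np.arange(n_total) * tr_s
    ramp = amp * (t / t[-1] - 0.5) if n_total > 1 else np.zeros(n_total)
    sine = 0.5 * amp * np.sin(2 * np.pi * t / config.drift_period_s)
    return ramp + sine


def _psc_field(
    schedule: RunSchedule,
    config: PhantomConfig,
    regressors: np.ndarray,
    block_multipliers: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free PSC time course per affected voxel.

    Returns (affected voxel indices, psc array (n_affected, n_total)).
    ``block_multipliers`` scales the planted amplitude block-by-block (used by
    the closed-loop simulator); default is 1 everywhere.
    """
    n_total = regressors.shape[1]
    if block_multipliers is None:
        block_multipliers = np.ones(len(schedule.blocks))
    affected = np.unique(np.concatenate([e.voxels for e in config.planted_effects]
                                        )) if config.planted_effects else np.array([], dtype=np.int64)
    pos = {int(v): i for i, v in enumerate(affected)}
    psc = np.zeros((affected.size, n_total))
    # blocks outer, effects inner: the closed-loop simulator accumulates the
    # same terms block-by-block, so this order keeps the two paths bit-equal
    for b, block in enumerate(schedule.blocks):
        for eff in config.planted_effects:
            if block.condition == eff.condition:
                rows = [pos[int(v)] for v in eff.voxels]
                contrib = eff.psc_amplitude * block_multipliers[b] * regressors[b]
                psc[rows] += contrib[None, :]
    return affected, psc


def _run_noise_and_drift(
    config: PhantomConfig, schedule: RunSchedule, run_seed: np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    n_total = schedule.n_dummy + schedule.n_volumes
    rng = np.random.default_rng(run_seed)
    noise = (
        _ar1_noise(rng, (config.n_voxels, n_total), config.noise_sd, config.ar1_coef)
        if config.noise_sd > 0
        else np.zeros((config.n_voxels, n_total))
    )
    drift = _drift(config, n_total, schedule.tr_s)
    return noise, drift


def _assemble_run(
    schedule: RunSchedule,
    config: PhantomConfig,
    run_seed: np.random.SeedSequence,
    block_multipliers: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Full run as (x, y, z, n_total); deterministic in all arguments."""
    noise, drift = _run_noise_and_drift(config, schedule, run_seed)
    regressors = _block_regressors(schedule)
    affected, psc = _psc_field(schedule, config, regressors, block_multipliers)
    n_total = schedule.n_dummy + schedule.n_volumes
    flat = np.full((config.n_voxels, n_total), config.baseline_intensity)
    if affected.size:
        flat[affected] = config.baseline_intensity * (1.0 + psc)
    flat += drift[None, :]
    flat += noise
    return flat.reshape(*config.grid_dims, n_total)


def _session_seeds(config: PhantomConfig, n_runs: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence([config.seed, 404]).spawn(n_runs)


def generate_session(design: SessionDesign, config: PhantomConfig) -> SyntheticSession:
    """Synthesize all four runs of a session (open loop)."""
    seeds = _session_seeds(config, len(design.runs))
    runs = []
    for schedule, s in zip(design.runs, seeds):
        vols = _assemble_run(schedule, config, s)
        n_total = schedule.n_dummy + schedule.n_volumes
        if config.motion_trace is not None:
            motion = np.asarray(config.motion_trace)[:n_total]
        else:
            motion = synthesize_motion(n_total, seed=config.seed + schedule.run_index)
        runs.append(RunData(vols, schedule, motion))
    return SyntheticSession(runs, default_masks(config.grid_dims), config, design)


def generate_run(design: SessionDesign, config: PhantomConfig, run_index: int = 1) -> RunData:
    """Synthesize a single run, identical to the same run of
    :func:`generate_session` with the same configuration."""
    seeds = _session_seeds(config, len(design.runs))
    schedule = design.runs[run_index - 1]
    vols = _assemble_run(schedule, config, seeds[run_index - 1])
    n_total = schedule.n_dummy + schedule.n_volumes
    if config.motion_trace is not None:
        motion = np.asarray(config.motion_trace)[:n_total]
    else:
        motion = synthesize_motion(n_total, seed=config.seed + schedule.run_index)
    return RunData(vols, schedule, motion)


def expected_psc(
    config: PhantomConfig,
    schedule: RunSchedule,
    voxel: int | tuple[int, int, int],
    volume_index: int,
    condition: Optional[Condition] = None,
) -> float:
    """Noise-free PSC (fraction) at one voxel and volume from the convolution
    model; the test oracle for the planted ground truth.

    ``volume_index`` counts dummies, i.e. indexes the generated time axis.
    ``condition`` restricts to one condition's contribution; default is the
    sum over all planted conditions.
    """
    return float(expected_psc_series(config, schedule, voxel, condition)[volume_index])


def expected_psc_series(
    config: PhantomConfig,
    schedule: RunSchedule,
    voxel: int | tuple[int, int, int],
    condition: Optional[Condition] = None,
) -> np.ndarray:
    """Noise-free PSC time series at one voxel (length n_dummy + n_volumes)."""
    if isinstance(voxel, tuple):
        voxel = int(np.ravel_multi_index(voxel, config.grid_dims))
    regressors = _block_regressors(schedule)
    total = np.zeros(regressors.shape[1])
    for eff in config.planted_effects:
        if condition is not None and eff.condition != Condition(condition):
            continue
        if voxel in set(int(v) for v in eff.voxels):
            for b, block in enumerate(schedule.blocks):
                if block.condition == eff.condition:
                    total += eff.psc_amplitude * regressors[b]
    return total


# ---------------------------------------------------------------------------
# NIfTI / sidecar I/O


def _affine() -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = VOXEL_SIZE_MM
    return aff


def save_session(session: SyntheticSession, out_dir: str | Path) -> None:
    """Write volumes and masks as NIfTI-1, motion as TSV, ground truth as YAML."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine()
    for run in session.runs:
        r = run.schedule.run_index
        nib.Nifti1Image(run.volumes.astype(np.float32), aff).to_filename(
            str(out / f"run-{r}_bold.nii")
        )
        np.savetxt(out / f"run-{r}_motion.tsv", run.motion, delimiter="\t", fmt="%.6f")
    for name, mask in session.roi_masks.items():
        nib.Nifti1Image(mask.astype(np.uint8), aff).to_filename(str(out / f"mask-{name}.nii"))
    gt = session.ground_truth
    sidecar = {
        "grid_dims": list(gt.grid_dims),
        "baseline_intensity": gt.baseline_intensity,
        "noise_sd": gt.noise_sd,
        "ar1_coef": gt.ar1_coef,
        "drift_amplitude_per_run": gt.drift_amplitude_per_run,
        "seed": gt.seed,
        "planted_effects": [
            {
                "condition": e.condition.value,
                "psc_amplitude": e.psc_amplitude,
                "n_voxels": int(e.voxels.size),
            }
            for e in gt.planted_effects
        ],
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def load_run_volumes(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
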