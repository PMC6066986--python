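"""Block-design scheduling for neurofeedback sessions.

A session is four runs (one training run followed by three neurofeedback
runs). Each run interleaves 30-s neutral blocks with 46-s emotion blocks
(tenderness or anguish, four of each per run), so a run lasts
8*30 + 8*46 = 608 s = 304 volumes at TR = 2 s. The ROI method alternates
the two emotions; the SVM method groups the four blocks of each emotion
consecutively. Every emotion block is preceded by a neutral block, which
supplies the feedback baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd


class Condition(str, Enum):
    NEUTRAL = "neutral"
    TENDERNESS = "tenderness"
    ANGUISH = "anguish"


class Method(str, Enum):
    ROI = "ROI"
    SVM = "SVM"


EMOTIONS = (Condition.TENDERNESS, Condition.ANGUISH)

NEUTRAL_DURATION_S = 30.0
EMOTION_DURATION_S = 46.0

#: label for volumes that precede the run proper after the hemodynamic shift
DISCARD_LABEL = "discard"

DEFAULT_TR_S = 2.0
DEFAULT_N_DUMMY = 5
DEFAULT_SHIFT_VOLUMES = 2

BLOCKS_PER_EMOTION = 4


def _other_emotion(emotion: Condition) -> Condition:
    return EMOTIONS[1] if emotion == EMOTIONS[0] else EMOTIONS[0]


@dataclass(frozen=True)
class BlockSpec:
    """One condition block: neutral (30 s, silent) or emotion (46 s, music)."""

    condition: Condition
    duration_s: float
    music_track_id: Optional[str] = None

    def __post_init__(self) -> None:
        cond = Condition(self.condition)
        object.__setattr__(self, "condition", cond)
        if cond == Condition.NEUTRAL:
            if self.duration_s != NEUTRAL_DURATION_S:
                raise ValueError(
                    f"neutral blocks last {NEUTRAL_DURATION_S} s, got {self.duration_s}"
                )
            if self.music_track_id is not None:
                raise ValueError("neutral blocks carry no music track")
        else:
            if self.duration_s != EMOTION_DURATION_S:
                raise ValueError(
                    f"emotion blocks last {EMOTION_DURATION_S} s, got {self.duration_s}"
                )
            if self.music_track_id is None:
                raise ValueError("emotion blocks require a music track")


@dataclass(frozen=True)
class RunSchedule:
    """Ordered blocks of one run plus acquisition parameters.

    ``n_dummy`` volumes precede the run for magnetization equilibration and
    are not part of ``n_volumes``.
    """

    blocks: tuple[BlockSpec, ...]
    tr_s: float = DEFAULT_TR_S
    n_dummy: int = DEFAULT_N_DUMMY
    run_index: int = 1
    method: Method = Method.ROI

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "method", Method(self.method))
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not 1 <= self.run_index <= 4:
            raise ValueError("run_index must be in 1..4")
        total = self.total_duration_s
        if abs(total / self.tr_s - round(total / self.tr_s)) > 1e-9:
            raise ValueError("total duration must be an integer number of TRs")

    @property
    def total_duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    @property
    def n_volumes(self) -> int:
        return round(self.total_duration_s / self.tr_s)

    @property
    def onsets_s(self) -> list[float]:
        """Block onsets in seconds, 0-based from the first non-dummy volume."""
        onsets, t = [], 0.0
        for b in self.blocks:
            onsets.append(t)
            t += b.duration_s
        return onsets

    def block_at_time(self, t_s: float) -> Optional[int]:
        """Index of the block containing time ``t_s``, or None outside the run."""
        if t_s < 0:
            return None
        acc = 0.0
        for i, b in enumerate(self.blocks):
            acc += b.duration_s
            if t_s < acc:
                return i
        return None


@dataclass(frozen=True)
class SessionDesign:
    """Four-run session: one training run followed by three feedback runs."""

    method: Method
    start_emotion: Condition
    runs: tuple[RunSchedule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "runs", tuple(self.runs))
        if len(self.runs) != 4:
            raise ValueError("a session comprises exactly 4 runs")

    @property
    def total_volumes(self) -> int:
        return sum(r.n_volumes for r in self.runs)


def default_track_pool() -> dict[Condition, list[str]]:
    """Four distinct music-excerpt identifiers per emotion."""
    return {
        Condition.TENDERNESS: [f"tenderness-{i}" for i in range(1, 5)],
        Condition.ANGUISH: [f"anguish-{i}" for i in range(1, 5)],
    }


def build_run_schedule(
    method: Method | str,
    start_emotion: Condition | str,
    run_index: int,
    tr_s: float = DEFAULT_TR_S,
    n_dummy: int = DEFAULT_N_DUMMY,
    track_pool: Optional[dict[Condition, Sequence[str]]] = None,
) -> RunSchedule:
    """Build one run's block order.

    ROI method: emotions strictly alternate, ``[N, E1, N, E2] x 4``.
    SVM method: each emotion's four blocks are grouped, ``[N, E1] x 4`` then
    ``[N, E2] x 4``. ``E1`` is ``start_emotion`` on odd runs and the other
    emotion on even runs (counterbalancing across runs 1-4).
    """
    method = Method(method)
    start_emotion = Condition(start_emotion)
    if start_emotion not in EMOTIONS:
        raise ValueError("start_emotion must be tenderness or anguish")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")

    e1 = start_emotion if run_index % 2 == 1 else _other_emotion(start_emotion)
    e2 = _other_emotion(e1)

    if method == Method.ROI:
        order = [Condition.NEUTRAL, e1, Condition.NEUTRAL, e2] * BLOCKS_PER_EMOTION
    else:
        order = [Condition.NEUTRAL, e1] * BLOCKS_PER_EMOTION
        order += [Condition.NEUTRAL, e2] * BLOCKS_PER_EMOTION

    pool = track_pool if track_pool is not None else default_track_pool()
    counters = {e: 0 for e in EMOTIONS}
    blocks = []
    for cond in order:
        if cond == Condition.NEUTRAL:
            blocks.append(BlockSpec(cond, NEUTRAL_DURATION_S))
        else:
            tracks = list(pool[cond])
            if len(tracks) < BLOCKS_PER_EMOTION:
                raise ValueError(f"need >= {BLOCKS_PER_EMOTION} tracks for {cond.value}")
            # rotate the pool by run so consecutive runs reuse tracks in a
            # different order; each block of an emotion gets a distinct track
            idx = (counters[cond] + (run_index - 1)) % len(tracks)
            blocks.append(BlockSpec(cond, EMOTION_DURATION_S, tracks[idx]))
            counters[cond] += 1

    return RunSchedule(tuple(blocks), tr_s, n_dummy, run_index, method)


def build_session_design(
    method: Method | str,
    start_emotion: Condition | str,
    tr_s: float = DEFAULT_TR_S,
    n_dummy: int = DEFAULT_N_DUMMY,
    track_pool: Optional[dict[Condition, Sequence[str]]] = None,
) -> SessionDesign:
    runs = tuple(
        build_run_schedule(method, start_emotion, r, tr_s, n_dummy, track_pool)
        for r in range(1, 5)
    )
    return SessionDesign(Method(method), Condition(start_emotion), runs)


def assign_music(
    schedule: RunSchedule, track_pool: dict[Condition, Sequence[str]]
) -> RunSchedule:
    """Reassign music tracks from ``track_pool`` (>= 4 distinct per emotion).

    Each of an emotion's four blocks receives a distinct track; neutral
    blocks receive none.
    """
    for emo in EMOTIONS:
        tracks = list(track_pool.get(emo, []))
        if len(set(tracks)) < BLOCKS_PER_EMOTION:
            raise ValueError(
                f"track pool for {emo.value} must contain >= {BLOCKS_PER_EMOTION} distinct tracks"
            )
    counters = {e: 0 for e in EMOTIONS}
    blocks = []
    for b in schedule.blocks:
        if b.condition == Condition.NEUTRAL:
            blocks.append(b)
        else:
            blocks.append(
                replace(b, music_track_id=list(track_pool[b.condition])[counters[b.condition]])
            )
            counters[b.condition] += 1
    return replace(schedule, blocks=tuple(blocks))


def label_volumes(schedule: RunSchedule, shift_volumes: int = DEFAULT_SHIFT_VOLUMES) -> list[str]:
    """Condition label per non-dummy volume, shifted for hemodynamic delay.

    Volume ``i`` is labeled with the condition of the block containing time
    ``(i - shift_volumes) * tr_s``; volumes shifted before the run start are
    labeled ``"discard"``. Returns exactly ``n_volumes`` labels.
    """
    if not 0 <= shift_volumes <= 5:
        raise ValueError("shift_volumes must be in 0..5")
    labels = []
    for i in range(schedule.n_volumes):
        t = (i - shift_volumes) * schedule.tr_s
        blk = schedule.block_at_time(t)
        labels.append(DISCARD_LABEL if blk is None else schedule.blocks[blk].condition.value)
    return labels


def block_index_per_volume(
    schedule: RunSchedule, shift_volumes: int = DEFAULT_SHIFT_VOLUMES
) -> list[Optional[int]]:
    """Shifted block index per non-dummy volume (None before the run start)."""
    out = []
    for i in range(schedule.n_volumes):
        out.append(schedule.block_at_time((i - shift_volumes) * schedule.tr_s))
    return out


_EVENTS_COLUMNS = ["onset", "duration", "trial_type", "music_track"]


def write_events(schedule: RunSchedule, path: str | Path) -> None:
    """Write the run as a tab-separated events table.

    Columns: onset (s, 0-based from the first non-dummy volume), duration (s),
    trial_type, music_track ("n/a" for neutral). Run metadata is stored in
    ``#``-prefixed header lines so the table round-trips losslessly through
    :func:`read_events`.
    """
    rows = []
    for onset, b in zip(schedule.onsets_s, schedule.blocks):
        rows.append(
            {
                "onset": onset,
                "duration": b.duration_s,
                "trial_type": b.condition.value,
                "music_track": b.music_track_id if b.music_track_id else "n/a",
            }
        )
    df = pd.DataFrame(rows, columns=_EVENTS_COLUMNS)
    header = (
        f"# tr_s={schedule.tr_s}\n"
        f"# n_dummy={schedule.n_dummy}\n"
        f"# run_index={schedule.run_index}\n"
        f"# method={schedule.method.value}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_events(path: str | Path) -> RunSchedule:
    """Read an events table written by :func:`write_events`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    blocks = []
    for _, row in df.iterrows():
        track = None if str(row["music_track"]) == "n/a" else str(row["music_track"])
        blocks.append(BlockSpec(Condition(row["trial_type"]), float(row["duration"]), track))
    return RunSchedule(
        tuple(blocks),
        tr_s=float(meta["tr_s"]),
        n_dummy=int(meta["n_dummy"]),
        run_index=int(meta["run_index"]),
        method=Method(meta["method"]),
    )
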