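"""Task schedules for the three attention paradigms.

A session is organised as games -> blocks -> slots.  Each *game* keeps one
designated target identity for six consecutive *blocks*; each block presents
eight 625 ms stimulus cycles ("trials"), exactly one of which is the target.
The target's temporal slot is pseudorandomised under the constraint that it
never occupies the first two slots of a block, giving the classic
low-probability (12.5 %) oddball structure in every paradigm.

Three paradigms of graded difficulty share this skeleton:

``target_only``
    only the target shape is ever shown; the seven non-target slots are
    stimulus-free *dummy* intervals kept for temporal symmetry.
``oddball_target``
    the target appears among repeated presentations of one identical
    non-target shape (classic visual oddball).
``target_selection``
    the target must be found among seven heterogeneous distractor shapes,
    the most demanding, top-down condition.

To make all three paradigms the same 8-alternative decoding problem, every
block additionally carries a pseudorandom bijection of abstract *candidate
labels* onto its slots, with the game's target label pinned to the target
slot.  In ``target_selection`` the label coincides with the shape identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

__all__ = [
    "DUMMY",
    "TaskType",
    "TrialSpec",
    "TaskSchedule",
    "generate_task_schedule",
    "schedule_timing",
    "target_fraction",
]

#: Stimulus id used for stimulus-free dummy slots (target_only non-targets).
DUMMY = -1

#: Number of geometric shapes in the stimulus inventory.
N_SHAPES = 8

SCHEDULE_FORMAT_VERSION = "1.0"


class TaskType(str, Enum):
    """The three paradigms, in order of increasing cognitive demand."""

    TARGET_ONLY = "target_only"
    ODDBALL_TARGET = "oddball_target"
    TARGET_SELECTION = "target_selection"


class ScheduleError(ValueError):
    """Raised for unsatisfiable or invalid schedule parameters."""


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus cycle of a task.

    ``stimulus_id`` is a shape identity 0..7, or :data:`DUMMY` for
    stimulus-free slots.  ``candidate_label`` is the abstract 8-alternative
    label the decoder accumulates evidence over; ``is_target`` holds exactly
    when the label equals the game's target label.
    """

    game_index: int
    block_index: int
    slot_index: int
    stimulus_id: int
    candidate_label: int
    is_target: bool
    onset_s: float


@dataclass
class TaskSchedule:
    """Full trial-by-trial plan of one task for one subject."""

    task_type: TaskType
    n_games: int = 8
    n_blocks: int = 6
    n_slots: int = 8
    stimulus_duration_s: float = 0.375
    isi_s: float = 0.250
    intergame_break_s: float = 10.0
    target_label_per_game: list[int] = field(default_factory=list)
    trials: list[TrialSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def cycle_s(self) -> float:
        return self.stimulus_duration_s + self.isi_s

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`ScheduleError` on failure."""
        if len(self.trials) != self.n_games * self.n_blocks * self.n_slots:
            raise ScheduleError("trial count does not match games*blocks*slots")
        prev_onset = -np.inf
        for g in range(self.n_games):
            tgt_label = self.target_label_per_game[g]
            for b in range(self.n_blocks):
                block = [
                    t for t in self.trials
                    if t.game_index == g and t.block_index == b
                ]
                labels = sorted(t.candidate_label for t in block)
                if labels != list(range(self.n_slots)):
                    raise ScheduleError(f"game {g} block {b}: labels not a bijection")
                targets = [t for t in block if t.is_target]
                if len(targets) != 1:
                    raise ScheduleError(f"game {g} block {b}: expected 1 target")
                if targets[0].slot_index < 2:
                    raise ScheduleError(f"game {g} block {b}: target in first two slots")
                if targets[0].candidate_label != tgt_label:
                    raise ScheduleError(f"game {g} block {b}: target label mismatch")
        for t in self.trials:
            if t.onset_s <= prev_onset:
                raise ScheduleError("onsets not strictly increasing")
            prev_onset = t.onset_s
            if t.stimulus_id == DUMMY and (
                self.task_type is not TaskType.TARGET_ONLY or t.is_target
            ):
                raise ScheduleError("DUMMY allowed only in target_only non-target slots")

    # ------------------------------------------------------------------ I/O
    def to_json(self, path=None) -> str:
        """Serialise to JSON (flat trial array in presentation order)."""
        payload = {
            "format_version": SCHEDULE_FORMAT_VERSION,
            "task_type": self.task_type.value,
            "n_games": self.n_games,
            "n_blocks": self.n_blocks,
            "n_slots": self.n_slots,
            "stimulus_duration_s": self.stimulus_duration_s,
            "isi_s": self.isi_s,
            "intergame_break_s": self.intergame_break_s,
            "target_label_per_game": list(self.target_label_per_game),
            "seed": self.seed,
            "trials": [asdict(t) for t in self.trials],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TaskSchedule":
        """Load a schedule from a JSON string or file path."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        trials = [TrialSpec(**t) for t in payload.pop("trials")]
        payload.pop("format_version", None)
        payload["task_type"] = TaskType(payload["task_type"])
        return cls(trials=trials, **payload)


def generate_task_schedule(
    task_type: TaskType | str,
    n_games: int = 8,
    n_blocks: int = 6,
    n_slots: int = 8,
    seed: int = 0,
) -> TaskSchedule:
    """Generate a pseudorandomised task schedule.

    Per block, the target slot is drawn uniformly from slots ``2..n_slots-1``
    and candidate labels are a pseudorandom bijection onto slots with the
    game's target label on the target slot.  Stimulus identities follow the
    paradigm: distinct shapes (target_selection), one repeated non-target
    shape (oddball_target), or dummy slots (target_only).

    Parameters
    ----------
    task_type : TaskType or str
        Paradigm to schedule.
    n_games, n_blocks, n_slots : int
        Session geometry.  ``n_slots`` must be at least 3 so the
        "not in the first two slots" target constraint is satisfiable, and
        at most 8 for target_selection (shape inventory size).
    seed : int
        Seed of the pseudorandom generator; equal seeds give identical
        schedules.
    """
    task_type = TaskType(task_type)
    if n_games < 0 or n_blocks <= 0:
        raise ScheduleError("n_games must be >= 0 and n_blocks positive")
    if n_slots < 3:
        raise ScheduleError(
            "n_slots must be >= 3: the target cannot occupy the first two slots"
        )
    if task_type is TaskType.TARGET_SELECTION and n_slots > N_SHAPES:
        raise ScheduleError(
            f"target_selection needs n_slots <= {N_SHAPES} distinct shapes"
        )
    rng = np.random.default_rng(seed)

    cycle = 0.375 + 0.250
    sched = TaskSchedule(
        task_type=task_type, n_games=n_games, n_blocks=n_blocks,
        n_slots=n_slots, seed=seed,
    )
    game_s = n_blocks * n_slots * cycle

    trials: list[TrialSpec] = []
    for g in range(n_games):
        target_shape = int(rng.integers(N_SHAPES))
        # the abstract label held by the target throughout this game
        target_label = int(rng.integers(n_slots))
        sched.target_label_per_game.append(target_label)
        if task_type is TaskType.ODDBALL_TARGET:
            others = [s for s in range(N_SHAPES) if s != target_shape]
            oddball_nontarget_shape = int(rng.choice(others))
        game_start = g * (game_s + sched.intergame_break_s)
        for b in range(n_blocks):
            target_slot = int(rng.integers(2, n_slots))
            # bijection of labels onto slots with target_label pinned
            other_labels = [c for c in range(n_slots) if c != target_label]
            rng.shuffle(other_labels)
            labels = np.empty(n_slots, dtype=int)
            labels[target_slot] = target_label
            labels[[s for s in range(n_slots) if s != target_slot]] = other_labels
            if task_type is TaskType.TARGET_SELECTION:
                other_shapes = [s for s in range(N_SHAPES) if s != target_shape]
                rng.shuffle(other_shapes)
            for s in range(n_slots):
                is_target = s == target_slot
                if task_type is TaskType.TARGET_ONLY:
                    stim = target_shape if is_target else DUMMY
                elif task_type is TaskType.ODDBALL_TARGET:
                    stim = target_shape if is_target else oddball_nontarget_shape
                else:
                    stim = target_shape if is_target else other_shapes[
                        s if s < target_slot else s - 1
                    ]
                trials.append(TrialSpec(
                    game_index=g,
                    block_index=b,
                    slot_index=s,
                    stimulus_id=int(stim),
                    candidate_label=int(labels[s]),
                    is_target=bool(is_target),
                    onset_s=game_start + (b * n_slots + s) * cycle,
                ))
    sched.trials = trials
    sched.validate()
    return sched


def schedule_timing(schedule: TaskSchedule) -> dict:
    """Return cycle, game and task durations in seconds.

    ``task_s`` includes the inter-game breaks (inserted between games only).
    """
    cycle_s = schedule.stimulus_duration_s + schedule.isi_s
    game_s = schedule.n_blocks * schedule.n_slots * cycle_s
    if schedule.n_games == 0:
        task_s = 0.0
    else:
        task_s = (
            schedule.n_games * game_s
            + (schedule.n_games - 1) * schedule.intergame_break_s
        )
    return {"cycle_s": cycle_s, "game_s": game_s, "task_s": task_s}


def target_fraction(schedule: TaskSchedule) -> float:
    """Fraction of trials that are targets (1/n_slots by construction)."""
    if schedule.n_trials == 0:
        raise ScheduleError("empty schedule has no target fraction")
    n_targets = sum(t.is_target for t in schedule.trials)
    return n_targets / schedule.n_trials
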