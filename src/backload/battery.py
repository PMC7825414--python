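"""Task battery: the factorial set of pick-and-place tasks each participant performs.

The study battery is a cross product of box masses, origin/destination shelf
pairs, movement styles and repetitions, shuffled deterministically.  The
default factorization (4 masses x 5 shelf pairs x 4 styles x 5 repetitions)
yields the nominal 400 tasks per participant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

#: shelf heights in meters for the three-level shelving unit
SHELF_HEIGHTS = {"low": 0.25, "mid": 0.75, "high": 1.15}

STYLES = ("squat", "stoop", "lateral", "diagonal")

MAX_BOX_MASS = 23.0


@dataclass(frozen=True)
class ShelfSpec:
    name: str  # low | mid | high
    height: float  # m
    lateral_offset: float = 0.0  # m, + to the participant's right

    def __post_init__(self) -> None:
        if self.name not in SHELF_HEIGHTS:
            raise ValueError(f"unknown shelf {self.name!r}")


@dataclass(frozen=True)
class TaskSpec:
    """One pick-and-place task."""

    task_id: str
    box_mass: float  # kg
    origin_shelf: ShelfSpec
    destination_shelf: ShelfSpec
    style: str
    duration: float  # s
    pick_time: float  # s
    place_time: float  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.box_mass <= MAX_BOX_MASS:
            raise ValueError("box_mass must lie in [0, 23] kg")
        if not 0.0 < self.pick_time < self.place_time < self.duration:
            raise ValueError("require 0 < pick_time < place_time < duration")
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}")


@dataclass(frozen=True)
class BatteryConfig:
    """Factorial design of the task battery.

    ``move_duration`` is the nominal duration of each of the four movement
    phases (reach, lift-to-carry, carry-to-shelf, return); ``dwell`` is the
    stationary hold at pick and place during which the load transfers.
    """

    box_masses: tuple[float, ...] = (5.0, 10.0, 15.0, 23.0)
    shelf_pairs: tuple[tuple[str, str], ...] = (
        ("low", "mid"),
        ("mid", "low"),
        ("low", "high"),
        ("high", "low"),
        ("mid", "high"),
    )
    styles: tuple[str, ...] = STYLES
    repetitions: int = 5
    move_duration: float = 2.0  # s
    dwell: float = 0.35  # s
    duration_jitter: float = 0.07  # fractional sd on move_duration per task
    load_slowdown: float = 0.008  # fractional move slowdown per kg of box mass

    def __post_init__(self) -> None:
        if not self.box_masses or not self.shelf_pairs or not self.styles:
            raise ValueError("empty factor list")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def size(self) -> int:
        return len(self.box_masses) * len(self.shelf_pairs) * len(self.styles) * self.repetitions


def _lateral_offset(style: str, shelf_name: str, rng: np.random.Generator) -> float:
    # lateral/diagonal tasks place the origin shelf off to one side
    if style == "lateral":
        return float(rng.choice([-0.3, 0.3]))
    if style == "diagonal":
        return float(rng.choice([-0.2, 0.2]))
    return 0.0


def build_task_battery(config: BatteryConfig | None = None, seed: int = 0) -> list[TaskSpec]:
    """Enumerate the factorial battery and shuffle it deterministically."""
    config = config or BatteryConfig()
    rng = np.random.default_rng(seed)
    tasks: list[TaskSpec] = []
    factors = itertools.product(
        config.box_masses, config.shelf_pairs, config.styles, range(config.repetitions)
    )
    for i, (mass, (origin, dest), style, rep) in enumerate(factors):
        move = config.move_duration * (1.0 + config.load_slowdown * mass) * float(
            np.clip(1.0 + config.duration_jitter * rng.standard_normal(), 0.7, 1.3)
        )
        dwell = config.dwell
        duration = 4 * move + 2 * dwell
        pick = move + dwell / 2
        place = 3 * move + 1.5 * dwell
        tasks.append(
            TaskSpec(
                task_id=f"T{i + 1:04d}",
                box_mass=float(mass),
                origin_shelf=ShelfSpec(origin, SHELF_HEIGHTS[origin], _lateral_offset(style, origin, rng)),
                destination_shelf=ShelfSpec(dest, SHELF_HEIGHTS[dest], 0.0),
                style=style,
                duration=duration,
                pick_time=pick,
                place_time=place,
            )
        )
    order = rng.permutation(len(tasks))
    return [tasks[i] for i in order]
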