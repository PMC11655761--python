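"""Binary stimulus fixtures and the single-item training schedule.

Each "item" is a pair of sparse binary patterns delivered simultaneously to
the first and last area of the chain (by default 19 active cells out of
625 in each).  Items are always presented one at a time: the expanded
schedule never co-activates two items in the same trial, which is the
precondition for the anti-correlation-driven LTD pruning between emerging
assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .config import GridSpec, TrainingSchedule

__all__ = ["PatternPair", "Trial", "generate_pattern_set", "expand_schedule"]


@dataclass(frozen=True)
class PatternPair:
    """One item: binary stimulus vectors for the first and last area."""

    item_id: int
    first: np.ndarray  # bool, shape (n_cells,) — stimulus to area 0
    last: np.ndarray   # bool, shape (n_cells,) — stimulus to area N-1

    def __post_init__(self) -> None:
        if self.first.dtype != bool or self.last.dtype != bool:
            raise ValueError("stimulus vectors must be boolean")
        self.first.setflags(write=False)
        self.last.setflags(write=False)


class Trial(NamedTuple):
    """One presentation: the item plus its stimulation and silent phases."""

    item_id: int
    stim_duration: int
    isi_duration: int


def _draw(rng: np.random.Generator, n_cells: int, n_active: int) -> np.ndarray:
    v = np.zeros(n_cells, dtype=bool)
    v[rng.choice(n_cells, size=n_active, replace=False)] = True
    return v


def generate_pattern_set(n_items: int, n_active: int, grid: GridSpec,
                         min_hamming_active: int = 0,
                         seed: int | np.random.Generator = 0,
                         max_retries: int = 2000) -> list[PatternPair]:
    """Draw ``n_items`` pattern pairs of exactly ``n_active`` cells each.

    Active cells are drawn uniformly without replacement.  If
    ``min_hamming_active`` > 0, any two stimuli delivered to the same area
    may share at most ``n_active - min_hamming_active`` active cells
    (``min_hamming_active == n_active`` forces pairwise disjoint stimuli);
    draws violating the constraint are rejected, with a bounded retry budget.
    """
    if n_active > grid.n:
        raise ValueError("n_active exceeds the grid size")
    if min_hamming_active == n_active and n_items * n_active > grid.n:
        raise ValueError("disjointness constraint unsatisfiable for this grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_shared = n_active - min_hamming_active

    pairs: list[PatternPair] = []
    accepted: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for item in range(n_items):
        stims: list[np.ndarray] = []
        for side in (0, 1):
            for attempt in range(max_retries):
                v = _draw(rng, grid.n, n_active)
                if all((v & u).sum() <= max_shared for u in accepted[side]):
                    break
            else:
                raise ValueError(
                    f"could not satisfy min_hamming_active={min_hamming_active} "
                    f"after {max_retries} retries (item {item})")
            accepted[side].append(v)
            stims.append(v)
        pairs.append(PatternPair(item_id=item, first=stims[0], last=stims[1]))
    return pairs


def expand_schedule(schedule: TrainingSchedule, patterns: Sequence[PatternPair],
                    seed: int | np.random.Generator = 0) -> list[Trial]:
    """Expand a schedule into the ordered list of single-item trials.

    Every item occurs exactly ``presentations_per_item`` times.  Under
    ``randomized`` order the trial list is one reproducible permutation of
    the balanced list; ``round_robin`` cycles items 0, 1, ..., n-1.
    """
    ids = [p.item_id for p in patterns]
    reps = schedule.presentations_per_item
    if schedule.order == "round_robin":
        order = np.tile(ids, reps)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order = np.repeat(ids, reps)
        rng.shuffle(order)
    return [Trial(int(i), schedule.stim_duration, schedule.isi_duration)
            for i in order]
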