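"""In-memory containers for the network's dynamic state and training record."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import scipy.sparse as sp

from .config import NetworkConfig

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .connectivity import Projection
    from .patterns import PatternPair

__all__ = ["TrainingRecord", "NetworkState"]


@dataclass
class TrainingRecord:
    """What the network has been trained on.

    ``presentations`` counts completed single-item trials per item id;
    ``co_presented`` records unordered item pairs that ever shared a trial
    (always empty under the standard schedule — the record exists so the
    superposition protocol can *verify* independence of the items it
    co-activates).
    """

    presentations: dict[int, int] = field(default_factory=dict)
    co_presented: set[frozenset[int]] = field(default_factory=set)

    def log_trial(self, item_ids: tuple[int, ...]) -> None:
        for i in item_ids:
            self.presentations[i] = self.presentations.get(i, 0) + 1
        if len(item_ids) > 1:
            for i in item_ids:
                for j in item_ids:
                    if i < j:
                        self.co_presented.add(frozenset((i, j)))

    def ever_co_presented(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.co_presented


@dataclass
class NetworkState:
    """All mutable network quantities plus the immutable wiring.

    Per-area arrays are stacked as (n_areas, n_cells): membrane potentials
    ``V`` and outputs ``O`` of the excitatory grid, matched inhibitory
    potentials/outputs, per-cell adaptation, and one slow area-level
    inhibition scalar per area.
    """

    config: NetworkConfig
    projections: dict[tuple[int, int], "Projection"]
    inhib_pool: sp.csr_matrix
    V: np.ndarray
    O: np.ndarray
    V_inh: np.ndarray
    O_inh: np.ndarray
    adapt: np.ndarray
    global_inhib: np.ndarray
    t: int = 0
    training: TrainingRecord = field(default_factory=TrainingRecord)
    patterns: Optional[list["PatternPair"]] = None

    @classmethod
    def blank(cls, config: NetworkConfig,
              projections: dict[tuple[int, int], "Projection"],
              inhib_pool: sp.csr_matrix) -> "NetworkState":
        shape = (config.areas, config.grid.n)
        z = lambda: np.zeros(shape)
        return cls(config=config, projections=projections, inhib_pool=inhib_pool,
                   V=z(), O=z(), V_inh=z(), O_inh=z(), adapt=z(),
                   global_inhib=np.zeros(config.areas))

    @property
    def n_areas(self) -> int:
        return self.config.areas

    @property
    def n_cells(self) -> int:
        return self.config.grid.n

    def reset_dynamic(self, keep_adaptation: bool = False) -> None:
        """Zero the dynamic variables (weights untouched).

        With ``keep_adaptation`` the slow per-cell adaptation survives the
        reset: used between training trials, where it acts as an
        intrinsic-excitability memory spanning many trials.
        """
        for arr in (self.V, self.O, self.V_inh, self.O_inh):
            arr[:] = 0.0
        if not keep_adaptation:
            self.adapt[:] = 0.0
        self.global_inhib[:] = 0.0

    def structure_checksums(self) -> dict[tuple[int, int], int]:
        return {k: p.structure_checksum() for k, p in self.projections.items()}
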