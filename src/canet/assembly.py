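"""Cell-assembly extraction and overlap / orthogonality analysis.

A trained network is probed one item at a time with learning off; each
cell's output is averaged over the steady part of the stimulation window,
giving a response profile per item.  A cell belongs to the item's assembly
at threshold gamma iff its averaged response reaches gamma * M, where M is
the response of the maximally responsive cell anywhere in the network for
that item.  The strongly responsive core (response >= gamma_kernel * M) is
the assembly's kernel; the remaining members form its halo.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import substream
from .netcore import Phase, run
from .patterns import PatternPair
from .state import NetworkState
from .training import stimulus_array

__all__ = [
    "ResponseProfile",
    "CellAssembly",
    "OverlapReport",
    "measure_responses",
    "extract_ca",
    "extract_all",
    "overlap_report",
    "orthogonality",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResponseProfile:
    """Per-cell time-averaged response of the whole network to one item."""

    item_id: int
    responses: np.ndarray  # (n_areas, n_cells), values in [0, 1]

    def __post_init__(self) -> None:
        self.responses.setflags(write=False)

    @property
    def M(self) -> float:
        """Output of the maximally responsive cell (global over all areas)."""
        return float(self.responses.max())


@dataclass(frozen=True)
class CellAssembly:
    """Membership of one item's assembly at one extraction threshold."""

    item_id: int
    gamma: float
    members: np.ndarray  # bool, (n_areas, n_cells)
    kernel: np.ndarray   # bool, subset of members

    def __post_init__(self) -> None:
        self.members.setflags(write=False)
        self.kernel.setflags(write=False)

    @property
    def size(self) -> int:
        return int(self.members.sum())

    def member_sets(self) -> list[set[int]]:
        """Per-area sets of member cell indices."""
        return [set(np.flatnonzero(a)) for a in self.members]

    def restricted(self, areas: Sequence[int]) -> np.ndarray:
        return self.members[list(areas)]


def measure_responses(network: NetworkState, patterns: Sequence[PatternPair],
                      probe_steps: Optional[int] = None,
                      window: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None
                      ) -> list[ResponseProfile]:
    """Probe every item and return its time-averaged response profile.

    For each item the dynamic state is reset, the item's pattern pair is
    presented for ``probe_steps`` steps with learning off, and each cell's
    output is averaged over the final ``window`` steps (excluding the
    ignition transient).  Raises if the network produces an all-zero
    profile ("untrained or dead network").
    """
    ap = network.config.assembly
    probe_steps = probe_steps or ap.probe_stim_steps
    window = window or ap.probe_window
    if rng is None:
        rng = substream(network.config.master_seed, "probe-noise")
    profiles = []
    for pat in patterns:
        ext = stimulus_array(network, pat)
        trace = run(network, [Phase("probe", probe_steps, ext, learning_on=False,
                                    reset_before=True)], rng)
        mean = trace.phase_mean("probe", last=window)
        if mean.max() <= 0.0:
            raise RuntimeError(
                f"untrained or dead network: all-zero response profile for item "
                f"{pat.item_id}")
        profiles.append(ResponseProfile(item_id=pat.item_id, responses=mean))
    network.reset_dynamic()
    return profiles


def extract_ca(profile: ResponseProfile, gamma: float,
               gamma_kernel: float = 0.75) -> CellAssembly:
    """Threshold a response profile into assembly membership.

    Membership depends only on the ratio response / M, so profiles are
    scale-invariant; membership at a higher gamma is always a subset of
    membership at a lower one.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must be in (0, 1]")
    m = profile.M
    members = profile.responses >= gamma * m
    kernel = profile.responses >= max(gamma, gamma_kernel) * m
    return CellAssembly(item_id=profile.item_id, gamma=gamma,
                        members=members, kernel=kernel)


def extract_all(profiles: Sequence[ResponseProfile],
                gamma_grid: Iterable[float],
                gamma_kernel: float = 0.75) -> dict[float, list[CellAssembly]]:
    """Assemblies for every item at every gamma of the grid."""
    return {float(g): [extract_ca(p, float(g), gamma_kernel) for p in profiles]
            for g in gamma_grid}


@dataclass
class OverlapReport:
    """Pairwise assembly overlap (% of shared cells) across the gamma grid."""

    gamma_grid: list[float]
    mean_overlap_pct: dict[float, float]
    max_overlap_pct: dict[float, float]
    pair_matrices: dict[float, np.ndarray] = field(repr=False)
    item_ids: list[int] = field(default_factory=list)

    @property
    def grand_max(self) -> float:
        return max(self.max_overlap_pct.values())

    @property
    def grand_mean(self) -> float:
        return float(np.mean(list(self.mean_overlap_pct.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gamma": self.gamma_grid,
            "mean_pct": [self.mean_overlap_pct[g] for g in self.gamma_grid],
            "max_pct": [self.max_overlap_pct[g] for g in self.gamma_grid],
        })


def _pair_overlap_pct(a: np.ndarray, b: np.ndarray, denominator: str) -> float:
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    if denominator == "min":
        base = min(na, nb)
    elif denominator == "union":
        base = na + nb - inter
    else:  # mean
        base = 0.5 * (na + nb)
    return 100.0 * inter / base


def overlap_report(cas: Mapping[float, Sequence[CellAssembly]],
                   denominator: str = "min",
                   areas: Optional[Sequence[int]] = None) -> OverlapReport:
    """Mean and maximal pairwise overlap per gamma over all unordered pairs.

    ``denominator`` selects the percentage base: the smaller assembly
    ("min", the most conservative and the default), the union, or the mean
    cardinality.  Pairs in which either assembly is empty (possible at high
    gamma) are skipped and logged.  ``areas`` optionally restricts counting
    to a subset of areas (e.g. excluding the stimulated peripheral ones).
    """
    gammas = sorted(cas.keys())
    if any(len(cas[g]) < 2 for g in gammas):
        raise ValueError("overlap analysis requires at least two assemblies")
    mean_pct: dict[float, float] = {}
    max_pct: dict[float, float] = {}
    matrices: dict[float, np.ndarray] = {}
    item_ids = [ca.item_id for ca in cas[gammas[0]]]
    for g in gammas:
        group = cas[g]
        k = len(group)
        mat = np.full((k, k), np.nan)
        np.fill_diagonal(mat, 100.0)
        vals = []
        for i, j in itertools.combinations(range(k), 2):
            a = group[i].members if areas is None else group[i].restricted(areas)
            b = group[j].members if areas is None else group[j].restricted(areas)
            if a.sum() == 0 or b.sum() == 0:
                log.warning("empty assembly at gamma=%.2f (items %d/%d); pair skipped",
                            g, group[i].item_id, group[j].item_id)
                continue
            pct = _pair_overlap_pct(a, b, denominator)
            mat[i, j] = mat[j, i] = pct
            vals.append(pct)
        if not vals:
            raise ValueError(f"no valid assembly pairs at gamma={g}")
        mean_pct[g] = float(np.mean(vals))
        max_pct[g] = float(np.max(vals))
        matrices[g] = mat
    return OverlapReport(gamma_grid=gammas, mean_overlap_pct=mean_pct,
                         max_overlap_pct=max_pct, pair_matrices=matrices,
                         item_ids=item_ids)


def orthogonality(profiles: Sequence[ResponseProfile]) -> np.ndarray:
    """Pairwise cosine similarity of the items' steady-state activity vectors.

    Near-zero off-diagonal entries mean the items induce quasi-orthogonal
    network states.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    X = np.stack([p.responses.ravel() for p in profiles])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Xn = X / norms
    sim = Xn @ Xn.T
    return np.clip(sim, 0.0, 1.0)
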