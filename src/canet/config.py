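"""Configuration schema for the multi-area assembly network.

Every run of the simulator is fully determined by a :class:`NetworkConfig`
and nothing else: architecture, dynamics, plasticity, stimulus set, training
schedule and the master seed all live here, and the whole object round-trips
losslessly through YAML.  All randomness in the package is drawn from named
substreams derived from ``master_seed`` (see :func:`substream`), so a config
file plus a seed reproduces a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

SCHEMA_VERSION = 1

__all__ = [
    "GridSpec",
    "ProjectionDefaults",
    "ProjectionSpec",
    "DynamicsParams",
    "PlasticityParams",
    "PatternParams",
    "TrainingSchedule",
    "AssemblyParams",
    "ExperimentParams",
    "NetworkConfig",
    "substream",
    "default_config",
    "scaled_config",
]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return an independent random generator for a named purpose.

    The stream is keyed by ``(master_seed, crc32(name))`` so that, e.g., the
    connectivity draw does not depend on how many noise samples were consumed
    earlier, and adding a new consumer never perturbs existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), key)))


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid of cells; one grid of excitatory and one of
    (implicit, matched) inhibitory cells per area."""

    rows: int = 25
    cols: int = 25

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column coordinate of every cell, in index order."""
        idx = np.arange(self.n)
        return idx // self.cols, idx % self.cols


@dataclass(frozen=True)
class ProjectionDefaults:
    """Shared geometry/initialisation for one class of projections."""

    kernel_halfwidth: int = 3
    density: float = 0.35
    w_init_low: float = 0.0
    w_init_high: float = 0.30
    toroidal: bool = False


@dataclass(frozen=True)
class ProjectionSpec:
    """Parameters of a single source-area -> target-area projection."""

    source_area: int
    target_area: int
    kernel_halfwidth: int
    density: float
    w_init_low: float
    w_init_high: float
    allow_self: bool = True
    toroidal: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("empty projection: density must be in (0, 1]")
        if self.kernel_halfwidth < 0:
            raise ValueError("kernel_halfwidth must be >= 0")
        if self.w_init_low < 0 or self.w_init_high < self.w_init_low:
            raise ValueError("initial weight range must satisfy 0 <= low <= high")


@dataclass(frozen=True)
class DynamicsParams:
    """Time constants and gains of the graded-response dynamics.

    Time constants are in simulation steps (synchronous update, unit step).
    ``phi`` is the foot of the piecewise-linear squashing function: output is
    0 below ``phi``, rises with unit slope on [phi, phi + 1] and saturates
    at 1 above.
    """

    tau_membrane: float = 2.5
    tau_inhib: float = 3.0
    tau_adapt: float = 120.0
    tau_global: float = 2.5
    adapt_strength: float = 0.50
    local_inhib_gain: float = 2.0
    inhib_input_scale: float = 0.25
    global_inhib_gain: float = 0.045
    global_inhib_gain_sq: float = 0.0002
    global_inhib_cap: float = 16.0
    noise_amplitude: float = 0.25
    phi: float = 0.25
    w_max: float = 0.65
    inhib_kernel_halfwidth: int = 2
    squash: str = "piecewise"  # or "logistic"

    def __post_init__(self) -> None:
        for name in ("tau_membrane", "tau_inhib", "tau_adapt", "tau_global"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 step")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        for name in ("adapt_strength", "local_inhib_gain", "global_inhib_gain",
                     "global_inhib_gain_sq", "noise_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PlasticityParams:
    """Thresholds and step size of the ABS-style LTP/LTD rule.

    LTP (step ``+delta_w``) fires when the presynaptic output is >=
    ``theta_pre`` and the postsynaptic membrane potential is >=
    ``theta_plus``; homosynaptic LTD (step ``-ltd_scale * delta_w``) when
    the presynaptic cell is active but the postsynaptic potential sits in
    the intermediate window [theta_minus, theta_plus); heterosynaptic LTD
    (step further scaled by ``hetero_scale``, switchable) when the
    presynaptic cell is truly silent (output < ``theta_silent``) while the
    postsynaptic potential exceeds ``theta_plus``.  Weights are clipped to
    [0, w_max]; there is no normalisation or homeostatic scaling.
    """

    theta_pre: float = 0.50
    theta_silent: float = 0.10
    theta_plus: float = 0.35
    theta_minus: float = 0.10
    delta_w: float = 0.004
    ltd_scale: float = 0.55
    hetero_scale: float = 4.0
    w_max: float = 0.65
    heterosynaptic_ltd: bool = True

    def __post_init__(self) -> None:
        if not self.theta_minus < self.theta_plus:
            raise ValueError("theta_minus must be < theta_plus")
        if not (0 < self.delta_w < self.w_max):
            raise ValueError("delta_w must be in (0, w_max)")
        if self.ltd_scale <= 0 or self.hetero_scale <= 0:
            raise ValueError("ltd_scale and hetero_scale must be positive")


@dataclass(frozen=True)
class PatternParams:
    """Binary stimulus set: ``n_items`` pattern pairs, each activating
    ``n_active`` cells in the first and last area."""

    n_items: int = 12
    n_active: int = 19
    min_hamming_active: int = 18

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_active < 1:
            raise ValueError("n_items and n_active must be positive")
        if self.min_hamming_active < 0 or self.min_hamming_active > self.n_active:
            raise ValueError("min_hamming_active must be in [0, n_active]")


@dataclass(frozen=True)
class TrainingSchedule:
    """Presentation schedule: every item is shown ``presentations_per_item``
    times, one item per trial, in randomized or round-robin order."""

    presentations_per_item: int = 3000
    stim_duration: int = 14
    isi_duration: int = 4
    order: str = "randomized"

    def __post_init__(self) -> None:
        if self.presentations_per_item < 1:
            raise ValueError("presentations_per_item must be >= 1")
        if self.stim_duration < 1 or self.isi_duration < 0:
            raise ValueError("durations must be positive (isi may be 0)")
        if self.order not in ("randomized", "round_robin"):
            raise ValueError("order must be 'randomized' or 'round_robin'")


@dataclass(frozen=True)
class AssemblyParams:
    """Cell-assembly extraction and overlap analysis settings."""

    gamma_grid: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.901, 0.05), 2))
    gamma_kernel: float = 0.75
    denominator: str = "min"  # "min" | "union" | "mean"
    include_peripheral: bool = True
    probe_stim_steps: int = 30
    probe_window: int = 15

    def __post_init__(self) -> None:
        if not all(0 < g <= 1 for g in self.gamma_grid):
            raise ValueError("gamma values must be in (0, 1]")
        if not (0 < self.gamma_kernel <= 1):
            raise ValueError("gamma_kernel must be in (0, 1]")
        if self.denominator not in ("min", "union", "mean"):
            raise ValueError("denominator must be min|union|mean")


@dataclass(frozen=True)
class ExperimentParams:
    """Thresholds and phase durations of the ignition / working-memory /
    superposition protocols."""

    theta_on: float = 0.5       # per-cell output level counting as "on"
    theta_frac: float = 0.5     # fraction of kernel cells required "on"
    on_areas: str = "central"   # evaluate the on-criterion over "central" or "all" areas
    epsilon: float = 0.05       # relative L2 tolerance for return-to-initial
    ignite_stim_steps: int = 25
    settle_steps: int = 95
    observe_steps: int = 500
    probe_phase_steps: int = 20   # each of t1..t4
    release_phase_steps: int = 40  # each of t5..t8
    drift_window: int = 100
    drift_tolerance: float = 0.10


@dataclass(frozen=True)
class NetworkConfig:
    """Complete parameterization of one simulation campaign."""

    areas: int = 6
    grid: GridSpec = field(default_factory=GridSpec)
    recurrent: ProjectionDefaults = field(default_factory=ProjectionDefaults)
    forward: ProjectionDefaults = field(
        default_factory=lambda: ProjectionDefaults(kernel_halfwidth=5, density=0.28))
    backward: ProjectionDefaults = field(
        default_factory=lambda: ProjectionDefaults(kernel_halfwidth=5, density=0.28))
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    patterns: PatternParams = field(default_factory=PatternParams)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    experiment: ExperimentParams = field(default_factory=ExperimentParams)
    stim_amplitude: float = 4.5
    jumping_links: bool = False
    overlap_bound_pct: float = 5.0
    master_seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.areas < 2:
            raise ValueError("at least two areas are required (no between-area structure otherwise)")
        if self.patterns.n_active > self.grid.n:
            raise ValueError("n_active exceeds the number of cells per area")
        if self.plasticity.w_max != self.dynamics.w_max:
            raise ValueError("plasticity.w_max and dynamics.w_max must agree")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NetworkConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        kwargs: dict[str, Any] = {}
        nested = {
            "grid": GridSpec,
            "recurrent": ProjectionDefaults,
            "forward": ProjectionDefaults,
            "backward": ProjectionDefaults,
            "dynamics": DynamicsParams,
            "plasticity": PlasticityParams,
            "patterns": PatternParams,
            "schedule": TrainingSchedule,
            "assembly": AssemblyParams,
            "experiment": ExperimentParams,
        }
        errors = []
        for key, value in d.items():
            if key in nested:
                try:
                    if key == "assembly" and "gamma_grid" in value:
                        value = dict(value)
                        value["gamma_grid"] = tuple(value["gamma_grid"])
                    kwargs[key] = nested[key](**value)
                except (TypeError, ValueError) as exc:
                    errors.append(f"{key}: {exc}")
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                errors.append(f"{key}: unknown field")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return cls(**kwargs)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["assembly"]["gamma_grid"] = [float(g) for g in d["assembly"]["gamma_grid"]]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **kwargs: Any) -> "NetworkConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(master_seed: int = 0) -> NetworkConfig:
    """The full-size study configuration: 6 areas of 25x25 cells, 12 pattern
    pairs with 19 active cells each, 3000 presentations per item."""
    return NetworkConfig(master_seed=master_seed)


def scaled_config(master_seed: int = 0, n_items: int = 6,
                  presentations: int = 500) -> NetworkConfig:
    """A desk-scale variant of :func:`default_config` (same architecture and
    dynamics; fewer items and presentations) that trains in a few minutes."""
    cfg = default_config(master_seed)
    return cfg.replace(
        patterns=dataclasses.replace(cfg.patterns, n_items=n_items),
        schedule=dataclasses.replace(cfg.schedule, presentations_per_item=presentations),
    )
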