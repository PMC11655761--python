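"""Per-step dynamics of the graded-response network.

All cells are leaky integrators updated synchronously with unit time step.
An excitatory cell's net input combines external stimulation, excitatory
synaptic drive from every incoming projection, subtractive inhibition from
its matched local inhibitory cell and from the slow area-level inhibition
(a linear term that saturates above the single-assembly scale — leaving
headroom for two or more co-active assemblies — plus a supralinear term
that only engages far above the assembly scale),
subtractive spike-rate adaptation, and additive uniform noise.  Outputs pass
through a piecewise-linear squash: 0 below ``phi``, unit slope on
[phi, phi + 1], saturated at 1 above (a logistic alternative is available
via ``DynamicsParams.squash``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import plasticity
from .state import NetworkState

__all__ = ["Phase", "ExperimentTrace", "step", "run", "squash"]


def squash(v: np.ndarray, phi: float, kind: str = "piecewise") -> np.ndarray:
    """Bounded output nonlinearity mapping membrane potential to [0, 1]."""
    if kind == "piecewise":
        return np.clip(v - phi, 0.0, 1.0)
    if kind == "logistic":
        # matched so that output is 0.5 at the centre of the linear range
        return 1.0 / (1.0 + np.exp(-4.0 * (v - phi - 0.5)))
    raise ValueError(f"unknown squash kind {kind!r}")


def step(state: NetworkState, external_input: Optional[np.ndarray],
         rng: np.random.Generator, learning_on: bool) -> NetworkState:
    """Advance the whole network by one synchronous step (in place).

    ``external_input`` is an (n_areas, n_cells) array of input currents
    (zeros, or None, for unstimulated areas).  When ``learning_on`` the
    plasticity rule is applied to every excitatory projection using the
    fresh presynaptic outputs and postsynaptic potentials.
    """
    dp = state.config.dynamics
    O_prev = state.O  # safe: the update below rebinds state.O, never mutates it

    drive = np.zeros_like(state.V)
    for (src, tgt), proj in state.projections.items():
        drive[tgt] += proj.weights @ O_prev[src]

    net = drive
    if external_input is not None:
        net = net + external_input
    net -= dp.local_inhib_gain * state.O_inh
    gi = state.global_inhib
    net -= (dp.global_inhib_gain * np.minimum(gi, dp.global_inhib_cap)
            + dp.global_inhib_gain_sq * gi * gi)[:, None]
    net -= dp.adapt_strength * state.adapt
    if dp.noise_amplitude > 0:
        net += dp.noise_amplitude * rng.uniform(-1.0, 1.0, size=state.V.shape)

    state.V += (net - state.V) / dp.tau_membrane
    state.O = squash(state.V, dp.phi, dp.squash)

    inh_in = dp.inhib_input_scale * (state.inhib_pool @ O_prev.T).T
    state.V_inh += (inh_in - state.V_inh) / dp.tau_inhib
    state.O_inh = squash(state.V_inh, dp.phi, dp.squash)

    state.adapt += (state.O - state.adapt) / dp.tau_adapt
    state.global_inhib += (state.O.sum(axis=1) - state.global_inhib) / dp.tau_global

    if not np.isfinite(state.V).all():
        bad = int(np.argwhere(~np.isfinite(state.V).all(axis=1))[0, 0])
        raise FloatingPointError(
            f"dynamics diverged: non-finite potential in area {bad} at step {state.t}")

    if learning_on:
        for (src, tgt), proj in state.projections.items():
            plasticity.apply(proj, state.O[src], state.V[tgt],
                             state.config.plasticity)

    state.t += 1
    return state


@dataclass(frozen=True)
class Phase:
    """One homogeneous segment of a run schedule."""

    name: str
    duration: int
    external_input: Optional[np.ndarray] = None  # (n_areas, n_cells) or None
    learning_on: bool = False
    reset_before: bool = False

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("phase duration must be >= 1")


@dataclass
class ExperimentTrace:
    """Time-indexed record of per-cell outputs with phase bookkeeping.

    ``outputs`` has shape (T, n_areas, n_cells) (float32, possibly
    subsampled in time by ``stride``); ``phases`` maps phase names to
    [start, end) step indices on the recorded axis.
    """

    outputs: np.ndarray
    phases: dict[str, tuple[int, int]]
    stride: int = 1

    @property
    def n_steps(self) -> int:
        return self.outputs.shape[0]

    def phase_slice(self, name: str) -> np.ndarray:
        a, b = self.phases[name]
        return self.outputs[a:b]

    def window(self, last: int, upto_phase: Optional[str] = None) -> np.ndarray:
        """The last ``last`` recorded steps (optionally of a given phase) —
        e.g. the final 150 steps used for raster snapshots."""
        seg = self.phase_slice(upto_phase) if upto_phase else self.outputs
        return seg[-last:]

    def phase_mean(self, name: str, last: Optional[int] = None) -> np.ndarray:
        seg = self.phase_slice(name)
        if last is not None:
            seg = seg[-last:]
        return seg.mean(axis=0)


def run(state: NetworkState, schedule: Sequence[Phase],
        rng: np.random.Generator, record_stride: int = 1) -> ExperimentTrace:
    """Execute a phase schedule, recording outputs every ``record_stride`` steps.

    Deterministic given the state, schedule and generator. Raises on an
    empty schedule.
    """
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    frames: list[np.ndarray] = []
    bounds: dict[str, tuple[int, int]] = {}
    recorded = 0
    for phase in schedule:
        if phase.reset_before:
            state.reset_dynamic()
        start = recorded
        for i in range(phase.duration):
            step(state, phase.external_input, rng, phase.learning_on)
            if i % record_stride == 0:
                frames.append(state.O.astype(np.float32))
                recorded += 1
        bounds[phase.name] = (start, recorded)
    return ExperimentTrace(outputs=np.stack(frames), phases=bounds,
                           stride=record_stride)
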