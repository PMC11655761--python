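"""Experiment protocols: ignition, working-memory persistence, superposition.

All protocols run on a trained network with learning off.  An assembly is
"on" in a time window when at least ``theta_frac`` of its kernel cells have
mean output >= ``theta_on`` there — the operational version of a CA's
all-or-none activity state.  Because input-free reverberation is carried by
the central areas (reactivation in the two stimulated peripheral areas is
characteristically weak and partial), the criterion is evaluated over the
central areas by default (``ExperimentParams.on_areas``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import substream
from .assembly import CellAssembly
from .netcore import ExperimentTrace, Phase, run
from .patterns import PatternPair
from .state import NetworkState
from .training import stimulus_array

__all__ = [
    "SuperpositionResult",
    "ca_on",
    "ignite",
    "persistence_test",
    "superpose",
    "raster",
    "decode_on_set",
]


def _rng(network: NetworkState, name: str,
         rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else substream(network.config.master_seed, name)


def _pattern(network: NetworkState, item_id: int) -> PatternPair:
    if network.patterns is None:
        raise ValueError("network carries no pattern set")
    for p in network.patterns:
        if p.item_id == item_id:
            return p
    raise KeyError(f"unknown item {item_id}")


def _area_slice(n_areas: int, on_areas: str) -> slice:
    if on_areas == "central" and n_areas > 2:
        return slice(1, n_areas - 1)
    return slice(0, n_areas)


def ca_on(window_outputs: np.ndarray, ca: CellAssembly,
          theta_on: float, theta_frac: float, on_areas: str = "central") -> bool:
    """All-or-none state of one assembly over a (T, areas, cells) window."""
    mean = window_outputs.mean(axis=0)
    sl = _area_slice(mean.shape[0], on_areas)
    kernel_vals = mean[sl][ca.kernel[sl]]
    if kernel_vals.size == 0:
        return False
    return float((kernel_vals >= theta_on).mean()) >= theta_frac


def decode_on_set(window_outputs: np.ndarray,
                  cas: Mapping[int, CellAssembly],
                  theta_on: float, theta_frac: float,
                  on_areas: str = "central") -> set[int]:
    """Identity decoding: the set of learned items whose assembly is "on"."""
    return {item for item, ca in cas.items()
            if ca_on(window_outputs, ca, theta_on, theta_frac, on_areas)}


def _kernel_sum(outputs: np.ndarray, ca: CellAssembly,
                on_areas: str = "central") -> np.ndarray:
    """Summed kernel-cell activity per recorded step (central areas by
    default, where reverberation lives)."""
    sl = _area_slice(outputs.shape[1], on_areas)
    return outputs[:, sl][:, ca.kernel[sl]].sum(axis=1)


def ignite(network: NetworkState, ca: CellAssembly,
           stim_steps: Optional[int] = None, observe_steps: int = 100,
           pattern: Optional[PatternPair] = None,
           rng: Optional[np.random.Generator] = None
           ) -> tuple[ExperimentTrace, bool]:
    """Briefly stimulate an item and test for full assembly ignition.

    The network is reset, stimulated for ``stim_steps`` with the item's
    pattern pair (or an arbitrary ``pattern``, e.g. a non-learned control),
    then left input-free for ``observe_steps``.  ``ignited`` is judged from
    the final steps of stimulation with the kernel-fraction criterion.
    """
    ep = network.config.experiment
    stim_steps = stim_steps or ep.ignite_stim_steps
    pat = pattern if pattern is not None else _pattern(network, ca.item_id)
    ext = stimulus_array(network, pat)
    rng = _rng(network, "experiment-noise", rng)
    trace = run(network, [
        Phase("stim", stim_steps, ext, reset_before=True),
        Phase("free", observe_steps, None),
    ], rng)
    window = trace.phase_slice("stim")[-max(1, stim_steps // 3):]
    ignited = ca_on(window, ca, ep.theta_on, ep.theta_frac, ep.on_areas)
    return trace, ignited


def persistence_test(network: NetworkState, ca: CellAssembly,
                     observe_steps: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[bool, dict]:
    """Working-memory test: does the assembly reverberate without input?

    The item is ignited, input removed, and the summed kernel activity
    followed for ``observe_steps`` (default 500).  ``self_sustained`` is
    True iff that activity never falls below ``theta_on`` times its
    post-ignition level, where the level is taken after the slow adaptation
    transient has equilibrated (a freshly ignited assembly settles from its
    stimulation-driven peak to its reverberant level over a few adaptation
    time constants).  Also reports the worst relative drift over any
    ``drift_window`` span of the settled free phase (fixed-point check).
    """
    ep = network.config.experiment
    observe_steps = observe_steps or ep.observe_steps
    rng = _rng(network, "experiment-noise", rng)
    trace, ignited = ignite(network, ca, observe_steps=observe_steps, rng=rng)
    free = trace.phase_slice("free")
    act = _kernel_sum(free, ca, ep.on_areas)
    tau_a = network.config.dynamics.tau_adapt
    settle = min(int(2.5 * tau_a), observe_steps // 2)
    level = act[settle:settle + 20].mean()
    self_sustained = bool(ignited and level > 0
                          and act[settle:].min() >= ep.theta_on * level)
    # worst-case drift of the running mean over sliding windows
    w = min(ep.drift_window, max(2, act.size // 2))
    post = act[settle:]
    drift = float("nan")
    if post.size >= w and level > 0:
        means = np.convolve(post, np.ones(w) / w, mode="valid")
        drift = float((means.max() - means.min()) / means.mean()) if means.mean() > 0 else float("inf")
    stats = {"ignited": ignited, "post_ignition_level": float(level),
             "min_activity": float(act[settle:].min()), "max_drift": drift}
    return self_sustained, stats


@dataclass
class SuperpositionResult:
    """Outcome of one two-item superposition episode (phases t0..t8)."""

    sustained_item: int
    probed_item: int
    both_on_during_stimulation: bool
    probed_fades_after_removal: bool
    sustained_survives: bool
    interference: float          # relative change of sustained kernel activity
    returned_to_initial: bool    # final state within epsilon of pre-probe state
    decoded_at_t4: set[int] = dataclasses.field(default_factory=set)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["decoded_at_t4"] = sorted(d["decoded_at_t4"])
        return json.dumps(d, indent=2)


def superpose(network: NetworkState, cas: Mapping[int, CellAssembly],
              sustained_item: int, probed_item: int,
              rng: Optional[np.random.Generator] = None
              ) -> tuple[SuperpositionResult, ExperimentTrace]:
    """Nine-phase superposition protocol.

    t0: ignite the sustained item and let it settle into self-sustained
    reverberation.  t1-t4: switch the external input to the probed item's
    pattern pair; both assemblies must be "on" by t4, and the decoded on-set
    over *all* learned items must equal exactly the stimulated pair.  t5-t8:
    remove all input; in the default regime the probed assembly fades while
    the sustained one survives, returning the network to its initial state.

    Raises if the two items were ever co-presented during training
    ("condition B violated").
    """
    ep = network.config.experiment
    if sustained_item != probed_item and network.training.ever_co_presented(
            sustained_item, probed_item):
        raise ValueError("condition B violated: items were co-presented during training")
    ca_s = cas[sustained_item]
    ca_p = cas[probed_item]
    rng = _rng(network, "experiment-noise", rng)

    ext_s = stimulus_array(network, _pattern(network, sustained_item))
    ext_p = stimulus_array(network, _pattern(network, probed_item))
    phases = [
        Phase("t0_stim", ep.ignite_stim_steps, ext_s, reset_before=True),
        Phase("t0", ep.settle_steps, None),
    ]
    phases += [Phase(f"t{i}", ep.probe_phase_steps, ext_p) for i in range(1, 5)]
    phases += [Phase(f"t{i}", ep.release_phase_steps, None) for i in range(5, 9)]
    trace = run(network, phases, rng)

    pre = trace.phase_slice("t0")[-30:]
    t4 = trace.phase_slice("t4")
    post = trace.phase_slice("t8")[-30:]

    both_on = (ca_on(t4, ca_s, ep.theta_on, ep.theta_frac, ep.on_areas)
               and ca_on(t4, ca_p, ep.theta_on, ep.theta_frac, ep.on_areas))
    decoded = decode_on_set(t4, cas, ep.theta_on, ep.theta_frac, ep.on_areas)
    sustained_survives = ca_on(post, ca_s, ep.theta_on, ep.theta_frac, ep.on_areas)
    probed_fades = (sustained_item == probed_item) or not ca_on(
        post, ca_p, ep.theta_on, ep.theta_frac, ep.on_areas)

    pre_level = _kernel_sum(pre, ca_s, ep.on_areas).mean()
    post_level = _kernel_sum(post, ca_s, ep.on_areas).mean()
    interference = abs(post_level - pre_level) / pre_level if pre_level > 0 else float("inf")

    pre_state = pre.mean(axis=0).ravel()
    post_state = post.mean(axis=0).ravel()
    denom = np.linalg.norm(pre_state)
    dist = np.linalg.norm(post_state - pre_state) / denom if denom > 0 else float("inf")
    returned = bool(dist <= ep.epsilon and sustained_survives)

    result = SuperpositionResult(
        sustained_item=sustained_item, probed_item=probed_item,
        both_on_during_stimulation=bool(both_on),
        probed_fades_after_removal=bool(probed_fades),
        sustained_survives=bool(sustained_survives),
        interference=float(interference),
        returned_to_initial=returned,
        decoded_at_t4=decoded,
    )
    return result, trace


def raster(trace: ExperimentTrace, cas: Sequence[CellAssembly],
           normalize: bool = True) -> np.ndarray:
    """Per-assembly, per-area summed activity over time.

    Returns an array of shape (n_cas, n_areas, T): entry (c, a, t) is the
    summed output of assembly c's member cells in area a at recorded step t.
    With ``normalize`` each (assembly, area) row is scaled by its own
    maximum (the gray scale used for raster rendering); all-zero rows are
    left at zero.
    """
    T, n_areas, _ = trace.outputs.shape
    out = np.zeros((len(cas), n_areas, T))
    for c, ca in enumerate(cas):
        for a in range(n_areas):
            sel = ca.members[a]
            if sel.any():
                out[c, a] = trace.outputs[:, a, sel].sum(axis=1)
    if normalize:
        peaks = out.max(axis=2, keepdims=True)
        peaks[peaks == 0] = 1.0
        out = out / peaks
    return out
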