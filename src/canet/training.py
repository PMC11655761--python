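"""Unsupervised training loop: repeated single-item pattern presentation.

Each trial stimulates one item's pattern pair (first and last area) for
``stim_duration`` steps with plasticity enabled, then silences and resets
the dynamic state for the inter-stimulus interval.  The reset at stimulus
offset guarantees that activity evoked by different items never overlaps in
time — the anti-correlation the LTD pathway relies on — and plays the role
of the between-trial activity wipe used when training attractor networks
whose learned states would otherwise persist into the next trial.  The
slow adaptation variable is *not* wiped between trials: cells that are
active in every trial regardless of the item accumulate adaptation and lose
their competitive edge, a sliding-excitability pressure that keeps learning
item-selective without any weight normalisation.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from .config import NetworkConfig, substream
from .connectivity import build_network
from .netcore import step
from .patterns import PatternPair, Trial, expand_schedule, generate_pattern_set
from .state import NetworkState

__all__ = ["stimulus_array", "train_network", "run_trials"]


def stimulus_array(state_or_config, pattern: PatternPair,
                   amplitude: Optional[float] = None) -> np.ndarray:
    """External-input array delivering one item's pair to the outer areas."""
    cfg = getattr(state_or_config, "config", state_or_config)
    amp = cfg.stim_amplitude if amplitude is None else amplitude
    ext = np.zeros((cfg.areas, cfg.grid.n))
    ext[0] = amp * pattern.first
    ext[-1] = amp * pattern.last
    return ext


def run_trials(state: NetworkState, trials: Sequence[Trial],
               patterns: Sequence[PatternPair], rng: np.random.Generator,
               progress: Optional[Callable[[int, int], None]] = None) -> NetworkState:
    """Present a list of single-item trials with plasticity on (in place)."""
    by_id = {p.item_id: p for p in patterns}
    ext_by_id = {i: stimulus_array(state, p) for i, p in by_id.items()}
    for k, trial in enumerate(trials):
        ext = ext_by_id[trial.item_id]
        for _ in range(trial.stim_duration):
            step(state, ext, rng, learning_on=True)
        state.reset_dynamic(keep_adaptation=True)
        for _ in range(trial.isi_duration):
            step(state, None, rng, learning_on=True)
        state.training.log_trial((trial.item_id,))
        if progress is not None and (k + 1) % 500 == 0:
            progress(k + 1, len(trials))
    return state


def train_network(config: NetworkConfig,
                  progress: Optional[Callable[[int, int], None]] = None
                  ) -> NetworkState:
    """Build, wire and train a network from a config; returns the trained state.

    Patterns, schedule order and dynamical noise each use their own named
    substream of ``config.master_seed``, so the result is reproducible
    bit-for-bit.
    """
    state = build_network(config)
    pats = generate_pattern_set(
        config.patterns.n_items, config.patterns.n_active, config.grid,
        min_hamming_active=config.patterns.min_hamming_active,
        seed=substream(config.master_seed, "patterns"))
    trials = expand_schedule(config.schedule, pats,
                             seed=substream(config.master_seed, "schedule"))
    noise_rng = substream(config.master_seed, "training-noise")
    run_trials(state, trials, pats, noise_rng, progress=progress)
    state.patterns = pats
    state.reset_dynamic()
    return state
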