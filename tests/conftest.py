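"""Shared fixtures.

``trained_bundle`` is the expensive session fixture: one scaled training run
(12 items, 600 presentations each, full six-area architecture) whose trained
network, response profiles, assemblies and overlap report are reused by the
acceptance tests and the trained-network property tests.
"""

from __future__ import annotations

import dataclasses

import pytest

import canet


@pytest.fixture(scope="session")
def scaled_cfg() -> canet.NetworkConfig:
    return canet.scaled_config(1, n_items=12, presentations=600)


@pytest.fixture(scope="session")
def trained_bundle(scaled_cfg):
    state = canet.train_network(scaled_cfg)
    profiles = canet.measure_responses(state, state.patterns)
    cas = canet.extract_all(profiles, scaled_cfg.assembly.gamma_grid,
                            scaled_cfg.assembly.gamma_kernel)
    report = canet.overlap_report(cas, scaled_cfg.assembly.denominator)
    cas05 = {p.item_id: canet.extract_ca(p, 0.5, scaled_cfg.assembly.gamma_kernel)
             for p in profiles}
    persistence = {iid: canet.persistence_test(state, ca, observe_steps=500)
                   for iid, ca in cas05.items()}
    return {
        "config": scaled_cfg,
        "state": state,
        "profiles": profiles,
        "cas": cas,
        "cas05": cas05,
        "report": report,
        "persistence": persistence,
    }


@pytest.fixture()
def tiny_cfg() -> canet.NetworkConfig:
    """A fast, small configuration for unit tests that need a whole network
    but no emergent structure."""
    cfg = canet.scaled_config(0, n_items=2, presentations=5)
    return cfg.replace(
        grid=canet.GridSpec(10, 10),
        patterns=dataclasses.replace(cfg.patterns, n_active=6, min_hamming_active=0),
    )

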