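"""Gamma-threshold extraction, overlap arithmetic, orthogonality."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canet
from canet.assembly import (ResponseProfile, extract_ca, measure_responses,
                            orthogonality, overlap_report)


def profile_from(arr, item_id=0):
    return ResponseProfile(item_id=item_id, responses=np.asarray(arr, float))


def test_gamma_one_keeps_only_maximal_cells():
    prof = profile_from([[0.2, 1.0, 0.5], [1.0, 0.1, 0.0]])
    ca = extract_ca(prof, 1.0)
    assert ca.members.sum() == 2  # the two cells at M


def test_small_gamma_keeps_almost_everything():
    prof = profile_from([[0.2, 1.0, 0.5], [0.9, 0.1, 0.001]])
    ca = extract_ca(prof, 0.001)
    assert ca.members.sum() == 6


def test_gamma_out_of_range():
    prof = profile_from([[0.5]])
    for g in (0.0, -1.0, 1.5):
        with pytest.raises(ValueError):
            extract_ca(prof, g)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.05, 0.95), st.floats(0.05, 0.95))
def test_nestedness_and_scale_invariance(seed, g1, g2):
    rng = np.random.default_rng(seed)
    prof = profile_from(rng.random((2, 40)))
    lo, hi = sorted((g1, g2))
    assert not (extract_ca(prof, hi).members & ~extract_ca(prof, lo).members).any()
    scaled = profile_from(0.37 * prof.responses)
    assert np.array_equal(extract_ca(prof, hi).members,
                          extract_ca(scaled, hi).members)


def test_kernel_subset_of_members():
    rng = np.random.default_rng(0)
    prof = profile_from(rng.random((3, 30)))
    ca = extract_ca(prof, 0.5, gamma_kernel=0.75)
    assert not (ca.kernel & ~ca.members).any()


def brute_force_overlap(mask_a, mask_b, denominator="min"):
    a = {tuple(x) for x in np.argwhere(mask_a)}
    b = {tuple(x) for x in np.argwhere(mask_b)}
    inter = len(a & b)
    if denominator == "min":
        base = min(len(a), len(b))
    elif denominator == "union":
        base = len(a | b)
    else:
        base = (len(a) + len(b)) / 2
    return 100.0 * inter / base


@pytest.mark.parametrize("denominator", ["min", "union", "mean"])
def test_overlap_matches_brute_force_set_oracle(denominator):
    rng = np.random.default_rng(3)
    profs = [profile_from(rng.random((2, 25)), item_id=i) for i in range(4)]
    gammas = [0.4, 0.6, 0.8]
    cas = {g: [extract_ca(p, g) for p in profs] for g in gammas}
    rep = overlap_report(cas, denominator)
    for g in gammas:
        group = cas[g]
        vals = [brute_force_overlap(group[i].members, group[j].members, denominator)
                for i, j in itertools.combinations(range(4), 2)]
        assert rep.mean_overlap_pct[g] == pytest.approx(np.mean(vals))
        assert rep.max_overlap_pct[g] == pytest.approx(np.max(vals))
        assert rep.max_overlap_pct[g] >= rep.mean_overlap_pct[g]


def test_disjoint_and_identical_extremes():
    a = np.zeros((1, 10), bool); a[0, :3] = True
    b = np.zeros((1, 10), bool); b[0, 5:8] = True
    assert brute_force_overlap(a, b) == 0.0
    prof = profile_from(np.linspace(0, 1, 10).reshape(1, -1))
    cas = {0.5: [extract_ca(prof, 0.5),
                 canet.CellAssembly(1, 0.5, prof.responses >= 0.5, prof.responses >= 0.75)]}
    rep = overlap_report(cas)
    assert rep.max_overlap_pct[0.5] == 100.0


def test_overlap_requires_two_assemblies():
    prof = profile_from(np.random.default_rng(0).random((1, 5)))
    with pytest.raises(ValueError):
        overlap_report({0.5: [extract_ca(prof, 0.5)]})


def test_orthogonality_extremes():
    p1 = profile_from([[1.0, 0.0, 0.5, 0.0]])
    p2 = profile_from([[1.0, 0.0, 0.5, 0.0]], item_id=1)
    p3 = profile_from([[0.0, 0.7, 0.0, 0.2]], item_id=2)
    sim = orthogonality([p1, p2, p3])
    assert sim[0, 1] == pytest.approx(1.0)
    assert sim[0, 2] == pytest.approx(0.0)
    assert np.allclose(np.diag(sim), 1.0)
    assert np.array_equal(sim, sim.T)


def test_dead_network_raises(tiny_cfg):
    import dataclasses
    cfg = tiny_cfg.replace(dynamics=dataclasses.replace(tiny_cfg.dynamics,
                                                        noise_amplitude=0.0),
                           stim_amplitude=0.0)
    state = canet.build_network(cfg)
    for proj in state.projections.values():
        proj.weights.data[:] = 0.0
    pats = canet.generate_pattern_set(1, 6, cfg.grid, seed=0)
    with pytest.raises(RuntimeError, match="untrained or dead network"):
        measure_responses(state, pats)


def test_probe_is_deterministic(tiny_cfg):
    state = canet.build_network(tiny_cfg)
    pats = canet.generate_pattern_set(2, 6, tiny_cfg.grid, seed=1)
    rng = lambda: canet.substream(0, "probe")
    a = measure_responses(state, pats, rng=rng())
    b = measure_responses(state, pats, rng=rng())
    for x, y in zip(a, b):
        assert np.array_equal(x.responses, y.responses)
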