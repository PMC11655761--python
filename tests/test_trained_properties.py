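"""Emergent properties of the trained network beyond the headline bounds."""

import numpy as np

import canet
from canet.experiments import _kernel_sum  # noqa: F401  (module import check)


def test_strong_selective_responders_in_central_areas(trained_bundle):
    # every item develops strong responders (>= 0.5 M) in every central
    # area, and a distributed set of them overall (individual areas can be
    # thin for weakly consolidated items at the scaled presentation count)
    for prof in trained_bundle["profiles"]:
        strong = (prof.responses >= 0.5 * prof.M).sum(axis=1)
        assert (strong[1:-1] >= 1).all()
        assert strong[1:-1].sum() >= 12


def test_quasi_orthogonal_activity_states(trained_bundle):
    sim = canet.orthogonality(trained_bundle["profiles"])
    off = sim[~np.eye(sim.shape[0], dtype=bool)]
    assert off.mean() < 0.2


def test_weight_distribution_is_bimodal(trained_bundle):
    # pooled within-assembly vs cross-assembly synapses: mass near w_max vs
    # mass near 0, with cross mean below 10% of within mean
    state = trained_bundle["state"]
    cas05 = trained_bundle["cas05"]
    w_max = state.config.dynamics.w_max
    within, cross = [], []
    items = list(cas05)
    for (src, tgt), proj in state.projections.items():
        for i in items[:6]:
            mi = cas05[i].members
            pre_i = mi[src][proj.cols]
            post_i = mi[tgt][proj.rows]
            within.append(proj.weights.data[pre_i & post_i])
            for j in items[:6]:
                if j == i:
                    continue
                post_j = cas05[j].members[tgt][proj.rows]
                cross.append(proj.weights.data[pre_i & post_j & ~post_i])
    within = np.concatenate(within)
    cross = np.concatenate(cross)
    assert within.mean() > 0.5 * w_max
    assert cross.mean() < 0.1 * within.mean()
    # bimodality: two-cluster separation of the pooled weights
    pooled = np.concatenate([within, cross])
    lo, hi = pooled < 0.2 * w_max, pooled > 0.8 * w_max
    assert (lo.sum() + hi.sum()) / pooled.size > 0.6


def test_random_pattern_ignites_no_learned_assembly(trained_bundle):
    # all-or-none selectivity: a novel random pattern of the same sparsity
    # fully ignites none of the learned circuits.  The novel pattern is drawn
    # outside the learned stimulus support so that partial-cue pattern
    # completion (a genuine assembly property) does not confound the check.
    state = trained_bundle["state"]
    cfg = trained_bundle["config"]
    rng = np.random.default_rng(123)

    used_first = np.any([p.first for p in state.patterns], axis=0)
    used_last = np.any([p.last for p in state.patterns], axis=0)

    def rand_stim(used):
        free = np.flatnonzero(~used)
        v = np.zeros(cfg.grid.n, dtype=bool)
        v[rng.choice(free, cfg.patterns.n_active, replace=False)] = True
        return v

    novel = canet.PatternPair(item_id=-1, first=rand_stim(used_first),
                              last=rand_stim(used_last))
    for ca in trained_bundle["cas05"].values():
        _, ignited = canet.ignite(state, ca, pattern=novel)
        assert not ignited


def test_learned_patterns_ignite_their_assembly(trained_bundle):
    state = trained_bundle["state"]
    hits = 0
    for iid, ca in trained_bundle["cas05"].items():
        _, ignited = canet.ignite(state, ca)
        hits += ignited
    assert hits >= len(trained_bundle["cas05"]) - 2  # near all-or-none


def test_reverberation_weaker_in_peripheral_areas(trained_bundle):
    # during self-sustained activity, mean member reactivation in the two
    # stimulated outer areas is below that of the central areas
    state = trained_bundle["state"]
    persistent = [i for i, (ok, _) in trained_bundle["persistence"].items() if ok]
    assert persistent
    ca = trained_bundle["cas05"][persistent[0]]
    trace, _ = canet.ignite(state, ca, observe_steps=400)
    free = trace.phase_slice("free")[-100:].mean(axis=0)
    peripheral = np.concatenate([free[0][ca.members[0]], free[-1][ca.members[-1]]])
    central = np.concatenate([free[a][ca.members[a]] for a in (1, 2, 3, 4)])
    assert peripheral.mean() < central.mean()


def test_attractor_activity_drift_small(trained_bundle):
    # fixed-point regime: settled within-assembly activity varies < 10%
    # over any 100-step window
    stats = [s for ok, s in trained_bundle["persistence"].values() if ok]
    assert stats and min(s["max_drift"] for s in stats) < 0.10


def test_overlap_report_reproducible_from_saved_network(trained_bundle, tmp_path):
    state = trained_bundle["state"]
    canet.save_network(state, tmp_path / "net.h5")
    loaded = canet.load_network(tmp_path / "net.h5")
    profs = canet.measure_responses(loaded, loaded.patterns)
    cfg = state.config
    cas = canet.extract_all(profs, cfg.assembly.gamma_grid, cfg.assembly.gamma_kernel)
    rep = canet.overlap_report(cas, cfg.assembly.denominator)
    orig = trained_bundle["report"]
    assert rep.mean_overlap_pct == orig.mean_overlap_pct
    assert rep.max_overlap_pct == orig.max_overlap_pct
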