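"""Topographic wiring: kernel geometry, sparseness, determinism, immutability."""

import numpy as np
import pytest

import canet
from canet.config import GridSpec, ProjectionSpec
from canet.connectivity import make_topographic_projection, neighbourhood_matrix


def spec(hw=2, density=0.28, low=0.0, high=0.3, allow_self=True, src=0, tgt=1,
         toroidal=False):
    return ProjectionSpec(source_area=src, target_area=tgt, kernel_halfwidth=hw,
                          density=density, w_init_low=low, w_init_high=high,
                          allow_self=allow_self, toroidal=toroidal)


def test_degenerate_kernel_is_identity():
    g = GridSpec(7, 7)
    proj = make_topographic_projection(spec(hw=0, density=1.0), g, g, 0)
    mask = proj.mask.toarray()
    assert np.array_equal(mask, np.eye(g.n))


def test_interior_fanout_matches_binomial_expectation():
    # 5x5 kernel at density 0.28: expected fan-out 0.28 * 25 = 7 for interior
    # sources; empirical mean within 3 standard errors (brute-force count).
    g = GridSpec(25, 25)
    proj = make_topographic_projection(spec(hw=2, density=0.28), g, g, 42)
    r, c = g.coords()
    interior = (r >= 2) & (r < 23) & (c >= 2) & (c < 23)
    counts = np.asarray(proj.mask.sum(axis=0)).ravel()[interior]
    n, p = 25, 0.28
    se = np.sqrt(n * p * (1 - p) / counts.size)
    assert abs(counts.mean() - n * p) < 3 * se


def test_same_seed_is_bit_identical():
    g = GridSpec(9, 9)
    a = make_topographic_projection(spec(), g, g, 7)
    b = make_topographic_projection(spec(), g, g, 7)
    assert np.array_equal(a.weights.toarray(), b.weights.toarray())
    c = make_topographic_projection(spec(), g, g, 8)
    assert not np.array_equal(a.weights.toarray(), c.weights.toarray())


@pytest.mark.parametrize("hw,toroidal", [(0, False), (1, False), (3, False),
                                         (2, True), (30, False)])
def test_topography_chebyshev_bound(hw, toroidal):
    # every existing synapse must stay within the kernel square (a kernel
    # larger than the grid clips to the whole grid and is still valid)
    g = GridSpec(8, 8)
    proj = make_topographic_projection(spec(hw=hw, density=0.5, toroidal=toroidal),
                                       g, g, 3)
    assert proj.n_synapses > 0
    assert (proj.chebyshev_distances(g, g) <= hw).all()


def test_zero_density_raises():
    with pytest.raises(ValueError, match="empty projection"):
        spec(density=0.0)


def test_no_self_synapse_when_recurrent():
    g = GridSpec(6, 6)
    proj = make_topographic_projection(
        spec(hw=2, density=1.0, allow_self=False, src=0, tgt=0), g, g, 0)
    assert proj.mask.diagonal().sum() == 0


def test_build_network_projection_counts(tiny_cfg):
    state = canet.build_network(tiny_cfg)
    keys = set(state.projections)
    assert len(keys) == 6 + 5 + 5  # recurrent + forward + backward
    assert all((a, a) in keys for a in range(6))
    w_max = tiny_cfg.dynamics.w_max
    for proj in state.projections.values():
        w = proj.weights.data
        assert (w >= 0).all() and (w <= w_max).all()


def test_two_area_chain_is_smallest():
    cfg = canet.scaled_config(0, n_items=2, presentations=1).replace(areas=2)
    state = canet.build_network(cfg)
    assert len(state.projections) == 2 + 1 + 1
    with pytest.raises(ValueError):
        canet.scaled_config(0).replace(areas=1)


def test_masks_immutable_under_training(tiny_cfg):
    state = canet.build_network(tiny_cfg)
    before = state.structure_checksums()
    pats = canet.generate_pattern_set(2, 6, tiny_cfg.grid, seed=0)
    trials = canet.expand_schedule(tiny_cfg.schedule, pats, seed=0)[:10]
    canet.run_trials(state, trials, pats, np.random.default_rng(0))
    assert state.structure_checksums() == before


def test_neighbourhood_matrix_symmetry():
    g = GridSpec(5, 5)
    pool = neighbourhood_matrix(g, 1).toarray()
    assert np.array_equal(pool, pool.T)
    assert pool[12].sum() == 9  # interior cell: full 3x3 neighbourhood
    assert pool[0].sum() == 4   # corner clips
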