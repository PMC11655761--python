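"""Sparse, random, topographic wiring.

Excitatory projections (within-area recurrent and between-area forward /
backward) connect a source cell only to target cells inside a square
Chebyshev neighbourhood centred on its topographically corresponding grid
position; inside the neighbourhood each potential synapse exists
independently with a fixed probability.  The synapse *mask* is drawn once
and is immutable: learning changes weights, never structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .config import GridSpec, NetworkConfig, ProjectionSpec, substream
from .state import NetworkState

__all__ = [
    "Projection",
    "make_topographic_projection",
    "neighbourhood_matrix",
    "build_network",
]


@dataclass
class Projection:
    """One excitatory projection: fixed sparsity structure plus mutable weights.

    ``weights`` is CSR of shape (n_target, n_source); drive into the target
    population is ``weights @ source_outputs``.  ``rows``/``cols`` give, for
    every stored synapse, its postsynaptic and presynaptic cell index — the
    flat views the plasticity rule operates on.
    """

    spec: ProjectionSpec
    weights: sp.csr_matrix
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    @property
    def n_synapses(self) -> int:
        return self.weights.data.size

    @property
    def mask(self) -> sp.csr_matrix:
        m = self.weights.copy()
        m.data = np.ones_like(m.data)
        return m

    def structure_checksum(self) -> int:
        """Hash of the sparsity structure only (mask immutability witness)."""
        return hash((self.weights.shape,
                     self.weights.indptr.tobytes(),
                     self.weights.indices.tobytes()))

    def chebyshev_distances(self, grid_src: GridSpec, grid_tgt: GridSpec) -> np.ndarray:
        """Grid distance between the end points of every stored synapse."""
        rs, cs = grid_src.coords()
        rt, ct = grid_tgt.coords()
        src_r, src_c = _map_coords(rs, cs, grid_src, grid_tgt)
        dr = np.abs(rt[self.rows] - src_r[self.cols])
        dc = np.abs(ct[self.rows] - src_c[self.cols])
        if self.spec.toroidal:
            dr = np.minimum(dr, grid_tgt.rows - dr)
            dc = np.minimum(dc, grid_tgt.cols - dc)
        return np.maximum(dr, dc)


def _map_coords(r: np.ndarray, c: np.ndarray, grid_src: GridSpec,
                grid_tgt: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Topographic correspondence between two grids (identity when the grids
    share a shape, proportional rescaling otherwise)."""
    if (grid_src.rows, grid_src.cols) == (grid_tgt.rows, grid_tgt.cols):
        return r, c
    def scale(x, n_src, n_tgt):
        if n_src == 1:
            return np.full_like(x, (n_tgt - 1) // 2)
        return np.rint(x * (n_tgt - 1) / (n_src - 1)).astype(int)
    return scale(r, grid_src.rows, grid_tgt.rows), scale(c, grid_src.cols, grid_tgt.cols)


def make_topographic_projection(spec: ProjectionSpec, grid_src: GridSpec,
                                grid_tgt: GridSpec,
                                rng: np.random.Generator | int) -> Projection:
    """Draw the synapse mask and initial weights of one projection.

    A synapse s -> t may exist only if t lies within the
    (2*kernel_halfwidth + 1)^2 square centred on s's corresponding position
    in the target grid (clipped at the edges, or wrapped if ``toroidal``).
    Each potential synapse exists independently with probability
    ``spec.density`` and receives a uniform initial weight in
    [w_init_low, w_init_high].
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    k = spec.kernel_halfwidth
    rs, cs = grid_src.coords()
    src_r, src_c = _map_coords(rs, cs, grid_src, grid_tgt)

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    offs = np.arange(-k, k + 1)
    dR, dC = np.meshgrid(offs, offs, indexing="ij")
    dR, dC = dR.ravel(), dC.ravel()
    for s in range(grid_src.n):
        tr = src_r[s] + dR
        tc = src_c[s] + dC
        if spec.toroidal:
            tr = tr % grid_tgt.rows
            tc = tc % grid_tgt.cols
            keep = np.ones(tr.size, dtype=bool)
        else:
            keep = (tr >= 0) & (tr < grid_tgt.rows) & (tc >= 0) & (tc < grid_tgt.cols)
        tgt = np.unique(tr[keep] * grid_tgt.cols + tc[keep])
        if not spec.allow_self and spec.source_area == spec.target_area:
            tgt = tgt[tgt != s]
        exists = rng.random(tgt.size) < spec.density
        tgt = tgt[exists]
        rows_out.append(tgt)
        cols_out.append(np.full(tgt.size, s, dtype=np.int64))

    rows = np.concatenate(rows_out)
    cols = np.concatenate(cols_out)
    w = rng.uniform(spec.w_init_low, spec.w_init_high, size=rows.size)
    mat = sp.csr_matrix((w, (rows, cols)), shape=(grid_tgt.n, grid_src.n))
    mat.sort_indices()
    # recover per-synapse row/col in the CSR storage order
    csr_rows = np.repeat(np.arange(grid_tgt.n), np.diff(mat.indptr))
    return Projection(spec=spec, weights=mat, rows=csr_rows,
                      cols=mat.indices.copy())


def neighbourhood_matrix(grid: GridSpec, halfwidth: int,
                         toroidal: bool = False) -> sp.csr_matrix:
    """Binary pooling matrix P with P[i, j] = 1 iff Chebyshev(i, j) <= halfwidth.

    Used for the fixed excitatory -> inhibitory wiring: inhibitory cell i
    integrates the summed output of the excitatory cells in its neighbourhood.
    """
    r, c = grid.coords()
    offs = np.arange(-halfwidth, halfwidth + 1)
    dR, dC = np.meshgrid(offs, offs, indexing="ij")
    dR, dC = dR.ravel(), dC.ravel()
    rows, cols = [], []
    for i in range(grid.n):
        tr, tc = r[i] + dR, c[i] + dC
        if toroidal:
            tr, tc = tr % grid.rows, tc % grid.cols
            keep = np.ones(tr.size, bool)
        else:
            keep = (tr >= 0) & (tr < grid.rows) & (tc >= 0) & (tc < grid.cols)
        j = np.unique(tr[keep] * grid.cols + tc[keep])
        rows.append(np.full(j.size, i, dtype=np.int64))
        cols.append(j)
    data = np.ones(sum(x.size for x in rows))
    return sp.csr_matrix((data, (np.concatenate(rows), np.concatenate(cols))),
                         shape=(grid.n, grid.n))


def build_network(config: NetworkConfig) -> NetworkState:
    """Assemble the full multi-area network in its blank (untrained) state.

    For a chain of N areas: one recurrent projection per area, plus forward
    and backward projections between each adjacent pair (reciprocal
    next-neighbour wiring), plus the fixed local inhibitory pooling.  All
    dynamic state arrays start at zero.
    """
    n_areas = config.areas
    grid = config.grid
    rng = substream(config.master_seed, "connectivity")
    projections: dict[tuple[int, int], Projection] = {}

    def spec_for(defaults, src, tgt, allow_self=True):
        return ProjectionSpec(
            source_area=src, target_area=tgt,
            kernel_halfwidth=defaults.kernel_halfwidth,
            density=defaults.density,
            w_init_low=defaults.w_init_low, w_init_high=defaults.w_init_high,
            allow_self=allow_self, toroidal=defaults.toroidal,
        )

    for a in range(n_areas):
        projections[(a, a)] = make_topographic_projection(
            spec_for(config.recurrent, a, a, allow_self=False), grid, grid, rng)
    for a in range(n_areas - 1):
        projections[(a, a + 1)] = make_topographic_projection(
            spec_for(config.forward, a, a + 1), grid, grid, rng)
        projections[(a + 1, a)] = make_topographic_projection(
            spec_for(config.backward, a + 1, a), grid, grid, rng)
    if config.jumping_links:
        for a in range(n_areas - 2):
            projections[(a, a + 2)] = make_topographic_projection(
                spec_for(config.forward, a, a + 2), grid, grid, rng)
            projections[(a + 2, a)] = make_topographic_projection(
                spec_for(config.backward, a + 2, a), grid, grid, rng)

    pool = neighbourhood_matrix(grid, config.dynamics.inhib_kernel_halfwidth,
                                toroidal=config.recurrent.toroidal)
    return NetworkState.blank(config, projections, pool)
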