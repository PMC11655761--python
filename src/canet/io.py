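"""Serialization: HDF5 run container plus CSV/JSON exports.

One container file holds everything needed to reproduce an analysis from a
trained network: the full config echo (YAML), every projection's sparsity
structure and weights, the dynamic state, the stimulus set and the training
record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import scipy.sparse as sp

from .config import NetworkConfig, ProjectionSpec
from .connectivity import Projection, neighbourhood_matrix
from .patterns import PatternPair
from .state import NetworkState, TrainingRecord
from .assembly import OverlapReport

__all__ = ["save_network", "load_network", "save_overlap_report", "save_trace"]

PathLike = Union[str, Path]


def save_network(state: NetworkState, path: PathLike) -> None:
    """Write a trained (or blank) network to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "canet-network"
        f.attrs["config_yaml"] = state.config.to_yaml()
        f.attrs["t"] = state.t
        g = f.create_group("state")
        for name in ("V", "O", "V_inh", "O_inh", "adapt", "global_inhib"):
            g.create_dataset(name, data=getattr(state, name))
        pg = f.create_group("projections")
        for (src, tgt), proj in state.projections.items():
            sub = pg.create_group(f"{src}->{tgt}")
            w = proj.weights
            sub.create_dataset("data", data=w.data)
            sub.create_dataset("indices", data=w.indices)
            sub.create_dataset("indptr", data=w.indptr)
            sub.attrs["shape"] = w.shape
            sub.attrs["spec"] = json.dumps(proj.spec.__dict__)
        if state.patterns is not None:
            sg = f.create_group("patterns")
            sg.create_dataset("first", data=np.stack([p.first for p in state.patterns]))
            sg.create_dataset("last", data=np.stack([p.last for p in state.patterns]))
            sg.create_dataset("item_ids",
                              data=np.array([p.item_id for p in state.patterns]))
        tg = f.create_group("training")
        items = sorted(state.training.presentations)
        tg.create_dataset("item_ids", data=np.array(items, dtype=np.int64))
        tg.create_dataset("counts", data=np.array(
            [state.training.presentations[i] for i in items], dtype=np.int64))
        co = sorted(tuple(sorted(p)) for p in state.training.co_presented)
        tg.create_dataset("co_presented",
                          data=np.array(co, dtype=np.int64).reshape(-1, 2))


def load_network(path: PathLike) -> NetworkState:
    """Reconstruct a :class:`NetworkState` from a container file."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "canet-network":
            raise ValueError(f"{path} is not a canet network container")
        config = NetworkConfig.from_yaml(f.attrs["config_yaml"])
        projections: dict[tuple[int, int], Projection] = {}
        for name, sub in f["projections"].items():
            src, tgt = (int(x) for x in name.split("->"))
            w = sp.csr_matrix(
                (sub["data"][:], sub["indices"][:], sub["indptr"][:]),
                shape=tuple(sub.attrs["shape"]))
            rows = np.repeat(np.arange(w.shape[0]), np.diff(w.indptr))
            spec = ProjectionSpec(**json.loads(sub.attrs["spec"]))
            projections[(src, tgt)] = Projection(
                spec=spec, weights=w, rows=rows, cols=w.indices.copy())
        pool = neighbourhood_matrix(config.grid,
                                    config.dynamics.inhib_kernel_halfwidth,
                                    toroidal=config.recurrent.toroidal)
        state = NetworkState.blank(config, projections, pool)
        g = f["state"]
        for name in ("V", "O", "V_inh", "O_inh", "adapt", "global_inhib"):
            getattr(state, name)[:] = g[name][:]
        state.t = int(f.attrs["t"])
        if "patterns" in f:
            sg = f["patterns"]
            state.patterns = [
                PatternPair(item_id=int(i), first=first.astype(bool),
                            last=last.astype(bool))
                for i, first, last in zip(sg["item_ids"][:], sg["first"][:],
                                          sg["last"][:])
            ]
        tg = f["training"]
        rec = TrainingRecord()
        for i, c in zip(tg["item_ids"][:], tg["counts"][:]):
            rec.presentations[int(i)] = int(c)
        for i, j in tg["co_presented"][:]:
            rec.co_presented.add(frozenset((int(i), int(j))))
        state.training = rec
    return state


def save_overlap_report(report: OverlapReport, csv_path: PathLike,
                        matrices_path: PathLike | None = None) -> None:
    """Export (gamma, mean_pct, max_pct) as CSV, optionally with the
    per-gamma pairwise matrices as an .npz."""
    report.to_frame().to_csv(csv_path, index=False)
    if matrices_path is not None:
        np.savez(matrices_path,
                 item_ids=np.array(report.item_ids),
                 **{f"gamma_{g:.2f}": m for g, m in report.pair_matrices.items()})


def save_trace(trace, path: PathLike, config: NetworkConfig | None = None) -> None:
    """Persist an experiment trace (outputs + phase table + config echo)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "canet-trace"
        f.create_dataset("outputs", data=trace.outputs, compression="gzip")
        pg = f.create_group("phases")
        for name, (a, b) in trace.phases.items():
            pg.attrs[name] = (a, b)
        f.attrs["stride"] = trace.stride
        if config is not None:
            f.attrs["config_yaml"] = config.to_yaml()
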