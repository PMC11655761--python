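"""ABS-style local synaptic plasticity.

Weight changes depend only on the presynaptic output, the postsynaptic
membrane potential and the synapse's current weight — nothing else.  The
rule distinguishes three regimes via one presynaptic and two postsynaptic
thresholds (theta_minus < theta_plus):

* LTP:  pre active and post strongly depolarized (>= theta_plus) -> +delta_w,
  up to saturation at w_max.
* homosynaptic LTD: pre active, post in the intermediate depolarization
  window [theta_minus, theta_plus) -> -delta_w.
* heterosynaptic LTD (optional, on by default): pre truly silent (output
  below ``theta_silent`` < theta_pre) while post is strongly depolarized ->
  -hetero_scale * ltd_scale * delta_w.  Presynaptic cells in the
  intermediate zone [theta_silent, theta_pre) trigger no change.  This is the
  pathway that cuts an emerging assembly off from cells driven by other
  items, whose activity is anti-correlated with its own under single-item
  training; its rate can exceed the homosynaptic one, which lets it win the
  tug-of-war over cells contested by two emerging assemblies.

Updates are fixed-size steps (LTD scaled by ``ltd_scale`` <= 1, reflecting
the smaller amplitude of depression relative to potentiation) with hard
clipping to [0, w_max]; there is no weight normalisation or homeostatic
scaling.
"""

from __future__ import annotations

import numpy as np

from .config import PlasticityParams
from .connectivity import Projection

__all__ = ["apply"]


def apply(projection: Projection, pre_outputs: np.ndarray,
          post_potentials: np.ndarray, params: PlasticityParams) -> Projection:
    """Apply one plasticity step to every existing synapse of a projection.

    Operates in place on the projection's weight data (the sparsity mask is
    never altered: a weight driven to zero remains a stored, silent synapse
    that may later re-potentiate).
    """
    if pre_outputs.shape[0] != projection.weights.shape[1]:
        raise ValueError("pre_outputs length does not match projection source size")
    if post_potentials.shape[0] != projection.weights.shape[0]:
        raise ValueError("post_potentials length does not match projection target size")

    pre = pre_outputs[projection.cols]
    post = post_potentials[projection.rows]
    pre_on = pre >= params.theta_pre
    post_high = post >= params.theta_plus

    ltp = pre_on & post_high
    homo = pre_on & ~post_high & (post >= params.theta_minus)

    w = projection.weights.data
    w += params.delta_w * ltp
    w -= params.ltd_scale * params.delta_w * homo
    if params.heterosynaptic_ltd:
        hetero = (pre < params.theta_silent) & post_high
        w -= params.hetero_scale * params.ltd_scale * params.delta_w * hetero
    np.clip(w, 0.0, params.w_max, out=w)
    return projection
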