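"""ON/OFF Filling-in Layers and the final brightness map.

Each Filling-in Layer runs the recurrent MAX circuit on the 4-neighbour
lattice: feature activity spreads isotropically until it is blocked by the
binary boundary gate, and a relay threshold keeps weak-input nodes (black
surfaces in the ON layer, white in the OFF layer) from starting or carrying
the spread.  At steady state every supported node holds the maximum feature
value of its boundary-and-support-connected component.  The brightness
percept is the min-max normalised difference of the ON and OFF steady
states.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .bcs import (
    BcsConfig,
    BoundaryMask,
    OrientedActivity,
    global_boundaries,
    lg_interaction,
    local_boundaries,
)
from .fcs_pathways import (
    FeatureField,
    PathwayConfig,
    contrast_pathway,
    feature_input,
    luminance_pathway,
)
from .maxcircuit import MaxNetwork, relax_fixed_point

__all__ = [
    "FillConfig",
    "ModelConfig",
    "BrightnessMap",
    "ModelOutputs",
    "fill_layer",
    "combine",
    "run_model",
]


@dataclass
class FillConfig:
    """Relay threshold (as a fraction of the layer's peak feature input)
    and convergence controls of a Filling-in Layer."""

    fill_threshold_frac: float = 0.2
    tol: float = 1e-12
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.fill_threshold_frac < 1:
            raise ValueError("fill_threshold_frac must lie in (0, 1)")


@dataclass
class ModelConfig:
    """Full model configuration: front end, boundary system, filling-in."""

    pathway: PathwayConfig = field(default_factory=PathwayConfig)
    bcs: BcsConfig = field(default_factory=BcsConfig)
    fill: FillConfig = field(default_factory=FillConfig)


@dataclass
class BrightnessMap:
    """Normalised brightness percept plus the ON/OFF steady states."""

    values: np.ndarray
    on_fill: np.ndarray
    off_fill: np.ndarray


@dataclass
class ModelOutputs:
    """Every intermediate map of a full model run."""

    image: np.ndarray
    contrast: FeatureField
    luminance: FeatureField
    feature: FeatureField
    lbd: OrientedActivity
    gbd: OrientedActivity
    mask: BoundaryMask
    on_fill: np.ndarray
    off_fill: np.ndarray
    brightness: BrightnessMap
    iterations: dict
    timings: dict


def _lattice_pairs(shape: tuple[int, int], mask: BoundaryMask) -> np.ndarray:
    """4-neighbour lattice pairs minus the edges cut by the boundary gate.

    A vertical-neighbour link is cut where the H gate is set at either
    endpoint; a horizontal-neighbour link where the V gate is set at either
    endpoint, so one-pixel contours cannot leak.
    """
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    vert_ok = ~(mask.h[:-1, :] | mask.h[1:, :])
    horiz_ok = ~(mask.v[:, :-1] | mask.v[:, 1:])
    pairs = []
    if vert_ok.any():
        pairs.append(np.column_stack([idx[:-1, :][vert_ok], idx[1:, :][vert_ok]]))
    if horiz_ok.any():
        pairs.append(np.column_stack([idx[:, :-1][horiz_ok], idx[:, 1:][horiz_ok]]))
    if not pairs:
        return np.empty((0, 2), dtype=np.intp)
    return np.vstack(pairs)


def fill_layer(
    feature: np.ndarray,
    mask: BoundaryMask,
    cfg: FillConfig | None = None,
    return_state: bool = False,
):
    """Boundary-gated isotropic recurrent MAX spreading of a feature map.

    Supported nodes (feature at or above the relay threshold) converge to the
    maximum feature value of their connected component; below-threshold nodes
    neither initiate nor relay spreading and simply keep their own input.
    """
    cfg = cfg or FillConfig()
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim != 2 or feature.shape != mask.h.shape:
        raise ValueError("feature map and boundary mask shapes must match")
    if np.any(feature < 0):
        raise ValueError("feature input must be nonnegative")
    peak = feature.max()
    support = feature >= cfg.fill_threshold_frac * peak if peak > 0 else np.zeros(
        feature.shape, dtype=bool
    )
    net = MaxNetwork.from_pairs(
        feature.ravel(),
        _lattice_pairs(feature.shape, mask),
        support=support.ravel(),
    )
    state = relax_fixed_point(net, tol=cfg.tol, max_iter=cfg.max_iter)
    filled = state.activity.reshape(feature.shape)
    if return_state:
        return filled, state
    return filled


def combine(on_fill: np.ndarray, off_fill: np.ndarray) -> BrightnessMap:
    """Min-max normalised ON minus OFF steady state; a constant difference
    normalises to 0.5 everywhere."""
    on_fill = np.asarray(on_fill, dtype=np.float64)
    off_fill = np.asarray(off_fill, dtype=np.float64)
    if on_fill.shape != off_fill.shape:
        raise ValueError("ON and OFF fill maps must share a shape")
    diff = on_fill - off_fill
    lo, hi = diff.min(), diff.max()
    if hi - lo < 1e-12:
        values = np.full_like(diff, 0.5)
    else:
        values = (diff - lo) / (hi - lo)
    return BrightnessMap(values=values, on_fill=on_fill, off_fill=off_fill)


def run_model(image: np.ndarray, config: ModelConfig | None = None) -> ModelOutputs:
    """Run the whole architecture on a luminance image.

    Stages: ON/OFF contrast and luminance pathways -> feature input;
    local -> global boundary detection -> L/G gate; ON and OFF filling-in
    against the same gate; ON-OFF combination and normalisation.
    Deterministic; per-stage timings and fill iteration counts are returned.
    """
    config = config or ModelConfig()
    image = np.asarray(image, dtype=np.float64)
    timings: dict = {}
    iterations: dict = {}

    t0 = time.perf_counter()
    contrast = contrast_pathway(image, config.pathway)
    luminance = luminance_pathway(image, config.pathway)
    feature = feature_input(contrast, luminance, config.pathway)
    timings["fcs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lbd = local_boundaries(contrast, config.bcs)
    gbd = global_boundaries(lbd, config.bcs)
    mask = lg_interaction(lbd, gbd, config.bcs)
    timings["bcs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    on_fill, on_state = fill_layer(feature.on, mask, config.fill, return_state=True)
    off_fill, off_state = fill_layer(feature.off, mask, config.fill, return_state=True)
    timings["fill"] = time.perf_counter() - t0
    iterations["on_fill"] = on_state.iterations
    iterations["off_fill"] = off_state.iterations
    if not (on_state.converged and off_state.converged):
        raise RuntimeError("filling-in failed to converge")

    brightness = combine(on_fill, off_fill)
    return ModelOutputs(
        image=image,
        contrast=contrast,
        luminance=luminance,
        feature=feature,
        lbd=lbd,
        gbd=gbd,
        mask=mask,
        on_fill=on_fill,
        off_fill=off_fill,
        brightness=brightness,
        iterations=iterations,
        timings=timings,
    )
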