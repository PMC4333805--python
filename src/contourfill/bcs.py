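"""Boundary Contour System: local detection, global facilitation, L/G gate.

Local Boundary Detection (LBD) builds polarity-invariant oriented contour
responses from the ON/OFF Contrast Pathways (simple-node lobes summed into
complex nodes, then a feedforward 3x3 MAX for uniform corners).  Global
Boundary Detection (GBD) runs the recurrent MAX circuit along each contour
orientation, with a longer reach in the collinear than in the parallel
direction, so strong contours raise aligned weak ones to their own level.
The L/G Interaction thresholds the local-to-global ratio into a binary
boundary gate: facilitated (low-ratio) contours are erased, unfacilitated
ones are kept.

Only the two rectilinear orientations {H, V} are represented; every stimulus
in the battery is rectilinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter, uniform_filter1d

from .fcs_pathways import FeatureField, PathwayConfig, contrast_pathway
from .maxcircuit import MaxNetwork, relax_fixed_point

__all__ = [
    "BcsConfig",
    "OrientedActivity",
    "BoundaryMask",
    "local_boundaries",
    "global_boundaries",
    "lg_interaction",
    "calibrate_lg_threshold",
]


@dataclass
class BcsConfig:
    lobe_offset: int = 1
    lobe_length: int = 3
    collinear_reach: int = 15
    parallel_reach: int = 5
    support_eps: float = 0.2
    lg_threshold: float = 0.75
    lg_eps: float = 0.02

    def __post_init__(self) -> None:
        if self.lobe_offset < 1 or self.lobe_length < 1:
            raise ValueError("lobe geometry must be at least one pixel")
        if not self.collinear_reach >= self.parallel_reach >= 1:
            raise ValueError("collinear reach must be at least parallel reach (>= 1)")
        if not 0 < self.lg_threshold <= 1:
            raise ValueError("lg_threshold must lie in (0, 1]")
        if self.support_eps <= 0 or self.lg_eps <= 0:
            raise ValueError("support_eps and lg_eps must be positive")


@dataclass
class OrientedActivity:
    """Per-orientation activity: ``h`` for horizontal contours (vertical
    luminance gradient), ``v`` for vertical contours."""

    h: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.h.shape != self.v.shape:
            raise ValueError("orientation maps must share a shape")

    @property
    def peak(self) -> float:
        return float(max(self.h.max(initial=0.0), self.v.max(initial=0.0)))


@dataclass
class BoundaryMask:
    """Binary per-orientation gate; 1 blocks filling-in, 0 lets it pass."""

    h: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=bool)
        self.v = np.asarray(self.v, dtype=bool)
        if self.h.shape != self.v.shape:
            raise ValueError("orientation masks must share a shape")


def _sample(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """a[y + dy, x + dx] with replicate clamping at the frame."""
    h, w = a.shape
    ys = np.clip(np.arange(h) + dy, 0, h - 1)
    xs = np.clip(np.arange(w) + dx, 0, w - 1)
    return a[np.ix_(ys, xs)]


def local_boundaries(contrast: FeatureField, cfg: BcsConfig | None = None) -> OrientedActivity:
    """Simple -> complex oriented contour responses plus the 3x3 MAX.

    A simple node's excitatory lobe is driven by ON minus OFF contrast on one
    side of the contour and its inhibitory lobe by OFF minus ON on the other;
    the two polarities at each site are rectified and summed into the complex
    response, which therefore grows with edge contrast regardless of polarity.
    """
    cfg = cfg or BcsConfig()
    d = contrast.on - contrast.off

    # vertical contours: lobes offset along x, elongated along y
    elong_v = uniform_filter1d(d, size=cfg.lobe_length, axis=0, mode="nearest")
    a = _sample(elong_v, 0, cfg.lobe_offset)
    b = _sample(elong_v, 0, -cfg.lobe_offset)
    complex_v = np.maximum(a - b, 0.0) + np.maximum(b - a, 0.0)

    # horizontal contours: lobes offset along y, elongated along x
    elong_h = uniform_filter1d(d, size=cfg.lobe_length, axis=1, mode="nearest")
    a = _sample(elong_h, cfg.lobe_offset, 0)
    b = _sample(elong_h, -cfg.lobe_offset, 0)
    complex_h = np.maximum(a - b, 0.0) + np.maximum(b - a, 0.0)

    return OrientedActivity(
        h=maximum_filter(complex_h, size=3, mode="nearest"),
        v=maximum_filter(complex_v, size=3, mode="nearest"),
    )


def _facilitation_pairs(
    sup: np.ndarray, reach_y: int, reach_x: int
) -> np.ndarray:
    """Undirected pairs linking supported sites along the two lattice axes.

    Links run between same-column sites up to ``reach_y`` apart and
    same-row sites up to ``reach_x`` apart.
    """
    h, w = sup.shape
    idx = np.arange(h * w).reshape(h, w)
    pairs = []
    for dy in range(1, reach_y + 1):
        keep = sup[:-dy, :] & sup[dy:, :]
        if keep.any():
            pairs.append(
                np.column_stack([idx[:-dy, :][keep], idx[dy:, :][keep]])
            )
    for dx in range(1, reach_x + 1):
        keep = sup[:, :-dx] & sup[:, dx:]
        if keep.any():
            pairs.append(
                np.column_stack([idx[:, :-dx][keep], idx[:, dx:][keep]])
            )
    if not pairs:
        return np.empty((0, 2), dtype=np.intp)
    return np.vstack(pairs)


def global_boundaries(lbd: OrientedActivity, cfg: BcsConfig | None = None) -> OrientedActivity:
    """Collinear/parallel recurrent MAX facilitation of the local signals.

    Support is restricted to sites carrying appreciable local contour signal,
    so no global signal ever appears on empty space between contours; off the
    support the output equals the input.
    """
    cfg = cfg or BcsConfig()
    scale = lbd.peak
    if scale <= 0:
        return OrientedActivity(h=lbd.h.copy(), v=lbd.v.copy())

    out = {}
    for name, fmap in (("h", lbd.h), ("v", lbd.v)):
        sup = fmap > cfg.support_eps * scale
        if name == "v":  # contour runs along y: collinear = y, parallel = x
            pairs = _facilitation_pairs(sup, cfg.collinear_reach, cfg.parallel_reach)
        else:  # contour runs along x: collinear = x, parallel = y
            pairs = _facilitation_pairs(sup, cfg.parallel_reach, cfg.collinear_reach)
        net = MaxNetwork.from_pairs(fmap.ravel(), pairs, support=sup.ravel())
        state = relax_fixed_point(net, tol=1e-12)
        out[name] = state.activity.reshape(fmap.shape)
    return OrientedActivity(h=out["h"], v=out["v"])


def lg_interaction(
    lbd: OrientedActivity, gbd: OrientedActivity, cfg: BcsConfig | None = None
) -> BoundaryMask:
    """Binary gate from the local/global ratio.

    A site emits a boundary iff its local signal clears an absolute floor and
    the local-to-global ratio reaches ``lg_threshold``.  Where the global
    signal towers over the local one (facilitated low-contrast contours) the
    ratio collapses and the boundary is erased.
    """
    cfg = cfg or BcsConfig()
    if lbd.h.shape != gbd.h.shape:
        raise ValueError("LBD and GBD shapes must match")
    # a boundary is only ever emitted on the contour support: off-support
    # skirt tails have ratio 1 by construction and must not gate filling
    floor = max(cfg.lg_eps, cfg.support_eps) * lbd.peak
    masks = {}
    for name in ("h", "v"):
        lo = getattr(lbd, name)
        gl = getattr(gbd, name)
        # gbd >= lbd by construction, so gbd == 0 implies lbd == 0 -> gate 0
        masks[name] = (lo > floor) & (lo >= cfg.lg_threshold * gl)
    return BoundaryMask(h=masks["h"], v=masks["v"])


def calibrate_lg_threshold(
    pathway_cfg: PathwayConfig | None = None,
    bcs_cfg: BcsConfig | None = None,
    size: int = 64,
) -> float:
    """Facilitated-edge ratio on a calibration step-edge pair.

    Builds a vertical edge whose upper segment is full contrast (black|white)
    and lower segment half contrast (black|gray), runs the BCS, and returns
    the smallest L/G ratio on the facilitated weak segment.  Raises if the
    configured ``lg_threshold`` does not sit strictly between that ratio and
    one, which is the condition for erasing facilitated edges while keeping
    unfacilitated ones.
    """
    pathway_cfg = pathway_cfg or PathwayConfig()
    bcs_cfg = bcs_cfg or BcsConfig()
    img = np.zeros((size, size))
    mid = size // 2
    img[:mid, mid:] = 1.0
    img[mid:, mid:] = 0.5
    lbd = local_boundaries(contrast_pathway(img, pathway_cfg), bcs_cfg)
    gbd = global_boundaries(lbd, bcs_cfg)
    # sample the weak segment away from the junction and the frame
    rows = slice(mid + size // 8, size - size // 8)
    cols = slice(mid - 1, mid + 2)
    lo = lbd.v[rows, cols]
    gl = gbd.v[rows, cols]
    sel = lo > bcs_cfg.lg_eps * lbd.peak
    if not sel.any():
        raise RuntimeError("calibration edge produced no boundary signal")
    ratio = float(np.min(lo[sel] / gl[sel]))
    if not ratio < bcs_cfg.lg_threshold <= 1.0:
        raise ValueError(
            f"lg_threshold={bcs_cfg.lg_threshold} must exceed the facilitated "
            f"edge ratio {ratio:.3f} and not exceed 1"
        )
    return ratio
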