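"""Feature Contour System front end: ON/OFF Contrast and Luminance Pathways.

The Contrast Pathways compute luminance ratios across borders with balanced
centre-surround receptive fields and divisive (shunting) inhibition; they are
silent on uniform regions.  The Luminance Pathways use centre-dominated
receptive fields and behave as approximate luminance detectors, responding on
uniform regions as well.  The OFF member of each pair is, by construction,
the ON operator applied to the inverted image, which makes the ON/OFF duality
of the front end exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PathwayConfig",
    "FeatureField",
    "contrast_pathway",
    "luminance_pathway",
    "feature_input",
]


@dataclass
class PathwayConfig:
    """Kernel scales and mixing weights of the FCS front end.

    ``sigma_center``/``sigma_surround`` are Gaussian widths in pixels with
    each lobe normalised to unit mass; ``shunt_floor`` is the decay constant
    of the divisive normalisation; ``luminance_surround_weight`` is the factor
    by which the Luminance Pathway's surround underweights its centre;
    ``w_contrast``/``w_luminance`` mix the two pathways into the feature
    signal delivered to the Filling-in Layers.
    """

    sigma_center: float = 1.0
    sigma_surround: float = 3.0
    shunt_floor: float = 2.0
    luminance_surround_weight: float = 0.3
    w_contrast: float = 2.0
    w_luminance: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_center < self.sigma_surround:
            raise ValueError("sigma_center must be smaller than sigma_surround")
        if self.shunt_floor <= 0:
            raise ValueError("shunt_floor must be positive")
        if not 0 <= self.luminance_surround_weight < 1:
            raise ValueError("luminance_surround_weight must lie in [0, 1)")
        if self.w_contrast < 0 or self.w_luminance < 0:
            raise ValueError("mixing weights must be nonnegative")
        if self.w_contrast == 0 and self.w_luminance == 0:
            raise ValueError("at least one mixing weight must be positive")


@dataclass
class FeatureField:
    """Paired nonnegative ON and OFF activity maps on the image lattice."""

    on: np.ndarray
    off: np.ndarray

    def __post_init__(self) -> None:
        self.on = np.asarray(self.on, dtype=np.float64)
        self.off = np.asarray(self.off, dtype=np.float64)
        if self.on.shape != self.off.shape:
            raise ValueError("ON and OFF maps must share a shape")


def _validate_image(image: np.ndarray) -> np.ndarray:
    grid = np.asarray(image, dtype=np.float64)
    if grid.ndim != 2:
        raise ValueError("luminance image must be 2-D")
    if grid.min() < -1e-12 or grid.max() > 1 + 1e-12:
        raise ValueError("luminance values must lie in [0, 1]")
    return grid


def _center_surround(grid: np.ndarray, cfg: PathwayConfig) -> tuple[np.ndarray, np.ndarray]:
    # replicate padding: no spurious responses at the frame
    c = gaussian_filter(grid, cfg.sigma_center, mode="nearest")
    s = gaussian_filter(grid, cfg.sigma_surround, mode="nearest")
    return c, s


def _shunting_on(grid: np.ndarray, cfg: PathwayConfig) -> np.ndarray:
    c, s = _center_surround(grid, cfg)
    return np.maximum(c - s, 0.0) / (cfg.shunt_floor + c + s)


def _luminance_on(grid: np.ndarray, cfg: PathwayConfig) -> np.ndarray:
    c, s = _center_surround(grid, cfg)
    return np.maximum(c - cfg.luminance_surround_weight * s, 0.0)


def contrast_pathway(image: np.ndarray, cfg: PathwayConfig | None = None) -> FeatureField:
    """Balanced centre-surround shunting responses at luminance borders.

    The ON map is strong on the bright side of an edge and vanishes on
    uniform regions; the OFF map is the polarity-reversed twin (the same
    operator applied to ``1 - I``), strong on the dark side.
    """
    cfg = cfg or PathwayConfig()
    grid = _validate_image(image)
    return FeatureField(
        on=_shunting_on(grid, cfg),
        off=_shunting_on(1.0 - grid, cfg),
    )


def luminance_pathway(image: np.ndarray, cfg: PathwayConfig | None = None) -> FeatureField:
    """Centre-dominated responses tracking luminance and its inverse."""
    cfg = cfg or PathwayConfig()
    grid = _validate_image(image)
    return FeatureField(
        on=_luminance_on(grid, cfg),
        off=_luminance_on(1.0 - grid, cfg),
    )


def feature_input(
    contrast: FeatureField,
    luminance: FeatureField,
    cfg: PathwayConfig | None = None,
) -> FeatureField:
    """Weighted sum of Contrast and Luminance Pathway activity, per location."""
    cfg = cfg or PathwayConfig()
    if contrast.on.shape != luminance.on.shape:
        raise ValueError("contrast and luminance fields must share a shape")
    return FeatureField(
        on=cfg.w_contrast * contrast.on + cfg.w_luminance * luminance.on,
        off=cfg.w_contrast * contrast.off + cfg.w_luminance * luminance.off,
    )
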