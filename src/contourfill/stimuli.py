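"""Parametric generation of the brightness-illusion battery.

Every stimulus is generated deterministically from its parameters on a
pixel-aligned grid with no anti-aliasing: the unique values of a generated
grid are exactly its declared palette.  Each case bundles the luminance
image with named binary target masks (interiors of the gray targets, a
one-pixel rim inside the border excluded) and the predicted brightness
relation between them.

Geometry is expressed in units of ``size // 64`` so the same construction
scales to any grid size that is a multiple of 64 (default 128).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

__all__ = [
    "LuminanceImage",
    "IllusionCase",
    "generate_stimulus",
    "list_stimuli",
    "STIMULUS_NAMES",
    "A_BRIGHTER",
    "A_EQUALS",
    "A_LOWER_CONTRAST",
]

BLACK, GRAY, WHITE = 0.0, 0.5, 1.0

A_BRIGHTER = "A_brighter_than_B"
A_EQUALS = "A_equals_B"
A_LOWER_CONTRAST = "A_lower_contrast_than_B"

MEAN_DIFFERENCE = "mean_difference"
RMS_CONTRAST_DIFFERENCE = "rms_contrast_difference"


@dataclass
class LuminanceImage:
    """A 2-D achromatic luminance grid with values in [0, 1]."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("luminance grid must be 2-D")
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("luminance values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


@dataclass
class IllusionCase:
    """A stimulus, its labelled target masks and the predicted relation."""

    name: str
    image: LuminanceImage
    target_masks: dict[str, np.ndarray]
    relation: str
    statistic: str
    params: dict = field(default_factory=dict)
    profile_row: int = 0
    palette: tuple[float, ...] = (BLACK, GRAY, WHITE)


def _erode(mask: np.ndarray) -> np.ndarray:
    return binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def _rect_mask(shape, y0, y1, x0, x1) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    return m


def _finalize(
    name: str,
    grid: np.ndarray,
    raw_masks: dict[str, np.ndarray],
    relation: str,
    statistic: str,
    params: dict,
    profile_row: int,
    palette: tuple[float, ...],
    target_levels: dict[str, float] | None = None,
) -> IllusionCase:
    uniq = np.unique(grid)
    if not np.all(np.isin(uniq, np.asarray(palette))):
        raise AssertionError(f"{name}: grid values escape the palette")
    masks = {}
    taken = np.zeros(grid.shape, dtype=bool)
    for key, raw in raw_masks.items():
        m = _erode(raw)
        if not m.any():
            raise ValueError(f"{name}: target {key} is degenerate (empty after rim removal)")
        if (m & taken).any():
            raise ValueError(f"{name}: target masks overlap")
        taken |= m
        if target_levels is not None:
            level = target_levels[key]
            if not np.all(grid[m] == level):
                raise AssertionError(f"{name}: mask {key} covers non-target pixels")
        masks[key] = m
    return IllusionCase(
        name=name,
        image=LuminanceImage(grid),
        target_masks=masks,
        relation=relation,
        statistic=statistic,
        params=params,
        profile_row=profile_row,
        palette=palette,
    )


# ---------------------------------------------------------------------------
# builders -- all coordinates in units of u = size // 64


def _sbc(size: int, u: int, params: dict) -> IllusionCase:
    half = params.get("target_half_size", 5) * u  # half side in px
    g = np.full((size, size), BLACK)
    g[:, size // 2 :] = WHITE
    cy = size // 2
    rects = {
        "A": (cy - half, cy + half, size // 4 - half, size // 4 + half),
        "B": (cy - half, cy + half, 3 * size // 4 - half, 3 * size // 4 + half),
    }
    masks = {}
    for k, (y0, y1, x0, x1) in rects.items():
        g[y0:y1, x0:x1] = GRAY
        masks[k] = _rect_mask(g.shape, y0, y1, x0, x1)
    return _finalize(
        "sbc", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, cy,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _dungeon(size: int, u: int, params: dict) -> IllusionCase:
    s, pitch, margin = 4 * u, 8 * u, 2 * u
    panel = size // 2
    g = np.empty((size, size))
    g[:, :panel] = WHITE  # left: white background, black lattice squares
    g[:, panel:] = BLACK  # right: black background, white lattice squares
    n_rows = (size - 2 * margin - s) // pitch + 1
    n_cols = (panel - 2 * margin - s) // pitch + 1
    t_row, t_col = params.get("target_row", 3), params.get("target_col", 2)
    if not (0 < t_row < n_rows - 1 and 0 < t_col < n_cols - 1):
        raise ValueError("dungeon: target must be circumscribed by lattice squares")
    masks = {}
    for side, (x_off, sq_color, key) in enumerate(
        [(0, BLACK, "A"), (panel, WHITE, "B")]
    ):
        for i in range(n_rows):
            for j in range(n_cols):
                y0 = margin + i * pitch
                x0 = x_off + margin + j * pitch
                if i == t_row and j == t_col:
                    g[y0 : y0 + s, x0 : x0 + s] = GRAY
                    masks[key] = _rect_mask(g.shape, y0, y0 + s, x0, x0 + s)
                else:
                    g[y0 : y0 + s, x0 : x0 + s] = sq_color
    profile_row = margin + t_row * pitch + s // 2
    return _finalize(
        "dungeon", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, profile_row,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _cube(size: int, u: int, params: dict) -> IllusionCase:
    panel = size // 2
    thick, arm, gap = 3 * u, 7 * u, params.get("gap_units", 3) * u
    L = 24 * u  # outline side
    g = np.empty((size, size))
    masks = {"A": np.zeros((size, size), dtype=bool), "B": np.zeros((size, size), dtype=bool)}
    for x_off, bg, fg, key in [(0, WHITE, BLACK, "A"), (panel, BLACK, WHITE, "B")]:
        g[:, x_off : x_off + panel] = bg
        yy0, xx0 = size // 2 - L // 2, x_off + 6 * u
        # corner brackets (L-shapes), arms of length `arm`, thickness `thick`
        for cy, cx, sy, sx in [
            (yy0, xx0, 1, 1),
            (yy0, xx0 + L - thick, 1, -1),
            (yy0 + L - thick, xx0, -1, 1),
            (yy0 + L - thick, xx0 + L - thick, -1, -1),
        ]:
            # horizontal arm
            hx0 = cx if sx > 0 else cx + thick - arm
            g[cy : cy + thick, hx0 : hx0 + arm] = fg
            # vertical arm
            vy0 = cy if sy > 0 else cy + thick - arm
            g[vy0 : vy0 + arm, cx : cx + thick] = fg
        # gray bars centred on each side, collinear with the bracket arms
        bar_lo = arm + gap  # offset from the outline corner, along the side
        bar_hi = L - arm - gap
        bars = [
            (yy0, yy0 + thick, xx0 + bar_lo, xx0 + bar_hi),  # top
            (yy0 + L - thick, yy0 + L, xx0 + bar_lo, xx0 + bar_hi),  # bottom
            (yy0 + bar_lo, yy0 + bar_hi, xx0, xx0 + thick),  # left
            (yy0 + bar_lo, yy0 + bar_hi, xx0 + L - thick, xx0 + L),  # right
        ]
        for y0, y1, x0, x1 in bars:
            g[y0:y1, x0:x1] = GRAY
            masks[key] |= _rect_mask(g.shape, y0, y1, x0, x1)
    return _finalize(
        "cube", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, size // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _grating(size: int, u: int, params: dict) -> IllusionCase:
    panel = size // 2
    bw, gap = 3 * u, 3 * u
    pitch = bw + gap
    n_bars = 5
    m = 2 * u
    y0, y1 = 12 * u, 52 * u
    g = np.empty((size, size))
    masks = {}
    for x_off, bg, fg, key in [(0, WHITE, BLACK, "A"), (panel, BLACK, WHITE, "B")]:
        g[:, x_off : x_off + panel] = bg
        for k in range(n_bars):
            x0 = x_off + m + k * pitch
            color = GRAY if k == n_bars // 2 else fg
            g[y0:y1, x0 : x0 + bw] = color
            if k == n_bars // 2:
                masks[key] = _rect_mask(g.shape, y0, y1, x0, x0 + bw)
    return _finalize(
        "grating", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, size // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _rings(size: int, u: int, params: dict) -> IllusionCase:
    t = 4 * u
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.maximum(np.abs(yy - c), np.abs(xx - c))
    band = ((rr - 0.5) // t).astype(int)
    # A: gray ring between white rings; B: gray ring between black rings
    colors = [WHITE, BLACK, WHITE, GRAY, WHITE, BLACK, GRAY, BLACK]
    g = np.full((size, size), BLACK)
    for k, col in enumerate(colors):
        g[band == k] = col
    masks = {"A": band == 3, "B": band == 6}
    return _finalize(
        "rings", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, size // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _bullseye(size: int, u: int, params: dict) -> IllusionCase:
    t = 3 * u
    panel = size // 2
    y_lo, y_hi = size // 2 - panel // 2, size // 2 + panel // 2
    g = np.full((size, size), GRAY)
    masks = {}
    for cx, first, key in [(panel / 2 - 0.5, WHITE, "A"), (panel * 1.5 - 0.5, BLACK, "B")]:
        cy = (size - 1) / 2.0
        yy, xx = np.mgrid[y_lo:y_hi, 0:size]
        rr = np.maximum(np.abs(yy - cy), np.abs(xx - cx))
        band = ((rr - 0.5) // t).astype(int)
        other = BLACK if first == WHITE else WHITE
        sub = np.full(band.shape, GRAY)
        for k in range(panel // (2 * t)):
            if k == 0:
                col = GRAY
            elif k % 2 == 1:
                col = first
            else:
                col = other
            sub[band == k] = col
        region = band < panel // (2 * t)
        view = g[y_lo:y_hi, :]
        view[region] = sub[region]
        m = np.zeros((size, size), dtype=bool)
        m[y_lo:y_hi, :] = band == 0
        masks[key] = m
    return _finalize(
        "bullseye", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, size // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _white_grating(size: int, u: int) -> np.ndarray:
    """Full-height square-wave grating; mirror-flipping it inverts it."""
    g = np.empty((size, size))
    bw = 4 * u
    for k in range(size // bw):
        g[:, k * bw : (k + 1) * bw] = WHITE if k % 2 else BLACK
    return g


def _white(size: int, u: int, params: dict) -> IllusionCase:
    bw = 4 * u
    g = _white_grating(size, u)
    y0, y1 = 26 * u, 38 * u
    ka, kb = 6, 9  # black bar and its mirror (white) bar
    masks = {}
    for k, key in [(ka, "A"), (kb, "B")]:
        x0 = k * bw
        g[y0:y1, x0 : x0 + bw] = GRAY
        masks[key] = _rect_mask(g.shape, y0, y1, x0, x0 + bw)
    return _finalize(
        "white", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, size // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _benary(size: int, u: int, params: dict) -> IllusionCase:
    g = np.full((size, size), WHITE)
    a0, a1 = 26 * u, 39 * u  # horizontal arm rows
    g[a0:a1, 5 * u : 59 * u] = BLACK  # horizontal arm
    g[5 * u : 59 * u, a0:a1] = BLACK  # vertical arm
    s = 7 * u
    # A: on the black arm, flush with its top edge
    ay0, ax0 = a0, 15 * u
    g[ay0 : ay0 + s, ax0 : ax0 + s] = GRAY
    # B: on the white ground, flush above the arm's top edge
    by0, bx0 = a0 - s, 42 * u
    g[by0 : by0 + s, bx0 : bx0 + s] = GRAY
    masks = {
        "A": _rect_mask(g.shape, ay0, ay0 + s, ax0, ax0 + s),
        "B": _rect_mask(g.shape, by0, by0 + s, bx0, bx0 + s),
    }
    return _finalize(
        "benary", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, ay0 + s // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _todorovic(size: int, u: int, params: dict) -> IllusionCase:
    panel = size // 2
    g = np.empty((size, size))
    masks = {}
    sq0, sq1 = 9 * u, 23 * u  # gray square, panel-relative
    occ = 8 * u
    occ_pos = [5 * u, 19 * u]
    for x_off, bg, occ_col, key in [(0, BLACK, WHITE, "A"), (panel, WHITE, BLACK, "B")]:
        g[:, x_off : x_off + panel] = bg
        g[sq0:sq1, x_off + sq0 : x_off + sq1] = GRAY
        gray = _rect_mask(g.shape, sq0, sq1, x_off + sq0, x_off + sq1)
        for oy in occ_pos:
            for ox in occ_pos:
                g[oy : oy + occ, x_off + ox : x_off + ox + occ] = occ_col
                gray &= ~_rect_mask(
                    g.shape, oy, oy + occ, x_off + ox, x_off + ox + occ
                )
        masks[key] = gray
    return _finalize(
        "todorovic", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, size // 2,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _checkerboard(size: int, u: int, params: dict, name: str = "checkerboard") -> IllusionCase:
    check = params.get("check_units", 4) * u
    n = size // check
    yy, xx = np.mgrid[0:size, 0:size]
    parity = (yy // check + xx // check) % 2
    g = np.where(parity == 0, BLACK, WHITE)
    # A replaces a black check (white edge-neighbours); B its mirrored white check
    i = n // 2 - 1
    ja = n // 4 + (0 if (i + n // 4) % 2 == 0 else 1)
    jb = n - 1 - ja
    masks = {}
    for j, key in [(ja, "A"), (jb, "B")]:
        y0, x0 = i * check, j * check
        g[y0 : y0 + check, x0 : x0 + check] = GRAY
        masks[key] = _rect_mask(g.shape, y0, y0 + check, x0, x0 + check)
    profile_row = i * check + check // 2
    return _finalize(
        name, g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params, profile_row,
        (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _checkerboard_extended(size: int, u: int, params: dict) -> IllusionCase:
    params = {"check_units": 2, **params}
    return _checkerboard(size, u, params, name="checkerboard_extended")


def _contrast_contrast(size: int, u: int, params: dict) -> IllusionCase:
    """Moderate-contrast texture patch on a high-contrast checkerboard (A)
    versus the same patch on a uniform field (B).

    Target masks sample the check interiors of each patch (grid-line and
    junction pixels excluded), where the surviving texture contrast lives.
    """
    lo_c, hi_c = params.get("patch_levels", (0.4, 0.6))
    panel = size // 2
    check = 4 * u
    g = np.full((size, size), GRAY)
    yy, xx = np.mgrid[0:size, 0:size]
    parity = (yy // check + xx // check) % 2
    # left panel: full-range checkerboard surround; right panel: uniform gray
    left = np.zeros(g.shape, dtype=bool)
    left[:, :panel] = True
    g[left & (parity == 0)] = BLACK
    g[left & (parity == 1)] = WHITE
    p0, p1 = 24 * u, 40 * u  # patch rows; 4x4 checks, grid-aligned
    masks = {}
    for x_off, key in [(8 * u, "A"), (40 * u, "B")]:
        patch = np.zeros(g.shape, dtype=bool)
        patch[p0:p1, x_off : x_off + 16 * u] = True
        g[patch & (parity == 0)] = lo_c
        g[patch & (parity == 1)] = hi_c
        # mask: every patch check shrunk one pixel (a further one-pixel rim
        # is removed during finalisation)
        m = np.zeros(g.shape, dtype=bool)
        for iy in range(4):
            for ix in range(4):
                y0 = p0 + iy * check
                x0 = x_off + ix * check
                m[y0 + 1 : y0 + check - 1, x0 + 1 : x0 + check - 1] = True
        masks[key] = m
    return _finalize(
        "contrast_contrast", g, masks, A_LOWER_CONTRAST, RMS_CONTRAST_DIFFERENCE,
        params, size // 2, (BLACK, lo_c, GRAY, hi_c, WHITE), None,
    )


def _white_yazdanbakhsh(size: int, u: int, params: dict) -> IllusionCase:
    # wider bars than the classic display so the detached targets' weak
    # contours stand clear of the bar edges yet within facilitation reach
    bw = 8 * u
    g = np.empty((size, size))
    for k in range(size // bw):
        g[:, k * bw : (k + 1) * bw] = WHITE if k % 2 else BLACK
    y0, y1 = 26 * u, 38 * u
    margin = 2 * u
    masks = {}
    # A embedded in a white bar (white margin all around), B in a black bar
    for k, key in [(3, "A"), (4, "B")]:
        x0 = k * bw + margin
        x1 = (k + 1) * bw - margin
        g[y0:y1, x0:x1] = GRAY
        masks[key] = _rect_mask(g.shape, y0, y1, x0, x1)
    return _finalize(
        "white_yazdanbakhsh", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params,
        size // 2, (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _banded_grating(size: int, u: int) -> tuple[np.ndarray, int, int]:
    """Grating band between a white field above and a black field below."""
    band0, band1 = 20 * u, 44 * u
    g = np.empty((size, size))
    g[:band0, :] = WHITE
    g[band1:, :] = BLACK
    bw = 4 * u
    for k in range(size // bw):
        g[band0:band1, k * bw : (k + 1) * bw] = WHITE if k % 2 else BLACK
    return g, band0, band1


def _white_anderson(size: int, u: int, params: dict) -> IllusionCase:
    offset = params.get("offset_units", 9) * u
    g, band0, band1 = _banded_grating(size, u)
    if offset <= 0 or band0 + offset >= band1 - offset:
        raise ValueError("white_anderson: offset must keep targets inside the band")
    bw = 4 * u
    y0, y1 = band0 + offset, band1 - offset
    masks = {}
    for k, key in [(6, "A"), (9, "B")]:  # A on a black bar, B on a white bar
        x0 = k * bw
        g[y0:y1, x0 : x0 + bw] = GRAY
        masks[key] = _rect_mask(g.shape, y0, y1, x0, x0 + bw)
    return _finalize(
        "white_anderson", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params,
        size // 2, (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _white_howe(size: int, u: int, params: dict) -> IllusionCase:
    g, band0, band1 = _banded_grating(size, u)
    bw = 4 * u
    masks = {}
    for k, key in [(6, "A"), (9, "B")]:
        x0 = k * bw
        g[band0:band1, x0 : x0 + bw] = GRAY
        masks[key] = _rect_mask(g.shape, band0, band1, x0, x0 + bw)
    return _finalize(
        "white_howe", g, masks, A_EQUALS, MEAN_DIFFERENCE, params,
        size // 2, (BLACK, GRAY, WHITE), {"A": GRAY, "B": GRAY},
    )


def _white_inverted(size: int, u: int, params: dict) -> IllusionCase:
    # bars span only the lower half of the luminance range, so the white
    # targets carry the strongest contours in the display: nothing can
    # facilitate (and hence erase) their boundaries, assimilation is shut
    # off, and only local contrast with the enclosing bar remains
    bw = 4 * u
    g = np.empty((size, size))
    for k in range(size // bw):
        g[:, k * bw : (k + 1) * bw] = GRAY if k % 2 else BLACK
    y0, y1 = 26 * u, 38 * u
    margin = u
    masks = {}
    # A embedded in a black bar (contrast direction: brighter), B in gray
    for k, key in [(6, "A"), (9, "B")]:
        x0 = k * bw + margin
        x1 = (k + 1) * bw - margin
        g[y0:y1, x0:x1] = WHITE
        masks[key] = _rect_mask(g.shape, y0, y1, x0, x1)
    return _finalize(
        "white_inverted", g, masks, A_BRIGHTER, MEAN_DIFFERENCE, params,
        size // 2, (BLACK, GRAY, WHITE), {"A": WHITE, "B": WHITE},
    )


_BUILDERS = {
    "dungeon": _dungeon,
    "cube": _cube,
    "grating": _grating,
    "rings": _rings,
    "bullseye": _bullseye,
    "sbc": _sbc,
    "white": _white,
    "benary": _benary,
    "todorovic": _todorovic,
    "checkerboard": _checkerboard,
    "checkerboard_extended": _checkerboard_extended,
    "contrast_contrast": _contrast_contrast,
    "white_yazdanbakhsh": _white_yazdanbakhsh,
    "white_anderson": _white_anderson,
    "white_howe": _white_howe,
    "white_inverted": _white_inverted,
}

STIMULUS_NAMES = tuple(_BUILDERS)


def generate_stimulus(name: str, params: dict | None = None) -> IllusionCase:
    """Generate one illusion case by name; deterministic in name + params."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown stimulus {name!r}; choose from {STIMULUS_NAMES}")
    params = dict(params or {})
    size = int(params.pop("size", 128))
    if size < 64 or size % 64:
        raise ValueError("size must be a multiple of 64, at least 64")
    u = size // 64
    case = _BUILDERS[name](size, u, params)
    case.params = {"size": size, **params}
    return case


def list_stimuli() -> list[dict]:
    """All stimulus identifiers with their default parameters, stable order."""
    return [{"name": name, "params": {"size": 128}} for name in STIMULUS_NAMES]
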