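"""Spatial input maps: assembly, alignment, interpolation, group averaging,
vertical profiles and region means.

Coordinate convention
---------------------
x is lateral (medial -> lateral positive), y vertical with pia-ward
positive; a pixel's value refers to its centre.  ``values`` arrays are
indexed ``[row, col]`` with row 0 the pia-most row, so ``y_coords`` is
stored descending while ``x_coords`` ascends.  In aligned frames the soma
(or home-barrel centre) sits at the origin.

Masking
-------
Masked pixels carry NaN in ``values`` and a code in ``mask``:
``VALID`` (0), ``DIRECT_EXCLUDED`` (1, a deleted direct response) or
``UNSAMPLED`` (2).  Mask propagation through resampling is conservative:
an output pixel whose bilinear stencil touches any masked input pixel is
masked — resampling never fabricates values where direct responses were
deleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import GridGeometry
from .exceptions import (IncompatibleMapsError, InvalidFrameError,
                         InvalidParameterError)

__all__ = [
    "VALID", "DIRECT_EXCLUDED", "UNSAMPLED",
    "InputMap", "GroupMap", "Rect",
    "build_cell_map", "align_to_soma", "align_to_barrel",
    "interpolate_half", "average_group", "vertical_profile", "region_mean",
    "plot_map",
]

log = logging.getLogger(__name__)

VALID = 0
DIRECT_EXCLUDED = 1
UNSAMPLED = 2


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (e.g. a barrel outline) by centre and size, um."""

    cx: float
    cy: float
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError("degenerate rectangle (zero width/height)")


@dataclass
class InputMap:
    """2-D grid of per-spot input strengths for one neuron."""

    values: np.ndarray            # (ny, nx), NaN on masked pixels
    mask: np.ndarray              # (ny, nx) int codes
    x_coords: np.ndarray          # ascending pixel-centre x, um
    y_coords: np.ndarray          # descending pixel-centre y, um
    frame: str = "slice"          # slice | soma_aligned | barrel_aligned
    soma_pos: Optional[tuple] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        if self.values.shape != self.mask.shape:
            raise InvalidParameterError("values and mask shapes differ")
        if self.values.shape != (self.y_coords.size, self.x_coords.size):
            raise InvalidParameterError("coordinate lengths do not match grid")

    @property
    def pixel_size(self) -> tuple:
        """(dx, dy) in um."""
        dx = float(np.mean(np.diff(self.x_coords))) if self.x_coords.size > 1 else 0.0
        dy = float(-np.mean(np.diff(self.y_coords))) if self.y_coords.size > 1 else 0.0
        return (dx, dy)

    @property
    def valid(self) -> np.ndarray:
        return self.mask == VALID


@dataclass
class GroupMap:
    """Genotype-average map with per-pixel contribution counts."""

    values: np.ndarray      # NaN where n < min_n
    n: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray
    frame: str
    min_n: int
    label: str = ""


# ---------------------------------------------------------------------------
# assembly and alignment

def build_cell_map(responses: list, geometry: GridGeometry,
                   soma_pos: tuple, metadata: Optional[dict] = None) -> InputMap:
    """Assemble per-spot evoked-response amplitudes into a slice-frame map.

    ``responses`` are :class:`~optomap.events.EvokedResponse` objects with
    ``grid_index`` set.  Excluded responses (pure direct, unusable fits)
    become ``DIRECT_EXCLUDED`` pixels; spots with no response are
    ``UNSAMPLED``.
    """
    vals = np.full((geometry.rows, geometry.cols), np.nan)
    mask = np.full((geometry.rows, geometry.cols), UNSAMPLED, dtype=np.int8)
    seen = set()
    for r in responses:
        if r.grid_index is None:
            raise InvalidParameterError("response without grid_index")
        if r.grid_index in seen:
            raise InvalidParameterError(f"duplicate grid index {r.grid_index}")
        seen.add(r.grid_index)
        row, col = r.grid_index
        if r.excluded or r.classification in ("direct", "unusable"):
            mask[row, col] = DIRECT_EXCLUDED
        else:
            vals[row, col] = r.amplitude
            mask[row, col] = VALID
    sx, sy = soma_pos
    r0, c0 = geometry.soma_pixel
    x = sx + (np.arange(geometry.cols) - c0) * geometry.x_spacing
    y = sy + (r0 - np.arange(geometry.rows)) * geometry.y_spacing
    return InputMap(values=vals, mask=mask, x_coords=x, y_coords=y,
                    frame="slice", soma_pos=(float(sx), float(sy)),
                    metadata=dict(metadata or {}))


def align_to_soma(m: InputMap) -> InputMap:
    """Translate coordinates so the soma sits at the origin."""
    if m.soma_pos is None:
        raise InvalidParameterError("soma position unknown; cannot align")
    sx, sy = m.soma_pos
    return replace(m, x_coords=m.x_coords - sx, y_coords=m.y_coords - sy,
                   frame="soma_aligned", soma_pos=(0.0, 0.0))


def _resample_bilinear(m: InputMap, new_x: np.ndarray, new_y: np.ndarray,
                       src_x: Optional[np.ndarray] = None,
                       src_y: Optional[np.ndarray] = None) -> tuple:
    """Bilinear resample with conservative mask propagation.

    Returns ``(values, mask)`` on the target grid.  An output pixel is
    masked if its stencil touches (with non-negligible weight) any masked
    input pixel, or if it falls outside the input extent; it inherits
    ``DIRECT_EXCLUDED`` over ``UNSAMPLED`` when both are touched.
    """
    xs = m.x_coords if src_x is None else src_x
    ys = m.y_coords if src_y is None else src_y
    # work with ascending axes
    y_asc = ys[::-1]
    v = m.values[::-1, :]
    msk = m.mask[::-1, :]
    ny_out = new_y.size
    out_y_asc = new_y[::-1]

    def axis_weights(src, dst):
        n = src.size
        eps = 1e-9 * max(1.0, float(np.max(np.abs(src))) if n else 1.0)
        outside = (dst < src[0] - eps) | (dst > src[-1] + eps)
        j = np.searchsorted(src, dst, side="right")
        i0 = np.clip(j - 1, 0, max(n - 2, 0))
        if n == 1:
            frac = np.zeros_like(dst)
        else:
            frac = (dst - src[i0]) / (src[i0 + 1] - src[i0])
        frac = np.clip(frac, 0.0, 1.0)
        return i0, frac, outside

    ix0, fx, out_x = axis_weights(xs, new_x)
    iy0, fy, out_y = axis_weights(y_asc, out_y_asc)
    wtol = 1e-9
    nx_out = new_x.size
    vals = np.zeros((ny_out, nx_out))
    direct_touch = np.zeros((ny_out, nx_out), dtype=bool)
    masked_touch = np.zeros((ny_out, nx_out), dtype=bool)
    corners = [(0, 0), (0, 1), (1, 0), (1, 1)]
    wx = {0: 1.0 - fx, 1: fx}
    wy = {0: 1.0 - fy, 1: fy}
    nsrc_x = xs.size
    nsrc_y = y_asc.size
    for cy, cx in corners:
        iy = np.clip(iy0 + cy, 0, nsrc_y - 1)
        ix = np.clip(ix0 + cx, 0, nsrc_x - 1)
        w = np.outer(wy[cy], wx[cx])
        corner_v = v[np.ix_(iy, ix)]
        corner_m = msk[np.ix_(iy, ix)]
        touched = w > wtol
        vals += np.where(touched, w * np.nan_to_num(corner_v), 0.0)
        masked_touch |= touched & (corner_m != VALID)
        direct_touch |= touched & (corner_m == DIRECT_EXCLUDED)
    outside = np.broadcast_to(out_y[:, None], (ny_out, nx_out)) | \
        np.broadcast_to(out_x[None, :], (ny_out, nx_out))
    out_mask = np.full((ny_out, nx_out), VALID, dtype=np.int8)
    out_mask[masked_touch | outside] = UNSAMPLED
    out_mask[direct_touch] = DIRECT_EXCLUDED
    vals = np.where(out_mask == VALID, vals, np.nan)
    # back to descending-y row order
    return vals[::-1, :], out_mask[::-1, :]


def interpolate_half(m: InputMap) -> InputMap:
    """Bilinear interpolation onto a grid with both pixel dimensions halved
    (e.g. 50 um -> 25 um), as used for genotype-averaged colour maps.

    Output coordinates run between the original pixel centres at half the
    spacing (``2n - 1`` points per axis), so original centres are preserved
    and affine fields reproduce exactly.
    """
    nx, ny = m.x_coords.size, m.y_coords.size
    new_x = np.linspace(m.x_coords[0], m.x_coords[-1], 2 * nx - 1) if nx > 1 \
        else m.x_coords.copy()
    new_y = np.linspace(m.y_coords[0], m.y_coords[-1], 2 * ny - 1) if ny > 1 \
        else m.y_coords.copy()
    vals, mask = _resample_bilinear(m, new_x, new_y)
    return replace(m, values=vals, mask=mask, x_coords=new_x, y_coords=new_y)


def align_to_barrel(m: InputMap, home_barrel: Rect, reference_barrel: Rect,
                    ml_flip: bool = False) -> InputMap:
    """Align a map to its home barrel: per-axis stretch about the barrel
    centre to normalise barrel size, then translation of the centre to the
    origin.

    ``ml_flip`` mirrors the x axis first so the medial -> lateral direction
    matches the reference orientation.  The stretched map is resampled onto
    a regular lattice through the origin at the map's own pixel spacing
    (the shared frame for group averaging); when the home barrel equals the
    reference the transform is a pure translation and grid-commensurate
    values are preserved exactly.
    """
    sx = reference_barrel.width / home_barrel.width
    sy = reference_barrel.height / home_barrel.height
    xs = m.x_coords.copy()
    cx = home_barrel.cx
    if ml_flip:
        xs, cx = -xs[::-1], -cx
        vals_in = m.values[:, ::-1]
        mask_in = m.mask[:, ::-1]
        m = replace(m, values=vals_in, mask=mask_in, x_coords=xs)
    tx = (xs - cx) * sx
    ty = (m.y_coords - home_barrel.cy) * sy
    dx, dy = m.pixel_size
    if dx <= 0 or dy <= 0:
        raise InvalidParameterError("map needs at least 2 pixels per axis")
    kx0 = int(np.ceil(tx[0] / dx - 1e-9))
    kx1 = int(np.floor(tx[-1] / dx + 1e-9))
    ky1 = int(np.floor(ty[0] / dy + 1e-9))    # ty descends
    ky0 = int(np.ceil(ty[-1] / dy - 1e-9))
    new_x = np.arange(kx0, kx1 + 1) * dx
    new_y = np.arange(ky1, ky0 - 1, -1) * dy
    vals, mask = _resample_bilinear(m, new_x, new_y, src_x=tx, src_y=ty)
    soma = None
    if m.soma_pos is not None:
        px = -m.soma_pos[0] if ml_flip else m.soma_pos[0]
        soma = ((px - cx) * sx, (m.soma_pos[1] - home_barrel.cy) * sy)
    return replace(m, values=vals, mask=mask, x_coords=new_x, y_coords=new_y,
                   frame="barrel_aligned", soma_pos=soma)


# ---------------------------------------------------------------------------
# group statistics

def average_group(maps: list, min_n: int = 8, label: str = "") -> GroupMap:
    """Per-pixel mean over valid contributions, masking pixels sampled by
    fewer than ``min_n`` neurons (the "black pixel" rule).

    All maps must share frame and pixel size and sit on one common lattice.
    """
    if not maps:
        raise IncompatibleMapsError("no maps to average")
    ref = maps[0]
    dx, dy = ref.pixel_size
    for m in maps[1:]:
        if m.frame != ref.frame:
            raise IncompatibleMapsError(
                f"mixed frames: {m.frame} vs {ref.frame}")
        mdx, mdy = m.pixel_size
        if not (np.isclose(mdx, dx) and np.isclose(mdy, dy)):
            raise IncompatibleMapsError("mixed pixel sizes")

    def lattice_index(coords, origin, step, name):
        k = (coords - origin) / step
        ki = np.round(k)
        if not np.allclose(k, ki, atol=1e-6):
            raise IncompatibleMapsError(f"{name} coordinates off the common lattice")
        return ki.astype(int)

    ox, oy = ref.x_coords[0], ref.y_coords[0]
    kxs = [lattice_index(m.x_coords, ox, dx, "x") for m in maps]
    kys = [lattice_index(m.y_coords, oy, -dy, "y") for m in maps]
    kx_min = min(k.min() for k in kxs)
    kx_max = max(k.max() for k in kxs)
    ky_min = min(k.min() for k in kys)
    ky_max = max(k.max() for k in kys)
    nx = kx_max - kx_min + 1
    ny = ky_max - ky_min + 1
    total = np.zeros((ny, nx))
    count = np.zeros((ny, nx), dtype=int)
    for m, kx, ky in zip(maps, kxs, kys):
        ok = m.valid & np.isfinite(m.values)
        sub_y = ky - ky_min
        sub_x = kx - kx_min
        block_t = total[np.ix_(sub_y, sub_x)]
        block_c = count[np.ix_(sub_y, sub_x)]
        block_t[ok] += m.values[ok]
        block_c[ok] += 1
        total[np.ix_(sub_y, sub_x)] = block_t
        count[np.ix_(sub_y, sub_x)] = block_c
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count >= min_n, total / np.maximum(count, 1), np.nan)
    x = ox + (np.arange(kx_min, kx_max + 1)) * dx
    y = oy - (np.arange(ky_min, ky_max + 1)) * dy
    return GroupMap(values=mean, n=count, x_coords=x, y_coords=y,
                    frame=ref.frame, min_n=min_n, label=label)


def vertical_profile(m):
    """Mean input strength per horizontal row vs vertical offset from soma.

    Accepts a soma- or barrel-aligned :class:`InputMap` or
    :class:`GroupMap`; returns an ``(offsets, values)`` pair of arrays in
    stored row order (pia-most first).  Rows without valid pixels are NaN.
    """
    frame = m.frame
    if frame not in ("soma_aligned", "barrel_aligned"):
        raise InvalidFrameError(f"vertical profile needs an aligned map, got {frame!r}")
    vals = m.values
    with np.errstate(invalid="ignore"):
        prof = np.nanmean(np.where(np.isfinite(vals), vals, np.nan), axis=1)
    return m.y_coords.copy(), prof


def region_mean(m: InputMap, region: tuple, power: Optional[float] = None) -> float:
    """Mean of valid pixel values whose centres fall in a rectangle.

    ``region`` is ``(x_min, x_max, y_min, y_max)`` in aligned-frame um.
    Returns NaN (with a log entry) when no valid pixel falls inside.
    ``power`` divides the result (normalisation to stimulus power).
    """
    x0, x1, y0, y1 = region
    inx = (m.x_coords >= x0) & (m.x_coords <= x1)
    iny = (m.y_coords >= y0) & (m.y_coords <= y1)
    sel = np.outer(iny, inx) & m.valid & np.isfinite(m.values)
    if not sel.any():
        log.warning("region %s contains no valid pixels", region)
        return float("nan")
    out = float(m.values[sel].mean())
    if power is not None:
        if power <= 0:
            raise InvalidParameterError("power must be positive")
        out /= power
    return out


def plot_map(m, ax=None, cmap: str = "hot", mask_color: str = "black"):
    """Render a map as a colour image (masked pixels black), return the axes."""
    import matplotlib.pyplot as plt
    from matplotlib import colors as mcolors
    if ax is None:
        _, ax = plt.subplots()
    vals = np.ma.masked_invalid(m.values)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(mcolors.to_rgba(mask_color))
    dx, dy = (m.pixel_size if isinstance(m, InputMap)
              else (float(np.mean(np.diff(m.x_coords))),
                    float(-np.mean(np.diff(m.y_coords)))))
    extent = [m.x_coords[0] - dx / 2, m.x_coords[-1] + dx / 2,
              m.y_coords[-1] - dy / 2, m.y_coords[0] + dy / 2]
    im = ax.imshow(vals, cmap=cm, extent=extent, origin="upper", aspect="equal")
    ax.figure.colorbar(im, ax=ax, label="input strength")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax
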