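"""Topographic rasterization of per-channel DE values.

Each 62-channel DE vector is painted onto a raster by a scattered-data
generalization of bilinear interpolation: for every pixel, the nearest
electrode in each of the four open quadrants (NW, NE, SW, SE) around the
pixel forms the stencil, weighted by the product of the coordinate
distances to the x- and y-opposite stencil members and normalized to sum
to one.  On a rectangular electrode grid this reduces exactly to textbook
bilinear interpolation; pixels that do not have an electrode in all four
quadrants (the scalp border) are zero, matching the dark rim of published
DE topography figures.

Electrode positions live in a unit disc obtained by azimuthal-equidistant
projection of standard extended 10-20 template positions; the disc is
mapped to the central 200/224 box of the raster, pixel centers at
half-integer coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .features import DE_FLOOR

__all__ = [
    "ElectrodeLayout", "InterpolationStencil", "TopographicStack",
    "DEFAULT_CHANNELS", "default_layout", "load_layout", "save_layout",
    "build_stencil", "rasterize", "rasterize_many", "stack_bands",
    "region_channels", "REGIONS",
]

#: fraction of the raster left as zero margin on each side (12 px of 224)
MARGIN_FRACTION = 12.0 / 224.0

#: 62-channel montage labels (extended 10-20; posterior pair PO9/PO10)
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2", "PO9", "PO10",
)

REGIONS = ("frontal", "central", "left_temporal", "right_temporal",
           "parietal", "occipital")


@dataclass(frozen=True)
class ElectrodeLayout:
    """Named 2-D electrode positions inside the unit disc."""

    names: tuple[str, ...]
    coords: np.ndarray  # n x 2

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.names), 2):
            raise ValueError("coords must be n x 2 matching names")
        dupes = {n for n in self.names if list(self.names).count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate channel names: {sorted(dupes)}")
        r = np.hypot(coords[:, 0], coords[:, 1])
        if (r > 1.0 + 1e-9).any():
            bad = [self.names[i] for i in np.where(r > 1.0 + 1e-9)[0]]
            raise ValueError(f"electrodes outside unit disc: {bad}")
        if len(np.unique(coords.round(12), axis=0)) != len(self.names):
            raise ValueError("electrode coordinates are not distinct")

    def __len__(self):
        return len(self.names)

    def digest(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(",".join(self.names).encode())
        h.update(np.ascontiguousarray(self.coords.round(9)).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class InterpolationStencil:
    """Electrode indices and convex weights interpolating one pixel."""

    indices: tuple[int, ...]
    weights: tuple[float, ...]


@dataclass
class TopographicStack:
    """Per-band rasterized DE maps for one window: bands x size x size."""

    maps: np.ndarray
    band_names: list[str]
    layout_digest: str
    window: int = 0

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3:
            raise ValueError("maps must be bands x H x W")


# --------------------------------------------------------------------- layout


@lru_cache(maxsize=1)
def default_layout() -> ElectrodeLayout:
    """62-channel layout from the standard extended 10-20 template.

    3-D template positions are projected azimuthal-equidistantly (vertex at
    the origin, planar radius proportional to the polar angle), then scaled
    so the outermost electrode sits at radius 0.95.
    """
    import warnings

    import mne
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    upper = {k.upper(): k for k in pos3d}
    coords = []
    for name in DEFAULT_CHANNELS:
        x, y, z = pos3d[upper[name]]
        rho = np.hypot(x, y)
        theta = np.arctan2(rho, z)           # polar angle from the vertex
        phi = np.arctan2(y, x)
        coords.append((theta * np.cos(phi), theta * np.sin(phi)))
    coords = np.asarray(coords)
    coords *= 0.95 / np.hypot(coords[:, 0], coords[:, 1]).max()
    return ElectrodeLayout(DEFAULT_CHANNELS, coords)


def load_layout(path) -> ElectrodeLayout:
    """Read a montage CSV with columns name,x,y."""
    names, coords = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            coords.append((float(row["x"]), float(row["y"])))
    return ElectrodeLayout(tuple(names), np.asarray(coords))


def save_layout(layout: ElectrodeLayout, path):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y"])
        for name, (x, y) in zip(layout.names, layout.coords):
            writer.writerow([name, repr(float(x)), repr(float(y))])


def region_channels(layout: ElectrodeLayout, region: str) -> list[int]:
    """Channel indices of a named scalp region (coordinate-based partition)."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; choose from {REGIONS}")
    idx = []
    for i, (x, y) in enumerate(layout.coords):
        if y > 0.35:
            r = "frontal"
        elif y < -0.55:
            r = "occipital"
        elif y <= -0.15:
            r = "parietal"
        elif x < -0.35:
            r = "left_temporal"
        elif x > 0.35:
            r = "right_temporal"
        else:
            r = "central"
        if r == region:
            idx.append(i)
    return idx


# ------------------------------------------------------------------- stencils


def build_stencil(pixel: tuple[float, float], layout: ElectrodeLayout,
                  eps: float = 1e-6) -> InterpolationStencil | None:
    """Four-quadrant interpolation stencil for one pixel, or None if the
    pixel lacks an electrode in some quadrant (it is then painted 0).

    A pixel within ``eps`` of an electrode gets that electrode with weight 1.
    """
    px, py = pixel
    dx = layout.coords[:, 0] - px
    dy = layout.coords[:, 1] - py
    dist2 = dx * dx + dy * dy
    nearest = int(np.argmin(dist2))
    if dist2[nearest] <= eps * eps:
        return InterpolationStencil((nearest,), (1.0,))
    # quadrant membership; points exactly on an axis count as east/north
    east, north = dx >= 0, dy >= 0
    quads = {
        "NE": east & north, "NW": ~east & north,
        "SE": east & ~north, "SW": ~east & ~north,
    }
    chosen: dict[str, int] = {}
    for q, mask in quads.items():
        if not mask.any():
            return None
        cand = np.where(mask)[0]
        chosen[q] = int(cand[np.argmin(dist2[cand])])
    xs = {q: layout.coords[i, 0] for q, i in chosen.items()}
    ys = {q: layout.coords[i, 1] for q, i in chosen.items()}
    opposite_x = {"NE": "NW", "NW": "NE", "SE": "SW", "SW": "SE"}
    opposite_y = {"NE": "SE", "SE": "NE", "NW": "SW", "SW": "NW"}
    order = ("NE", "NW", "SE", "SW")
    w = np.array([abs(xs[opposite_x[q]] - px) * abs(ys[opposite_y[q]] - py)
                  for q in order])
    total = w.sum()
    if total <= 0:  # degenerate collinear stencil: fall back to nearest
        return InterpolationStencil((nearest,), (1.0,))
    w /= total
    return InterpolationStencil(tuple(chosen[q] for q in order), tuple(w))


def pixel_grid(size: int) -> np.ndarray:
    """Disc-plane coordinates of all pixel centers; (size*size) x 2."""
    margin = round(size * MARGIN_FRACTION)
    half_box = (size - 2 * margin) / 2.0
    ax = np.arange(size) + 0.5
    x = (ax - size / 2.0) / half_box
    y = (size / 2.0 - ax) / half_box
    xx, yy = np.meshgrid(x, y)          # row-major: yy varies down rows
    return np.column_stack([xx.ravel(), yy.ravel()])


_MATRIX_CACHE: dict[tuple[str, int], np.ndarray] = {}


def interpolation_matrix(layout: ElectrodeLayout, size: int) -> np.ndarray:
    """Dense (size*size) x n_electrodes matrix applying the stencils."""
    key = (layout.digest(), size)
    if key not in _MATRIX_CACHE:
        grid = pixel_grid(size)
        mat = np.zeros((grid.shape[0], len(layout)), dtype=np.float64)
        for p, (px, py) in enumerate(grid):
            st = build_stencil((px, py), layout)
            if st is not None:
                for i, w in zip(st.indices, st.weights):
                    mat[p, i] += w
        _MATRIX_CACHE[key] = mat
    return _MATRIX_CACHE[key]


def rasterize(de_vector: np.ndarray, layout: ElectrodeLayout,
              size: int = 224) -> np.ndarray:
    """Paint one per-channel DE vector onto a size x size map."""
    de_vector = np.asarray(de_vector, dtype=np.float64)
    if de_vector.shape != (len(layout),):
        raise ValueError(f"expected {len(layout)} values, got {de_vector.shape}")
    return (interpolation_matrix(layout, size) @ de_vector).reshape(size, size)


def rasterize_many(de_vectors: np.ndarray, layout: ElectrodeLayout,
                   size: int = 224) -> np.ndarray:
    """Vectorized rasterization: (..., n_elec) -> (..., size, size)."""
    de_vectors = np.asarray(de_vectors, dtype=np.float64)
    if de_vectors.shape[-1] != len(layout):
        raise ValueError("last axis must index electrodes")
    flat = de_vectors.reshape(-1, len(layout))
    maps = flat @ interpolation_matrix(layout, size).T
    return maps.reshape(de_vectors.shape[:-1] + (size, size))


def stack_bands(de_window: np.ndarray, layout: ElectrodeLayout,
                size: int = 224, band_names=None, floor: float = DE_FLOOR,
                window: int = 0) -> TopographicStack:
    """Rasterize a channels x bands DE window into a bands x size x size stack."""
    de_window = np.asarray(de_window, dtype=np.float64)
    if de_window.ndim != 2 or de_window.shape[0] != len(layout):
        raise ValueError("expected channels x bands")
    clamped = np.maximum(de_window, floor)
    maps = rasterize_many(clamped.T, layout, size)
    names = list(band_names) if band_names is not None \
        else [f"band{i}" for i in range(de_window.shape[1])]
    return TopographicStack(maps, names, layout.digest(), window)


def save_debug_png(stack: TopographicStack, path):
    """Side-by-side grayscale rendering of the band maps (debug aid)."""
    from PIL import Image
    maps = stack.maps
    lo, hi = maps.min(), maps.max()
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    tiles = [((m - lo) * scale).astype(np.uint8) for m in maps]
    Image.fromarray(np.hstack(tiles), mode="L").save(path)
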