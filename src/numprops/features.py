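"""Extraction of numerical and visual properties from dot-array images.

Six property families are measured per stimulus: the dot ratio (smaller
count / larger count) and five visual-property groups — total/mean/SD of dot
areas, total/mean/SD of perimeters, convex-hull area, two density indices
(hull per dot, hull per unit dot area), and total/mean/SD of pairwise
centroid distances — plus three 64-bit perceptual-hash dissimilarities
(average, DCT and Haar-wavelet hashes, compared by Hamming distance).

Visual indices are expressed as ratios: the fewer-dot array's value divided
by the more-dot array's value, so every stimulus reduces to one row of 16
numbers regardless of whether its two arrays occupy separate panels or share
one panel with two colors.

Perimeters are computed from the equivalent-circle radius, perim = 2πr with
r = sqrt(area/π), so perimeter ratios are exactly radius (diameter) ratios
and carry no rasterization noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from PIL import Image
from scipy import ndimage
from scipy.fft import dctn
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

__all__ = [
    "SegmentedArray",
    "ArrayProperties",
    "segment",
    "segment_panel",
    "segment_colors",
    "geometry",
    "feature_vector",
    "hash_avg",
    "hash_perceptual",
    "hash_wavelet",
    "hamming",
    "extract_dataset",
    "FEATURE_COLUMNS",
    "VISUAL_PROPERTIES",
]

#: the 12 geometric ratio indices + 3 hash distances, in output order
VISUAL_PROPERTIES = [
    "perim_total", "perim_mean", "perim_sd",
    "area_total", "area_mean", "area_sd",
    "convex_hull", "ch_per_dot", "ch_per_area",
    "dist_total", "dist_mean", "dist_sd",
    "hash_avg", "hash_perc", "hash_wav",
]

FEATURE_COLUMNS = ["STIMID", "dot_ratio"] + VISUAL_PROPERTIES

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class SegmentedArray:
    """Connected components of one dot array.

    pixels holds all foreground pixel coordinates as (x, y) rows; centroids
    are per-component pixel means; pixel_areas are per-component counts.
    """

    centroids: np.ndarray      # (n, 2) float, (x, y)
    pixel_areas: np.ndarray    # (n,) int
    pixels: np.ndarray         # (N, 2) int, (x, y) of every foreground pixel
    labels: np.ndarray | None = None  # label image (panel-shaped)

    @property
    def n(self) -> int:
        return len(self.pixel_areas)


@dataclass
class ArrayProperties:
    """Scalar geometric descriptors of one dot array.

    SDs are population SDs by default.  Distance statistics are NaN for
    single-dot arrays (undefined).  convex_hull_area is the shoelace area of
    the hull of all dot pixels and may legitimately fall below area_total
    for tight singleton configurations.
    """

    n_dots: int
    area_total: float
    area_mean: float
    area_sd: float
    perim_total: float
    perim_mean: float
    perim_sd: float
    convex_hull_area: float
    ch_per_dot: float
    ch_per_area: float
    dist_total: float
    dist_mean: float
    dist_sd: float


def _as_array(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        image = np.asarray(image)
    return np.asarray(image)


def _pack_rgb(img: np.ndarray) -> np.ndarray:
    """Encode the last (channel) axis into one integer per pixel."""
    flat = img.astype(np.uint32)
    packed = flat[..., 0]
    for c in range(1, img.shape[-1]):
        packed = (packed << 8) | flat[..., c]
    return packed


def _background_value(img: np.ndarray):
    """Most frequent pixel value — dots are sparse, so this is the background."""
    if img.ndim == 2:
        vals, counts = np.unique(img, return_counts=True)
        return vals[np.argmax(counts)]
    packed = _pack_rgb(img).ravel()
    vals, counts = np.unique(packed, return_counts=True)
    bg = int(vals[np.argmax(counts)])
    n = img.shape[-1]
    return np.array([(bg >> (8 * (n - 1 - c))) & 0xFF for c in range(n)],
                    dtype=img.dtype)


def _label_mask(mask: np.ndarray) -> SegmentedArray:
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        raise ValueError("empty panel: no foreground components")
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(int)
    # center_of_mass returns (row, col); convert to (x, y)
    com = np.array(ndimage.center_of_mass(mask, labels, idx), dtype=float)
    centroids = com[:, ::-1]
    ys, xs = np.nonzero(mask)
    pixels = np.column_stack([xs, ys])
    return SegmentedArray(centroids, areas, pixels, labels)


def segment_panel(image) -> SegmentedArray:
    """Segment a single-panel image: 8-connected components of non-background."""
    img = _as_array(image)
    bg = _background_value(img)
    mask = (img != bg) if img.ndim == 2 else np.any(img != bg, axis=-1)
    return _label_mask(mask)


def segment_colors(image) -> tuple[SegmentedArray, SegmentedArray]:
    """Segment a two-color mixed image into its two color-defined arrays."""
    img = _as_array(image)
    if img.ndim != 3:
        raise ValueError("by_color segmentation requires an RGB image")
    packed = _pack_rgb(img)
    bg = _pack_rgb(_background_value(img)[None, :])[0]
    colors = np.unique(packed[packed != bg])
    if len(colors) != 2:
        raise ValueError(
            f"expected exactly 2 foreground colors, found {len(colors)}")
    segs = tuple(_label_mask(packed == c) for c in colors)
    return segs


def segment(image, mode: str = "by_panel", image_b=None,
            split_x: int | None = None
            ) -> tuple[SegmentedArray, SegmentedArray]:
    """Split a stimulus into its two arrays and label each one.

    mode="by_panel": either pass the two per-panel images (``image``,
    ``image_b``) or one composite image plus the recorded ``split_x`` column.
    mode="by_color": one image whose two arrays differ in dot color.
    """
    if mode == "by_color":
        return segment_colors(image)
    if mode != "by_panel":
        raise ValueError(f"unknown segmentation mode {mode!r}")
    if image_b is not None:
        return segment_panel(image), segment_panel(image_b)
    if split_x is None:
        raise ValueError("by_panel needs either image_b or split_x")
    img = _as_array(image)
    return segment_panel(img[:, :split_x]), segment_panel(img[:, split_x:])


def geometry(seg: SegmentedArray, ddof: int = 0) -> ArrayProperties:
    """Geometric descriptors of one segmented array.

    Areas are pixel counts; perimeters use the equivalent-circle model
    (perim = 2·sqrt(π·area)); pairwise distances are Euclidean between
    centroids over all C(n,2) pairs; the hull is the convex hull of all
    foreground pixel centers (area 0 when degenerate/collinear).
    """
    areas = seg.pixel_areas.astype(float)
    n = seg.n
    radii = np.sqrt(areas / np.pi)
    perims = 2.0 * np.pi * radii

    def _sd(x):
        return float(np.std(x, ddof=ddof)) if len(x) > ddof else np.nan

    if n >= 2:
        d = pdist(seg.centroids)
        dist_total, dist_mean, dist_sd = float(d.sum()), float(d.mean()), _sd(d)
    else:
        dist_total = dist_mean = dist_sd = np.nan

    pts = seg.pixels.astype(float)
    if len(pts) >= 3:
        try:
            hull_area = float(ConvexHull(pts).volume)
        except QhullError:  # collinear pixel set
            hull_area = 0.0
    else:
        hull_area = 0.0

    area_total = float(areas.sum())
    return ArrayProperties(
        n_dots=n,
        area_total=area_total,
        area_mean=float(areas.mean()),
        area_sd=_sd(areas),
        perim_total=float(perims.sum()),
        perim_mean=float(perims.mean()),
        perim_sd=_sd(perims),
        convex_hull_area=hull_area,
        ch_per_dot=hull_area / n,
        ch_per_area=hull_area / area_total,
        dist_total=dist_total,
        dist_mean=dist_mean,
        dist_sd=dist_sd,
    )


_RATIO_FIELDS = {
    "perim_total": "perim_total", "perim_mean": "perim_mean",
    "perim_sd": "perim_sd", "area_total": "area_total",
    "area_mean": "area_mean", "area_sd": "area_sd",
    "convex_hull": "convex_hull_area", "ch_per_dot": "ch_per_dot",
    "ch_per_area": "ch_per_area", "dist_total": "dist_total",
    "dist_mean": "dist_mean", "dist_sd": "dist_sd",
}


def feature_vector(props_a: ArrayProperties, props_b: ArrayProperties,
                   hashes: dict[str, float] | None = None) -> dict:
    """One stimulus row: dot ratio, 12 ratio indices, 3 hash distances.

    Orientation is count-determined: each visual index is the fewer-dot
    array's value divided by the more-dot array's.  Equal counts fall back
    to the given order with a warning.  Zero/NaN denominators yield NaN
    (missing), never ±inf.
    """
    if props_a.n_dots == props_b.n_dots:
        warnings.warn("equal dot counts: falling back to input order",
                      RuntimeWarning, stacklevel=2)
        fewer, more = props_a, props_b
    elif props_a.n_dots < props_b.n_dots:
        fewer, more = props_a, props_b
    else:
        fewer, more = props_b, props_a
    row = {"dot_ratio": fewer.n_dots / more.n_dots}
    for key, attr in _RATIO_FIELDS.items():
        num = getattr(fewer, attr)
        den = getattr(more, attr)
        row[key] = (np.nan if not np.isfinite(den) or den == 0
                    or not np.isfinite(num) else num / den)
    hashes = hashes or {}
    for key in ("hash_avg", "hash_perc", "hash_wav"):
        row[key] = hashes.get(key, np.nan)
    return row


# ---------------------------------------------------------------------------
# 64-bit perceptual hashes

def _to_gray(image) -> Image.Image:
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, np.ndarray):
        image = Image.fromarray(image)
    return image.convert("L")


def _resample(image, size: int) -> np.ndarray:
    """Area-average downsample to size x size, as float64."""
    img = _to_gray(image).resize((size, size), Image.Resampling.BOX)
    return np.asarray(img, dtype=float)


def _lower_median(values: np.ndarray) -> float:
    return float(np.sort(values, kind="stable")[(len(values) - 1) // 2])


def hash_avg(image) -> np.ndarray:
    """Average hash: 8x8 downsample, bit = pixel strictly above the mean."""
    px = _resample(image, 8)
    return (px > px.mean()).astype(np.uint8).ravel()


def hash_perceptual(image, literal_8x8: bool = False) -> np.ndarray:
    """Perceptual (DCT) hash: bit = low-frequency DCT coefficient above median.

    The image is downsampled to 32x32, a 2-D type-II DCT taken, and the
    top-left 8x8 low-frequency block thresholded at its (lower) median.
    ``literal_8x8`` instead applies the DCT directly to the 8x8 downsample,
    keeping all 64 coefficients.
    """
    size = 8 if literal_8x8 else 32
    px = _resample(image, size)
    coef = dctn(px, type=2, norm="ortho")[:8, :8].ravel()
    return (coef > _lower_median(coef)).astype(np.uint8)


def hash_wavelet(image) -> np.ndarray:
    """Wavelet hash: one-level 2-D Haar DWT of the 8x8 downsample.

    All 64 coefficients (approximation followed by the three 4x4 detail
    subbands) are thresholded at their lower median, so both the
    low-frequency structure and the high-frequency detail contribute bits.
    """
    px = _resample(image, 8)
    cA, (cH, cV, cD) = pywt.dwt2(px, "haar")
    coef = np.concatenate([c.ravel() for c in (cA, cH, cV, cD)])
    return (coef > _lower_median(coef)).astype(np.uint8)


def hamming(h1, h2) -> int:
    """Number of differing bits between two equal-length hash vectors."""
    h1 = np.asarray(h1).ravel()
    h2 = np.asarray(h2).ravel()
    if h1.shape != h2.shape:
        raise ValueError(f"hash length mismatch: {h1.size} vs {h2.size}")
    return int(np.count_nonzero(h1 != h2))


def hash_distances(image_a, image_b, literal_8x8: bool = False
                   ) -> dict[str, int]:
    """All three hash Hamming distances between two array images."""
    return {
        "hash_avg": hamming(hash_avg(image_a), hash_avg(image_b)),
        "hash_perc": hamming(hash_perceptual(image_a, literal_8x8),
                             hash_perceptual(image_b, literal_8x8)),
        "hash_wav": hamming(hash_wavelet(image_a), hash_wavelet(image_b)),
    }


# ---------------------------------------------------------------------------
# dataset-level driver

def _isolate_color(img: np.ndarray, seg: SegmentedArray, bg) -> np.ndarray:
    """Render one color-defined array alone on the shared background."""
    out = np.empty_like(img)
    out[:] = bg
    mask = seg.labels > 0
    out[mask] = img[mask]
    return out


def extract_dataset(stimlist: pd.DataFrame, pics_dir,
                    ddof: int = 0, literal_8x8: bool = False) -> pd.DataFrame:
    """Extract one feature row per stimulus-list row.

    Two-image stimuli are segmented per panel; mixed-color stimuli are
    segmented by color and their hash distances computed between the two
    color-isolated renderings.  A ``seg_mismatch`` column flags stimuli
    whose segmented counts disagree with the stimulus list.
    """
    pics_dir = Path(pics_dir)
    rows = []
    for rec in stimlist.itertuples(index=False):
        joint = getattr(rec, "file_joint", "") or ""
        if isinstance(joint, str) and joint:
            img = _as_array(pics_dir / joint)
            seg_a, seg_b = segment_colors(img)
            bg = _background_value(img)
            img_a = _isolate_color(img, seg_a, bg)
            img_b = _isolate_color(img, seg_b, bg)
        else:
            path_a, path_b = pics_dir / rec.file_a, pics_dir / rec.file_b
            for p in (path_a, path_b):
                if not p.exists():
                    raise FileNotFoundError(f"missing stimulus image: {p}")
            img_a, img_b = _as_array(path_a), _as_array(path_b)
            seg_a, seg_b = segment_panel(img_a), segment_panel(img_b)
        props_a, props_b = geometry(seg_a, ddof), geometry(seg_b, ddof)
        hashes = hash_distances(img_a, img_b, literal_8x8)
        row = {"STIMID": rec.STIMID}
        row.update(feature_vector(props_a, props_b, hashes))
        expected = {int(rec.n_a), int(rec.n_b)}
        observed = {seg_a.n, seg_b.n}
        row["seg_mismatch"] = expected != observed
        if row["seg_mismatch"]:
            warnings.warn(f"{rec.STIMID}: segmented counts {sorted(observed)} "
                          f"!= stimulus list {sorted(expected)}",
                          RuntimeWarning, stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["seg_mismatch"])
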