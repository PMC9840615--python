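"""Generation of dot-array numerosity-comparison stimuli.

Five stimulus-set designs are supported, mirroring the classic layouts of
large-scale numerosity-comparison batteries:

* ``D1`` — 120 side-by-side white-dot pairs, 5-32 dots, larger:smaller count
  ratio in [1.12, 2.00], half equal-total-area / half equal-mean-dot-area.
* ``D2`` — 36 white-dot pairs, 5-12 dots, count ratios 2:3 / 5:7 / 3:4,
  total-area ratios 2:1 / 1:1 / 1:2 (larger-count : smaller-count array),
  12 pairs per area condition.
* ``D3`` — 138 black-dot pairs presented sequentially, 7-14 dots, total-area
  ratios 2:3 / 1:1 / 3:2.
* ``D4`` — 100 single-panel stimuli mixing yellow and blue dots with no
  overlap, 5-16 dots per color, half equal-total / half equal-mean area.
* ``D5`` — 100 single-panel stimuli mixing red and blue dots, 5-16 dots per
  color, color-count ratios 1:2 / 2:3 / 3:4 / 5:6 / 7:8, total-area ratio
  close to 1:1.

Dots are hard discs placed by rejection sampling with a minimum boundary gap,
and rendered with center-in-disc rasterization (a pixel belongs to a dot iff
its integer-grid center lies inside the disc) so segmentation downstream is
unambiguous.  Because the area-control conditions are verified downstream on
*pixel* areas, each array's radii are rescaled after placement so that the
rasterized total pixel area matches the analytic target (see
:func:`calibrate_pixel_area`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Dot",
    "DotArray",
    "PairSpec",
    "StimulusPair",
    "GeometryConfig",
    "InfeasibleAreaError",
    "PlacementError",
    "solve_radii",
    "place_dots",
    "calibrate_pixel_area",
    "build_pair",
    "generate_dataset",
    "render",
    "render_dataset",
    "STYLES",
    "STIMLIST_COLUMNS",
]

STYLES = ("D1", "D2", "D3", "D4", "D5")

#: foreground colors (array_a, array_b) and background per style
STYLE_COLORS = {
    "D1": ("white", "white", "black"),
    "D2": ("white", "white", "black"),
    "D3": ("black", "black", "white"),
    "D4": ("yellow", "blue", "black"),
    "D5": ("red", "blue", "black"),
}

#: dot-count range (inclusive) per style
STYLE_COUNT_RANGE = {
    "D1": (5, 32),
    "D2": (5, 12),
    "D3": (7, 14),
    "D4": (5, 16),
    "D5": (5, 16),
}

#: styles whose two arrays share one panel (mixed colors)
JOINT_STYLES = frozenset({"D4", "D5"})

COLOR_RGB = {
    "white": (255, 255, 255),
    "black": (0, 0, 0),
    "yellow": (255, 255, 0),
    "blue": (0, 0, 255),
    "red": (255, 0, 0),
}

#: total-area ratio (larger-count array / smaller-count array) per condition;
#: None marks conditions resolved at build time.
AREA_CONDITIONS = {
    "equal_total": 1.0,
    "equal_mean": None,
    "area_ratio_2_1": 2.0,
    "area_ratio_1_1": 1.0,
    "area_ratio_1_2": 0.5,
    "area_ratio_2_3": 2.0 / 3.0,
    "area_ratio_3_2": 1.5,
    "approx_1_1": None,
}

STYLE_AREA_CONDITIONS = {
    "D1": ("equal_total", "equal_mean"),
    "D2": ("area_ratio_2_1", "area_ratio_1_1", "area_ratio_1_2"),
    "D3": ("area_ratio_2_3", "area_ratio_1_1", "area_ratio_3_2"),
    "D4": ("equal_total", "equal_mean"),
    "D5": ("approx_1_1",),
}

D5_COLOR_RATIOS = (Fraction(1, 2), Fraction(2, 3), Fraction(3, 4),
                   Fraction(5, 6), Fraction(7, 8))

STIMLIST_COLUMNS = ["STIMID", "style", "file_a", "file_b", "file_joint",
                    "n_a", "n_b", "area_condition", "seed"]


class InfeasibleAreaError(ValueError):
    """Raised when an area budget cannot accommodate the requested dots."""


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all dots."""


@dataclass(frozen=True)
class Dot:
    """One circular dot: continuous center (pixels, origin top-left), radius."""

    x: float
    y: float
    radius: float
    color: str = "white"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("dot radius must be positive")


@dataclass
class DotArray:
    """An ordered set of non-overlapping dots inside one panel."""

    dots: list[Dot]
    panel_width: int = 400
    panel_height: int = 400
    background: str = "black"

    @property
    def n(self) -> int:
        return len(self.dots)

    @property
    def centers(self) -> np.ndarray:
        return np.array([(d.x, d.y) for d in self.dots], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([d.radius for d in self.dots], dtype=float)

    @property
    def total_area(self) -> float:
        """Analytic total dot area, Σπr² (px²)."""
        return float(np.pi * np.sum(self.radii**2))

    @property
    def mean_area(self) -> float:
        return self.total_area / self.n

    def pixel_areas(self) -> np.ndarray:
        """Rasterized pixel count of each dot (center-in-disc rule)."""
        return np.array([disc_pixel_count(d.x, d.y, d.radius) for d in self.dots])

    def min_boundary_gap(self) -> float:
        """Smallest boundary-to-boundary distance over all dot pairs (inf if n<2)."""
        if self.n < 2:
            return math.inf
        c, r = self.centers, self.radii
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        gap = d - r[:, None] - r[None, :]
        iu = np.triu_indices(self.n, 1)
        return float(gap[iu].min())

    def check(self, min_gap: float = 0.0) -> None:
        if self.n >= 2 and self.min_boundary_gap() < min_gap - 1e-9:
            raise ValueError("dot discs overlap or violate min_gap")
        for d in self.dots:
            if not (d.radius <= d.x <= self.panel_width - 1 - d.radius
                    and d.radius <= d.y <= self.panel_height - 1 - d.radius):
                raise ValueError("dot disc extends outside panel")


@dataclass(frozen=True)
class PairSpec:
    """Design cell for one stimulus: style, counts, and area condition."""

    style: str
    n_small: int
    n_large: int
    area_condition: str
    stim_id: str = ""

    def __post_init__(self):
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}")
        if not (1 <= self.n_small <= self.n_large):
            raise ValueError("need 1 <= n_small <= n_large")
        lo, hi = STYLE_COUNT_RANGE[self.style]
        if not (lo <= self.n_small and self.n_large <= hi):
            raise ValueError(
                f"{self.style} dot counts must lie in [{lo}, {hi}]")
        if self.area_condition not in STYLE_AREA_CONDITIONS[self.style]:
            raise ValueError(
                f"{self.area_condition!r} not valid for {self.style}")
        ratio = self.n_large / self.n_small
        frac = Fraction(self.n_small, self.n_large)
        if self.style in ("D1", "D4") and not 1.12 <= ratio <= 2.00:
            raise ValueError(
                f"{self.style} count ratio {ratio:.3f} outside [1.12, 2.00]")
        if self.style == "D2" and frac not in (
                Fraction(2, 3), Fraction(5, 7), Fraction(3, 4)):
            raise ValueError("D2 count ratio must be 2:3, 5:7 or 3:4")
        if self.style == "D3" and self.n_small == self.n_large:
            raise ValueError("D3 requires distinct counts")
        if self.style == "D5" and frac not in D5_COLOR_RATIOS:
            raise ValueError("D5 color-count ratio must be one of "
                             "1:2, 2:3, 3:4, 5:6, 7:8")

    @property
    def dot_ratio(self) -> float:
        return self.n_small / self.n_large


@dataclass
class StimulusPair:
    """A built stimulus: spec plus the two realized arrays.

    ``array_a`` always holds the smaller-count array.  ``image_paths`` is
    filled by :func:`render`.
    """

    spec: PairSpec
    array_a: DotArray
    array_b: DotArray
    image_paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.array_a.n, self.array_b.n) != (self.spec.n_small, self.spec.n_large):
            raise ValueError("realized dot counts do not match spec")


@dataclass
class GeometryConfig:
    """Geometry defaults for stimulus construction.

    total_area is the analytic pixel-area budget of the reference array
    (the smaller-count array, or the larger-count array under equal_mean);
    only ratios between the two arrays matter downstream.  radius_margin is
    the fractional radius head-room reserved during placement so that the
    post-placement pixel-area calibration can scale radii up without
    creating overlap.
    """

    panel_width: int = 400
    panel_height: int = 400
    total_area: float = 8000.0
    min_gap: float = 2.0
    dispersion: float = 0.3
    min_radius: float = 2.0
    radius_margin: float = 0.15
    max_attempts: int = 10_000
    max_restarts: int = 20
    calibrate: bool = True
    area_rel_tol: float = 0.002


def solve_radii(n: int, total_area: float, dispersion: float = 0.0,
                rng: np.random.Generator | None = None,
                min_radius: float = 2.0) -> np.ndarray:
    """Radii of ``n`` discs with Σπr² = ``total_area`` exactly.

    Radii are jittered multiplicatively by ``dispersion`` (uniform factors in
    [1-dispersion, 1+dispersion]) and rescaled so the total analytic area is
    preserved to machine precision.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if not 0 <= dispersion < 1:
        raise ValueError("dispersion must lie in [0, 1)")
    base = math.sqrt(total_area / (n * math.pi))
    if base < min_radius:
        raise InfeasibleAreaError(
            f"total_area {total_area:g} too small for {n} dots at minimum "
            f"radius {min_radius:g}")
    if dispersion > 0:
        if rng is None:
            rng = np.random.default_rng()
        radii = base * (1.0 + dispersion * rng.uniform(-1.0, 1.0, size=n))
    else:
        radii = np.full(n, base)
    radii *= math.sqrt(total_area / (math.pi * float(np.sum(radii**2))))
    return radii


def place_dots(radii, panel: tuple[int, int] = (400, 400),
               min_gap: float = 2.0,
               rng: np.random.Generator | None = None,
               colors=None, background: str = "black",
               radius_margin: float = 0.0,
               max_attempts: int = 10_000,
               max_restarts: int = 20) -> DotArray:
    """Place discs by rejection sampling; no two discs closer than min_gap.

    Collision and panel-containment checks use inflated radii
    ``r * (1 + radius_margin)``, reserving room for later upscaling.
    Placement proceeds in descending radius order (easier packing) but the
    returned dot order matches the input order.
    """
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    if colors is None:
        colors = ["white"] * n
    if rng is None:
        rng = np.random.default_rng()
    w, h = panel
    eff = radii * (1.0 + radius_margin)
    order = np.argsort(-radii, kind="stable")
    for _restart in range(max_restarts):
        centers = np.empty((n, 2))
        attempts = 0
        failed = False
        for k, i in enumerate(order):
            re = eff[i]
            if re > (w - 1) / 2 or re > (h - 1) / 2:
                raise PlacementError(f"disc of radius {radii[i]:.1f} does not "
                                     f"fit in a {w}x{h} panel")
            while True:
                attempts += 1
                if attempts > max_attempts:
                    failed = True
                    break
                cx = rng.uniform(re, w - 1 - re)
                cy = rng.uniform(re, h - 1 - re)
                if k == 0:
                    break
                prev = order[:k]
                d = np.hypot(centers[prev, 0] - cx, centers[prev, 1] - cy)
                if np.all(d >= eff[prev] + re + min_gap):
                    break
            if failed:
                break
            centers[i] = (cx, cy)
        if not failed:
            dots = [Dot(centers[i, 0], centers[i, 1], radii[i], colors[i])
                    for i in range(n)]
            arr = DotArray(dots, w, h, background)
            arr.check(min_gap)
            return arr
    raise PlacementError(
        f"could not place {n} dots within {max_attempts} attempts per layout "
        f"({max_restarts} layout restarts)")


def disc_pixel_count(cx: float, cy: float, r: float) -> int:
    """Number of integer-grid pixels whose center lies in the disc."""
    x0, x1 = math.ceil(cx - r), math.floor(cx + r)
    y0, y1 = math.ceil(cy - r), math.floor(cy + r)
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    return int(np.count_nonzero(dx2[None, :] + dy2[:, None] <= r * r))


def calibrate_pixel_area(array: DotArray, target_area: float,
                         lo: float = 0.85, hi: float = 1.15,
                         iters: int = 45) -> DotArray:
    """Rescale all radii by one factor so Σ(pixel areas) ≈ ``target_area``.

    The rasterized total is a monotone step function of the scale factor;
    bisection finds the step closest to the target.  Placement must have
    reserved at least ``hi - 1`` fractional radius margin.
    """
    centers = array.centers
    radii = array.radii

    def total(s: float) -> int:
        return sum(disc_pixel_count(cx, cy, s * r)
                   for (cx, cy), r in zip(centers, radii))

    best_s, best_err = 1.0, abs(total(1.0) - target_area)
    a, b = lo, hi
    for _ in range(iters):
        mid = 0.5 * (a + b)
        t = total(mid)
        err = abs(t - target_area)
        if err < best_err:
            best_s, best_err = mid, err
        if t < target_area:
            a = mid
        else:
            b = mid
        if err == 0:
            break
    dots = [replace(d, radius=d.radius * best_s) for d in array.dots]
    return DotArray(dots, array.panel_width, array.panel_height,
                    array.background)


def _target_areas(spec: PairSpec, geometry: GeometryConfig,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Analytic total-area targets (smaller-count array, larger-count array)."""
    A = geometry.total_area
    cond = spec.area_condition
    if cond == "equal_total":
        return A, A
    if cond == "equal_mean":
        mean = A / spec.n_large
        return mean * spec.n_small, A
    if cond == "approx_1_1":
        return A, A * rng.uniform(0.96, 1.04)
    ratio = AREA_CONDITIONS[cond]  # larger-count / smaller-count
    return A, A * ratio


def build_pair(spec: PairSpec, geometry: GeometryConfig | None = None,
               rng: np.random.Generator | None = None) -> StimulusPair:
    """Realize one stimulus pair satisfying its spec's area condition.

    The two arrays either occupy separate panels (D1-D3) or share one panel
    with distinct colors (D4, D5).  After placement each array's radii are
    rescaled so its rasterized pixel area hits the analytic target
    (``geometry.calibrate``), keeping extractor-measured area ratios within
    ``geometry.area_rel_tol`` of the design value.
    """
    if geometry is None:
        geometry = GeometryConfig()
    if rng is None:
        rng = np.random.default_rng()
    color_a, color_b, background = STYLE_COLORS[spec.style]
    area_a, area_b = _target_areas(spec, geometry, rng)
    radii_a = solve_radii(spec.n_small, area_a, geometry.dispersion, rng,
                          geometry.min_radius)
    radii_b = solve_radii(spec.n_large, area_b, geometry.dispersion, rng,
                          geometry.min_radius)
    panel = (geometry.panel_width, geometry.panel_height)
    common = dict(panel=panel, min_gap=geometry.min_gap, rng=rng,
                  background=background,
                  radius_margin=geometry.radius_margin,
                  max_attempts=geometry.max_attempts,
                  max_restarts=geometry.max_restarts)
    if spec.style in JOINT_STYLES:
        radii = np.concatenate([radii_a, radii_b])
        colors = [color_a] * spec.n_small + [color_b] * spec.n_large
        joint = place_dots(radii, colors=colors, **common)
        arr_a = DotArray(joint.dots[:spec.n_small], *panel, background)
        arr_b = DotArray(joint.dots[spec.n_small:], *panel, background)
    else:
        arr_a = place_dots(radii_a, colors=[color_a] * spec.n_small, **common)
        arr_b = place_dots(radii_b, colors=[color_b] * spec.n_large, **common)
    if geometry.calibrate:
        hi = 1.0 + geometry.radius_margin
        arr_a = calibrate_pixel_area(arr_a, area_a, lo=2.0 - hi, hi=hi)
        arr_b = calibrate_pixel_area(arr_b, area_b, lo=2.0 - hi, hi=hi)
        for arr, target in ((arr_a, area_a), (arr_b, area_b)):
            realized = arr.pixel_areas().sum()
            if abs(realized / target - 1.0) > geometry.area_rel_tol:
                raise PlacementError(
                    f"pixel-area calibration missed target by "
                    f"{abs(realized / target - 1.0):.2%} for {spec.stim_id}")
    pair = StimulusPair(spec, arr_a, arr_b)
    if spec.style in JOINT_STYLES:
        # re-verify joint no-overlap after calibration
        DotArray(arr_a.dots + arr_b.dots, *panel, background).check(
            geometry.min_gap)
    return pair


# ---------------------------------------------------------------------------
# dataset designs

def _count_grid(lo: int, hi: int, rmin: float, rmax: float):
    return [(ns, nl) for ns in range(lo, hi + 1)
            for nl in range(ns + 1, hi + 1) if rmin <= nl / ns <= rmax]


def _specs_d1(rng) -> list[PairSpec]:
    grid = _count_grid(5, 32, 1.12, 2.00)
    idx = rng.integers(0, len(grid), size=120)
    conds = ["equal_total"] * 60 + ["equal_mean"] * 60
    return [PairSpec("D1", *grid[i], cond, f"D1_{k + 1:03d}")
            for k, (i, cond) in enumerate(zip(idx, conds))]


def _specs_d2(rng) -> list[PairSpec]:
    by_ratio = {
        Fraction(2, 3): [(6, 9), (8, 12)],
        Fraction(5, 7): [(5, 7)],
        Fraction(3, 4): [(6, 8), (9, 12)],
    }
    specs, k = [], 0
    for cond in STYLE_AREA_CONDITIONS["D2"]:
        for ratio, options in by_ratio.items():
            for j in range(4):  # 3 ratios x 4 = 12 pairs per area condition
                ns, nl = options[j % len(options)]
                k += 1
                specs.append(PairSpec("D2", ns, nl, cond, f"D2_{k:03d}"))
    return specs


def _specs_d3(rng) -> list[PairSpec]:
    combos = [(ns, nl) for ns in range(7, 15) for nl in range(ns + 1, 15)]
    specs, k = [], 0
    for cond in STYLE_AREA_CONDITIONS["D3"]:
        picks = list(rng.permutation(len(combos)))
        picks += list(rng.integers(0, len(combos), size=46 - len(combos)))
        for i in picks:
            ns, nl = combos[i]
            k += 1
            specs.append(PairSpec("D3", ns, nl, cond, f"D3_{k:03d}"))
    return specs


def _specs_d4(rng) -> list[PairSpec]:
    grid = _count_grid(5, 16, 1.12, 2.00)
    idx = rng.integers(0, len(grid), size=100)
    conds = ["equal_total"] * 50 + ["equal_mean"] * 50
    return [PairSpec("D4", *grid[i], cond, f"D4_{k + 1:03d}")
            for k, (i, cond) in enumerate(zip(idx, conds))]


def _specs_d5(rng) -> list[PairSpec]:
    by_ratio = {
        Fraction(1, 2): [(5, 10), (6, 12), (7, 14), (8, 16)],
        Fraction(2, 3): [(6, 9), (8, 12), (10, 15)],
        Fraction(3, 4): [(6, 8), (9, 12), (12, 16)],
        Fraction(5, 6): [(5, 6), (10, 12)],
        Fraction(7, 8): [(7, 8), (14, 16)],
    }
    specs, k = [], 0
    for ratio, options in by_ratio.items():
        for j in range(20):  # 5 ratios x 20 = 100 stimuli
            ns, nl = options[j % len(options)]
            k += 1
            specs.append(PairSpec("D5", ns, nl, "approx_1_1", f"D5_{k:03d}"))
    return specs


_SPEC_BUILDERS = {"D1": _specs_d1, "D2": _specs_d2, "D3": _specs_d3,
                  "D4": _specs_d4, "D5": _specs_d5}


def dataset_specs(style: str, seed: int | np.random.Generator) -> list[PairSpec]:
    """The design table (counts, ratios, area conditions) for one style."""
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return _SPEC_BUILDERS[style](rng)


def generate_dataset(style: str, seed: int,
                     geometry: GeometryConfig | None = None
                     ) -> list[StimulusPair]:
    """Generate the full stimulus set of one style, deterministically."""
    rng = np.random.default_rng(seed)
    specs = dataset_specs(style, rng)
    return [build_pair(spec, geometry, rng) for spec in specs]


# ---------------------------------------------------------------------------
# rendering

def _render_arrays(arrays, panel_width, panel_height, background) -> Image.Image:
    """Rasterize dot arrays into one image (center-in-disc rule, no AA)."""
    colors = {d.color for a in arrays for d in a.dots} | {background}
    mono = colors <= {"white", "black"}
    bg = COLOR_RGB[background]
    if mono:
        img = np.full((panel_height, panel_width), bg[0], dtype=np.uint8)
    else:
        img = np.zeros((panel_height, panel_width, 3), dtype=np.uint8)
        img[:] = bg
    for arr in arrays:
        for d in arr.dots:
            x0, x1 = math.ceil(d.x - d.radius), math.floor(d.x + d.radius)
            y0, y1 = math.ceil(d.y - d.radius), math.floor(d.y + d.radius)
            xs = np.arange(x0, x1 + 1)
            ys = np.arange(y0, y1 + 1)
            mask = ((xs[None, :] - d.x) ** 2 + (ys[:, None] - d.y) ** 2
                    <= d.radius**2)
            block = img[y0:y1 + 1, x0:x1 + 1]
            fg = COLOR_RGB[d.color]
            block[mask] = fg[0] if mono else fg
    return Image.fromarray(img)


def render(pair: StimulusPair, out_dir) -> dict[str, str]:
    """Write the stimulus to PNG files; returns {role: filename}.

    Two-array styles (D1-D3) get one image per panel (``file_a`` holds the
    smaller-count array); mixed-color styles (D4, D5) get one joint image.
    Filenames are relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = pair.spec
    w, h = pair.array_a.panel_width, pair.array_a.panel_height
    bg = STYLE_COLORS[spec.style][2]
    paths: dict[str, str] = {}
    if spec.style in JOINT_STYLES:
        name = f"{spec.stim_id}.png"
        _render_arrays([pair.array_a, pair.array_b], w, h, bg).save(
            out_dir / name)
        paths["file_joint"] = name
    else:
        for role, arr in (("file_a", pair.array_a), ("file_b", pair.array_b)):
            name = f"{spec.stim_id}_{role[-1]}.png"
            _render_arrays([arr], w, h, bg).save(out_dir / name)
            paths[role] = name
    pair.image_paths = paths
    return paths


def render_dataset(pairs: list[StimulusPair], out_dir,
                   seed: int | None = None) -> pd.DataFrame:
    """Render all pairs and return the stimulus-list table.

    The table's file columns hold filenames relative to ``out_dir``;
    one-image styles leave ``file_a``/``file_b`` empty, two-image styles
    leave ``file_joint`` empty.
    """
    rows = []
    for pair in pairs:
        paths = render(pair, out_dir)
        rows.append({
            "STIMID": pair.spec.stim_id,
            "style": pair.spec.style,
            "file_a": paths.get("file_a", ""),
            "file_b": paths.get("file_b", ""),
            "file_joint": paths.get("file_joint", ""),
            "n_a": pair.spec.n_small,
            "n_b": pair.spec.n_large,
            "area_condition": pair.spec.area_condition,
            "seed": seed if seed is not None else "",
        })
    return pd.DataFrame(rows, columns=STIMLIST_COLUMNS)
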