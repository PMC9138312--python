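"""Synthetic AFM height-map generation for fibril populations.

Renders a :class:`~fibrilfrag.simulate.FibrilPopulation` as an AFM-like
topography frame: each fibril is deposited as a discrete worm-like chain
on the mica-like field, painted as a ridge with Gaussian cross-section
(emulating probe-tip dilation), overlaid with per-scan-line tilt, a
frame-level bow, and pixel noise. The output is what the quantification
stage consumes, so the tracing/measurement code is testable without a
microscope.

Conventions: heights in nm; planar coordinates in nm with the origin at
the centre of the top-left pixel, x along scan lines (columns), y down
rows; pixel indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.spatial import cKDTree

from .simulate import FibrilPopulation

__all__ = [
    "RenderConfig",
    "PlanarContour",
    "HeightMap",
    "lay_contours",
    "render_heightmap",
    "wormlike_chain_r2",
    "write_heightmap",
    "read_heightmap",
]


@dataclass(frozen=True)
class RenderConfig:
    """Geometry, optics and noise of a synthetic AFM frame.

    ``background_coeffs`` is ``(line_offset_sd, line_tilt_sd, bow_amp)``
    in nm: each scan line receives a random constant offset and a random
    linear tilt across the frame, and the whole frame a quadratic bow of
    amplitude ``bow_amp`` at the centre — the minimal scanner background
    that makes flattening non-trivial.
    """

    image_px: int = 2048
    scan_size: float = 10_000.0          # nm per side
    ridge_width_sigma: float = 6.0       # nm; Gaussian cross-section std
    noise_sd: float = 0.15               # nm
    background_coeffs: tuple[float, float, float] = (2.0, 1.0, 5.0)
    persistence_length: float = 2000.0   # nm
    clustering_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.image_px < 64:
            raise ValueError("image_px must be >= 64")
        if self.scan_size <= 0:
            raise ValueError("scan_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.clustering_strength < 0:
            raise ValueError("clustering_strength must be >= 0")

    @property
    def pixel_size(self) -> float:
        return self.scan_size / self.image_px


@dataclass
class PlanarContour:
    """Backbone polyline of one deposited fibril.

    ``points`` is an (n, 2) array of (x, y) nm coordinates with
    consecutive spacing <= pixel_size/2; arc length equals the source
    fibril's length by construction. ``height`` is the ridge peak height.
    """

    points: np.ndarray
    height: float
    source_index: int = -1

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def end_to_end(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))


@dataclass
class HeightMap:
    """2D topography frame: heights (nm) on a square pixel grid."""

    heights: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite everywhere")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


def wormlike_chain_r2(L: float, persistence_length: float) -> float:
    """Closed-form mean squared end-to-end distance of the 2D chain model.

    For planar heading diffusion with tangent correlation length
    P = 2 * persistence_length:  <R^2> = 2 P L (1 - (P/L)(1 - exp(-L/P))).
    """
    P = 2.0 * persistence_length
    return 2.0 * P * L * (1.0 - (P / L) * (1.0 - np.exp(-L / P)))


def _sample_chain(L: float, step: float, lp: float, rng: np.random.Generator) -> np.ndarray:
    """Discrete worm-like chain of total arc length L, centred on origin."""
    n = max(1, int(np.ceil(L / step)))
    ds = L / n
    dtheta = rng.normal(0.0, np.sqrt(ds / lp), size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(dtheta) - dtheta[0]
    steps = np.column_stack([np.cos(theta), np.sin(theta)]) * ds
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts - pts.mean(axis=0)


def lay_contours(
    pop: FibrilPopulation,
    config: RenderConfig,
    seed: int = 0,
    min_separation: float = 0.0,
    deposition_margin: float = 0.0,
    max_tries: int = 200,
) -> list[PlanarContour]:
    """Deposit each fibril as a worm-like chain placed in the field.

    Segment headings follow a Gaussian random walk with per-step variance
    ``step / persistence_length``; placement is uniform. With the default
    ``deposition_margin = 0`` every fibril is placed fully inside the
    frame (with a small margin). With ``deposition_margin`` > 0, centres
    are drawn uniformly over the frame extended by that many nm on every
    side, so long fibrils genuinely cross the frame edge with the
    length-dependent probability that the edge-exclusion bias correction
    undoes — set it to at least half the longest fibril's length to
    emulate deposition from a large surface.

    With ``clustering_strength`` > 0, fibrils are preferentially dropped
    near previously placed ones, emulating the clustering tendency of
    sticky polymorphs. With ``min_separation`` > 0, placements closer
    than that distance (nm) to an existing contour are rejected and
    retried — useful for generating deliberately isolated scenes.

    Raises
    ------
    ValueError
        If a fibril is longer than the field diagonal (cannot fit when
        ``deposition_margin`` is 0), or no admissible placement is found
        in ``max_tries`` attempts.
    """
    rng = np.random.default_rng(seed)
    S = config.scan_size
    margin = 3.0 * config.ridge_width_sigma + config.pixel_size
    diag = np.sqrt(2.0) * S
    step = config.pixel_size / 2.0
    m = float(deposition_margin)
    contours: list[PlanarContour] = []
    placed_tree: cKDTree | None = None
    placed_pts: list[np.ndarray] = []

    for i, (L, h) in enumerate(zip(pop.lengths, pop.heights)):
        if m == 0 and L > diag:
            raise ValueError(
                f"fibril {i} (length {L:.0f} nm) exceeds the field diagonal {diag:.0f} nm"
            )
        ok = False
        for _ in range(max_tries):
            rel = _sample_chain(float(L), step, config.persistence_length, rng)
            lo = rel.min(axis=0)
            hi = rel.max(axis=0)
            if m == 0 and np.any(hi - lo > S - 2 * margin):
                continue  # conformation does not fit; redraw
            cluster = (
                placed_pts
                and rng.uniform() < config.clustering_strength / (1.0 + config.clustering_strength)
            )
            if cluster:
                anchor = placed_pts[rng.integers(len(placed_pts))]
                centre = anchor[rng.integers(anchor.shape[0])] + rng.normal(0, S / 40.0, 2)
            else:
                centre = rng.uniform(-m + (margin if m == 0 else 0.0),
                                     S + m - (margin if m == 0 else 0.0), size=2)
            offset = centre - (lo + hi) / 2.0
            pts = rel + offset
            if m == 0 and (np.any(pts < margin) or np.any(pts > S - margin)):
                continue
            if min_separation > 0 and placed_tree is not None:
                d, _ = placed_tree.query(pts, k=1)
                if np.min(d) < min_separation:
                    continue
            ok = True
            break
        if not ok:
            raise ValueError(f"could not place fibril {i} (length {L:.0f} nm) in the field")
        contours.append(PlanarContour(points=pts, height=float(h), source_index=i))
        placed_pts.append(pts)
        if min_separation > 0:
            placed_tree = cKDTree(np.vstack(placed_pts))
    return contours


def render_heightmap(
    contours: list[PlanarContour],
    config: RenderConfig,
    seed: int = 0,
) -> HeightMap:
    """Rasterise contours into an AFM-like height map.

    Each contour is painted as a ridge with Gaussian cross-section (peak =
    its assigned height, lateral std ``ridge_width_sigma``); overlapping
    ridges combine by per-pixel maximum, as AFM topography records the top
    surface rather than cumulative material. Scanner background (per-line
    tilt, frame bow) and i.i.d. Gaussian pixel noise are then added.
    """
    rng = np.random.default_rng(seed)
    n = config.image_px
    px = config.pixel_size
    sigma = config.ridge_width_sigma
    canvas = np.zeros((n, n))

    reach = 3.5 * sigma
    fine = min(px, sigma) / 4.0
    for c in contours:
        pts = _resample_polyline(c.points, fine)
        lo = np.floor((pts.min(axis=0) - reach) / px).astype(int)
        hi = np.ceil((pts.max(axis=0) + reach) / px).astype(int)
        if np.any(hi < 0) or np.any(lo > n - 1):
            continue  # fibril entirely outside the frame
        c0, r0 = np.clip(lo, 0, n - 1)
        c1, r1 = np.clip(hi, 0, n - 1)
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        gx, gy = np.meshgrid(cols * px, rows * px)
        tree = cKDTree(pts)
        d, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), k=1,
                          distance_upper_bound=reach)
        ridge = np.where(np.isfinite(d), c.height * np.exp(-d**2 / (2 * sigma**2)), 0.0)
        block = canvas[r0:r1 + 1, c0:c1 + 1]
        np.maximum(block, ridge.reshape(gy.shape), out=block)

    off_sd, tilt_sd, bow = config.background_coeffs
    u = np.linspace(0.0, 1.0, n)
    if off_sd > 0:
        canvas += rng.normal(0.0, off_sd, size=(n, 1))
    if tilt_sd > 0:
        canvas += rng.normal(0.0, tilt_sd, size=(n, 1)) * (u[None, :] - 0.5)
    if bow != 0:
        canvas += bow * 4.0 * u[None, :] * (1.0 - u[None, :])
    if config.noise_sd > 0:
        canvas += rng.normal(0.0, config.noise_sd, size=(n, n))

    meta = {"seed": seed, "config": asdict(config)}
    return HeightMap(heights=canvas, pixel_size=px, meta=meta)


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing (endpoints kept)."""
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1]
    m = max(2, int(np.ceil(total / spacing)) + 1)
    si = np.linspace(0.0, total, m)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# I/O: 32-bit float single-page TIFF + JSON sidecar, or plain matrix text.

def write_heightmap(hmap: HeightMap, path) -> None:
    """Write a float32 TIFF of heights (nm) plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, hmap.heights.astype(np.float32))
    sidecar = {"pixel_size_nm": hmap.pixel_size, **_jsonable(hmap.meta)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_heightmap(path, pixel_size: float | None = None) -> HeightMap:
    """Read a TIFF or whitespace-delimited matrix text height map.

    ``pixel_size`` (nm/px) is taken from the JSON sidecar when present,
    otherwise it must be given explicitly.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = pixel_size or meta.get("pixel_size_nm")
    if pixel_size is None:
        raise ValueError("pixel_size not given and no JSON sidecar found")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.loadtxt(path)
    return HeightMap(heights=np.asarray(data, dtype=float), pixel_size=float(pixel_size), meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
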