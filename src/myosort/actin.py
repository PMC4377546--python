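"""Digitized actin meshworks: synthetic keratocyte-like skeletons, per-pixel
filament orientation, outward polarity fields, and mesh-size estimation.

The lamellipodium of a fish keratocyte is a dense quasi-2D actin network in
which Arp2/3 branching orients filaments near +/-35 degrees about the axis
pointing toward the leading edge, with a mean mesh (pore) size of ~30 nm.
Here such a network is represented as a binary raster skeleton (every skeleton
pixel is a candidate motor binding site) together with a per-pixel filament
orientation (defined modulo 180 degrees), an outward polarity field, and a
mesh-size estimate obtained from the distance transform of the pores.

Coordinate convention: image axis 0 is y (rows), axis 1 is x (columns); the
outward polarity axis points along +x and orientation angles are measured in
degrees from the +x axis toward +y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import skeletonize
from skimage.transform import rescale


@dataclass
class ActinNetwork:
    """Raster skeleton of binding sites with orientation and polarity fields.

    ``orientation`` is in degrees modulo 180, NaN off the skeleton and on
    excluded pixels; ``polarity`` is a (H, W, 2) array of outward unit vectors
    (x, y components); ``excluded`` flags skeleton pixels whose local line fit
    was too poor to define an orientation.
    """

    skeleton: np.ndarray
    pixel_size: float
    orientation: np.ndarray | None = None
    polarity: np.ndarray | None = None
    excluded: np.ndarray | None = None
    mesh_size: float | None = None
    seed: int | None = None
    _points_nm: np.ndarray | None = field(default=None, repr=False)
    _kdtree: object = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.skeleton.shape

    def skeleton_points_nm(self) -> np.ndarray:
        """(N, 2) array of skeleton pixel centres in nm, columns (x, y)."""
        if self._points_nm is None:
            rows, cols = np.nonzero(self.skeleton)
            self._points_nm = np.column_stack([cols, rows]).astype(float) \
                * self.pixel_size
        return self._points_nm

    def kdtree(self):
        """KD-tree over the skeleton points (nm), built lazily."""
        if self._kdtree is None:
            from scipy.spatial import cKDTree
            self._kdtree = cKDTree(self.skeleton_points_nm())
        return self._kdtree

    def pixel_index(self, xy_nm) -> tuple[int, int]:
        """(row, col) of the pixel containing a point given in nm."""
        col = int(round(xy_nm[0] / self.pixel_size))
        row = int(round(xy_nm[1] / self.pixel_size))
        row = min(max(row, 0), self.skeleton.shape[0] - 1)
        col = min(max(col, 0), self.skeleton.shape[1] - 1)
        return row, col


def orientation_field(skeleton: np.ndarray, box: int = 7,
                      r2_min: float = 0.25):
    """Per-pixel filament orientation by local total-least-squares line fits.

    A ``box`` x ``box`` window (truncated at image borders) is centred on each
    skeleton pixel and a line is fitted to the skeleton pixels inside it by
    total least squares (principal axis of the pixel-coordinate covariance;
    perpendicular residuals, so vertical filaments are handled).  The angle is
    the direction of the principal axis, modulo 180 degrees.  The fit quality
    ``R^2 = 1 - lambda_min/lambda_max`` is 1 for a perfect line and 0 for an
    isotropic blob; pixels with ``R^2 < r2_min`` (or fewer than 3 neighbours)
    are flagged excluded.

    Returns
    -------
    orientation : float array, degrees in [0, 180), NaN where undefined
    excluded : bool array (on-skeleton pixels with a poor fit)
    excluded_fraction : float
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("skeleton is empty")
    h, w = skeleton.shape
    m = skeleton.astype(float)
    ys, xs = np.mgrid[0:h, 0:w].astype(float)

    def boxsum(a):
        return ndimage.uniform_filter(a, size=box, mode="constant", cval=0.0) \
            * box * box

    n = boxsum(m)
    sx = boxsum(m * xs)
    sy = boxsum(m * ys)
    sxx = boxsum(m * xs * xs)
    syy = boxsum(m * ys * ys)
    sxy = boxsum(m * xs * ys)

    with np.errstate(invalid="ignore", divide="ignore"):
        mx, my = sx / n, sy / n
        cxx = sxx / n - mx * mx
        cyy = syy / n - my * my
        cxy = sxy / n - mx * my
        tr = cxx + cyy
        disc = np.sqrt(np.maximum((cxx - cyy) ** 2 + 4 * cxy ** 2, 0.0))
        lam1 = 0.5 * (tr + disc)
        lam2 = 0.5 * (tr - disc)
        angle = 0.5 * np.degrees(np.arctan2(2 * cxy, cxx - cyy))
        r2 = np.where(lam1 > 0, 1.0 - np.maximum(lam2, 0.0) / lam1, 0.0)

    good = skeleton & (n >= 3) & (lam1 > 1e-12) & (r2 >= r2_min)
    excluded = skeleton & ~good
    orientation = np.full((h, w), np.nan)
    orientation[good] = np.mod(angle[good], 180.0)
    excluded_fraction = float(excluded.sum() / skeleton.sum())
    if not good.any():
        raise ValueError("all skeleton pixels were excluded by the fit")
    return orientation, excluded, excluded_fraction


def _draw_line_family(canvas: np.ndarray, angle_deg: float, spacing_px: float,
                      rng: np.random.Generator, jitter_frac: float = 0.15,
                      gap_prob: float = 0.0) -> None:
    """Rasterize a family of parallel lines at ``angle_deg`` from +x."""
    h, w = canvas.shape
    theta = np.radians(angle_deg)
    d = np.array([np.cos(theta), np.sin(theta)])   # along-line direction (x, y)
    nvec = np.array([-d[1], d[0]])                 # unit normal
    diag = float(np.hypot(h, w))
    centre = np.array([w / 2.0, h / 2.0])
    n_lines = int(np.ceil(diag / spacing_px)) + 2
    length = diag
    ts = np.linspace(-length / 2.0, length / 2.0, int(2 * length) + 1)
    for k in range(-n_lines, n_lines + 1):
        if gap_prob and rng.random() < gap_prob:
            continue
        c = k * spacing_px + rng.normal(0.0, jitter_frac * spacing_px)
        pts = centre + c * nvec + ts[:, None] * d
        cols = np.round(pts[:, 0]).astype(int)
        rows = np.round(pts[:, 1]).astype(int)
        keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        canvas[rows[keep], cols[keep]] = True


def _radial_polarity(shape: tuple[int, int]) -> np.ndarray:
    """Uniform outward polarity field along +x (toward the leading edge)."""
    pol = np.zeros(shape + (2,))
    pol[..., 0] = 1.0
    return pol


def generate_network(width: float, height: float, pixel_size: float = 2.4,
                     mesh_size: float = 30.0, branch_angle: float = 35.0,
                     seed=None, jitter_frac: float = 0.08) -> ActinNetwork:
    """Build a synthetic keratocyte-like actin skeleton.

    Two interlaced families of filaments oriented at ``+/-branch_angle`` about
    the outward (+x) polarity axis are rasterized with perpendicular spacing
    of one ``mesh_size`` (the rhombic cells then have an inscribed-pore
    diameter of one mesh size), with Gaussian jitter on the line offsets.
    The spacing carries a one-pixel compensation for the finite rasterized
    filament width, so the distance-transform mesh estimator recovers the
    requested mesh size.  The polarity field points uniformly toward the
    leading edge at +x.

    Parameters are in nm.  Requires ``mesh_size >= 3 * pixel_size`` so pores
    are resolvable on the raster.
    """
    if mesh_size < 3 * pixel_size:
        raise ValueError("unsatisfiable geometry: mesh_size must be at least "
                         "3 pixels wide")
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    rng = np.random.default_rng(seed)
    h = int(round(height / pixel_size))
    w = int(round(width / pixel_size))
    canvas = np.zeros((h, w), dtype=bool)
    spacing_px = mesh_size / pixel_size + 1.0  # finite filament width
    for angle in (branch_angle, -branch_angle):
        _draw_line_family(canvas, angle, spacing_px, rng,
                          jitter_frac=jitter_frac)
    canvas = skeletonize(canvas)
    net = ActinNetwork(skeleton=canvas, pixel_size=pixel_size,
                       polarity=_radial_polarity(canvas.shape),
                       seed=seed if isinstance(seed, int) else None)
    net.orientation, net.excluded, _ = orientation_field(canvas)
    net.mesh_size = mean_mesh_size(net)
    return net


def mean_mesh_size(network: ActinNetwork, min_distance_px: int = 2) -> float:
    """Mean pore diameter from the distance transform of the pores.

    The Euclidean distance from every non-skeleton pixel to the nearest
    skeleton pixel is computed; local maxima of this map (pore centres) are
    found and the estimate is twice their mean distance, i.e. the mean
    inscribed-pore diameter, in nm.  A border margin of one mesh estimate is
    ignored to avoid open boundary pores.
    """
    skel = np.asarray(network.skeleton, dtype=bool)
    if not skel.any():
        raise ValueError("skeleton is empty")
    dist = ndimage.distance_transform_edt(~skel)
    border = max(int(np.ceil(dist.max())) + 1, min_distance_px + 1)
    if 2 * border >= min(skel.shape):
        border = 0
    peaks = peak_local_max(dist, min_distance=min_distance_px,
                           exclude_border=border, threshold_abs=0.5)
    if peaks.shape[0] == 0:
        raise ValueError("no pores found; degenerate skeleton")
    radii = dist[peaks[:, 0], peaks[:, 1]]
    return float(2.0 * radii.mean() * network.pixel_size)


def scale_network(network: ActinNetwork, factor: float) -> ActinNetwork:
    """Geometrically rescale the skeleton; the mesh size scales by ``factor``.

    The binary skeleton is rescaled as an image (linear interpolation, then
    re-thinned to single-pixel width); pixel size is unchanged, so a factor
    below 1 shrinks the pores.  Orientation, polarity and mesh estimate are
    recomputed on the rescaled raster.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1.0:
        scaled = network.skeleton.copy()
    else:
        img = rescale(network.skeleton.astype(float), factor, order=1,
                      anti_aliasing=factor < 1)
        scaled = skeletonize(img > 0.2)
    net = ActinNetwork(skeleton=scaled, pixel_size=network.pixel_size,
                       polarity=_radial_polarity(scaled.shape),
                       seed=network.seed)
    net.orientation, net.excluded, _ = orientation_field(scaled)
    net.mesh_size = mean_mesh_size(net)
    return net


def save_network(network: ActinNetwork, prefix: str) -> None:
    """Write ``<prefix>.tif`` (binary skeleton) and ``<prefix>.json`` sidecar."""
    tifffile.imwrite(f"{prefix}.tif",
                     network.skeleton.astype(np.uint8) * 255)
    meta = {"pixel_size_nm": network.pixel_size,
            "mesh_size_nm": network.mesh_size,
            "leading_edge": "+x",
            "seed": network.seed}
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_network(prefix: str) -> ActinNetwork:
    """Load a network bundle written by :func:`save_network`."""
    skel = tifffile.imread(f"{prefix}.tif") > 0
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    net = ActinNetwork(skeleton=skel, pixel_size=float(meta["pixel_size_nm"]),
                       polarity=_radial_polarity(skel.shape),
                       mesh_size=meta.get("mesh_size_nm"),
                       seed=meta.get("seed"))
    net.orientation, net.excluded, _ = orientation_field(skel)
    return net
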