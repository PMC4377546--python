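"""Synthetic inputs: lamellipodium-like cell geometries and motor-scaffold
trajectories with a specified directional flux and speeds.

The generator emulates the observable structure of scaffold movement on a
keratocyte: each track commits to a single direction (strictly
unidirectional, drawn outward with probability ``phi_out``), moves at a
roughly constant speed along the local polarity direction, and is blurred by
Gaussian localization noise.  Tracks are sampled at 2 Hz (0.5 s frame
interval).  The module's contract is parameter recovery: the analysis
pipeline applied to its output re-estimates the flux, speeds and filter pass
rates it was given.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .stats import as_rng
from .tracks import CellGeometry, Trajectory, save_tracks_csv


@dataclass(frozen=True)
class TrajectoryGenSpec:
    """Parameters of the synthetic track generator.

    Speeds default to the measured 1V:1VI scaffold values (outward 162 nm/s,
    inward 66 nm/s); ``localization_sd`` is the per-frame isotropic Gaussian
    localization error and ``speed_jitter_cv`` the per-track relative spread
    of the speed.
    """

    n_tracks: int = 200
    phi_out: float = 0.52
    speed_out: float = 162.0
    speed_in: float = 66.0
    frame_interval: float = 0.5
    duration_range: tuple[float, float] = (5.0, 60.0)
    localization_sd: float = 15.0
    speed_jitter_cv: float = 0.1
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_out <= 1.0:
            raise ValueError("phi_out must be in [0, 1]")
        if self.speed_out <= 0 or self.speed_in <= 0:
            raise ValueError("speeds must be positive")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")


def generate_geometry(width: float = 30000.0, height: float = 10000.0,
                      seed=None, n_vertices: int = 64) -> CellGeometry:
    """Elliptical lamellipodium-like cell outline (dimensions in nm).

    The default emulates the ~30 um x ~10 um spread keratocyte lamellipodium;
    the outward polarity field is radial from the centre, i.e. normal to the
    (convex) leading edge.
    """
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    rng = as_rng(seed)
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r_jit = 1.0 + 0.02 * rng.standard_normal(n_vertices)
    xs = 0.5 * width * np.cos(ang) * r_jit
    ys = 0.5 * height * np.sin(ang) * r_jit
    centre = np.array([0.0, 0.0])
    return CellGeometry(boundary=Polygon(np.column_stack([xs, ys])),
                        center=centre)


def _sample_point_inside(geometry: CellGeometry, rng, margin: float,
                         max_tries: int = 10000) -> np.ndarray:
    minx, miny, maxx, maxy = geometry.boundary.bounds
    inner = geometry.boundary.buffer(-margin)
    if inner.is_empty:
        inner = geometry.boundary
    for _ in range(max_tries):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if inner.contains(Point(p)) and np.linalg.norm(p - geometry.center) > margin / 4:
            return p
    raise RuntimeError("could not sample a start point inside the cell")


def generate_trajectories(spec: TrajectoryGenSpec, geometry: CellGeometry,
                          rng=None) -> list[Trajectory]:
    """Draw unidirectional tracks with Bernoulli(``phi_out``) direction.

    Each track starts inside the cell, walks along +/- the local polarity
    direction at a per-track constant speed (Gaussian-jittered around
    ``speed_out`` or ``speed_in``), and is truncated before it would leave
    the cell; independent localization noise is added to every sample.
    """
    rng = as_rng(rng if rng is not None else spec.seed)
    tracks = []
    margin = 4 * spec.localization_sd + 50.0
    for i in range(spec.n_tracks):
        outward = rng.random() < spec.phi_out
        base = spec.speed_out if outward else spec.speed_in
        speed = max(base * (1 + spec.speed_jitter_cv * rng.standard_normal()),
                    0.1 * base)
        duration = rng.uniform(*spec.duration_range)
        n = max(int(np.floor(duration / spec.frame_interval)) + 1, 2)
        start = _sample_point_inside(geometry, rng, margin)
        u = geometry.polarity(start) * (1 if outward else -1)
        t = np.arange(n) * spec.frame_interval
        path = start[None, :] + np.outer(t * speed, u)
        inner = geometry.boundary.buffer(-margin)
        inside = np.array([inner.contains(Point(p)) for p in path])
        if not inside.all():
            cut = int(np.argmin(inside))
            if cut < 2:
                continue
            path, t = path[:cut], t[:cut]
        noisy = path + rng.normal(0.0, spec.localization_sd, size=path.shape)
        tracks.append(Trajectory(f"track{i:05d}", t, noisy,
                                 frame_interval=spec.frame_interval))
    return tracks


def write_bundle(spec: TrajectoryGenSpec, geometry: CellGeometry,
                 out_prefix: str, rng=None) -> list[Trajectory]:
    """Emit ``<prefix>_tracks.csv``, ``<prefix>_geometry.json`` and a
    manifest recording all generator parameters and the seed."""
    tracks = generate_trajectories(spec, geometry, rng)
    save_tracks_csv(tracks, f"{out_prefix}_tracks.csv")
    geometry.to_json(f"{out_prefix}_geometry.json")
    with open(f"{out_prefix}_manifest.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return tracks
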