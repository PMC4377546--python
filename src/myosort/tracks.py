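"""Directional-flux analysis of single-particle trajectories on keratocytes.

A tracked scaffold yields a time-stamped 2D trajectory.  After filtering out
short or immobile tracks, each trajectory is classified as outward (toward
the cell periphery) or inward by comparing the distance to the periphery,
measured along the local actin polarity direction, at the start and at the
end of the track: moving away from the cell centre shortens that distance.
The outward flux is the fraction of outward tracks; uncertainties use the
half-sample bootstrap.  Additional operations cover mean speeds, the linear
dependence of flux on the myosin V/VI copy-number difference, and pre/post
speed comparison for photo-cleavage experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import LineString, Point, Polygon

from .stats import FluxEstimate, as_rng, bootstrap_sem, make_flux_estimate

#: Camera pixel size implied by the "8 pixels = 860 nm" distance filter.
CAMERA_PIXEL_NM = 107.5

#: Displacement differences below this (nm) count as tangential movement.
DIRECTION_EPS_NM = 1.0


@dataclass(frozen=True)
class Trajectory:
    """One particle track: strictly increasing times (s), positions (nm)."""

    track_id: str
    t: np.ndarray
    xy: np.ndarray
    frame_interval: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "xy", np.asarray(self.xy, dtype=float))
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("t must be (n,), xy must be (n, 2)")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def max_displacement(self) -> float:
        """Largest distance of any sample from the starting point (nm)."""
        return float(np.linalg.norm(self.xy - self.xy[0], axis=1).max())

    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.xy, axis=0), axis=1).sum())


@dataclass
class CellGeometry:
    """Cell boundary polygon (nm), centre, and outward polarity field.

    ``polarity_field`` maps a position to an outward unit vector; the default
    is the radial direction from the cell centre, a good approximation to the
    leading-edge normal over a convex lamellipodium.
    """

    boundary: Polygon
    center: np.ndarray
    polarity_field: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.boundary.contains(Point(self.center)):
            raise ValueError("center must lie inside the boundary")

    def polarity(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        if self.polarity_field is not None:
            v = np.asarray(self.polarity_field(pos), dtype=float)
        else:
            v = pos - self.center
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("polarity undefined at the cell centre")
        return v / n

    def distance_to_periphery(self, pos) -> float:
        """Distance from ``pos`` to the boundary along the outward polarity
        ray (nm); raises if the ray misses the boundary."""
        pos = np.asarray(pos, dtype=float)
        u = self.polarity(pos)
        span = 4.0 * np.sqrt(self.boundary.area)
        ray = LineString([pos, pos + span * u])
        hit = ray.intersection(self.boundary.exterior)
        if hit.is_empty:
            raise ValueError("polarity ray does not reach the boundary")
        p0 = Point(pos)
        if hit.geom_type == "Point":
            return float(p0.distance(hit))
        return float(min(p0.distance(g) for g in getattr(hit, "geoms", [hit])))

    def to_json(self, path) -> None:
        import json
        data = {"boundary": [list(c) for c in self.boundary.exterior.coords],
                "center": list(self.center)}
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "CellGeometry":
        import json
        with open(path) as fh:
            data = json.load(fh)
        return cls(boundary=Polygon(data["boundary"]),
                   center=np.array(data["center"]))


def load_tracks_csv(path) -> list[Trajectory]:
    """Read a track table (columns track_id, frame, t_s, x_nm, y_nm)."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("t_s")
        out.append(Trajectory(str(tid), grp["t_s"].to_numpy(),
                              grp[["x_nm", "y_nm"]].to_numpy()))
    return out


def save_tracks_csv(tracks: Iterable[Trajectory], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "track_id": tr.track_id,
            "frame": np.arange(tr.n_frames),
            "t_s": tr.t, "x_nm": tr.xy[:, 0], "y_nm": tr.xy[:, 1]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def filter_trajectories(tracks: Iterable[Trajectory], min_frames: int = 6,
                        min_distance_nm: float = 860.0) -> list[Trajectory]:
    """Keep tracks with strictly more than ``min_frames`` frames AND a
    maximum displacement strictly greater than ``min_distance_nm`` (the
    default reproduces the >6-frame / >8-pixel motility filters)."""
    return [tr for tr in tracks
            if tr.n_frames > min_frames
            and tr.max_displacement() > min_distance_nm]


def classify_direction(traj: Trajectory, geometry: CellGeometry) -> str:
    """Classify a trajectory as ``"outward"``, ``"inward"`` or
    ``"undetermined"``.

    The distance to the cell periphery along the local polarity direction is
    evaluated at the start (``dx_start``) and end (``dx_finish``) of the
    track; movement away from the cell centre gives a negative
    ``dx_finish - dx_start``.  Tracks whose distance change is below the
    tangential tolerance are undetermined and excluded from flux counts.
    """
    for pos in (traj.xy[0], traj.xy[-1]):
        if not geometry.boundary.contains(Point(pos)):
            raise ValueError("trajectory endpoints must lie inside the cell")
    dx_start = geometry.distance_to_periphery(traj.xy[0])
    dx_finish = geometry.distance_to_periphery(traj.xy[-1])
    delta = dx_finish - dx_start
    if abs(delta) <= DIRECTION_EPS_NM:
        return "undetermined"
    return "outward" if delta < 0 else "inward"


def outward_flux(labels: Iterable[str], B: int = 1000,
                 rng=None) -> FluxEstimate:
    """Outward flux from direction labels, with half-sample bootstrap SEM.

    ``undetermined`` labels are excluded from the denominator.
    """
    labels = [lb for lb in labels if lb in ("outward", "inward")]
    if not labels:
        raise ValueError("no classified trajectories")
    n_plus = sum(lb == "outward" for lb in labels)
    return make_flux_estimate(n_plus, len(labels) - n_plus, bootstrap=True,
                              B=B, rng=rng)


def mean_speed(traj: Trajectory) -> float:
    """Along-path speed: total path length over elapsed time (nm/s)."""
    if traj.duration <= 0:
        raise ValueError("trajectory has no duration")
    return traj.path_length() / traj.duration


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float


def fit_flux_line(points: Sequence[tuple[float, float]]) -> LineFit:
    """Ordinary least squares of outward flux against the myosin V minus
    myosin VI copy-number difference.

    ``points`` are (x - y, phi_out) pairs; at least three distinct abscissa
    values are required.
    """
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x - y values")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LineFit(slope=float(model.params[1]),
                   intercept=float(model.params[0]),
                   r_squared=float(model.rsquared),
                   slope_se=float(model.bse[1]))


@dataclass(frozen=True)
class CleavageComparison:
    pre_speed: float
    post_speed: float
    p_value: float
    n_pre: int
    n_post: int


def _frame_speeds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    dt = np.diff(traj.t)
    v = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1) / dt
    midtimes = 0.5 * (traj.t[:-1] + traj.t[1:])
    return midtimes, v


def photocleavage_compare(traj: Trajectory, t_cleave: float,
                          n_perm: int = 10000,
                          rng=None) -> CleavageComparison:
    """Compare mean speeds before and after photo-cleavage at ``t_cleave``.

    Frame-to-frame speeds are split at the cleavage time and compared with a
    one-sided permutation test (post > pre).  Both segments must be
    non-empty.
    """
    rng = as_rng(rng)
    midtimes, v = _frame_speeds(traj)
    pre = v[midtimes < t_cleave]
    post = v[midtimes >= t_cleave]
    if pre.size == 0 or post.size == 0:
        raise ValueError("t_cleave must split the track into two non-empty "
                         "segments")
    observed = post.mean() - pre.mean()
    pooled = np.concatenate([pre, post])
    n_post = post.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:n_post].mean() - perm[n_post:].mean()
        if diff >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CleavageComparison(pre_speed=float(pre.mean()),
                              post_speed=float(post.mean()),
                              p_value=float(p), n_pre=int(pre.size),
                              n_post=int(n_post))


def analyze_tracks(tracks: Iterable[Trajectory], geometry: CellGeometry,
                   min_frames: int = 6, min_distance_nm: float = 860.0,
                   B: int = 1000, rng=None) -> dict:
    """Full pipeline: filter, classify, flux with bootstrap SEM, speeds.

    Returns a summary dict (n_plus, n_minus, phi_out, sem, speeds by
    direction with bootstrap SEMs).
    """
    rng = as_rng(rng)
    kept = filter_trajectories(tracks, min_frames, min_distance_nm)
    labels = [classify_direction(tr, geometry) for tr in kept]
    est = outward_flux(labels, B=B, rng=rng)
    speeds = {"outward": [], "inward": []}
    for tr, lb in zip(kept, labels):
        if lb in speeds:
            speeds[lb].append(mean_speed(tr))
    summary = {"n_tracks": len(kept), "n_plus": est.n_plus,
               "n_minus": est.n_minus, "phi_out": est.phi_out,
               "sem": est.sem, "sem_bootstrap": est.sem_bootstrap}
    for lb, vals in speeds.items():
        summary[f"speed_{lb}_nm_s"] = float(np.mean(vals)) if vals else None
        summary[f"speed_{lb}_sem"] = (bootstrap_sem(vals, rng=rng)
                                      if len(vals) >= 2 else None)
    return summary
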