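"""Stochastic stepping of two spring-coupled dimeric motors on a digitized
actin network, and the per-step inter-motor tension change it produces.

Each dimeric motor has two heads 36 +/- 7.2 nm apart, bound to skeleton
pixels; the two motors' centres of mass are joined by a linear spring of
stiffness ``k_s`` with a 65 nm rest length (placement band 65 +/- 15 nm).
A stepping motor pivots its trailing head about the lead head to a new
binding site chosen among geometrically admissible pixels by a Boltzmann
weight over the deformation energy

    G_i = 1/2 k_F |r_i - r_target|^2 + 1/2 k_s (stretch_i)^2

where ``r_target`` is the unstrained post-stroke position one step size ahead
of the lead head along the local filament axis, ``k_F`` is the flexural
rigidity of the lever arm (penalizing any deviation -- lateral or
longitudinal -- of the new head from the relaxed stroke endpoint), and
``stretch_i`` is the deviation of the post-step centre-of-mass separation
from the spring rest length.  Rigid levers (k_F/k_s >> 1) force near-axial
full steps and recover the single-filament tension gain dT = k_s * s;
flexible levers (k_F/k_s << 1) pick sites that minimize spring stretch and
hence accrue less tension per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actin import ActinNetwork
from .motors import MYOSIN_V, MYOSIN_VI
from .stats import as_rng

STEP_NM = 36.0        #: unstrained step size s
ARC_TOL = 7.2         #: half-width of the head-separation band (36 +/- 7.2)
COM_REST = 65.0       #: inter-motor centre-of-mass rest separation
COM_TOL = 15.0        #: half-width of the centre-of-mass band (65 +/- 15)


@dataclass(frozen=True)
class StiffnessParams:
    """Mechanical stiffnesses: lever ``k_F`` and inter-motor spring ``k_s``
    in pN/nm, thermal energy ``kT`` in pN nm."""

    k_F: float
    k_s: float = 0.05
    kT: float = 4.1

    def __post_init__(self) -> None:
        if self.k_F <= 0 or self.k_s <= 0 or self.kT <= 0:
            raise ValueError("all stiffness parameters must be positive")

    @property
    def ratio(self) -> float:
        return self.k_F / self.k_s


@dataclass
class EnsembleState2D:
    """Two dimeric motors on the network.

    ``heads[m]`` is a (2, 2) array of the two head positions (nm, columns
    x/y) of motor ``m``; ``lead[m]`` indexes the leading head; ``sign[m]``
    is +1 for the motor walking along the polarity field and -1 against.
    """

    heads: np.ndarray
    lead: np.ndarray
    sign: np.ndarray

    def com(self, m: int) -> np.ndarray:
        return self.heads[m].mean(axis=0)

    @property
    def separation(self) -> float:
        """Inter-motor centre-of-mass distance (the spring extension base)."""
        return float(np.linalg.norm(self.com(0) - self.com(1)))

    def lead_pos(self, m: int) -> np.ndarray:
        return self.heads[m, self.lead[m]]

    def trail_pos(self, m: int) -> np.ndarray:
        return self.heads[m, 1 - self.lead[m]]


@dataclass(frozen=True)
class StepCandidate:
    """A candidate binding site with its deformation energy and Boltzmann
    selection probability."""

    site: tuple[float, float]
    energy: float
    probability: float = field(default=np.nan)


def _forward_dir(network: ActinNetwork, pos_nm: np.ndarray,
                 sign: int) -> np.ndarray:
    row, col = network.pixel_index(pos_nm)
    vec = network.polarity[row, col] * sign
    nrm = np.linalg.norm(vec)
    return vec / nrm if nrm > 0 else np.array([float(sign), 0.0])


def _filament_axis(network: ActinNetwork, pos_nm: np.ndarray,
                   forward: np.ndarray) -> np.ndarray:
    """Unit vector along the local filament, directed with ``forward``."""
    row, col = network.pixel_index(pos_nm)
    ang = network.orientation[row, col] if network.orientation is not None \
        else np.nan
    if np.isnan(ang):
        return forward
    axis = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
    return axis if axis @ forward >= 0 else -axis


def place_ensemble(network: ActinNetwork, rng=None,
                   max_tries: int = 5000) -> EnsembleState2D:
    """Place two antagonistic dimers on the skeleton.

    Head separations must lie within 36 +/- 7.2 nm and the centre-of-mass
    separation within 65 +/- 15 nm; within each motor the leading head is the
    one further along that motor's forward direction.  Motor 0 walks with the
    polarity field (outward), motor 1 against it.
    """
    rng = as_rng(rng)
    pts = network.skeleton_points_nm()
    if pts.shape[0] < 4:
        raise ValueError("network has too few binding sites for placement")
    tree = network.kdtree()
    lo, hi = STEP_NM - ARC_TOL, STEP_NM + ARC_TOL

    def annulus(centre, r_lo, r_hi):
        idx = np.asarray(tree.query_ball_point(centre, r_hi), dtype=int)
        if idx.size == 0:
            return idx
        d = np.linalg.norm(pts[idx] - centre, axis=1)
        return idx[d >= r_lo]

    for _ in range(max_tries):
        a1 = pts[rng.integers(pts.shape[0])]
        i1 = annulus(a1, lo, hi)
        if i1.size == 0:
            continue
        b1 = pts[i1[rng.integers(i1.size)]]
        com1 = 0.5 * (a1 + b1)
        inear = annulus(com1, COM_REST - COM_TOL - hi / 2,
                        COM_REST + COM_TOL + hi / 2)
        if inear.size == 0:
            continue
        near = pts[inear]
        a2 = near[rng.integers(near.shape[0])]
        d2 = np.linalg.norm(near - a2, axis=1)
        cand2 = near[(d2 >= lo) & (d2 <= hi)]
        if cand2.shape[0] == 0:
            continue
        b2 = cand2[rng.integers(cand2.shape[0])]
        com2 = 0.5 * (a2 + b2)
        sep = np.linalg.norm(com1 - com2)
        if not (COM_REST - COM_TOL <= sep <= COM_REST + COM_TOL):
            continue
        heads = np.array([[a1, b1], [a2, b2]])
        sign = np.array([+1, -1])
        lead = np.empty(2, dtype=int)
        for m in range(2):
            fwd = _forward_dir(network, heads[m].mean(axis=0), sign[m])
            proj = heads[m] @ fwd
            lead[m] = int(np.argmax(proj))
        return EnsembleState2D(heads=heads, lead=lead, sign=sign)
    raise RuntimeError("could not place ensemble within the distance bands; "
                       "network too sparse?")


def candidate_sites(state: EnsembleState2D, stepping_motor: int,
                    network: ActinNetwork,
                    params: StiffnessParams | None = None) -> list[StepCandidate]:
    """Admissible binding sites for the stepping motor's trailing head.

    The trailing head pivots about the lead head; a site qualifies if it is
    (a) 36 +/- 7.2 nm from the leading head, (b) lies forward of the lead
    head along the local polarity, and (c) advances the centre of mass by at
    most one step size (a hand-over-hand step cannot translocate the motor
    further than its working stroke, which bounds the tension gained per step
    by ``k_s * s``).  The 65 +/- 15 nm inter-motor band is a hard constraint
    only at placement; during stepping the spring resists extension through
    the quadratic stretch term of the site energy, which keeps the
    single-filament limit (a full axial step, ``dT = k_s * s``) reachable.

    With ``params`` given, deformation energies and Boltzmann probabilities
    are filled in; otherwise both are NaN and an empty list signals a no-step
    event.
    """
    m = stepping_motor
    lead = state.lead_pos(m)
    other_com = state.com(1 - m)
    old_com = state.com(m)
    all_pts = network.skeleton_points_nm()
    idx = np.asarray(network.kdtree().query_ball_point(lead,
                                                       STEP_NM + ARC_TOL),
                     dtype=int)
    pts = all_pts[idx] if idx.size else np.empty((0, 2))

    d_lead = np.linalg.norm(pts - lead, axis=1)
    ok = d_lead >= STEP_NM - ARC_TOL
    new_com = 0.5 * (lead + pts)
    fwd = _forward_dir(network, lead, int(state.sign[m]))
    ok &= (pts - lead) @ fwd > 0
    ok &= np.linalg.norm(new_com - old_com, axis=1) <= STEP_NM
    sites = pts[ok]
    if sites.shape[0] == 0:
        return []
    if params is None:
        return [StepCandidate(tuple(s), np.nan) for s in sites]
    energies = _site_energies(sites, lead, other_com, fwd, network, params)
    z = np.exp(-(energies - energies.min()) / params.kT)
    probs = z / z.sum()
    return [StepCandidate(tuple(s), float(g), float(p))
            for s, g, p in zip(sites, energies, probs)]


def _site_energies(sites: np.ndarray, lead: np.ndarray, other_com: np.ndarray,
                   fwd: np.ndarray, network: ActinNetwork,
                   params: StiffnessParams) -> np.ndarray:
    axis = _filament_axis(network, lead, fwd)
    target = lead + STEP_NM * axis
    dev = np.linalg.norm(sites - target, axis=1)
    new_sep = np.linalg.norm(0.5 * (lead + sites) - other_com, axis=1)
    stretch = np.abs(new_sep - COM_REST)
    return 0.5 * params.k_F * dev ** 2 + 0.5 * params.k_s * stretch ** 2


def site_energy(candidate, state: EnsembleState2D, stepping_motor: int,
                params: StiffnessParams, network: ActinNetwork) -> float:
    """Deformation energy (pN nm) of one candidate site for the stepping
    motor (zero when the site is the unstrained post-stroke target and the
    spring stays at rest length)."""
    site = np.atleast_2d(np.asarray(candidate, dtype=float))
    lead = state.lead_pos(stepping_motor)
    fwd = _forward_dir(network, lead, int(state.sign[stepping_motor]))
    return float(_site_energies(site, lead, state.com(1 - stepping_motor),
                                fwd, network, params)[0])


def boltzmann_select(candidates: list[StepCandidate], kT: float,
                     rng=None) -> StepCandidate:
    """Draw one candidate with probability exp(-G_i/kT) / sum_j exp(-G_j/kT)."""
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    rng = as_rng(rng)
    g = np.array([c.energy for c in candidates])
    z = np.exp(-(g - g.min()) / kT)
    p = z / z.sum()
    idx = rng.choice(len(candidates), p=p)
    return candidates[idx]


def step_and_measure_dT(state: EnsembleState2D, params: StiffnessParams,
                        network: ActinNetwork, rng=None,
                        taus: tuple[float, float] = (MYOSIN_V.unloaded_dwell,
                                                     MYOSIN_VI.unloaded_dwell)):
    """Let the motor with the shorter dwell step; return (state, dT).

    ``dT = k_s * (dx_post - dx_pre)`` where ``dx`` is the inter-motor
    centre-of-mass separation before and after the step (pN).  If the
    stepping motor has no admissible site, a no-step event is signalled by
    ``dT = None`` and the state is unchanged.
    """
    rng = as_rng(rng)
    dwells = rng.exponential(taus)
    m = int(np.argmin(dwells))
    cands = candidate_sites(state, m, network, params)
    if not cands:
        return state, None
    chosen = boltzmann_select(cands, params.kT, rng)
    dx_pre = state.separation
    new_head = np.asarray(chosen.site, dtype=float)
    old_lead_idx = state.lead[m]
    state.heads[m, 1 - old_lead_idx] = new_head
    state.lead[m] = 1 - old_lead_idx   # the moved head is now leading
    dx_post = state.separation
    return state, params.k_s * (dx_post - dx_pre)


def sample_dT(network: ActinNetwork, params: StiffnessParams, n_steps: int,
              rng=None, max_attempts_factor: int = 20) -> np.ndarray:
    """Collect ``n_steps`` tension changes from independent placements.

    Each sample places a fresh ensemble and performs a single step; no-step
    events (empty candidate sets) are excluded from the statistics and
    retried with a new placement.
    """
    rng = as_rng(rng)
    out = np.empty(n_steps)
    got = 0
    for _ in range(max_attempts_factor * n_steps):
        if got >= n_steps:
            break
        st = place_ensemble(network, rng)
        st, dT = step_and_measure_dT(st, params, network, rng)
        if dT is not None:
            out[got] = dT
            got += 1
    if got < n_steps:
        raise RuntimeError("too many no-step events; network too sparse")
    return out


def mean_dT_vs_stiffness(network: ActinNetwork, kF_over_ks_values,
                         k_s: float = 0.05, n_steps: int = 400,
                         seed=None) -> pd.DataFrame:
    """Mean +/- sd of the per-step tension change as a function of lever
    rigidity ``k_F/k_s`` (>= 400 independent placements/steps per point)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rows = []
    for ratio in kF_over_ks_values:
        rng = as_rng(seed)
        p = StiffnessParams(k_F=ratio * k_s, k_s=k_s)
        dts = sample_dT(network, p, n_steps, rng)
        rows.append({"kF_over_ks": ratio, "mean_dT_pN": dts.mean(),
                     "sd_dT_pN": dts.std(ddof=1), "n_steps": n_steps})
    return pd.DataFrame(rows)


def dT_ratio(kF_rigid: float, kF_flexible: float, k_s: float,
             network: ActinNetwork, n_steps: int = 400, seed=None) -> float:
    """Ratio of mean per-step tension change, rigid over flexible lever.

    Both stiffness settings are simulated on the same network with the same
    seed schedule; the result feeds the keratocyte-mode tug-of-war as
    ``dT_high/dT_low``.
    """
    if kF_rigid < kF_flexible:
        raise ValueError("kF_rigid must be >= kF_flexible")
    d_rigid = sample_dT(network, StiffnessParams(kF_rigid, k_s), n_steps,
                        as_rng(seed))
    d_flex = sample_dT(network, StiffnessParams(kF_flexible, k_s), n_steps,
                       as_rng(seed))
    return float(d_rigid.mean() / d_flex.mean())
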