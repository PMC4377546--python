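"""Stochastic tug-of-war between two antagonistic motors on a shared scaffold.

Two processive motors of opposite directionality are coupled through a linear
spring.  Starting from zero inter-motor tension ``T``, the motors race
exponentially distributed dwell times; the winner of each race steps forward,
raising ``T`` by a Gaussian increment of mean ``dT`` (the tension gained per
step, ``dT = k_s * s``) and standard deviation ``noise_cv * dT``.  The
competition resolves when a step drives ``T`` past a stall force: the motor
designated by the resolution rule undergoes a conformational change, begins
back-stepping, and is the loser; the scaffold then moves unidirectionally
behind the winner.  Repeating the competition many times yields the outward
flux ``phi_out = n+ / (n+ + n-)``, the fraction of runs won by the stronger
(plus-end directed) motor.

Everything is simulated in normalized units: forces in units of the weaker
motor's stall force ``F_low`` (so the stronger motor stalls at ``r_s =
F_high/F_low``) and times in ms.  The only mechanical free parameter of the
single-filament (1D) mode is ``dT/F_low``; the keratocyte (network) mode uses
two increments, ``dT_high`` accrued when the rigid/stronger motor steps and
``dT_low`` when the flexible/weaker motor steps.

Resolution rules
----------------
``"stepper_attempt"`` (default)
    A motor loses when its *own* step raises ``T`` above its *own* stall
    force.  With the default load-independent dwell race this is the variant
    that reproduces the calibrated tension-per-step of the antagonistic
    myosin V/VI pair; it also corresponds to reading the load factor of the
    force-velocity relation as a property of the stepping motor applied to
    the whole ensemble, which cancels in an exponential race.
``"exceeded_stall"``
    After any step, a motor whose stall force ``T`` now exceeds back-steps
    and loses; if one step crosses both stalls the stepping motor loses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .motors import MYOSIN_V, MYOSIN_VI, STALL_EPS, MotorSpec, sample_dwell
from .stats import FluxEstimate, as_rng, make_flux_estimate

RESOLUTION_RULES = ("stepper_attempt", "exceeded_stall")


class UncalibratableError(RuntimeError):
    """Raised when a target flux cannot be matched by any parameter value."""


@dataclass(frozen=True)
class TugOfWarParams:
    """Configuration of a tug-of-war simulation (normalized units).

    ``dT_norm`` selects the single-filament mode; ``dT_high_norm`` /
    ``dT_low_norm`` select the keratocyte mode (both in units of ``F_low``).
    Exactly one of the two modes must be specified.
    """

    r_s: float = 1.5
    dT_norm: float | None = None
    dT_high_norm: float | None = None
    dT_low_norm: float | None = None
    noise_cv: float = 0.1
    resolution_rule: str = "stepper_attempt"
    load_dependent_dwell: bool = False
    n_runs: int = 1000
    seed: int | None = 0
    max_steps: int = 10**6

    def __post_init__(self) -> None:
        if self.r_s < 1:
            raise ValueError("r_s must be >= 1 (stronger motor over weaker)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.resolution_rule not in RESOLUTION_RULES:
            raise ValueError(f"unknown resolution_rule {self.resolution_rule!r}")
        onedim = self.dT_norm is not None
        kerato = self.dT_high_norm is not None or self.dT_low_norm is not None
        if onedim == kerato:
            raise ValueError("specify either dT_norm (1D mode) or both "
                             "dT_high_norm and dT_low_norm (keratocyte mode)")
        if kerato and (self.dT_high_norm is None or self.dT_low_norm is None):
            raise ValueError("keratocyte mode needs dT_high_norm and dT_low_norm")
        for val in (self.dT_norm, self.dT_high_norm, self.dT_low_norm):
            if val is not None and val <= 0:
                raise ValueError("tension increments must be positive")

    @property
    def mode(self) -> str:
        return "1d" if self.dT_norm is not None else "keratocyte"

    @property
    def increments(self) -> tuple[float, float]:
        """(dT when the stronger motor steps, dT when the weaker motor steps)."""
        if self.dT_norm is not None:
            return (self.dT_norm, self.dT_norm)
        return (self.dT_high_norm, self.dT_low_norm)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k) for k in self.__dataclass_fields__},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TugOfWarParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CompetitionState:
    """Mutable state of one running competition."""

    tension: float = 0.0
    step_count: int = 0

    def __post_init__(self) -> None:
        if self.tension < 0:
            raise ValueError("tension must be non-negative")


@dataclass(frozen=True)
class CompetitionOutcome:
    """Result of one resolved competition."""

    winner: str
    n_steps_to_resolution: int
    final_tension: float


def default_motor_pair(r_s: float = 1.5) -> tuple[MotorSpec, MotorSpec]:
    """The myosin V/VI pair in normalized force units (F_low = 1)."""
    strong = replace(MYOSIN_V, stall_force=float(r_s))
    weak = replace(MYOSIN_VI, stall_force=1.0)
    return strong, weak


def step_increment(stepper_is_strong: bool, params: TugOfWarParams,
                   rng: np.random.Generator) -> float:
    """Draw one tension increment for a forward step (truncated at zero)."""
    d_high, d_low = params.increments
    mean = d_high if stepper_is_strong else d_low
    return max(float(rng.normal(mean, params.noise_cv * mean)), 0.0)


def apply_step(state: CompetitionState, stepper: MotorSpec,
               params: TugOfWarParams, rng: np.random.Generator,
               strong: MotorSpec | None = None) -> CompetitionState:
    """Apply one forward step of ``stepper`` to the competition state.

    The increment mean is mode-appropriate: ``dT`` in 1D mode, ``dT_high`` or
    ``dT_low`` by stepper identity in keratocyte mode (``strong`` identifies
    the stronger motor; by default any motor with stall force > 1 normalized).
    """
    if strong is None:
        is_strong = stepper.stall_force > 1.0
    else:
        is_strong = stepper is strong
    inc = step_increment(is_strong, params, rng)
    state.tension += inc
    state.step_count += 1
    return state


def _race(tension: float, motors: Sequence[MotorSpec],
          params: TugOfWarParams, rng: np.random.Generator) -> int:
    """Index of the motor with the shorter sampled dwell at this tension."""
    while True:
        if params.load_dependent_dwell:
            dwells = [sample_dwell(tension, m, rng) for m in motors]
        else:
            dwells = [rng.exponential(m.unloaded_dwell) for m in motors]
        if dwells[0] != dwells[1]:
            return int(dwells[1] < dwells[0])


def resolve_competition(params: TugOfWarParams,
                        motors: Sequence[MotorSpec] | None = None,
                        rng=None) -> CompetitionOutcome:
    """Run one competition to resolution and return the winner.

    ``motors`` is the (stronger, weaker) pair; when omitted the normalized
    myosin V/VI pair at the configured stall-force ratio is used.
    """
    rng = as_rng(rng if rng is not None else params.seed)
    if motors is None:
        motors = default_motor_pair(params.r_s)
    strong, weak = motors
    state = CompetitionState()
    rule = params.resolution_rule
    for _ in range(params.max_steps):
        if params.load_dependent_dwell and rule == "stepper_attempt":
            # A motor driven to stall can no longer attempt a forward step:
            # its conformational change makes it the loser outright.
            over = [1.0 - state.tension / m.stall_force <= STALL_EPS
                    for m in motors]
            if any(over):
                loser = (0 if over[0] and (not over[1] or
                                           state.tension / strong.stall_force
                                           >= state.tension / weak.stall_force)
                         else 1) if over[0] else 1
                winner = motors[1 - loser]
                return CompetitionOutcome(winner.label, state.step_count,
                                          state.tension)
        i = _race(state.tension, motors, params, rng)
        stepper = motors[i]
        apply_step(state, stepper, params, rng, strong=strong)
        if rule == "stepper_attempt":
            if state.tension > stepper.stall_force:
                winner = motors[1 - i]
                return CompetitionOutcome(winner.label, state.step_count,
                                          state.tension)
        else:  # exceeded_stall
            over = [state.tension > m.stall_force for m in motors]
            if over[0] and over[1]:
                loser = i  # tie broken toward the stepping motor
            elif over[0]:
                loser = 0
            elif over[1]:
                loser = 1
            else:
                continue
            winner = motors[1 - loser]
            return CompetitionOutcome(winner.label, state.step_count,
                                      state.tension)
    raise RuntimeError("competition did not resolve within max_steps; "
                       "degenerate parameters?")


def _simulate_batch(params: TugOfWarParams, n: int,
                    rng: np.random.Generator,
                    tau: tuple[float, float] = (MYOSIN_V.unloaded_dwell,
                                                MYOSIN_VI.unloaded_dwell)):
    """Vectorized competitions; returns (strong_won, n_steps, final_T) arrays.

    Motor 0 is the stronger motor (stall ``r_s``), motor 1 the weaker
    (stall 1).  The keratocyte mode with equal increments follows exactly the
    same code path (and random stream) as the 1D mode.
    """
    F = np.array([params.r_s, 1.0])
    d = np.array(params.increments)
    cv = params.noise_cv
    rule = params.resolution_rule

    T = np.zeros(n)
    steps = np.zeros(n, dtype=np.int64)
    winner = np.full(n, -1, dtype=np.int8)
    active = np.arange(n)

    for _ in range(params.max_steps):
        if active.size == 0:
            break
        t = T[active]
        if params.load_dependent_dwell:
            f0 = np.maximum(1.0 - t / F[0], 0.0)
            f1 = np.maximum(1.0 - t / F[1], 0.0)
            if rule == "stepper_attempt":
                stalled0 = f0 <= STALL_EPS
                stalled1 = f1 <= STALL_EPS
                dead = stalled0 | stalled1
                if dead.any():
                    # stalled motor loses outright; deeper-stalled loses a tie
                    lose0 = stalled0 & (~stalled1 | (t / F[0] >= t / F[1]))
                    winner[active[dead & lose0]] = 1
                    winner[active[dead & ~lose0]] = 0
                    active = active[~dead]
                    t, f0, f1 = t[~dead], f0[~dead], f1[~dead]
                    if active.size == 0:
                        break
            scale0 = np.where(f0 > STALL_EPS, tau[0] / np.maximum(f0, STALL_EPS),
                              np.inf)
            scale1 = np.where(f1 > STALL_EPS, tau[1] / np.maximum(f1, STALL_EPS),
                              np.inf)
        else:
            scale0 = np.full(active.size, tau[0])
            scale1 = np.full(active.size, tau[1])
        dwell0 = rng.exponential(scale0)
        dwell1 = rng.exponential(scale1)
        stepper = (dwell1 < dwell0).astype(np.int8)  # 0 strong, 1 weak

        mean = d[stepper]
        inc = np.maximum(rng.normal(mean, cv * mean), 0.0)
        t_new = t + inc
        T[active] = t_new
        steps[active] += 1

        if rule == "stepper_attempt":
            lost = t_new > F[stepper]
            winner[active[lost]] = 1 - stepper[lost]
        else:
            over0 = t_new > F[0]
            over1 = t_new > F[1]
            lost = over0 | over1
            loser = np.where(over0 & over1, stepper,
                             np.where(over0, 0, 1)).astype(np.int8)
            winner[active[lost]] = 1 - loser[lost]
        active = active[~lost]
    else:
        raise RuntimeError("competitions did not resolve within max_steps")

    return winner == 0, steps, T


def estimate_flux(params: TugOfWarParams,
                  motors: Sequence[MotorSpec] | None = None, rng=None, *,
                  bootstrap: bool = True,
                  return_outcomes: bool = False):
    """Estimate the outward flux over ``params.n_runs`` competitions.

    Returns a :class:`FluxEstimate`; with ``return_outcomes=True`` also a
    per-run DataFrame (run_id, winner, n_steps, final_T).  The SEM is the
    binomial standard error; a half-sample bootstrap SEM is attached for
    cross-checking.
    """
    rng = as_rng(rng if rng is not None else params.seed)
    if motors is None:
        motors = default_motor_pair(params.r_s)
    tau = (motors[0].unloaded_dwell, motors[1].unloaded_dwell)
    strong_won, steps, final_T = _simulate_batch(params, params.n_runs, rng,
                                                 tau=tau)
    n_plus = int(strong_won.sum())
    est = make_flux_estimate(n_plus, params.n_runs - n_plus,
                             bootstrap=bootstrap, rng=rng)
    if return_outcomes:
        frame = pd.DataFrame({
            "run_id": np.arange(params.n_runs),
            "winner": np.where(strong_won, motors[0].label, motors[1].label),
            "n_steps": steps,
            "final_T": final_T,
        })
        return est, frame
    return est


def flux_grid(r_s_values: Sequence[float], dT_norm_values: Sequence[float],
              n_runs: int = 1000, seed: int | None = 0,
              **param_kwargs) -> pd.DataFrame:
    """Outward-flux grid over stall-force ratio and normalized tension step.

    Rows are ``r_s`` values, columns ``dT/F_low`` values, in input order.
    Save with ``df.to_csv(path)``.
    """
    if len(r_s_values) == 0 or len(dT_norm_values) == 0:
        raise ValueError("axes must be non-empty")
    rng = as_rng(seed)
    grid = np.empty((len(r_s_values), len(dT_norm_values)))
    for i, rs in enumerate(r_s_values):
        for j, d in enumerate(dT_norm_values):
            p = TugOfWarParams(r_s=rs, dT_norm=d, n_runs=n_runs,
                               seed=None, **param_kwargs)
            grid[i, j] = estimate_flux(p, rng=rng, bootstrap=False).phi_out
    df = pd.DataFrame(grid, index=pd.Index(r_s_values, name="r_s"),
                      columns=pd.Index(dT_norm_values, name="dT_over_Flow"))
    return df


@dataclass(frozen=True)
class CalibrationResult:
    """Inverted parameter value with Monte-Carlo uncertainty."""

    value: float
    uncertainty: float
    achieved_flux: float
    target_flux: float
    tolerance_effective: float
    evaluations: pd.DataFrame = field(repr=False, default=None)


def _calibrate_monotone(simulate, grid: np.ndarray, target: float,
                        tolerance: float, n_runs: int) -> CalibrationResult:
    """Grid scan + band-midpoint inversion of a monotone noisy flux curve.

    ``simulate(x)`` returns an estimated flux at parameter ``x``.  All points
    whose estimate is within the effective tolerance (the larger of the
    requested tolerance and 3 binomial SE) of the target form the matching
    band; the centre of the contiguous band around the best match is
    returned.  If no grid point matches, the bracketing interval around the
    target crossing is bisected.
    """
    phis = np.array([simulate(x) for x in grid])
    se0 = float(np.sqrt(0.25 / n_runs))
    eff_tol = max(tolerance, 3.0 * se0)
    span = phis.max() - phis.min()
    if span < max(5.0 * se0, 2.0 * tolerance):
        raise UncalibratableError(
            "flux is insensitive to the parameter over the search range; "
            "no unique root")
    if not (phis.min() - eff_tol <= target <= phis.max() + eff_tol):
        raise UncalibratableError(
            f"target flux {target} outside attainable range "
            f"[{phis.min():.3f}, {phis.max():.3f}]")
    frame = pd.DataFrame({"x": grid, "phi_out": phis})
    close = np.abs(phis - target) <= eff_tol
    step = float(np.median(np.diff(grid))) if grid.size > 1 else 0.0
    if close.any():
        best = int(np.argmin(np.abs(phis - target)))
        lo = best
        while lo > 0 and close[lo - 1]:
            lo -= 1
        hi = best
        while hi < grid.size - 1 and close[hi + 1]:
            hi += 1
        value = 0.5 * (grid[lo] + grid[hi])
        unc = 0.5 * (grid[hi] - grid[lo]) + 0.5 * step
        achieved = simulate(value)
        return CalibrationResult(float(value), float(unc), float(achieved),
                                 target, eff_tol, frame)
    # no matching band: bisect the bracketing pair (curve decreasing)
    diffs = phis - target
    sign_change = np.where(np.diff(np.sign(diffs)) != 0)[0]
    if sign_change.size == 0:
        raise UncalibratableError("no crossing of the target flux found")
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    fa = diffs[sign_change[0]]
    for _ in range(12):
        mid = 0.5 * (a + b)
        fm = simulate(mid) - target
        if abs(fm) <= eff_tol or (b - a) < max(step / 8.0, 1e-4):
            achieved = fm + target
            return CalibrationResult(float(mid), float(0.5 * (b - a)),
                                     float(achieved), target, eff_tol, frame)
        if np.sign(fm) == np.sign(fa):
            a, fa = mid, fm
        else:
            b = mid
    mid = 0.5 * (a + b)
    return CalibrationResult(float(mid), float(0.5 * (b - a)),
                             float(simulate(mid)), target, eff_tol, frame)


def calibrate_dT_norm(target_flux: float, r_s: float = 1.5,
                      n_runs: int = 5000, tolerance: float = 0.01,
                      rng=None, grid: Sequence[float] | None = None,
                      **param_kwargs) -> CalibrationResult:
    """Invert the 1D simulator: find ``dT/F_low`` matching a measured flux.

    Scans ``dT/F_low`` over ``grid`` (default 0.05..1.0 in steps of 0.05) at
    ``n_runs`` competitions per evaluation and returns the band-midpoint /
    bisection root (see :func:`_calibrate_monotone`).

    Raises
    ------
    UncalibratableError
        If the target lies outside the attainable flux range at this ``r_s``
        or the flux curve is flat (e.g. matched motors at ``r_s = 1``).
    """
    rng = as_rng(rng)
    if grid is None:
        grid = np.arange(0.05, 1.0001, 0.05)
    grid = np.asarray(grid, dtype=float)

    def simulate(d: float) -> float:
        p = TugOfWarParams(r_s=r_s, dT_norm=float(d), n_runs=n_runs,
                           seed=None, **param_kwargs)
        return estimate_flux(p, rng=rng, bootstrap=False).phi_out

    return _calibrate_monotone(simulate, grid, target_flux, tolerance, n_runs)


def calibrate_dT_ratio(target_flux: float, dT_low_norm: float = 0.55,
                       r_s: float = 1.5, n_runs: int = 5000,
                       tolerance: float = 0.01, rng=None,
                       grid: Sequence[float] | None = None,
                       **param_kwargs) -> CalibrationResult:
    """Invert the keratocyte-mode simulator for ``dT_high/dT_low``.

    The flexible (weaker) motor's increment is held at ``dT_low_norm`` and
    the ratio is searched over ``grid`` (default 1.0..2.4 in steps of 0.05).
    At ratio 1 the keratocyte mode reduces exactly to the 1D mode.
    """
    rng = as_rng(rng)
    if grid is None:
        grid = np.arange(1.0, 2.4001, 0.05)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 1.0:
        raise ValueError("ratio search is restricted to dT_high/dT_low >= 1")

    def simulate(ratio: float) -> float:
        p = TugOfWarParams(r_s=r_s, dT_high_norm=float(ratio) * dT_low_norm,
                           dT_low_norm=dT_low_norm, n_runs=n_runs,
                           seed=None, **param_kwargs)
        return estimate_flux(p, rng=rng, bootstrap=False).phi_out

    return _calibrate_monotone(simulate, grid, target_flux, tolerance, n_runs)
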