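"""Limit-cycle model of the human circadian pacemaker driven by light and
sleep/wake state, and its DLMO prediction and training machinery.

The model has three state variables: the pacemaker pair (x, xc) on a
higher-order van der Pol limit cycle, and the fraction n of activated
retinal photoreceptors (Process L). Light of illuminance I activates
photoreceptors at rate alpha(I) and produces the photic drive

    B = G * alpha * (1 - n) * (1 - b*x) * (1 - b*xc),

whose shape constant b sets the balance of the delay and advance regions of
the phase response curve and G its amplitude. Sleep/wake state adds a small
non-photic drive. Core body temperature minimum (CBTmin) is read off as the
minimum of x each cycle, and DLMO is taken 7 h before CBTmin.

State equations (time in hours):

    dn/dt  = 60 * (alpha*(1 - n) - beta*n),  alpha = alpha0*(I/I0)^p * I/(I+100)
    dx/dt  = (pi/12) * (xc + mu*(x/3 + 4x^3/3 - 256x^7/105) + B + Ns)
    dxc/dt = (pi/12) * (q*B*xc - x*((24/(c*tau))^2 + kappa*B))

The stiffness mu, Process-L constants, and the drive coefficients q and
kappa are configuration defaults from the model lineage; the period
correction c is pinned by the free-running calibration requirement that the
simulated period in darkness equal tau (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .actigraphy_io import EpochSeries, Recording
from .clock import circular_mean_clock, linearize, wrap_diff_hours
from .errors import ConfigError, DegenerateTrajectoryError, InsufficientDataError
from .light_preprocess import PreprocessConfig, preprocess_recording

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f
        return wrap


@dataclass(frozen=True)
class DynamicParams:
    """Pacemaker model constants.

    tau : intrinsic circadian period (h); default 24.15, trained 24.40.
    b : PRC shape constant of the photic drive; default 0.40, trained 0.45.
    G : PRC amplitude constant; default 37.
    alpha0, beta, p, I0 : Process-L photoreceptor kinetics.
    mu : limit-cycle stiffness.
    q, kappa : photic-drive coefficients in dxc/dt.
    rho : non-photic drive magnitude; nonphotic_gated enables suppression of
        the drive during the pacemaker's subjective night.
    c : period-correction constant, calibrated so that the free-running
        period in darkness equals tau.
    psi_dlmo_cbtmin : fixed DLMO-to-CBTmin phase angle (h).
    """

    tau: float = 24.15
    b: float = 0.40
    G: float = 37.0
    alpha0: float = 0.05
    beta: float = 0.0075
    p: float = 0.5
    I0: float = 9500.0
    mu: float = 0.23
    q: float = 1.0 / 3.0
    kappa: float = 0.55
    rho: float = 0.032
    c: float = 0.99160
    psi_dlmo_cbtmin: float = 7.0
    nonphotic_gated: bool = False


#: Parameter set selected by training against the delayed-phase cohort.
TRAINED_PARAMS = DynamicParams(tau=24.40, b=0.45, G=37.0)

INITIAL_STATE = (-1.0, 0.0, 0.5)


@dataclass
class Trajectory:
    """Sampled solution of the pacemaker model with detected phase events."""

    dt_h: float
    x: np.ndarray
    cbtmin_events: np.ndarray  # hours from simulation start
    dlmo_events: np.ndarray
    start_clock: float  # hour-of-day of simulation start
    rep_period_h: float  # duration of one input repetition
    total_h: float

    def times(self) -> np.ndarray:
        return np.arange(self.x.size) * self.dt_h


def photoreceptor_activation(I, params: DynamicParams = DynamicParams()):
    """Photoreceptor activation rate alpha(I); 0 in darkness, monotone in I."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("illuminance must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = params.alpha0 * (I / params.I0) ** params.p * (I / (I + 100.0))
    a = np.where(I > 0, a, 0.0)
    return float(a) if a.ndim == 0 else a


def photic_drive(x: float, xc: float, n: float, alpha: float,
                 params: DynamicParams = DynamicParams()) -> float:
    """Photic drive B = G*alpha*(1-n)*(1-b*x)*(1-b*xc)."""
    return params.G * alpha * (1.0 - n) * (1.0 - params.b * x) * (1.0 - params.b * xc)


def nonphotic_drive(sleep_state: float, x: float,
                    params: DynamicParams = DynamicParams()) -> float:
    """Sleep/wake (non-photic) drive.

    Ungated default: rho*(1/3 - s), positive during wake, negative during
    sleep. The gated variant additionally suppresses the drive while the
    pacemaker is in subjective night (x high).
    """
    ns = params.rho * (1.0 / 3.0 - float(sleep_state))
    if params.nonphotic_gated:
        ns *= 0.5 * (1.0 - np.tanh(10.0 * x))
    return ns


@njit(cache=True)
def _simulate(I_steps, S_steps, dt, tau, b, G, alpha0, beta, p, I0, mu, q,
              kappa, rho, c, gated, x0, xc0, n0):  # pragma: no cover - numba
    n_steps = I_steps.size
    xs = np.empty(n_steps + 1)
    x, xc, n = x0, xc0, n0
    xs[0] = x
    w2 = (24.0 / (c * tau)) ** 2
    pi12 = np.pi / 12.0
    for i in range(n_steps):
        Ii = I_steps[i]
        Si = S_steps[i]
        if Ii > 0.0:
            a = alpha0 * (Ii / I0) ** p * (Ii / (Ii + 100.0))
        else:
            a = 0.0
        # classical RK4; forcing held constant across the step
        cx, cxc, cn = x, xc, n
        k1x = k1xc = k1n = 0.0
        for stage in range(4):
            B = G * a * (1.0 - cn) * (1.0 - b * cx) * (1.0 - b * cxc)
            Ns = rho * (1.0 / 3.0 - Si)
            if gated == 1:
                Ns *= 0.5 * (1.0 - math.tanh(10.0 * cx))
            dx = pi12 * (cxc + mu * (cx / 3.0 + 4.0 * cx ** 3 / 3.0
                                     - 256.0 * cx ** 7 / 105.0) + B + Ns)
            dxc = pi12 * (q * B * cxc - cx * (w2 + kappa * B))
            dn = 60.0 * (a * (1.0 - cn) - beta * cn)
            if stage == 0:
                k1x, k1xc, k1n = dx, dxc, dn
                acc_x, acc_xc, acc_n = dx, dxc, dn
                cx, cxc, cn = x + 0.5 * dt * dx, xc + 0.5 * dt * dxc, n + 0.5 * dt * dn
            elif stage == 1:
                acc_x += 2.0 * dx
                acc_xc += 2.0 * dxc
                acc_n += 2.0 * dn
                cx, cxc, cn = x + 0.5 * dt * dx, xc + 0.5 * dt * dxc, n + 0.5 * dt * dn
            elif stage == 2:
                acc_x += 2.0 * dx
                acc_xc += 2.0 * dxc
                acc_n += 2.0 * dn
                cx, cxc, cn = x + dt * dx, xc + dt * dxc, n + dt * dn
            else:
                acc_x += dx
                acc_xc += dxc
                acc_n += dn
        x += dt / 6.0 * acc_x
        xc += dt / 6.0 * acc_xc
        n += dt / 6.0 * acc_n
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        xs[i + 1] = x
    return xs


def _refine_minima(x: np.ndarray, dt: float) -> np.ndarray:
    """Interior local minima of a sampled trajectory with quadratic
    interpolation between samples."""
    interior = (x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])
    idx = np.flatnonzero(interior) + 1
    if idx.size == 0:
        raise DegenerateTrajectoryError("no local minima found in trajectory")
    denom = x[idx - 1] - 2.0 * x[idx] + x[idx + 1]
    offset = np.where(np.abs(denom) > 1e-15,
                      0.5 * (x[idx - 1] - x[idx + 1]) / np.where(denom == 0, 1, denom),
                      0.0)
    times = (idx + np.clip(offset, -0.5, 0.5)) * dt
    # collapse spurious pairs closer than half a cycle, keeping the deeper one
    keep = []
    for i, t in enumerate(times):
        if keep and t - times[keep[-1]] < 12.0:
            if x[idx[i]] < x[idx[keep[-1]]]:
                keep[-1] = i
        else:
            keep.append(i)
    return times[keep]


def detect_cbtmin(traj: Trajectory | np.ndarray, x: np.ndarray | None = None
                  ) -> np.ndarray:
    """CBTmin event times: one per cycle at the local minimum of x.

    Accepts a :class:`Trajectory`, or a pair of (times, x) arrays for
    direct use on sampled signals.
    """
    if isinstance(traj, Trajectory):
        return _refine_minima(traj.x, traj.dt_h)
    times = np.asarray(traj, dtype=float)
    xv = np.asarray(x, dtype=float)
    dt = times[1] - times[0]
    return times[0] + _refine_minima(xv, dt)


def integrate(light: EpochSeries, sleep: np.ndarray | EpochSeries,
              params: DynamicParams = DynamicParams(),
              total_days: float = 60.0,
              initial_state: tuple[float, float, float] = INITIAL_STATE
              ) -> Trajectory:
    """Integrate the pacemaker over the light segment repeated to >= 60 days.

    ``light`` must be a gap-free whole-day segment (per-bin piecewise
    constant forcing); ``sleep`` is the matching binary sleep state per bin.
    Fixed-step RK4 with step = min(1 min, bin width); deterministic.
    """
    if isinstance(sleep, EpochSeries):
        sleep = sleep.values
    sleep = np.asarray(sleep, dtype=float)
    if sleep.size != light.n:
        raise ValueError("sleep forcing must match the light segment length")
    if light.missing.any():
        raise ValueError("light segment must be gap-free (fill gaps first)")
    seg_days = light.duration_hours / 24.0
    if seg_days < 1.0 - 1e-9:
        raise InsufficientDataError("light segment shorter than 24 h")
    if abs(seg_days - round(seg_days)) > 1e-9:
        raise ValueError("light segment must be a whole number of days")
    seg_days = round(seg_days)

    n_reps = int(np.ceil(total_days / seg_days))
    dt_min = min(1.0, light.epoch_width)
    steps_per_bin = int(round(light.epoch_width / dt_min))
    I_steps = np.tile(np.repeat(light.values, steps_per_bin), n_reps)
    S_steps = np.tile(np.repeat(sleep, steps_per_bin), n_reps)
    dt = dt_min / 60.0

    xs = _simulate(I_steps, S_steps, dt, params.tau, params.b, params.G,
                   params.alpha0, params.beta, params.p, params.I0, params.mu,
                   params.q, params.kappa, params.rho, params.c,
                   1 if params.nonphotic_gated else 0, *initial_state)

    events = _refine_minima(xs, dt)
    start_clock = (light.start_time.hour + light.start_time.minute / 60.0
                   + light.start_time.second / 3600.0)
    return Trajectory(dt_h=dt, x=xs, cbtmin_events=events,
                      dlmo_events=events - params.psi_dlmo_cbtmin,
                      start_clock=start_clock,
                      rep_period_h=seg_days * 24.0,
                      total_h=n_reps * seg_days * 24.0)


def predict_dlmo_dynamic(rec: Recording,
                         params: DynamicParams = DynamicParams(),
                         cfg: PreprocessConfig = PreprocessConfig(),
                         total_days: float = 60.0) -> float:
    """Predict DLMO (linearized clock hours) for one recording.

    The cleaned, binned, gap-filled light segment is repeated for >= 60 days
    so the model settles onto a steady entrained cycle; the prediction is
    the mean clock time of (CBTmin - 7 h) over the final input repetition.
    """
    segment, sleep_seg = preprocess_recording(rec, cfg)
    traj = integrate(segment, sleep_seg, params, total_days=total_days)
    return dlmo_from_trajectory(traj)


def dlmo_from_trajectory(traj: Trajectory) -> float:
    """Mean clock time of the DLMO events over the final input repetition.

    One CBTmin falls in each entrained day, so the final repetition is the
    last ``rep_period / 24`` events (the very last cycle's minimum may land
    just beyond the simulation end).
    """
    n_days = max(1, int(round(traj.rep_period_h / 24.0)))
    final = traj.dlmo_events[-n_days:]
    if final.size == 0:
        raise DegenerateTrajectoryError("no DLMO events in the final repetition")
    clock = linearize((traj.start_clock + final) % 24.0)
    return circular_mean_clock(np.atleast_1d(clock))


def free_running_period(params: DynamicParams, days: float = 50.0,
                        burn_days: float = 20.0, dt_min: float = 1.0) -> float:
    """Free-running period (h) in darkness (0 lux, constant wake).

    Mean CBTmin-to-CBTmin interval over the post-burn-in cycles.
    """
    n_steps = int(round(days * 24.0 * 60.0 / dt_min))
    I = np.zeros(n_steps)
    S = np.zeros(n_steps)
    dt = dt_min / 60.0
    xs = _simulate(I, S, dt, params.tau, params.b, params.G, params.alpha0,
                   params.beta, params.p, params.I0, params.mu, params.q,
                   params.kappa, params.rho, params.c,
                   1 if params.nonphotic_gated else 0, *INITIAL_STATE)
    events = _refine_minima(xs, dt)
    events = events[events > burn_days * 24.0]
    if events.size < 2:
        raise DegenerateTrajectoryError("too few cycles after burn-in")
    return float((events[-1] - events[0]) / (events.size - 1))


def calibrate_period_constant(tau: float, params: DynamicParams = DynamicParams(),
                              tol: float = 1e-4, max_iter: int = 12) -> float:
    """Solve for the correction constant c such that the free-running period
    in darkness equals tau (secant iteration)."""
    c0, c1 = params.c * 0.999, params.c * 1.001
    f0 = free_running_period(replace(params, tau=tau, c=c0)) - tau
    f1 = free_running_period(replace(params, tau=tau, c=c1)) - tau
    for _ in range(max_iter):
        if abs(f1) < tol:
            return c1
        c2 = c1 - f1 * (c1 - c0) / (f1 - f0)
        c0, f0, c1 = c1, f1, c2
        f1 = free_running_period(replace(params, tau=tau, c=c1)) - tau
    return c1


def _default_grids() -> dict:
    return {
        "tau": [round(24.15 + 0.05 * i, 2) for i in range(26)],  # up to 25.40
        "b": [round(0.40 + 0.05 * i, 2) for i in range(9)],      # up to 0.80
        "G": [37.0 * 1.05 ** j for j in range(11)],
        "bin_width_min": [1, 2, 5, 10, 15, 30, 60, 120],
        "bin_stat": ["mean", "max"],
        "gap_policy": ["zero_fill", "mean_prev_2h"],
        "max_gap_h": [1, 2, 3, 4, 5, 6],
    }


@dataclass
class GridSearchResult:
    params: DynamicParams
    preprocess: PreprocessConfig
    rmse_min: float
    n_used: int
    n_evaluated: int


def grid_search(train: list[tuple[Recording, float]],
                grids: dict | None = None,
                base_params: DynamicParams = DynamicParams(),
                total_days: float = 60.0) -> GridSearchResult:
    """Exhaustive search over model and preprocessing grids minimising the
    training RMSE of predicted vs. measured DLMO.

    ``train`` pairs each recording with its measured DLMO (linearized
    hours). ``grids`` may restrict any of the seven searched dimensions;
    unlisted dimensions collapse to their defaults. Ties in RMSE break
    toward the configuration closest to the defaults, compared
    lexicographically in the order (tau, b, G, bin width, stat, policy,
    max gap).
    """
    g = _default_grids()
    if grids:
        for k, v in grids.items():
            if k not in g:
                raise ConfigError(f"unknown grid dimension {k!r}")
            g[k] = list(v)
    if any(len(v) == 0 for v in g.values()):
        raise ConfigError("empty grid dimension")

    defaults = PreprocessConfig()
    best_key, best = None, None
    n_evaluated = 0
    for bw, stat, policy, gap in itertools.product(
            g["bin_width_min"], g["bin_stat"], g["gap_policy"], g["max_gap_h"]):
        cfg = PreprocessConfig(bin_width_min=bw, bin_stat=stat,
                               gap_policy=policy, max_gap_h=gap)
        prepped = []
        for rec, dlmo in train:
            try:
                prepped.append((preprocess_recording(rec, cfg), dlmo))
            except InsufficientDataError:
                continue
        if not prepped:
            continue
        for tau, b, G in itertools.product(g["tau"], g["b"], g["G"]):
            params = replace(base_params, tau=tau, b=b, G=G)
            errs = []
            for (segment, sleep_seg), dlmo in prepped:
                traj = integrate(segment, sleep_seg, params, total_days=total_days)
                pred = dlmo_from_trajectory(traj)
                errs.append(wrap_diff_hours(pred, dlmo))
            rmse = float(np.sqrt(np.mean(np.square(errs))))
            n_evaluated += 1
            key = (rmse,
                   abs(tau - base_params.tau), abs(b - base_params.b),
                   abs(np.log(G / base_params.G)),
                   abs(bw - defaults.bin_width_min),
                   stat != defaults.bin_stat,
                   policy != defaults.gap_policy,
                   abs(gap - defaults.max_gap_h))
            if best_key is None or key < best_key:
                best_key = key
                best = GridSearchResult(params, cfg, rmse, len(prepped), 0)
    if best is None:
        raise InsufficientDataError("no training recording survived preprocessing")
    best.n_evaluated = n_evaluated
    return best
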