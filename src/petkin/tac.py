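"""Model time-activity curves: residue-AIF convolution and the 2C model.

Tissue curves are convolutions of a residue with the arterial input,
``mu(t) = (R * C_p)(t - delay)``.  PET frames record time-integrated counts,
so model curves are averaged over each frame interval rather than sampled at
mid-frame.  Convolutions are evaluated on a fine uniform grid (0.1 s by
default) via FFT and then frame-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.signal import fftconvolve

from .curves import SampledCurve
from .residue import ResidueFunction
from .schedule import FrameSchedule

__all__ = [
    "TwoCompartmentParams",
    "FineGrid",
    "frame_average",
    "convolve_residue_aif",
    "two_compartment_tac",
    "fit_two_compartment",
]

DEFAULT_DT_S = 0.1


@dataclass(frozen=True)
class FineGrid:
    """Uniform quadrature grid covering a frame schedule."""

    t_min: np.ndarray  # grid times, minutes
    dt_min: float
    frame_slices: list  # per-frame index slices into t_min

    @classmethod
    def for_schedule(cls, schedule: FrameSchedule, dt_s: float = DEFAULT_DT_S) -> "FineGrid":
        dt_min = dt_s / 60.0
        end_min = schedule.end_s[-1] / 60.0
        n = int(round(end_min / dt_min)) + 1
        t = np.arange(n) * dt_min
        slices = []
        for s, e in zip(schedule.start_s / 60.0, schedule.end_s / 60.0):
            i0 = int(np.floor(s / dt_min + 1e-9))
            i1 = max(i0 + 1, int(np.floor(e / dt_min + 1e-9)))
            slices.append(slice(i0, min(i1, n)))
        return cls(t, dt_min, slices)

    def average(self, values: np.ndarray) -> np.ndarray:
        """Frame averages of a gridded signal (last axis = time)."""
        return np.stack([values[..., sl].mean(axis=-1) for sl in self.frame_slices], axis=-1)


def frame_average(curve_on_grid: np.ndarray, grid: FineGrid) -> np.ndarray:
    return grid.average(curve_on_grid)


def _shifted_input(cp: SampledCurve, delay_min: float, grid: FineGrid) -> np.ndarray:
    """Input curve on the grid, delayed by ``delay_min`` (zero before start)."""
    t = grid.t_min - delay_min
    vals = np.interp(t, cp.time_min, cp.values)
    vals[t < cp.time_min[0]] = cp.values[0]
    return vals


def _grid_convolve(kernel_vals: np.ndarray, input_vals: np.ndarray, dt_min: float) -> np.ndarray:
    """Causal convolution (integral form) of two gridded signals.

    Trapezoid-rule quadrature: the raw discrete convolution is corrected by
    half the endpoint terms so the result is second-order accurate in dt.
    """
    n = input_vals.size
    raw = fftconvolve(kernel_vals, input_vals)[:n] * dt_min
    return raw - 0.5 * dt_min * (kernel_vals[0] * input_vals
                                 + kernel_vals[:n] * input_vals[0])


def convolve_residue_aif(R: ResidueFunction, cp: SampledCurve, delay_min: float,
                         schedule: FrameSchedule, dt_s: float = DEFAULT_DT_S,
                         grid: FineGrid | None = None) -> SampledCurve:
    """Frame-averaged tissue curve ``(R * C_p)(t - delay)``.

    A constant residue reproduces the running integral of the AIF (the
    irreversible-trapping, Patlak limit); a zero input gives a zero curve.
    """
    if grid is None:
        grid = FineGrid.for_schedule(schedule, dt_s)
    if delay_min >= grid.t_min[-1]:
        raise ValueError("delay pushes the input outside the scan window")
    cvals = _shifted_input(cp, delay_min, grid)
    rvals = R(np.minimum(grid.t_min, R.t_end))
    y = _grid_convolve(rvals, cvals, grid.dt_min)
    return SampledCurve(schedule.mid_min, grid.average(y), label="model TAC")


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Parameters of the two-exponential compartmental TAC model.

    ``eta(t) = f_b C_p(t - delay) + sum_m A_m int exp(-lam_m (t-s)) C_p(s - delay) ds``
    with all parameters except the delay constrained non-negative.
    """

    delay_min: float
    f_b: float
    A_1: float
    A_2: float
    lam_1: float
    lam_2: float

    def __post_init__(self):
        if min(self.f_b, self.A_1, self.A_2, self.lam_1, self.lam_2) < 0:
            raise ValueError("all parameters except the delay must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.delay_min, self.f_b, self.A_1, self.A_2,
                         self.lam_1, self.lam_2])


def _two_compartment_design(delay_min, lam_1, lam_2, cp, grid: FineGrid) -> np.ndarray:
    """Columns [C_p(t-d), exp(-lam_1)*C_p, exp(-lam_2)*C_p], frame-averaged."""
    cvals = _shifted_input(cp, delay_min, grid)
    cols = [grid.average(cvals)]
    for lam in (lam_1, lam_2):
        kern = np.exp(-lam * grid.t_min)
        cols.append(grid.average(_grid_convolve(kern, cvals, grid.dt_min)))
    return np.column_stack(cols)


def two_compartment_tac(params: TwoCompartmentParams, cp: SampledCurve,
                        schedule: FrameSchedule, dt_s: float = DEFAULT_DT_S,
                        grid: FineGrid | None = None) -> SampledCurve:
    """Frame-averaged curve of the two-compartment model."""
    if grid is None:
        grid = FineGrid.for_schedule(schedule, dt_s)
    X = _two_compartment_design(params.delay_min, params.lam_1, params.lam_2, cp, grid)
    y = X @ np.array([params.f_b, params.A_1, params.A_2])
    return SampledCurve(schedule.mid_min, y, label="2C model")


def fit_two_compartment(tac: np.ndarray, weights: np.ndarray, cp: SampledCurve,
                        schedule: FrameSchedule, delay_grid_min: np.ndarray | None = None,
                        dt_s: float = DEFAULT_DT_S):
    """Weighted least-squares fit of the two-compartment model.

    The amplitudes (f_b, A_1, A_2) enter linearly and are profiled out by
    non-negative least squares; the decay rates are optimised by Nelder-Mead
    on the log scale from several starting pairs; the delay by grid search
    (default -10 s .. +30 s in 2 s steps).

    Returns ``(TwoCompartmentParams, weighted_residual_norm)``.
    """
    tac = np.asarray(tac, dtype=float)
    w = np.asarray(weights, dtype=float)
    if tac.size != schedule.n_frames:
        raise ValueError("TAC length must equal the number of frames")
    if not np.all(np.isfinite(w)) or np.all(w <= 0):
        raise ValueError("weights must be positive somewhere and finite")
    if tac.size < 6:
        raise ValueError("need at least as many frames as parameters")
    if delay_grid_min is None:
        delay_grid_min = np.arange(-10.0, 30.0 + 1e-9, 2.0) / 60.0
    if len(np.atleast_1d(delay_grid_min)) == 0:
        raise ValueError("empty delay grid")
    grid = FineGrid.for_schedule(schedule, dt_s)
    sw = np.sqrt(w)
    b = sw * tac

    # per-delay caches: shifted input on the grid, its frame average, and the
    # frame-averaged exponential convolutions for each candidate rate
    delay_grid_min = np.atleast_1d(delay_grid_min)
    cache = {}

    def delay_parts(delay):
        if delay not in cache:
            cvals = _shifted_input(cp, delay, grid)
            cache[delay] = (cvals, grid.average(cvals), {})
        return cache[delay]

    def exp_col(delay, lam):
        cvals, _, cols = delay_parts(delay)
        if lam not in cols:
            kern = np.exp(-lam * grid.t_min)
            cols[lam] = grid.average(_grid_convolve(kern, cvals, grid.dt_min))
        return cols[lam]

    def profiled_sse(log_lams, delay):
        lam_1, lam_2 = np.exp(np.clip(log_lams, -12.0, 6.0))
        _, c0, _ = delay_parts(delay)
        X = np.column_stack([c0, exp_col(delay, lam_1), exp_col(delay, lam_2)])
        amps, rnorm = nnls(sw[:, None] * X, b)
        return rnorm ** 2, amps, (lam_1, lam_2)

    # coarse scan over delays and log-spaced rate pairs, then local refine
    lam_grid = np.exp(np.linspace(-4.5, 2.0, 8))
    coarse = []
    for delay in delay_grid_min:
        for i1 in range(lam_grid.size):
            for i2 in range(i1, lam_grid.size):
                p = np.log([lam_grid[i1], lam_grid[i2]])
                sse = profiled_sse(p, delay)[0]
                coarse.append((sse, delay, p))
    coarse.sort(key=lambda c: c[0])
    best = None
    seen_delays = set()
    for sse0, delay, p0 in coarse:
        if delay in seen_delays and len(seen_delays) >= 3:
            continue
        seen_delays.add(delay)
        res = minimize(lambda p: profiled_sse(p, delay)[0], x0=p0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-18, "maxiter": 400})
        sse, amps, lams = profiled_sse(res.x, delay)
        if best is None or sse < best[0]:
            best = (sse, delay, amps, lams)
        if len(seen_delays) >= 3 and sse0 > 4.0 * best[0] + 1e-30:
            break
    sse, delay, amps, (lam_1, lam_2) = best
    params = TwoCompartmentParams(delay_min=float(delay), f_b=float(amps[0]),
                                  A_1=float(amps[1]), A_2=float(amps[2]),
                                  lam_1=float(lam_1), lam_2=float(lam_2))
    return params, float(np.sqrt(sse))
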