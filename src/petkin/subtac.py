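"""Sub-TAC modelling and basis selection.

Segment mean curves are modelled, per injection, as one of

* a non-parametric residue convolved with the arterial input (the default),
* a scaled injection-site signal, or
* a non-parametric, non-decreasing distribution function convolved with the
  input (to absorb accumulation signals such as the bladder).

Apart from the tracer-arrival delay, every unknown enters linearly, so each
candidate delay reduces to a non-negative least-squares problem; the
monotone-residue constraint is encoded by writing the residue as a
non-negative combination of unit "drop" elements plus a constant, and the
delay is optimised by grid search.  The modelled curves, supplemented by the
input curve itself (spike residue) and its running integral (constant
residue, the Patlak element), form the candidate basis; cross-validated
backwards elimination then prunes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .curves import SampledCurve
from .residue import ResidueFunction
from .schedule import FrameSchedule
from .tac import FineGrid, _grid_convolve, _shifted_input

__all__ = [
    "InjectionWindow",
    "SubTAC",
    "SubTACBasis",
    "SubTACModeller",
    "fit_subtac",
    "select_segment_model",
    "build_basis",
    "injection_windows",
    "residue_knots",
    "DEFAULT_DELAY_GRID_MIN",
]

#: delay grid: -10 s to +30 s in 2 s steps
DEFAULT_DELAY_GRID_MIN = np.arange(-10.0, 30.0 + 1e-9, 2.0) / 60.0

#: internal quadrature step for sub-TAC design matrices (seconds)
MODEL_DT_S = 0.25

RESIDUE_KINDS = ("residue", "patlak")  # kinds that carry residue information


def residue_knots(t_end_min: float, n_knots: int = 12,
                  t_b_min: float = 0.25) -> np.ndarray:
    """Geometric knot grid, dense early where residues change fastest.

    A knot is pinned at the large-vessel bound T_B (15 s) so that vascular
    spikes can complete their drop exactly at the decomposition boundary.
    """
    first = min(1.0 / 15.0, t_end_min / n_knots)  # 4 s or finer
    inner = np.geomspace(first, t_end_min, n_knots - 1)
    if 0 < t_b_min < t_end_min:
        inner = np.unique(np.concatenate([inner, [t_b_min]]))
        # drop the inner knot closest to T_B (other than T_B itself) to keep
        # the grid size stable
        if inner.size > n_knots - 1:
            d = np.abs(inner - t_b_min)
            d[inner == t_b_min] = np.inf
            inner = np.delete(inner, int(np.argmin(d)))
    return np.concatenate([[0.0], inner])


@dataclass(frozen=True)
class InjectionWindow:
    """One injection's input curve and its frames within the full schedule."""

    tracer: str
    aif: SampledCurve            # on the injection-local clock
    schedule_local: FrameSchedule
    frame_index: np.ndarray      # indices into the full schedule


def injection_windows(source) -> list:
    """Extract InjectionWindow descriptors from a phantom SourceModel."""
    out = []
    masks = source.injection_frame_masks()
    for inj, mask in zip(source.injections, masks):
        local = FrameSchedule(inj.schedule.start_s - inj.start_s,
                              inj.schedule.duration_s)
        out.append(InjectionWindow(inj.tracer, inj.aif, local,
                                   np.flatnonzero(mask)))
    return out


@dataclass(frozen=True)
class SubTAC:
    """A modelled segment time-course over the full frame schedule."""

    kind: str                       # residue | iv_site | distribution | aif_spike | patlak
    curve: np.ndarray               # (N_T,) modelled values, >= 0
    delays_min: tuple               # per-injection fitted delay
    residues: tuple                 # per-injection ResidueFunction or None
    distributions: tuple = ()       # per-injection (knots, values) or None
    weighted_sse: float = np.nan
    source_segment: Optional[int] = None
    window_index: Optional[int] = None  # set for per-injection supplements
    scales: tuple = ()              # per-injection input-curve scale (spike kinds)

    @property
    def is_residue_kind(self) -> bool:
        return self.kind in RESIDUE_KINDS


@dataclass(frozen=True)
class SubTACBasis:
    """Selected sub-TAC columns assembled into the design matrix X."""

    columns: tuple                  # of SubTAC
    windows: tuple                  # of InjectionWindow

    def __post_init__(self):
        if not self.columns:
            raise ValueError("basis must contain at least one column")
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "windows", tuple(self.windows))

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([c.curve for c in self.columns])

    @property
    def n_frames(self) -> int:
        return self.columns[0].curve.size

    @property
    def K(self) -> int:
        return len(self.columns)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.columns) if c.is_residue_kind],
                        dtype=int)

    def restricted_X(self, frame_idx: np.ndarray) -> np.ndarray:
        return self.X[frame_idx]


class SubTACModeller:
    """Precomputes per-injection, per-delay design matrices for sub-TAC fits.

    The design columns (residue drop elements + constant; distribution rise
    elements + constant; the input and its integral) depend only on the
    injection windows and the delay grid, so one modeller is shared across
    all segments of a study.
    """

    def __init__(self, windows: Sequence[InjectionWindow],
                 delay_grid_min: Optional[np.ndarray] = None,
                 n_knots: int = 12, dt_s: float = MODEL_DT_S):
        if delay_grid_min is None:
            delay_grid_min = DEFAULT_DELAY_GRID_MIN
        self.delay_grid = np.atleast_1d(np.asarray(delay_grid_min, dtype=float))
        if self.delay_grid.size == 0:
            raise ValueError("empty delay grid")
        self.windows = list(windows)
        self.n_frames = 1 + max(int(w.frame_index.max()) for w in self.windows)
        self._per_window = []
        for w in self.windows:
            grid = FineGrid.for_schedule(w.schedule_local, dt_s)
            t_end = w.schedule_local.scan_end_min
            knots = residue_knots(t_end, n_knots)
            drop = _drop_elements(knots, grid.t_min)       # (m, n_grid)
            rise = 1.0 - drop                               # distribution ramps
            entry = {"grid": grid, "knots": knots, "designs": {}}
            for d in self.delay_grid:
                cvals = _shifted_input(w.aif, d, grid)
                conv_drop = np.stack([
                    grid.average(_grid_convolve(b, cvals, grid.dt_min))
                    for b in drop
                ])
                conv_const = grid.average(_grid_convolve(np.ones_like(cvals),
                                                         cvals, grid.dt_min))
                conv_rise = np.stack([conv_const - cd for cd in conv_drop])
                spike = grid.average(cvals)
                entry["designs"][float(d)] = {
                    "residue": np.vstack([conv_drop, conv_const]).T,
                    "distribution": np.vstack([conv_rise, conv_const]).T,
                    "iv_site": spike[:, None],
                    "spike": spike,
                    "patlak": conv_const,
                }
            self._per_window.append(entry)

    # -- fitting -------------------------------------------------------
    def fit(self, zbar: np.ndarray, sigma: np.ndarray, kind: str,
            source_segment: Optional[int] = None,
            shared_delay: bool = True) -> SubTAC:
        """Fit one sub-TAC of the given kind to a segment mean curve.

        Windows are temporally disjoint, so for a given delay each
        injection's constrained linear problem is solved by NNLS with
        weights 1/sigma^2.  With ``shared_delay`` (the default) one common
        tissue-arrival delay is grid-searched over the summed weighted SSE
        of all windows -- a sharp early injection then anchors the delay for
        injections whose input is too slow to resolve it; otherwise each
        window's delay is optimised independently.
        """
        zbar = np.asarray(zbar, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
            raise ValueError("segment SDs must be positive and finite")
        if kind not in {"residue", "iv_site", "distribution"}:
            raise ValueError(f"unknown sub-TAC kind {kind!r}")

        # per-window, per-delay NNLS solutions
        sols = []  # [window][delay] = (sse, coef, A)
        for w, entry in zip(self.windows, self._per_window):
            idx = w.frame_index
            y = zbar[idx]
            sw = 1.0 / sigma[idx]
            per_delay = []
            for d in self.delay_grid:
                A = entry["designs"][float(d)][kind]
                coef, rnorm = nnls(A * sw[:, None], y * sw)
                per_delay.append((rnorm ** 2, coef, A))
            sols.append(per_delay)
        if shared_delay:
            joint = [sum(sols[wi][di][0] for wi in range(len(self.windows)))
                     for di in range(self.delay_grid.size)]
            picks = [int(np.argmin(joint))] * len(self.windows)
        else:
            picks = [int(np.argmin([s[0] for s in per_delay]))
                     for per_delay in sols]

        curve = np.zeros(self.n_frames)
        delays, residues, dists, scales = [], [], [], []
        total_sse = 0.0
        for (w, entry), per_delay, di in zip(zip(self.windows, self._per_window),
                                             sols, picks):
            idx = w.frame_index
            sse, coef, A = per_delay[di]
            d = self.delay_grid[di]
            total_sse += sse
            curve[idx] = A @ coef
            delays.append(float(d))
            knots = entry["knots"]
            if kind == "residue":
                # coef = (drops d_1..d_m, terminal level c)
                drops, c = coef[:-1], coef[-1]
                vals = c + np.concatenate([np.cumsum(drops[::-1])[::-1], [0.0]])
                residues.append(ResidueFunction(knots, np.maximum(vals, 0.0)))
                dists.append(None)
            elif kind == "distribution":
                rises, c = coef[:-1], coef[-1]
                vals = c + np.concatenate([[0.0], np.cumsum(rises)])
                residues.append(None)
                dists.append((knots.copy(), vals))
            else:  # iv_site: single input-curve scale
                residues.append(None)
                dists.append(None)
                scales.append(float(coef[0]))
        return SubTAC(kind, curve, tuple(delays), tuple(residues),
                      tuple(dists), float(total_sse), source_segment,
                      scales=tuple(scales))

    def supplement(self, which: str, window_index: int, delay_min: float = 0.0) -> SubTAC:
        """Spike (input itself) or Patlak (input integral) basis column."""
        w = self.windows[window_index]
        entry = self._per_window[window_index]
        d = float(self.delay_grid[np.argmin(np.abs(self.delay_grid - delay_min))])
        curve = np.zeros(self.n_frames)
        des = entry["designs"][d]
        delays = [0.0] * len(self.windows)
        residues: list = [None] * len(self.windows)
        delays[window_index] = d
        scales = [0.0] * len(self.windows)
        if which == "aif_spike":
            curve[w.frame_index] = des["spike"]
            scales[window_index] = 1.0
            kind = "aif_spike"
        elif which == "patlak":
            curve[w.frame_index] = des["patlak"]
            # the Patlak element is the curve of a unit constant residue
            knots = entry["knots"]
            residues[window_index] = ResidueFunction(knots, np.ones_like(knots))
            kind = "patlak"
        else:
            raise ValueError(which)
        return SubTAC(kind, curve, tuple(delays), tuple(residues),
                      window_index=window_index, scales=tuple(scales))


def _drop_elements(knots: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit drop elements: 1 up to knot i-1, linear to 0 at knot i, 0 after."""
    m = knots.size - 1
    out = np.empty((m, t.size))
    for i in range(1, m + 1):
        t0, t1 = knots[i - 1], knots[i]
        out[i - 1] = np.clip((t1 - t) / (t1 - t0), 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# public one-shot wrappers
# ---------------------------------------------------------------------------

def fit_subtac(zbar, sigma, windows, kind: str = "residue",
               delay_grid_min=None, n_knots: int = 12,
               source_segment: Optional[int] = None) -> SubTAC:
    """Fit a single sub-TAC (see :meth:`SubTACModeller.fit`)."""
    modeller = SubTACModeller(windows, delay_grid_min, n_knots)
    return modeller.fit(zbar, sigma, kind, source_segment)


def select_segment_model(zbar, sigma, windows_or_modeller,
                         delay_grid_min=None, improvement_threshold: float = 0.10,
                         source_segment: Optional[int] = None) -> SubTAC:
    """Fit all sub-TAC kinds and keep the residue fit unless beaten.

    An alternative kind replaces the residue fit only when it lowers the
    weighted SSE by more than ``improvement_threshold`` (relative), so ties
    and marginal gains retain the physiologically interpretable residue.
    """
    if isinstance(windows_or_modeller, SubTACModeller):
        modeller = windows_or_modeller
    else:
        modeller = SubTACModeller(windows_or_modeller, delay_grid_min)
    fits = {k: modeller.fit(zbar, sigma, k, source_segment)
            for k in ("residue", "iv_site", "distribution")}
    base = fits["residue"]
    if base.weighted_sse <= 0:
        return base
    best = base
    for kind in ("iv_site", "distribution"):
        alt = fits[kind]
        if alt.weighted_sse < (1.0 - improvement_threshold) * base.weighted_sse \
                and alt.weighted_sse < best.weighted_sse:
            best = alt
    return best


# ---------------------------------------------------------------------------
# basis selection
# ---------------------------------------------------------------------------

def _cv_score(cols: list, ds, folds: list, weighted: bool) -> float:
    """Cross-validated weighted SSE of fitting segment means with NNLS.

    ``folds`` are interleaved subsets of the frame axis: for every segment
    and fold the coefficients are fitted on the remaining frames and the
    weighted squared error accumulated on the held-out frames, so columns
    that only chase noise in the segment means are penalised.
    """
    X = np.column_stack([c.curve for c in cols])
    n_frames = X.shape[0]
    total = 0.0
    for hold in folds:
        train = np.ones(n_frames, dtype=bool)
        train[hold] = False
        for s in range(ds.n_segments):
            y = ds.means[s]
            w = 1.0 / ds.sds[s] if weighted else np.ones_like(y)
            coef, _ = nnls((X * w[:, None])[train], (y * w)[train])
            resid = (y - X @ coef) * w
            total += float(np.sum(resid[hold] ** 2))
    return total


def build_basis(modelled: Sequence[SubTAC], ds, modeller: SubTACModeller,
                cv_folds: int = 5, rise_tolerance: float = 0.02,
                weighted: bool = True, add_supplements: bool = True) -> SubTACBasis:
    """Backwards elimination of candidate sub-TACs guided by cross-validation.

    Candidates are the modelled segment curves plus, per injection, the
    input curve (spike residue) and its integral (Patlak element).  Columns
    are removed one at a time, always the one whose removal gives the lowest
    cross-validated error, until the best removal would raise the CV error
    by more than ``rise_tolerance`` (relative).
    """
    cols = [c for c in modelled if np.any(c.curve != 0)]
    if not cols and not add_supplements:
        raise ValueError("no non-zero candidate sub-TACs")
    if add_supplements:
        for j in range(len(modeller.windows)):
            cols.append(modeller.supplement("aif_spike", j))
            cols.append(modeller.supplement("patlak", j))
    n_frames = ds.n_frames
    cv_folds = max(2, min(cv_folds, n_frames))
    folds = [np.arange(f, n_frames, cv_folds) for f in range(cv_folds)]
    score = _cv_score(cols, ds, folds, weighted)
    reference = score  # best CV error seen along the elimination path
    while len(cols) > 1:
        trial = [(_cv_score(cols[:i] + cols[i + 1:], ds, folds, weighted), i)
                 for i in range(len(cols))]
        best_score, best_i = min(trial)
        if best_score <= (1.0 + rise_tolerance) * reference:
            del cols[best_i]
            score = best_score
            reference = min(reference, best_score)
        else:
            break
    return SubTACBasis(tuple(cols), tuple(modeller.windows))
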