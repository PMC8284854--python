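"""Synthetic sources for simulation studies.

The simulated activity distribution is a spatial mixture of temporal
components, ``lambda(x, t) = sum_k alpha_k(x) mu_k(t)``: each tissue class k
has a non-negative coefficient profile ``alpha_k`` on the image grid and a
component time course ``mu_k`` obtained by convolving that tissue's residue
with the arterial input of each injection.

Two study families are generated:

* ``h2o_fdg`` -- a water bolus scan followed by an FDG infusion scan in the
  same session, with the total expected counts split between the tracers by
  a dose ratio (water:FDG between 16:1 and 64:1);
* ``repeat_h2o`` -- J identical water-bolus injections (J in {2, 4, 6, 8}),
  each with its own acquisition window.

Component curves are surrogates built from one-compartment (water) and
irreversible two-compartment (FDG) kinetics with parameters spanning the
tissue classes seen in breast-cancer flow-metabolism imaging; they emulate
the qualitative shape of patient-fitted curves, not any particular patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curves import SampledCurve
from .residue import ResidueFunction, kety_residue, two_compartment_residue
from .schedule import FDG_FRAMING, H2O_FRAMING, FrameSchedule, build_frame_schedule
from .tac import FineGrid, convolve_residue_aif

__all__ = [
    "RegionMap",
    "Injection",
    "SourceModel",
    "StudyDesign",
    "synth_aif",
    "build_phantom_1d",
    "build_phantom_2d",
    "build_source",
    "make_study",
    "load_phantom_spec",
    "DOSE_LEVELS",
    "DOSE_RATIOS",
    "REPEAT_COUNTS",
]

#: dose grid (relative expected-count levels) used across the experiments
DOSE_LEVELS = (0.3, 0.5, 0.7, 1.0, 1.5, 2.2, 3.2)
#: water:FDG expected-count ratios
DOSE_RATIOS = (16, 20, 25, 32, 40, 51, 64)
#: numbers of injections in the repeat-water designs
REPEAT_COUNTS = (2, 4, 6, 8)

#: expected total counts of a dose-1.0 study (sets the absolute noise level;
#: chosen so peak-frame voxel noise is in the 10-30% range typical of
#: clinical dynamic PET -- see docs/methods.md)
REFERENCE_TOTAL_COUNTS = 2.0e6


# ---------------------------------------------------------------------------
# Arterial input functions
# ---------------------------------------------------------------------------

def _gamma_variate(t, peak_delay, amplitude, sharpness):
    """Gamma-variate bolus: peak ``amplitude`` at ``peak_delay`` after onset."""
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_delay
    out[pos] = amplitude * x ** sharpness * np.exp(sharpness * (1.0 - x))
    return out


def synth_aif(tracer_kind: str, t_end_min: float, injection_min: float = 1.0,
              peak_delay_min: float = 0.5, amplitude: float = 30.0,
              sharpness: float = 3.0, infusion_min: float = 2.0,
              tail_fraction: float = 0.12, tail_slow_min: float = 40.0,
              dt_min: float = 1.0 / 120.0, label: str = "") -> SampledCurve:
    """Synthetic arterial input function.

    ``h2o_bolus`` is a gamma-variate bolus with a sharp peak shortly after
    injection and fast washout plus a small slow recirculation tail;
    ``fdg_infusion`` is the same base shape convolved with a rectangular
    infusion window (default 2 min, constant-pump administration).  As the
    infusion duration goes to zero the infusion shape converges to the bolus.
    """
    if min(peak_delay_min, amplitude, sharpness) < 0 or tail_fraction < 0:
        raise ValueError("AIF shape parameters must be non-negative")
    if tracer_kind not in {"h2o_bolus", "fdg_infusion"}:
        raise ValueError(f"unknown tracer kind {tracer_kind!r}")
    t = np.arange(0.0, t_end_min + dt_min / 2, dt_min)
    rel = t - injection_min
    base = _gamma_variate(rel, peak_delay_min, amplitude, sharpness)
    # slow recirculation tail, rises over ~1 min then decays slowly
    pos = rel > 0
    tail = np.zeros_like(t)
    tail[pos] = (tail_fraction * amplitude * (1.0 - np.exp(-rel[pos] / 1.0))
                 * np.exp(-rel[pos] / tail_slow_min))
    base = base + tail
    if tracer_kind == "fdg_infusion" and infusion_min > 0:
        n_box = max(1, int(round(infusion_min / dt_min)))
        box = np.full(n_box, 1.0 / n_box)
        base = np.convolve(base, box)[: t.size]
    return SampledCurve(t, base, label or tracer_kind)


# ---------------------------------------------------------------------------
# Coefficient maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Non-negative coefficient profiles alpha_k(x) with region names."""

    profiles: np.ndarray  # (K, *grid_shape)
    names: tuple

    def __post_init__(self):
        p = np.asarray(self.profiles, dtype=float)
        if p.ndim < 2:
            raise ValueError("profiles must be (K, *grid) shaped")
        if np.any(p < 0):
            raise ValueError("coefficient profiles must be non-negative")
        if not np.any(p > 0):
            raise ValueError("at least one region must be non-zero")
        object.__setattr__(self, "profiles", p)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_regions(self) -> int:
        return self.profiles.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.profiles.shape[1:]


def _ramp_profile(n, center, width, amplitude, edge):
    """Trapezoidal bump: flat top of ``width`` with linear ramps of ``edge``."""
    x = np.arange(n, dtype=float)
    half = width / 2.0
    d = np.abs(x - center)
    prof = np.clip((half + edge - d) / edge, 0.0, 1.0)
    return amplitude * prof


def _gauss_profile(n, center, width, amplitude, edge):
    x = np.arange(n, dtype=float)
    sigma = max(width / 2.355, 1e-6)  # width acts as FWHM
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


#: default six-region 1-D layout, loosely following the tissue classes of a
#: thoracic flow-metabolism field of view (positions on a 128-point axis)
DEFAULT_REGIONS_1D = (
    ("soft_tissue", 63.5, 200, 0.15),   # full-axis background activity
    ("spleen", 14, 12, 0.7),
    ("tumour", 38, 10, 1.0),
    ("myocardium", 60, 10, 0.9),
    ("normal_breast", 80, 14, 0.5),
    ("liver", 102, 14, 0.8),
    ("lv_blood", 120, 8, 1.0),
)

#: brain-like layout for repeat-water studies (grey/white/activation/background)
DEFAULT_REGIONS_REPEAT = (
    ("soft_tissue", 63.5, 200, 0.15),
    ("white_matter", 24, 28, 0.8),
    ("grey_matter", 64, 26, 1.0),
    ("activation", 96, 10, 1.0),
    ("background", 116, 12, 0.6),
)


def build_phantom_1d(region_spec: Optional[Sequence] = None, n: int = 128,
                     edge: float = 6.0, profile: str = "ramp") -> RegionMap:
    """Coefficient profiles on a 1-D axis.

    ``region_spec`` is a sequence of ``(name, center, width, amplitude)``;
    profiles are continuous trapezoids by default (``profile='ramp'``) or
    Gaussian bumps (``profile='gauss'``).  The default layout has six tissue
    classes covering the axis.  Continuous piecewise-linear profiles have a
    polynomial spectral tail, which keeps the reconstruction-MSE dose
    exponent in the regime studied here (see docs/methods.md).
    """
    if region_spec is None:
        region_spec = DEFAULT_REGIONS_1D
    region_spec = list(region_spec)
    if not region_spec:
        raise ValueError("region spec must contain at least one region")
    maker = {"ramp": _ramp_profile, "gauss": _gauss_profile}[profile]
    names, profs = [], []
    for name, center, width, amplitude in region_spec:
        if not (0 <= center < n):
            raise ValueError(f"region {name!r} center outside [0, {n})")
        names.append(name)
        profs.append(maker(n, center, width, amplitude, edge))
    return RegionMap(np.stack(profs), tuple(names))


def build_phantom_2d(region_spec: Optional[Sequence] = None, n: int = 128,
                     edge: float = 5.0) -> RegionMap:
    """Coefficient maps on an n x n grid: trapezoid-profile discs.

    ``region_spec`` entries are ``(name, (cy, cx), radius, amplitude)``.
    """
    if region_spec is None:
        region_spec = (
            ("tumour", (44, 48), 12, 1.0),
            ("normal_breast", (80, 64), 22, 0.5),
            ("myocardium", (40, 88), 10, 0.9),
            ("lv_blood", (58, 92), 6, 1.0),
        )
    region_spec = list(region_spec)
    if not region_spec:
        raise ValueError("region spec must contain at least one region")
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    names, profs = [], []
    for name, (cy, cx), radius, amplitude in region_spec:
        d = np.hypot(yy - cy, xx - cx)
        profs.append(amplitude * np.clip((radius + edge - d) / edge, 0.0, 1.0))
        names.append(name)
    return RegionMap(np.stack(profs), tuple(names))


# ---------------------------------------------------------------------------
# Source models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Injection:
    """One tracer administration and its acquisition window."""

    tracer: str                 # 'h2o' or 'fdg'
    aif: SampledCurve           # input curve on the injection-local clock
    schedule: FrameSchedule     # frames on the study clock
    start_s: float              # window start on the study clock


@dataclass(frozen=True)
class SourceModel:
    """Mixture source lambda(x,t) = sum_k alpha_k(x) mu_k(t) on a schedule."""

    region_map: RegionMap
    component_curves: np.ndarray      # (K, N_T) frame-averaged mu_k
    schedule: FrameSchedule           # full study schedule
    injections: tuple                 # of Injection
    residues: tuple                   # per region: {tracer: ResidueFunction}
    delays_min: tuple                 # per region: arrival delay (minutes)
    vascular_fractions: tuple = ()    # per region: blood-pool fraction fb

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames

    def frame_images(self) -> np.ndarray:
        """True activity, shape (N_T, *grid)."""
        K = self.region_map.n_regions
        profs = self.region_map.profiles.reshape(K, -1)
        lam = self.component_curves.T @ profs  # (N_T, n_vox)
        return lam.reshape((self.n_frames,) + self.region_map.grid_shape)

    def voxel_curves(self) -> np.ndarray:
        """True activity, shape (n_vox, N_T)."""
        K = self.region_map.n_regions
        profs = self.region_map.profiles.reshape(K, -1)
        return profs.T @ self.component_curves

    def injection_frame_masks(self) -> list:
        """Boolean masks assigning each frame to its injection window."""
        masks = []
        for inj in self.injections:
            m = np.zeros(self.n_frames, dtype=bool)
            lo = inj.schedule.start_s[0] - 1e-6
            hi = inj.schedule.end_s[-1] + 1e-6
            m[(self.schedule.start_s >= lo) & (self.schedule.end_s <= hi)] = True
            masks.append(m)
        return masks


#: surrogate kinetic parameters per tissue class:
#: water flow (K_1, mL/mL/min) and volume of distribution V = K_1/k_2;
#: FDG (K_1, k_2, k_3) with trapping flux K_i = K_1 k_3/(k_2+k_3);
#: vascular fraction adds a scaled copy of the input itself.
#: each component is a pure residue convolution except dedicated blood-pool
#: regions (fb > 0, no residue), whose component is the input curve itself
TISSUE_KINETICS = {
    "soft_tissue":   {"h2o": (0.15, 0.75), "fdg": (0.04, 0.50, 0.01), "fb": 0.0},
    "spleen":        {"h2o": (0.85, 0.90), "fdg": (0.30, 0.55, 0.02), "fb": 0.0},
    "tumour":        {"h2o": (0.45, 0.80), "fdg": (0.25, 0.45, 0.12), "fb": 0.0},
    "myocardium":    {"h2o": (0.80, 0.85), "fdg": (0.35, 0.50, 0.10), "fb": 0.0},
    "normal_breast": {"h2o": (0.12, 0.70), "fdg": (0.05, 0.40, 0.02), "fb": 0.0},
    "liver":         {"h2o": (0.55, 0.85), "fdg": (0.28, 0.70, 0.01), "fb": 0.0},
    "lv_blood":      {"h2o": None, "fdg": None, "fb": 1.0},
    # brain classes for repeat-water studies (K_1 in the grey/white range,
    # K_1/k_2 between 0.6 and 1.0 mL/mL)
    "white_matter":  {"h2o": (0.22, 0.80), "fdg": None, "fb": 0.0},
    "grey_matter":   {"h2o": (0.55, 0.90), "fdg": None, "fb": 0.0},
    "activation":    {"h2o": (0.85, 1.00), "fdg": None, "fb": 0.0},
    "background":    {"h2o": (0.35, 0.70), "fdg": None, "fb": 0.0},
}

#: per-region tracer arrival delays (seconds) -- staggered, on the 2 s grid
DEFAULT_REGION_DELAYS_S = (0.0, 4.0, 2.0, 6.0, 4.0, 0.0, 2.0, 6.0)


def _region_residue(name: str, tracer: str, t_end_min: float) -> ResidueFunction:
    params = TISSUE_KINETICS[name]
    if tracer == "h2o":
        if params["h2o"] is None:
            return ResidueFunction([0.0, t_end_min], [0.0, 0.0])
        K1, V = params["h2o"]
        return kety_residue(K1, K1 / V, T_E=t_end_min)
    if tracer == "fdg":
        if params["fdg"] is None:
            return ResidueFunction([0.0, t_end_min], [0.0, 0.0])
        K1, k2, k3 = params["fdg"]
        return two_compartment_residue(K1, k2, k3, T_E=t_end_min)
    raise ValueError(f"unknown tracer {tracer!r}")


def build_source(region_map: RegionMap, injections: Sequence[Injection],
                 kinetics: Optional[dict] = None,
                 delays_min: Optional[Sequence[float]] = None,
                 dt_s: float = 0.25) -> SourceModel:
    """Assemble the mixture source for a study.

    Each region's component curve is the concatenation, over injection
    windows, of the frame-averaged convolution of the region residue for
    that tracer with the injection's input curve, plus the region's vascular
    fraction of the input itself.  Windows are disjoint, so with J identical
    injections the component curve is the superposition of J shifted copies
    of the single-injection curve.
    """
    injections = tuple(injections)
    full = injections[0].schedule
    for inj in injections[1:]:
        full = full.concatenate(inj.schedule)
    if delays_min is None:
        delays_min = [DEFAULT_REGION_DELAYS_S[i % len(DEFAULT_REGION_DELAYS_S)] / 60.0
                      for i in range(region_map.n_regions)]
    delays_min = tuple(float(d) for d in delays_min)

    K = region_map.n_regions
    curves = np.zeros((K, full.n_frames))
    residues = []
    fbs = []
    offset = 0
    # precompute per-injection local grids once
    local = []
    for inj in injections:
        sched_local = FrameSchedule(inj.schedule.start_s - inj.start_s,
                                    inj.schedule.duration_s)
        grid = FineGrid.for_schedule(sched_local, dt_s)
        cp_on_grid = np.interp(grid.t_min, inj.aif.time_min, inj.aif.values,
                               left=inj.aif.values[0], right=inj.aif.values[-1])
        local.append((sched_local, grid, cp_on_grid))
    for k, name in enumerate(region_map.names):
        if kinetics is not None and name in kinetics:
            spec = kinetics[name]
        else:
            spec = TISSUE_KINETICS[name]
        offset = 0
        reg_res = {}
        for inj, (sched_local, grid, cp_grid) in zip(injections, local):
            t_end = sched_local.scan_end_min
            if isinstance(spec, ResidueFunction):
                R = spec
            else:
                R = _region_residue(name, inj.tracer, t_end) if name in TISSUE_KINETICS \
                    else spec[inj.tracer]
            reg_res[inj.tracer] = R
            fb = spec["fb"] if isinstance(spec, dict) and "fb" in spec else 0.0
            cp_local = SampledCurve(grid.t_min, cp_grid)
            tac = convolve_residue_aif(R, cp_local, delays_min[k], sched_local,
                                       grid=grid).values
            if fb:
                shifted = np.interp(grid.t_min - delays_min[k], grid.t_min,
                                    cp_grid, left=cp_grid[0])
                tac = tac + fb * grid.average(shifted)
            n = sched_local.n_frames
            curves[k, offset:offset + n] = tac
            offset += n
        residues.append(reg_res)
        fbs.append(float(spec["fb"]) if isinstance(spec, dict) and "fb" in spec
                   else 0.0)
    curves = np.maximum(curves, 0.0)  # guard round-off from the quadrature
    return SourceModel(region_map, curves, full, injections, tuple(residues),
                       delays_min, tuple(fbs))


def load_phantom_spec(path) -> RegionMap:
    """Read a 1-D region layout from a YAML or JSON config file.

    Expected structure::

        edge: 4.0            # optional, ramp width in bins
        profile: ramp        # optional, 'ramp' or 'gauss'
        regions:
          - {name: tumour, center: 38, width: 10, amplitude: 1.0}
          - ...
    """
    import json

    import yaml

    text = open(path).read()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    regions = [(r["name"], r["center"], r["width"], r["amplitude"])
               for r in cfg["regions"]]
    return build_phantom_1d(regions, edge=cfg.get("edge", 6.0),
                            profile=cfg.get("profile", "ramp"))


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """A fully specified, replicable simulation design."""

    kind: str                   # 'h2o_fdg' or 'repeat_h2o'
    dose: float                 # relative dose level
    ratio: Optional[int]        # water:FDG count ratio (h2o_fdg)
    n_injections: int
    n_replicates: int
    seed: int
    source: SourceModel
    total_counts: float         # expected counts for the whole study
    injection_counts: tuple     # expected counts per injection window

    def replicate_seeds(self) -> np.ndarray:
        """Deterministic per-replicate seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        return np.array([int(s.generate_state(1)[0] % (2 ** 31))
                         for s in ss.spawn(self.n_replicates)])


def _h2o_injection(start_s: float, t_end_min: float) -> Injection:
    sched = build_frame_schedule(H2O_FRAMING, origin_s=start_s)
    aif = synth_aif("h2o_bolus", t_end_min=t_end_min, injection_min=1.0,
                    peak_delay_min=0.5, amplitude=30.0)
    return Injection("h2o", aif, sched, start_s)


def _fdg_injection(start_s: float, t_end_min: float) -> Injection:
    sched = build_frame_schedule(FDG_FRAMING, origin_s=start_s)
    aif = synth_aif("fdg_infusion", t_end_min=t_end_min, injection_min=1.0,
                    peak_delay_min=0.5, amplitude=8.0, infusion_min=2.0)
    return Injection("fdg", aif, sched, start_s)


def make_study(kind: str, dose: float = 1.0, ratio_or_j=25, n_replicates: int = 50,
               seed: int = 0, region_map: Optional[RegionMap] = None,
               allow_off_grid: bool = False) -> StudyDesign:
    """Build a replicable study design.

    ``kind='h2o_fdg'`` uses a water bolus scan followed by an FDG infusion
    scan, splitting expected counts ratio:1 between them (water gets
    r/(r+1)); ``kind='repeat_h2o'`` uses J identical water scans with equal
    count shares.  Doses and ratios are validated against the supported
    grids unless ``allow_off_grid``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if not allow_off_grid and not np.any(np.isclose(dose, DOSE_LEVELS)):
        raise ValueError(f"dose {dose} not on the supported grid {DOSE_LEVELS}")
    if kind == "h2o_fdg":
        ratio = int(ratio_or_j)
        if not allow_off_grid and ratio not in DOSE_RATIOS:
            raise ValueError(f"ratio {ratio} not on the supported grid {DOSE_RATIOS}")
        if region_map is None:
            region_map = build_phantom_1d()
        h2o_end = build_frame_schedule(H2O_FRAMING).total_duration_s
        inj1 = _h2o_injection(0.0, h2o_end / 60.0)
        inj2 = _fdg_injection(h2o_end, 61.0)
        source = build_source(region_map, [inj1, inj2])
        total = dose * REFERENCE_TOTAL_COUNTS
        shares = (total * ratio / (ratio + 1.0), total / (ratio + 1.0))
        return StudyDesign(kind, float(dose), ratio, 2, int(n_replicates),
                           int(seed), source, total, shares)
    if kind == "repeat_h2o":
        J = int(ratio_or_j)
        if not allow_off_grid and J not in REPEAT_COUNTS:
            raise ValueError(f"J {J} not in the supported set {REPEAT_COUNTS}")
        if region_map is None:
            region_map = build_phantom_1d(DEFAULT_REGIONS_REPEAT)
        block = build_frame_schedule(H2O_FRAMING).total_duration_s
        injections = [_h2o_injection(j * block, block / 60.0) for j in range(J)]
        source = build_source(region_map, injections)
        total = dose * REFERENCE_TOTAL_COUNTS
        shares = tuple(total / J for _ in range(J))
        return StudyDesign(kind, float(dose), None, J, int(n_replicates),
                           int(seed), source, total, shares)
    raise ValueError(f"unknown study kind {kind!r}")
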