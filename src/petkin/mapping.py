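"""Voxel-level fitting and kinetic-parameter mapping.

Each voxel time course is approximated by a non-negative combination of the
selected sub-TACs (a small quadratic program solved by NNLS); the voxel
residue is the same combination of the residue-carrying columns, and the
kinetic summaries (V_B, V_D, K_D, K_i, K_1, extraction, MTT) follow from its
decomposition.  The voxel delay is the flow-weighted average of the column
delays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .residue import (DEFAULT_TB_MIN, KineticSummaries, ResidueFunction,
                      residue_decompose, residue_summaries)
from .segmentation import segment_image
from .subtac import (SubTAC, SubTACBasis, SubTACModeller, injection_windows,
                     select_segment_model)

__all__ = [
    "VoxelFit",
    "fit_voxel",
    "map_voxel_kinetics",
    "map_image",
    "estimate_basis",
    "basis_from_source",
    "true_parameter_maps",
    "PARAMETER_NAMES",
]

PARAMETER_NAMES = ("V_B", "V_D", "K_D", "K_i", "MTT", "extraction")


@dataclass(frozen=True)
class VoxelFit:
    """Non-negative linear fit of one voxel time course."""

    alpha: np.ndarray          # (K,) coefficients, >= 0
    fitted: np.ndarray         # (N_T,) X @ alpha
    residual_norm: float       # ||y - X alpha|| (weighted if weights given)


def fit_voxel(z: np.ndarray, basis: SubTACBasis | np.ndarray,
              weights: Optional[np.ndarray] = None) -> VoxelFit:
    """Weighted NNLS fit of a voxel curve onto the sub-TAC basis."""
    X = basis.X if isinstance(basis, SubTACBasis) else np.asarray(basis, float)
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size != X.shape[0]:
        raise ValueError("voxel curve length must match the basis rows")
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    if weights is None:
        alpha, rnorm = nnls(X, z)
        fitted = X @ alpha
    else:
        w = np.sqrt(np.asarray(weights, dtype=float))
        alpha, rnorm = nnls(X * w[:, None], z * w)
        fitted = X @ alpha
    return VoxelFit(alpha, fitted, float(rnorm))


def map_voxel_kinetics(fit: VoxelFit, basis: SubTACBasis, injection: int = 0,
                       T_B: float = DEFAULT_TB_MIN) -> KineticSummaries:
    """Kinetic summaries of one voxel for a given injection.

    The voxel residue is the alpha-weighted sum of the residue-carrying
    columns (non-parametric residues and Patlak/constant elements); input
    (spike) columns of this injection contribute their coefficient to the
    vascular volume.  The delay is the flow-weighted mean of column delays.
    Voxels with no residue-carrying support return all-zero summaries.
    """
    t_end = basis.windows[injection].schedule_local.scan_end_min
    combined: Optional[ResidueFunction] = None
    wsum = 0.0
    dsum = 0.0
    spike_vb = 0.0
    for k, col in enumerate(basis.columns):
        a = fit.alpha[k]
        if a <= 0:
            continue
        if col.kind in ("aif_spike", "iv_site"):
            # blood-pool/injection-site columns: coefficient (times the
            # column's input-curve scale) is vascular volume
            if col.scales:
                spike_vb += a * col.scales[injection] if len(col.scales) > injection \
                    else 0.0
            elif col.window_index in (None, injection):
                spike_vb += a
            continue
        if not col.is_residue_kind:
            continue
        R = col.residues[injection]
        if R is None:
            continue
        scaled = R.scaled(a)
        combined = scaled if combined is None else combined + scaled
        kd_k = _column_flow(R, T_B, t_end)
        wsum += a * kd_k
        dsum += a * kd_k * col.delays_min[injection]
    delay = dsum / wsum if wsum > 0 else 0.0
    if combined is None or not np.any(combined.knot_values > 0):
        return KineticSummaries(V_B=spike_vb, V_D=0.0, K_D=0.0, K_i=0.0,
                                delay_min=delay)
    dec = residue_decompose(combined, T_B=T_B, T_E=min(t_end, max(combined.t_end, T_B * 2)))
    s = residue_summaries(dec, delay_min=delay)
    return KineticSummaries(V_B=s.V_B + spike_vb, V_D=s.V_D, K_D=s.K_D,
                            K_i=s.K_i, delay_min=delay)


def _column_flow(R: ResidueFunction, T_B: float, t_end: float) -> float:
    """K_D of a unit column residue (used for flow-weighted delays)."""
    if not np.any(R.knot_values > 0):
        return 0.0
    dec = residue_decompose(R, T_B=T_B, T_E=min(t_end, max(R.t_end, T_B * 2)))
    return float(dec.R_D(0.0))


def map_image(Z: np.ndarray, basis: SubTACBasis,
              weights: Optional[np.ndarray] = None, injection: int = 0,
              T_B: float = DEFAULT_TB_MIN):
    """Fit every voxel and return parameter maps plus fit diagnostics.

    Returns ``(maps, alphas, residual_norms)`` where ``maps`` is a dict of
    (n_vox,) arrays for V_B, V_D, K_D, K_i, K_1, MTT, extraction and delay.
    Undefined MTT/extraction values are stored as NaN.
    """
    Z = np.asarray(Z, dtype=float)
    n_vox = Z.shape[0]
    maps = {p: np.zeros(n_vox) for p in
            ("V_B", "V_D", "K_D", "K_i", "K_1", "MTT", "extraction", "delay")}
    maps["MTT"][:] = np.nan
    maps["extraction"][:] = np.nan
    alphas = np.zeros((n_vox, basis.K))
    rnorms = np.zeros(n_vox)
    for i in range(n_vox):
        fit = fit_voxel(Z[i], basis, weights)
        alphas[i] = fit.alpha
        rnorms[i] = fit.residual_norm
        s = map_voxel_kinetics(fit, basis, injection, T_B)
        maps["V_B"][i] = s.V_B
        maps["V_D"][i] = s.V_D
        maps["K_D"][i] = s.K_D
        maps["K_i"][i] = s.K_i
        maps["K_1"][i] = s.K_1
        maps["delay"][i] = s.delay_min
        if s.mtt_min is not None:
            maps["MTT"][i] = s.mtt_min
        if s.extraction is not None:
            maps["extraction"][i] = s.extraction
    return maps, alphas, rnorms


# ---------------------------------------------------------------------------
# basis construction routes
# ---------------------------------------------------------------------------

def estimate_basis(Z: np.ndarray, windows, s_target: int = 12,
                   delay_grid_min=None, n_knots: int = 12, cv_folds: int = 5,
                   improvement_threshold: float = 0.10,
                   rise_tolerance: float = 0.02) -> SubTACBasis:
    """Data-adaptive basis: segment, model each segment, prune by CV.

    This is the full two-step construction run on reconstructed data; the
    alternative :func:`basis_from_source` uses the known simulation truth.
    """
    from .subtac import build_basis  # local import to keep module load light

    ds = segment_image(Z, s_target=s_target)
    modeller = SubTACModeller(windows, delay_grid_min, n_knots)
    modelled = [select_segment_model(ds.means[s], ds.sds[s], modeller,
                                     improvement_threshold=improvement_threshold,
                                     source_segment=s)
                for s in range(ds.n_segments)]
    return build_basis(modelled, ds, modeller, cv_folds=cv_folds,
                       rise_tolerance=rise_tolerance)


def basis_from_source(source) -> SubTACBasis:
    """Oracle basis whose columns are the true component curves."""
    windows = injection_windows(source)
    fbs = source.vascular_fractions or (0.0,) * source.region_map.n_regions
    cols = []
    for k, name in enumerate(source.region_map.names):
        residues = tuple(source.residues[k].get(w.tracer) for w in windows)
        delays = tuple(source.delays_min[k] for _ in windows)
        has_tissue = any(R is not None and np.any(R.knot_values > 0)
                         for R in residues)
        if not has_tissue and fbs[k] > 0:
            # pure blood-pool component: the input curve itself
            cols.append(SubTAC("aif_spike", source.component_curves[k].copy(),
                               delays, tuple(None for _ in windows),
                               scales=tuple(fbs[k] for _ in windows)))
        else:
            cols.append(SubTAC("residue", source.component_curves[k].copy(),
                               delays, residues, source_segment=None))
    return SubTACBasis(tuple(cols), tuple(windows))


def true_parameter_maps(source, injection: int = 0,
                        T_B: float = DEFAULT_TB_MIN) -> dict:
    """Ground-truth kinetic maps implied by the phantom mixture."""
    windows = injection_windows(source)
    basis = basis_from_source(source)
    profs = source.region_map.profiles.reshape(source.region_map.n_regions, -1)
    n_vox = profs.shape[1]
    maps = {p: np.zeros(n_vox) for p in ("V_B", "V_D", "K_D", "K_i", "K_1")}
    per_region = []
    for k in range(profs.shape[0]):
        fake = VoxelFit(np.eye(profs.shape[0])[k], np.zeros(basis.n_frames), 0.0)
        per_region.append(map_voxel_kinetics(fake, basis, injection, T_B))
    for p in maps:
        vals = np.array([getattr(s, p) if p != "K_1" else s.K_1
                         for s in per_region])
        maps[p] = vals @ profs
    return maps
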