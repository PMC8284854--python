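"""Combined-versus-separate estimation and MSE evaluation statistics.

For a multiple-injection study the voxel coefficients can be estimated once
from the full time course (combined analysis) or per injection window
(separate analysis).  Under Gaussian approximation the ratio of the
combined to the separate MSE for a kinetic parameter of injection j is

    MSE_C / MSE_j = sigma_j^{-2} / (sigma_1^{-2} + ... + sigma_J^{-2}),

which is 1/J for identical replicate injections, so the percent improvement
grows proportionally to (J - 1).  Simulated designs are scored by a
normalised squared-error functional over injection windows, summarised over
replicates, and interpreted through small meta-regressions of the scaled
MSE on design covariates and of the reconstruction error on dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mapping import fit_voxel
from .subtac import SubTACBasis

__all__ = [
    "ErrorAssessment",
    "MseSummary",
    "MetaRegressionFit",
    "fit_combined_and_separate",
    "predict_sources",
    "assess_error",
    "summarize_mse",
    "theory_mse_ratio",
    "simulate_mse_ratio",
    "fit_scaled_mse",
    "fit_dose_model",
    "dose_equivalence",
    "improvement_from_coefficient",
    "relative_rmse",
    "local_error_slopes",
]


# ---------------------------------------------------------------------------
# combined / separate voxel estimation
# ---------------------------------------------------------------------------

def fit_combined_and_separate(Z: np.ndarray, basis: SubTACBasis,
                              masks: Sequence[np.ndarray],
                              weights: Optional[np.ndarray] = None):
    """Non-negative voxel fits on the full time course and per window.

    Returns ``(alpha_C, alpha_S)`` with shapes (n_vox, K) and
    (J, n_vox, K); the separate fit for window j uses only the frames of
    that window (columns that vanish there simply get zero coefficients).
    With a single injection the two coincide.
    """
    Z = np.asarray(Z, dtype=float)
    X = basis.X
    n_vox = Z.shape[0]
    K = X.shape[1]
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if any(not m.any() for m in masks):
        raise ValueError("empty injection window")
    alpha_C = np.empty((n_vox, K))
    alpha_S = np.empty((len(masks), n_vox, K))
    for i in range(n_vox):
        alpha_C[i] = fit_voxel(Z[i], X, weights).alpha
        for j, m in enumerate(masks):
            wj = None if weights is None else weights[m]
            alpha_S[j, i] = fit_voxel(Z[i][m], X[m], wj).alpha
    return alpha_C, alpha_S


def predict_sources(basis_X: np.ndarray, alpha_C: np.ndarray,
                    alpha_S: np.ndarray, masks: Sequence[np.ndarray]):
    """Fitted sources for combined and separate coefficient sets.

    The separate-source prediction uses, within each window, the curve
    implied by that window's own coefficients.
    """
    lam_C = alpha_C @ basis_X.T
    lam_S = np.empty_like(lam_C)
    for j, m in enumerate(masks):
        lam_S[:, m] = alpha_S[j] @ basis_X[m].T
    return lam_C, lam_S


# ---------------------------------------------------------------------------
# squared-error functional and MSE summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorAssessment:
    """Per-replicate normalised squared errors for the two analyses."""

    se_combined: np.ndarray
    se_separate: np.ndarray
    durations: np.ndarray          # window durations D_j (minutes)
    peak_intensities: np.ndarray   # window maxima of the true source

    def __post_init__(self):
        for name in ("se_combined", "se_separate"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0):
                raise ValueError("squared errors must be non-negative")
            object.__setattr__(self, name, v)


def assess_error(lam_hat: np.ndarray, lam_true: np.ndarray,
                 durations_min: np.ndarray, masks: Sequence[np.ndarray],
                 peak_mode: str = "max") -> float:
    """Normalised squared error of a fitted source.

    ``Se = mean_x sum_j (1/(D_j lbar_j^2)) int_{T_j} (lam_hat - lam)^2 dt``
    with the time integral taken by frame-duration weighting, D_j the window
    duration and lbar_j the spatio-temporal maximum (or 99th percentile,
    ``peak_mode='q99'``) of the true source in window j.  The spatial
    integral is the mean over voxels so values are comparable across grids.
    """
    lam_hat = np.asarray(lam_hat, dtype=float)
    lam_true = np.asarray(lam_true, dtype=float)
    if lam_hat.shape != lam_true.shape:
        raise ValueError("fitted and true sources must share a grid")
    durations_min = np.asarray(durations_min, dtype=float)
    sq = (lam_hat - lam_true) ** 2
    total = 0.0
    for m in masks:
        m = np.asarray(m, dtype=bool)
        D_j = durations_min[m].sum()
        window_vals = lam_true[:, m]
        if peak_mode == "max":
            lbar = float(window_vals.max())
        elif peak_mode == "q99":
            lbar = float(np.quantile(window_vals, 0.99))
        else:
            raise ValueError(peak_mode)
        if D_j <= 0 or lbar <= 0:
            raise ValueError("windows need positive duration and intensity")
        integ = (sq[:, m] * durations_min[m]).sum(axis=1)  # per-voxel time integral
        total += float(np.mean(integ)) / (D_j * lbar ** 2)
    return total


@dataclass(frozen=True)
class MseSummary:
    """Replicate means of the squared-error functional and their contrast."""

    mse_combined: float
    mse_separate: float
    se_combined_stderr: float
    se_separate_stderr: float
    n_replicates: int

    @property
    def percent_improvement(self) -> float:
        """(MSE_S / MSE_C - 1) x 100."""
        return (self.mse_separate / self.mse_combined - 1.0) * 100.0

    @property
    def percent_improvement_stderr(self) -> float:
        # delta-method on the ratio with independent numerator/denominator
        r = self.mse_separate / self.mse_combined
        rel = np.sqrt((self.se_separate_stderr / self.mse_separate) ** 2
                      + (self.se_combined_stderr / self.mse_combined) ** 2)
        return 100.0 * r * rel


def summarize_mse(se_combined: np.ndarray, se_separate: np.ndarray) -> MseSummary:
    se_c = np.asarray(se_combined, dtype=float)
    se_s = np.asarray(se_separate, dtype=float)
    if se_c.size < 2 or se_s.size < 2:
        raise ValueError("need at least two replicates for standard errors")
    return MseSummary(
        mse_combined=float(se_c.mean()),
        mse_separate=float(se_s.mean()),
        se_combined_stderr=float(se_c.std(ddof=1) / np.sqrt(se_c.size)),
        se_separate_stderr=float(se_s.std(ddof=1) / np.sqrt(se_s.size)),
        n_replicates=int(se_c.size),
    )


# ---------------------------------------------------------------------------
# theory: the MSE ratio under Gaussian approximation
# ---------------------------------------------------------------------------

def theory_mse_ratio(sigmas: Sequence[float], j: int = 0) -> float:
    """``sigma_j^{-2} / sum_k sigma_k^{-2}`` -- always <= 1.

    ``sigmas`` are the per-injection standard deviations of the kinetic
    parameter; ``j`` indexes the injection of interest (0-based).
    """
    s = np.asarray(sigmas, dtype=float)
    if np.any(s <= 0):
        raise ValueError("per-injection standard deviations must be positive")
    if not 0 <= j < s.size:
        raise ValueError("injection index out of range")
    prec = s ** (-2.0)
    return float(prec[j] / prec.sum())


def simulate_mse_ratio(sigmas: Sequence[float], n_replicates: int = 2000,
                       seed: int = 0, j: int = 0, n_obs: int = 24,
                       n_params: int = 3):
    """Monte-Carlo check of the MSE-ratio formula in a Gaussian linear model.

    All J injections share a random full-rank design X and true coefficients;
    injection j's data carry noise scale ``sigmas[j]``.  The separate
    estimate is per-injection least squares; the combined estimate is
    precision-weighted least squares on the stacked data.  Returns
    ``(ratio_hat, stderr)`` for the first coefficient of injection ``j``.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    J = sigmas.size
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_obs, n_params))
    # make the Gram matrix comfortably positive definite
    X[:, 0] += 2.0
    beta = rng.normal(size=n_params)
    prec = sigmas ** -2.0
    err_sep = np.empty(n_replicates)
    err_com = np.empty(n_replicates)
    XtX_inv = np.linalg.inv(X.T @ X)
    H_sep = XtX_inv @ X.T
    H_com = np.linalg.inv(X.T @ X * prec.sum())  # GLS with shared design
    for r in range(n_replicates):
        noise = rng.normal(size=(J, n_obs)) * sigmas[:, None]
        y = X @ beta + noise
        b_sep = H_sep @ y[j]
        # GLS: sum_j w_j X^T y_j
        rhs = X.T @ (prec @ y)
        b_com = H_com @ rhs
        err_sep[r] = (b_sep[0] - beta[0]) ** 2
        err_com[r] = (b_com[0] - beta[0]) ** 2
    ratio = err_com.mean() / err_sep.mean()
    rel = np.sqrt(err_com.std(ddof=1) ** 2 / err_com.mean() ** 2
                  + err_sep.std(ddof=1) ** 2 / err_sep.mean() ** 2) / np.sqrt(n_replicates)
    return float(ratio), float(ratio * rel)


# ---------------------------------------------------------------------------
# meta-regressions of simulation summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaRegressionFit:
    """OLS fit of a log-scale meta-model over simulation cells."""

    params: dict
    bse: dict
    r_squared: float

    def __getitem__(self, name):
        return self.params[name]


def improvement_from_coefficient(coef: float) -> float:
    """Method-indicator coefficient -> percent improvement, 100 (e^c - 1)."""
    return 100.0 * float(np.expm1(coef))


def fit_scaled_mse(table: pd.DataFrame, design_kind: str) -> MetaRegressionFit:
    """OLS of log(MSE / sigma2_uptake) on the design covariates.

    ``design_kind='h2o_fdg'`` fits an intercept, a separate-analysis
    indicator and the dose ratio; ``'repeat'`` fits the indicator, the
    number of injections and their interaction.  The table needs columns
    ``mse``, ``uptake_var``, ``method`` ('combined'/'separate') and either
    ``dose_ratio`` or ``n_injections``.
    """
    df = table.copy()
    y = np.log(df["mse"].to_numpy() / df["uptake_var"].to_numpy())
    I = (df["method"] == "separate").astype(float).to_numpy()
    if design_kind == "h2o_fdg":
        X = pd.DataFrame({"const": 1.0, "I": I,
                          "DR": df["dose_ratio"].to_numpy(dtype=float)})
    elif design_kind == "repeat":
        J = df["n_injections"].to_numpy(dtype=float)
        X = pd.DataFrame({"const": 1.0, "I": I, "J": J, "IxJ": I * J})
    else:
        raise ValueError(design_kind)
    # a single-cell table makes some covariates constant; drop them
    for col in list(X.columns):
        if col != "const" and X[col].nunique() == 1:
            X = X.drop(columns=col)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient meta-regression design")
    res = sm.OLS(y, X).fit()
    return MetaRegressionFit(dict(res.params), dict(res.bse),
                             float(res.rsquared))


def fit_dose_model(table: pd.DataFrame) -> MetaRegressionFit:
    """Dose decay of the reconstruction error: log(var) ~ g0 - g_tau log(tau) + g_M M.

    ``table`` needs columns ``uptake_var`` and ``dose`` and optionally ``M``
    (dose ratio or number of injections).  The returned ``gamma_tau`` is the
    positive decay exponent of variance with dose.
    """
    df = table.copy()
    if df["dose"].nunique() < 2:
        raise ValueError("need at least two dose levels")
    y = np.log(df["uptake_var"].to_numpy(dtype=float))
    cols = {"const": 1.0, "log_tau": np.log(df["dose"].to_numpy(dtype=float))}
    if "M" in df.columns and df["M"].nunique() > 1:
        cols["M"] = df["M"].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    res = sm.OLS(y, X).fit()
    params = dict(res.params)
    params["gamma_tau"] = -params.pop("log_tau")
    bse = dict(res.bse)
    bse["gamma_tau"] = bse.pop("log_tau")
    return MetaRegressionFit(params, bse, float(res.rsquared))


def dose_equivalence(improvement_fraction: float, gamma_tau: float) -> float:
    """Percent dose increase matching a given MSE improvement.

    With reconstruction MSE decaying as tau^-gamma, an MSE improvement of
    fraction f by combined analysis is worth a ``100 ((1+f)^{1/gamma} - 1)``
    percent dose increase under separate analysis.
    """
    if gamma_tau <= 0:
        raise ValueError("gamma_tau must be positive")
    if improvement_fraction <= -1:
        raise ValueError("improvement fraction must exceed -1")
    return 100.0 * ((1.0 + improvement_fraction) ** (1.0 / gamma_tau) - 1.0)


# ---------------------------------------------------------------------------
# relative RMSE and local-error analysis
# ---------------------------------------------------------------------------

def relative_rmse(rmse_reference: np.ndarray, rmse_method: np.ndarray):
    """Cellwise RMSE ratio reference/method, averaged with a standard error."""
    num = np.asarray(rmse_reference, dtype=float)
    den = np.asarray(rmse_method, dtype=float)
    if np.any(den <= 0):
        raise ValueError("method RMSE must be positive")
    e = (num / den).ravel()
    return float(e.mean()), float(e.std(ddof=1) / np.sqrt(e.size)) if e.size > 1 else 0.0


def local_error_slopes(rmse_param: np.ndarray, theta: np.ndarray,
                       local_error: np.ndarray):
    """Slope and R^2 of log(RMSE/theta) on log(sigma_local/theta).

    Pooled over voxels (and doses, if stacked); entries with non-positive
    truth, RMSE or local error are excluded.
    """
    r = np.asarray(rmse_param, dtype=float).ravel()
    th = np.asarray(theta, dtype=float).ravel()
    s = np.asarray(local_error, dtype=float).ravel()
    ok = (r > 0) & (th > 0) & (s > 0)
    if ok.sum() < 3:
        raise ValueError("not enough valid voxels for the local-error fit")
    y = np.log(r[ok] / th[ok])
    x = np.log(s[ok] / th[ok])
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.rsquared)
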