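"""Correlation and cross-validation inference for brain-behavior coupling.

Three layers of evidence are computed for the association between a
TMS-derived predictor (typically CSP duration) and the behavioral outcome
(SSRT):

1. Plain Pearson correlations across a small family of predictors, tested
   against a Bonferroni-adjusted alpha (0.05 / m).
2. A skipped Pearson correlation: bivariate outliers are flagged by
   projecting all points onto the directions from a robust
   (minimum-covariance-determinant) centre to each point and applying the
   MAD-median rule with the chi-square cutoff sqrt(chi2(2, 0.975)); Pearson's
   r is then computed on the retained points.  Significance and the 95% CI
   come from a percentile bootstrap over subject pairs.
3. Leave-one-out cross-validation: an OLS line is fit on n-1 subjects and
   evaluated on the held-out one; the Pearson correlation between
   predicted and observed outcomes measures predictive power, with a
   permutation null (shuffling the outcome and rerunning the whole LOO
   pipeline) providing the p value.  Because cross-validated predictions
   anticorrelate with the outcome under independence, the permutation null
   of the predicted-observed r is markedly left-shifted; the p value is
   therefore the upper-tail count on the empirical null with the add-one
   correction, p = (1 + #{r_null >= r_obs}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet

from .errors import AnalysisError

__all__ = [
    "CorrelationResult",
    "LoocvResult",
    "pearson_family",
    "skipped_pearson",
    "loocv_predict",
    "loocv_permutation_test",
]

#: sqrt of the 0.975 quantile of chi-square with 2 df — the conventional
#: bivariate outlier cutoff for projected, MAD-standardised distances.
PROJECTION_CUTOFF = float(np.sqrt(stats.chi2.ppf(0.975, df=2)))
MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass
class CorrelationResult:
    name: str
    r: float
    n: int
    p: float
    ci: tuple[float, float] | None = None
    alpha_adjusted: float | None = None
    significant: bool | None = None
    outlier_indices: list[int] = field(default_factory=list)
    n_boot: int | None = None
    seed: int | None = None


@dataclass
class LoocvResult:
    predictions: np.ndarray
    r_pred_obs: float
    p_perm: float
    n_perm: int
    seed: int | None = None


def _as_clean_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise AnalysisError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise AnalysisError(f"{name} contains non-finite values")
    return arr


def pearson_family(
    x_by_name: dict[str, object], y, alpha: float = 0.05
) -> list[CorrelationResult]:
    """Pearson r (with two-tailed t-based p) for each named predictor
    against ``y``, flagged against the Bonferroni-adjusted alpha / m."""
    y_arr = _as_clean_array(y, "y")
    m = len(x_by_name)
    if m == 0:
        raise AnalysisError("no predictors supplied")
    alpha_adj = alpha / m
    out = []
    for name, x in x_by_name.items():
        x_arr = _as_clean_array(x, name)
        if x_arr.size != y_arr.size:
            raise AnalysisError(f"{name} and y differ in length")
        if x_arr.size < 3:
            raise AnalysisError("need at least 3 observations")
        if np.ptp(x_arr) == 0:
            raise AnalysisError(f"correlation undefined: {name} has zero variance")
        if np.ptp(y_arr) == 0:
            raise AnalysisError("correlation undefined: y has zero variance")
        r, p = stats.pearsonr(x_arr, y_arr)
        out.append(
            CorrelationResult(
                name=name,
                r=float(r),
                n=int(x_arr.size),
                p=float(p),
                alpha_adjusted=alpha_adj,
                significant=bool(p < alpha_adj),
            )
        )
    return out


def _projection_outliers(xy: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Union of MAD-median projection flags over all point directions.

    For each data point, all points are projected onto the unit direction
    from the robust centre to that point; a point is an outlier if its
    standardised distance from the projection median exceeds
    ``PROJECTION_CUTOFF`` on any direction.
    """
    d = xy - center
    norms = np.linalg.norm(d, axis=1)
    flagged = np.zeros(len(xy), dtype=bool)
    for i in range(len(xy)):
        if norms[i] == 0:
            continue
        proj = d @ (d[i] / norms[i])
        med = np.median(proj)
        madn = np.median(np.abs(proj - med)) * MAD_TO_SD
        if madn == 0:
            continue
        flagged |= np.abs(proj - med) > PROJECTION_CUTOFF * madn
    return flagged


def _skipped_r(xy: np.ndarray, mcd_seed: int) -> tuple[float, np.ndarray]:
    with warnings.catch_warnings():
        # the FastMCD determinant monotonicity warning fires routinely on
        # small bootstrap resamples and carries no actionable signal here
        warnings.filterwarnings("ignore", message="Determinant has increased")
        mcd = MinCovDet(random_state=mcd_seed).fit(xy)
    flagged = _projection_outliers(xy, mcd.location_)
    kept = xy[~flagged]
    if len(kept) < 3 or np.ptp(kept[:, 0]) == 0 or np.ptp(kept[:, 1]) == 0:
        raise AnalysisError("degenerate sample after outlier removal")
    r = float(np.corrcoef(kept[:, 0], kept[:, 1])[0, 1])
    return r, flagged


def skipped_pearson(
    x, y, n_boot: int = 2000, seed: int | None = 0
) -> CorrelationResult:
    """Skipped Pearson correlation with percentile-bootstrap inference.

    Bivariate outliers are identified once on the full sample (robust MCD
    centre + projection MAD-median rule) and removed before computing r.
    The bootstrap resamples subject *pairs* and reruns the entire skipped
    procedure per resample; the CI is the [2.5, 97.5] percentile interval
    and p = 2·min(P(r* <= 0), P(r* >= 0)).  Deterministic for fixed seed.
    With ``n_boot=0`` only the point estimate and outlier set are computed
    (CI and p are unset).
    """
    x_arr = _as_clean_array(x, "x")
    y_arr = _as_clean_array(y, "y")
    if x_arr.size != y_arr.size:
        raise AnalysisError("x and y differ in length")
    n = x_arr.size
    if n < 10:
        raise AnalysisError("skipped correlation requires n >= 10")
    xy = np.column_stack([x_arr, y_arr])
    rng = np.random.default_rng(seed)
    mcd_seed = int(rng.integers(2**31 - 1))
    r, flagged = _skipped_r(xy, mcd_seed)
    if n_boot == 0:
        return CorrelationResult(
            name="skipped_pearson",
            r=r,
            n=n,
            p=float("nan"),
            outlier_indices=[int(i) for i in np.flatnonzero(flagged)],
            n_boot=0,
            seed=seed,
        )

    boot_r = np.empty(n_boot)
    boot_r.fill(np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot_r[b], _ = _skipped_r(xy[idx], mcd_seed)
        except AnalysisError:
            continue  # degenerate resample: dropped from the distribution
    boot_r = boot_r[np.isfinite(boot_r)]
    if boot_r.size == 0:
        raise AnalysisError("all bootstrap resamples degenerate")
    ci = (float(np.percentile(boot_r, 2.5)), float(np.percentile(boot_r, 97.5)))
    p = 2.0 * min(float(np.mean(boot_r <= 0)), float(np.mean(boot_r >= 0)))
    p = float(min(max(p, 1.0 / boot_r.size), 1.0))
    return CorrelationResult(
        name="skipped_pearson",
        r=r,
        n=n,
        p=p,
        ci=ci,
        outlier_indices=[int(i) for i in np.flatnonzero(flagged)],
        n_boot=int(n_boot),
        seed=seed,
    )


def _loocv_predictions_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOO predictions of simple OLS for each row of ``Y`` (m × n).

    Uses closed-form leave-one-out sums, so the whole permutation null is
    a handful of vectorised array operations.
    """
    n = x.size
    sx, sxx = x.sum(), (x * x).sum()
    sy = Y.sum(axis=1, keepdims=True)
    sxy = Y @ x
    # per-fold sums with observation i removed
    sx_i = sx - x  # (n,)
    sxx_i = sxx - x * x
    sy_i = sy - Y  # (m, n)
    sxy_i = sxy[:, None] - Y * x
    m_ = n - 1
    denom = sxx_i - sx_i**2 / m_
    if np.any(denom <= 1e-12):
        bad = int(np.argmin(denom))
        raise AnalysisError(f"zero-variance fold when leaving out observation {bad}")
    slope = (sxy_i - sx_i * sy_i / m_) / denom
    intercept = sy_i / m_ - slope * sx_i / m_
    return intercept + slope * x


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def loocv_predict(x, y) -> tuple[np.ndarray, float]:
    """Leave-one-out linear predictions of ``y`` from ``x``.

    For each subject i an OLS line is fit on the remaining n-1 subjects
    and evaluated at x_i.  Returns ``(predictions, r_pred_obs)`` where
    ``r_pred_obs`` is the Pearson correlation between predictions and
    observed values.
    """
    x_arr = _as_clean_array(x, "x")
    y_arr = _as_clean_array(y, "y")
    if x_arr.size != y_arr.size:
        raise AnalysisError("x and y differ in length")
    if x_arr.size < 4:
        raise AnalysisError("leave-one-out regression requires n >= 4")
    preds = _loocv_predictions_many(x_arr, y_arr[None, :])[0]
    r = float(_rowwise_pearson(preds[None, :], y_arr[None, :])[0])
    return preds, r


def loocv_permutation_test(
    x, y, n_perm: int = 5000, seed: int | None = 0
) -> LoocvResult:
    """Permutation test for the LOO predicted-observed correlation.

    The outcome is shuffled ``n_perm`` times and the full leave-one-out
    pipeline rerun on each shuffle, building a null distribution of
    predicted-observed r values; p is the add-one upper-tail count of null
    r values at least as large as the observed one.
    """
    x_arr = _as_clean_array(x, "x")
    y_arr = _as_clean_array(y, "y")
    preds, r_obs = loocv_predict(x_arr, y_arr)
    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.tile(y_arr, (n_perm, 1)), axis=1)
    null_preds = _loocv_predictions_many(x_arr, Y)
    r_null = _rowwise_pearson(null_preds, Y)
    r_null = r_null[np.isfinite(r_null)]
    p = (1.0 + float(np.sum(r_null >= r_obs))) / (r_null.size + 1.0)
    return LoocvResult(
        predictions=preds,
        r_pred_obs=r_obs,
        p_perm=float(p),
        n_perm=int(n_perm),
        seed=seed,
    )
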