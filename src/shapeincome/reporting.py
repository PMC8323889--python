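"""Nonclassical reporting-error diagnostics for self-reported height/weight.

A reporting error is ``reported - measured``.  Classical measurement error
is independent of the truth; the diagnostics here are built to detect the
*nonclassical* patterns seen in validation data — over-reported height with
extra over-reporting by short women, and a weight error whose conditional
mean crosses zero near a pivot (light people over-report, heavy people
under-report).

The workhorse is a Nadaraya-Watson conditional-mean estimator with an
Epanechnikov kernel and Silverman rule-of-thumb bandwidth, wrapped in a
Model/Results pair (:class:`KernelRegression` -> :class:`KernelCurve`) with
pointwise nonparametric-bootstrap confidence bands.  Linear-mean and
quantile regressions of the error on the truth, and a zero-crossing locator
for the estimated curve, complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ErrorSeries",
    "KernelCurve",
    "KernelRegression",
    "compute_reporting_errors",
    "epanechnikov",
    "silverman_bandwidth",
    "kernel_conditional_mean",
    "error_mean_regression",
    "error_quantile_regression",
    "zero_crossing",
]

# Canonical Epanechnikov constant for Silverman's rule; the 1.349 factor
# converts an interquartile range to a normal-equivalent standard deviation.
SILVERMAN_EPANECHNIKOV_C = 2.34
IQR_NORMALIZER = 1.349


@dataclass
class ErrorSeries:
    """Paired truth/error vectors for one variable and gender."""

    truth: np.ndarray
    error: np.ndarray
    variable: str = "weight"   # {height, weight}
    gender: str = "all"

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=np.float64)
        self.error = np.asarray(self.error, dtype=np.float64)
        if self.truth.shape != self.error.shape or self.truth.ndim != 1:
            raise ValueError("truth and error must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.truth)) and np.all(np.isfinite(self.error))):
            raise ValueError("truth and error must be finite")

    def __len__(self) -> int:
        return len(self.truth)


def compute_reporting_errors(
    reported: np.ndarray,
    measured: np.ndarray,
    variable: str = "weight",
    gender: str = "all",
) -> ErrorSeries:
    """Reporting error = reported - measured, paired with the measured truth."""
    reported = np.asarray(reported, dtype=np.float64)
    measured = np.asarray(measured, dtype=np.float64)
    if reported.shape != measured.shape:
        raise ValueError("reported and measured must have equal shapes")
    return ErrorSeries(truth=measured, error=reported - measured,
                       variable=variable, gender=gender)


def epanechnikov(u) -> np.ndarray:
    """Epanechnikov kernel: 0.75*(1-u^2) on |u| <= 1, zero outside."""
    u = np.asarray(u, dtype=np.float64)
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u ** 2), 0.0)


def silverman_bandwidth(x, constant: float = SILVERMAN_EPANECHNIKOV_C) -> float:
    """Silverman's rule-of-thumb bandwidth for the Epanechnikov kernel.

    ``h = C * min(sd, IQR/1.349) * n^(-1/5)`` with the kernel's canonical
    constant C = 2.34 by default.  Scale-equivariant in x; errors out on a
    zero-spread sample.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 observations for a bandwidth")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / IQR_NORMALIZER) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("sample has zero spread; bandwidth undefined")
    return constant * spread * x.size ** (-0.2)


def _nw_estimate(x, y, grid, h) -> tuple[np.ndarray, np.ndarray]:
    """Direct Nadaraya-Watson evaluation; returns (estimate, defined mask)."""
    u = (x[None, :] - grid[:, None]) / h
    w = epanechnikov(u)
    total = w.sum(axis=1)
    defined = total > 0
    est = np.full(grid.shape, np.nan)
    est[defined] = (w[defined] @ y) / total[defined]
    return est, defined


def default_grid(x, n_points: int = 101,
                 quantiles: tuple = (0.01, 0.99)) -> np.ndarray:
    """Evaluation grid: equally spaced between inner quantiles of the truth.

    Trimming to the 1st-99th percentile avoids the unstable boundary of the
    kernel estimate where almost no observations fall.
    """
    lo, hi = np.quantile(np.asarray(x, dtype=np.float64), quantiles)
    if not hi > lo:
        raise ValueError("degenerate grid: upper quantile must exceed lower")
    return np.linspace(lo, hi, n_points)


@dataclass
class KernelCurve:
    """A fitted conditional-mean curve, optionally with bootstrap bands."""

    grid: np.ndarray
    estimate: np.ndarray
    bandwidth: float
    kernel: str = "epanechnikov"
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    band_level: float | None = None
    n_boot: int | None = None
    series: ErrorSeries | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def band_violations(self) -> int:
        """Grid points where the estimate escapes its own percentile band.

        Percentile bands need not contain the point estimate exactly; a
        nonzero count flags them rather than erroring.
        """
        if self.band_lower is None:
            return 0
        ok = (self.band_lower <= self.estimate) & (self.estimate <= self.band_upper)
        return int(np.sum(~ok & np.isfinite(self.estimate)))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"grid": self.grid, "estimate": self.estimate})
        if self.band_lower is not None:
            out["band_lower"] = self.band_lower
            out["band_upper"] = self.band_upper
        return out


class KernelRegression:
    """Nadaraya-Watson conditional mean of a reporting error given the truth.

    Model object over an :class:`ErrorSeries`; ``fit`` evaluates the kernel
    estimate on a grid, ``fit_with_bands`` adds pointwise percentile bands
    from a pairs (x, y) nonparametric bootstrap.

    Parameters
    ----------
    series : ErrorSeries
    kernel : only "epanechnikov" is implemented (the reference choice).
    """

    def __init__(self, series: ErrorSeries, kernel: str = "epanechnikov"):
        if kernel != "epanechnikov":
            raise ValueError("only the Epanechnikov kernel is implemented")
        self.series = series
        self.kernel = kernel

    def fit(self, grid: np.ndarray | None = None,
            bandwidth: float | None = None) -> KernelCurve:
        x, y = self.series.truth, self.series.error
        h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        if grid is None:
            grid = default_grid(x)
        grid = np.asarray(grid, dtype=np.float64)
        est, defined = _nw_estimate(x, y, grid, h)
        if not defined.any():
            raise ValueError("no grid point has positive kernel weight")
        return KernelCurve(grid=grid, estimate=est, bandwidth=h,
                           kernel=self.kernel, series=self.series)

    def fit_with_bands(self, grid: np.ndarray | None = None,
                       bandwidth: float | None = None, B: int = 500,
                       level: float = 0.95, seed: int = 0) -> KernelCurve:
        """Kernel fit plus pointwise percentile bootstrap bands.

        Pairs ``(x_i, y_i)`` are resampled with replacement ``B`` times and
        the curve re-estimated each time (same bandwidth and grid, matching
        a bootstrap of the plotted estimator); the band at each grid point
        is the empirical ``(1-level)/2`` and ``(1+level)/2`` quantile range.
        Reproducible from ``seed``.
        """
        if B < 100:
            raise ValueError("use at least 100 bootstrap replicates")
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        curve = self.fit(grid=grid, bandwidth=bandwidth)
        x, y = self.series.truth, self.series.error
        n = len(x)
        rng = np.random.default_rng(seed)
        boot = np.empty((B, len(curve.grid)))
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            boot[b], _ = _nw_estimate(x[idx], y[idx], curve.grid, curve.bandwidth)
        alpha = (1.0 - level) / 2.0
        with np.errstate(invalid="ignore"):
            lower = np.nanquantile(boot, alpha, axis=0)
            upper = np.nanquantile(boot, 1.0 - alpha, axis=0)
        return KernelCurve(grid=curve.grid, estimate=curve.estimate,
                           bandwidth=curve.bandwidth, kernel=self.kernel,
                           band_lower=lower, band_upper=upper,
                           band_level=level, n_boot=B, series=self.series)


def kernel_conditional_mean(series: ErrorSeries, grid: np.ndarray,
                            bandwidth: float) -> KernelCurve:
    """Functional shortcut for ``KernelRegression(series).fit(grid, h)``."""
    return KernelRegression(series).fit(grid=grid, bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# Parametric error regressions
# ---------------------------------------------------------------------------

def error_mean_regression(series: ErrorSeries,
                          covariates: pd.DataFrame | None = None):
    """OLS of the reporting error on the truth (plus optional covariates).

    Returns a statsmodels results object with heteroskedasticity-robust
    (HC1) standard errors; the slope on ``truth`` is the linear-mean test of
    error/truth dependence.
    """
    import statsmodels.api as sm

    X = pd.DataFrame({"truth": series.truth})
    if covariates is not None:
        if len(covariates) != len(series):
            raise ValueError("covariates must match series length")
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        raise ValueError(f"collinear design: rank {rank} < {X.shape[1]} "
                         f"columns {list(X.columns)}")
    return sm.OLS(series.error, X).fit(cov_type="HC1")


def error_quantile_regression(series: ErrorSeries, tau: float = 0.5,
                              n_boot: int = 200, seed: int = 0):
    """Linear quantile (check-loss) regression of the error on the truth.

    Fits ``Q_tau(error | truth) = a + b * truth`` by iteratively reweighted
    least squares (statsmodels) and attaches pairs-bootstrap standard
    errors, which are robust to the estimator's non-smoothness in small
    samples.  Returns ``(results, bootstrap_se)``.
    """
    import statsmodels.api as sm

    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    X = sm.add_constant(pd.DataFrame({"truth": series.truth}))
    res = sm.QuantReg(series.error, X).fit(q=tau)
    rng = np.random.default_rng(seed)
    n = len(series)
    draws = np.empty((n_boot, 2))
    Xv = X.to_numpy(float)
    yv = series.error
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import IterationLimitWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", IterationLimitWarning)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            draws[b] = sm.QuantReg(yv[idx], Xv[idx]).fit(q=tau).params
    se = pd.Series(draws.std(axis=0, ddof=1), index=res.params.index,
                   name=f"bootstrap_se_tau{tau}")
    return res, se


def zero_crossing(curve: KernelCurve) -> list[float]:
    """Linear-interpolated sign changes of the estimated curve.

    Returns every crossing location left-to-right (the first is the
    headline pivot); an empty list if the curve never changes sign.  Grid
    points where the estimate is undefined are skipped.
    """
    ok = np.isfinite(curve.estimate)
    g, e = curve.grid[ok], curve.estimate[ok]
    if len(g) < 2:
        raise ValueError("need the estimate on at least 2 grid points")
    crossings = []
    for i in range(len(g) - 1):
        a, b = e[i], e[i + 1]
        if a == 0.0:
            crossings.append(float(g[i]))
        elif a * b < 0.0:
            crossings.append(float(g[i] - a * (g[i + 1] - g[i]) / (b - a)))
    if e[-1] == 0.0:
        crossings.append(float(g[-1]))
    return crossings
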