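"""Income equations: OLS with classical or deep-learned body measures,
subject-level bootstrap bands, and a control-function endogeneity correction.

The core specification is a log family income equation

    log FamilyIncome_i = alpha' X_i + beta' BodyShape_i + eps_i

where ``X_i`` collects education, experience (and its square), race,
occupation, marital status and number of children, and ``BodyShape_i`` is
either a classical set (BMI, height, weight, hip-to-waist ratio) or the
autoencoder body parameters P1..Pd.  Estimation is least squares with
heteroskedasticity-robust standard errors; confidence bands come from a
nonparametric bootstrap over subjects.

Stature may be endogenous (unobserved ability drives both). The
control-function estimator regresses the endogenous term on instruments
(shoe / jacket-or-blouse / pants size) plus ``X`` in a first stage, adds the
first-stage residual to the income equation, and reads the residual
coefficient's t-test as the exogeneity test; bootstrap inference re-runs
both stages per resample, as generated-regressor inference requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "IncomeModel",
    "IncomeResults",
    "ControlFunctionModel",
    "ControlFunctionResults",
    "BootstrapBands",
    "bmi",
    "hip_to_waist",
    "augment_table",
    "build_design",
    "bootstrap_fit",
    "dollar_effect",
    "per_unit_rescale",
]

# Declared category orders; the first level is the reference absorbed by the
# intercept when categoricals are expanded to dummies.
CATEGORY_LEVELS = {
    "race": ("white", "black", "asian", "other"),
    "marital_status": ("married", "single", "other"),
    "occupation": ("managerial", "technical", "service", "manual", "other"),
}

DEFAULT_COVARIATES = (
    "education_years", "experience_years", "experience_sq",
    "race", "occupation", "marital_status", "n_children",
)


def bmi(weight_kg, height_cm):
    """Body mass index, kg/m^2: weight / (height/100)^2."""
    w = np.asarray(weight_kg, dtype=np.float64)
    h = np.asarray(height_cm, dtype=np.float64)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    out = w / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def hip_to_waist(hip_cm, waist_cm):
    """Hip-to-waist ratio: hip circumference / waist circumference x 100."""
    hip = np.asarray(hip_cm, dtype=np.float64)
    waist = np.asarray(waist_cm, dtype=np.float64)
    if np.any(waist <= 0):
        raise ValueError("waist circumference must be positive")
    out = hip / waist * 100.0
    return float(out) if out.ndim == 0 else out


def augment_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived regressors (experience_sq, hip_to_waist) where missing."""
    out = table.copy()
    if "experience_sq" not in out and "experience_years" in out:
        out["experience_sq"] = out["experience_years"].astype(float) ** 2
    if ("hip_to_waist" not in out and
            {"hip_circumference_cm", "waist_circumference_cm"} <= set(out.columns)):
        out["hip_to_waist"] = hip_to_waist(
            out["hip_circumference_cm"], out["waist_circumference_cm"])
    return out


@dataclass
class ModelSpec:
    """What to regress on what, and for whom.

    ``body_terms`` name columns of the subject table (classical measures or
    P-parameters).  ``endogenous_term`` with ``instruments`` switches on the
    control-function machinery; the endogenous column must then appear in
    ``body_terms`` as well.
    """

    body_terms: tuple
    covariates: tuple = DEFAULT_COVARIATES
    gender: str | None = None
    dependent: str = "log_family_income"
    endogenous_term: str | None = None
    instruments: tuple | None = None

    def __post_init__(self) -> None:
        self.body_terms = tuple(self.body_terms)
        self.covariates = tuple(self.covariates)
        if self.instruments is not None:
            self.instruments = tuple(self.instruments)
        if self.endogenous_term is not None:
            if not self.instruments:
                raise ValueError("an endogenous term requires >= 1 instrument")
            if self.endogenous_term not in self.body_terms:
                raise ValueError("endogenous_term must be one of body_terms")


def build_design(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Design matrix with an intercept and declared-reference dummy coding."""
    parts = [pd.Series(1.0, index=table.index, name="const")]
    for col in columns:
        if col in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[col]
            vals = table[col]
            unknown = set(vals.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unknown {col} levels {sorted(unknown)}")
            for lev in levels[1:]:
                parts.append(pd.Series((vals == lev).astype(float),
                                       name=f"{col}[{lev}]"))
        else:
            if col not in table:
                raise KeyError(f"column {col!r} missing from table")
            parts.append(table[col].astype(float))
    return pd.concat(parts, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        sd = arr.std(axis=0)
        suspects = [c for c, s in zip(X.columns, sd) if s == 0 and c != "const"]
        raise ValueError(
            f"collinear design (rank {rank} < {arr.shape[1]}); "
            f"zero-variance columns: {suspects or 'none — linear dependence'}")


def _subsample(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    t = augment_table(table)
    if spec.gender is not None:
        t = t[t["gender"] == spec.gender]
        if len(t) == 0:
            raise ValueError(f"empty {spec.gender!r} subsample")
    return t.reset_index(drop=True)


@dataclass
class IncomeResults:
    """Fitted income equation: estimates, robust SEs, fit diagnostics.

    ``bands`` (90% bootstrap by default) is attached by
    :func:`bootstrap_fit`; ``sm_results`` is the underlying statsmodels
    object for anything not surfaced here.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int
    rsquared: float
    rsquared_adj: float
    resid: np.ndarray
    spec: ModelSpec
    sm_results: object = field(repr=False)
    bands: pd.DataFrame | None = None

    def summary(self) -> str:
        body = ", ".join(self.spec.body_terms)
        head = (f"Income equation ({self.spec.gender or 'all'}; body terms: {body})\n"
                f"n = {self.nobs}, R2 = {self.rsquared:.4f}, "
                f"adj R2 = {self.rsquared_adj:.4f}\n")
        return head + str(self.sm_results.summary())


class IncomeModel:
    """OLS income equation on a subject table.

    statsmodels does the fitting; this class owns the design construction
    (categorical expansion with declared reference levels, derived columns,
    gender subsampling) and returns an :class:`IncomeResults`.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.table = _subsample(table, spec)
        self.X = build_design(self.table, tuple(spec.covariates) + tuple(spec.body_terms))
        self.y = self.table[spec.dependent].to_numpy(float)
        if len(self.table) <= self.X.shape[1]:
            raise ValueError("need more subjects than parameters")
        _check_rank(self.X)

    def fit(self, cov_type: str = "HC1") -> IncomeResults:
        import statsmodels.api as sm

        res = sm.OLS(self.y, self.X).fit(cov_type=cov_type)
        return IncomeResults(
            params=res.params, bse=res.bse, tvalues=res.tvalues,
            pvalues=res.pvalues, nobs=int(res.nobs), rsquared=res.rsquared,
            rsquared_adj=res.rsquared_adj, resid=np.asarray(res.resid),
            spec=self.spec, sm_results=res)


@dataclass
class ControlFunctionResults:
    """Two-stage control-function fit with the exogeneity test.

    ``residual_coefficient`` is the second-stage coefficient on the
    first-stage residual; its robust t-test is the test of the null that
    the endogenous term is exogenous.  ``first_stage_F`` is the robust Wald
    F on the excluded instruments (weak-instrument diagnostic).
    """

    first_stage: IncomeResults
    second_stage: IncomeResults
    residual_coefficient: float
    residual_se: float
    exogeneity_tstat: float
    exogeneity_pvalue: float
    first_stage_F: float
    weak_instruments: bool
    spec: ModelSpec

    @property
    def params(self) -> pd.Series:
        return self.second_stage.params

    def summary(self) -> str:
        verdict = ("reject exogeneity" if self.exogeneity_pvalue < 0.05
                   else "fail to reject exogeneity")
        return (
            f"Control-function fit ({self.spec.gender or 'all'}): "
            f"{self.spec.endogenous_term} instrumented by "
            f"{', '.join(self.spec.instruments)}\n"
            f"first-stage F = {self.first_stage_F:.2f}"
            f"{'  (WEAK)' if self.weak_instruments else ''}\n"
            f"exogeneity test: t = {self.exogeneity_tstat:.3f}, "
            f"p = {self.exogeneity_pvalue:.4f}  -> {verdict} at 5%\n\n"
            + self.second_stage.summary())


class ControlFunctionModel:
    """Control-function (two-stage residual inclusion) income model.

    Stage 1 regresses the endogenous body term on the instruments plus all
    exogenous covariates; stage 2 re-estimates the income equation with the
    stage-1 residual appended.  A weak first stage (robust F below
    ``weak_f_floor``) is flagged, never fatal.
    """

    RESID_COL = "_cf_residual"

    def __init__(self, table: pd.DataFrame, spec: ModelSpec,
                 weak_f_floor: float = 10.0):
        if spec.endogenous_term is None:
            raise ValueError("spec must declare an endogenous term")
        self.spec = spec
        self.weak_f_floor = weak_f_floor
        self.table = _subsample(table, spec)
        exog_body = tuple(b for b in spec.body_terms if b != spec.endogenous_term)
        self.X1 = build_design(
            self.table, tuple(spec.covariates) + exog_body + tuple(spec.instruments))
        self.s = self.table[spec.endogenous_term].to_numpy(float)
        self.X2_base = build_design(
            self.table, tuple(spec.covariates) + tuple(spec.body_terms))
        self.y = self.table[spec.dependent].to_numpy(float)
        _check_rank(self.X1)
        _check_rank(self.X2_base)

    def fit(self, cov_type: str = "HC1") -> ControlFunctionResults:
        import statsmodels.api as sm

        res1 = sm.OLS(self.s, self.X1).fit(cov_type=cov_type)
        constraint = ", ".join(f"{z} = 0" for z in self.spec.instruments)
        fstat = float(np.squeeze(res1.wald_test(constraint, use_f=True, scalar=True).statistic))
        resid = np.asarray(res1.resid)

        X2 = self.X2_base.copy()
        X2[self.RESID_COL] = resid
        res2 = sm.OLS(self.y, X2).fit(cov_type=cov_type)

        stage1 = IncomeResults(
            params=res1.params, bse=res1.bse, tvalues=res1.tvalues,
            pvalues=res1.pvalues, nobs=int(res1.nobs), rsquared=res1.rsquared,
            rsquared_adj=res1.rsquared_adj, resid=resid, spec=self.spec,
            sm_results=res1)
        stage2 = IncomeResults(
            params=res2.params, bse=res2.bse, tvalues=res2.tvalues,
            pvalues=res2.pvalues, nobs=int(res2.nobs), rsquared=res2.rsquared,
            rsquared_adj=res2.rsquared_adj, resid=np.asarray(res2.resid),
            spec=self.spec, sm_results=res2)
        weak = fstat < self.weak_f_floor
        if weak:
            warnings.warn(
                f"weak instruments: first-stage F = {fstat:.2f} "
                f"< {self.weak_f_floor}", stacklevel=2)
        return ControlFunctionResults(
            first_stage=stage1, second_stage=stage2,
            residual_coefficient=float(res2.params[self.RESID_COL]),
            residual_se=float(res2.bse[self.RESID_COL]),
            exogeneity_tstat=float(res2.tvalues[self.RESID_COL]),
            exogeneity_pvalue=float(res2.pvalues[self.RESID_COL]),
            first_stage_F=fstat, weak_instruments=weak, spec=self.spec)


# ---------------------------------------------------------------------------
# Bootstrap over subjects
# ---------------------------------------------------------------------------

@dataclass
class BootstrapBands:
    """Percentile bands per coefficient from resampling subjects."""

    bands: pd.DataFrame      # columns: estimate, lower, upper
    level: float
    B: int
    n_skipped: int
    seed: int


def _lstsq_params(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def bootstrap_fit(model, B: int = 400, level: float = 0.90,
                  seed: int = 0) -> BootstrapBands:
    """Nonparametric subject bootstrap of an income or control-function model.

    Resamples rows with replacement ``B`` times and refits by least squares
    (both stages, for a control-function model, so the generated-regressor
    step is inside the bootstrap).  A resample that empties a category level
    (zero-variance design column) is skipped, counted and warned about.
    Bands are pointwise percentile intervals at ``level``; reproducible from
    ``seed``.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    is_cf = isinstance(model, ControlFunctionModel)
    if is_cf:
        X1 = model.X1.to_numpy(float)
        X2b = model.X2_base.to_numpy(float)
        s, y = model.s, model.y
        names = list(model.X2_base.columns) + [model.RESID_COL]
        g1 = _lstsq_params(X1, s)
        resid = s - X1 @ g1
        point = _lstsq_params(np.column_stack([X2b, resid]), y)
        n = len(y)
        dummy_cols = [j for j, c in enumerate(model.X2_base.columns) if "[" in c]
        dummy_cols1 = [j for j, c in enumerate(model.X1.columns) if "[" in c]
    else:
        X = model.X.to_numpy(float)
        y = model.y
        names = list(model.X.columns)
        point = _lstsq_params(X, y)
        n = len(y)
        dummy_cols = [j for j, c in enumerate(model.X.columns) if "[" in c]

    draws = np.empty((B, len(names)))
    skipped = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        if is_cf:
            X1b, X2bb = X1[idx], X2b[idx]
            if ((dummy_cols and not X2bb[:, dummy_cols].any(axis=0).all()) or
                    (dummy_cols1 and not X1b[:, dummy_cols1].any(axis=0).all())):
                skipped += 1
                draws[b] = np.nan
                continue
            rb = s[idx] - X1b @ _lstsq_params(X1b, s[idx])
            draws[b] = _lstsq_params(np.column_stack([X2bb, rb]), y[idx])
        else:
            Xb = X[idx]
            if dummy_cols and not Xb[:, dummy_cols].any(axis=0).all():
                skipped += 1
                draws[b] = np.nan
                continue
            draws[b] = _lstsq_params(Xb, y[idx])
    if skipped:
        warnings.warn(f"{skipped}/{B} bootstrap resamples skipped "
                      "(empty category level)", stacklevel=2)
    alpha = (1.0 - level) / 2.0
    with np.errstate(invalid="ignore"):
        lower = np.nanquantile(draws, alpha, axis=0)
        upper = np.nanquantile(draws, 1.0 - alpha, axis=0)
    bands = pd.DataFrame(
        {"estimate": point, "lower": lower, "upper": upper}, index=names)
    return BootstrapBands(bands=bands, level=level, B=B,
                          n_skipped=skipped, seed=seed)


# ---------------------------------------------------------------------------
# Effect-size conversions
# ---------------------------------------------------------------------------

class DollarEffect(NamedTuple):
    exact: float    # base * (exp(coef) - 1)
    linear: float   # base * coef


def dollar_effect(coefficient_per_unit: float,
                  base_income_dollars: float) -> DollarEffect:
    """Dollar change of a log-income coefficient at a base income.

    The exact convention is ``base * (exp(c) - 1)``; the first-order
    approximation ``base * c`` is returned alongside since published
    per-unit dollar figures may use either.
    """
    if base_income_dollars <= 0:
        raise ValueError("base income must be positive")
    c = float(coefficient_per_unit)
    return DollarEffect(exact=base_income_dollars * float(np.expm1(c)),
                        linear=base_income_dollars * c)


def per_unit_rescale(coefficient_per_sd: float, sd_in_native_units: float) -> float:
    """Convert a per-standard-deviation coefficient to per native unit.

    ``sd_in_native_units`` is how much the native measurement (e.g. decoded
    height in cm) moves per one SD of the parameter — measured from decoded
    parameter sweeps, never assumed.
    """
    if sd_in_native_units <= 0:
        raise ValueError("sd must be positive")
    return float(coefficient_per_sd) / float(sd_in_native_units)
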