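"""Cohort-fitted continuous metabolic-syndrome scores.

These are the classical, sample-specific continuous scores against which
the siMS score is validated:

* **z-sum**: each component (waist, systolic blood pressure,
  triglycerides, HDL, and a glycemic variable) is regressed on age and
  gender by ordinary least squares, the residuals are standardised to
  z-scores (HDL sign-flipped so that higher is always worse), and the five
  z's are summed.  Triglycerides, insulin and HOMA-IR enter on the natural
  log scale.
* **PCA factor scores**: the five components (with mean arterial pressure
  in place of systolic) are standardised and the principal components of
  their correlation matrix extracted.  Either the first component score is
  used directly, or the first two component scores are combined weighted
  by their explained-variance fractions (the eigenvalue-greater-than-one
  retention rule decides how many factors exist; when only one does, the
  weighted sum degrades to the first component with a warning).

Both scores can be computed on the whole cohort or independently within
age strata (the conventional strata being <18, 18–30, 31+ years).

Being fitted to the sample, these scores are exposed statsmodels-style:
``ComparatorModel(cohort, spec).fit()`` returns a
:class:`ComparatorResults` carrying per-subject scores and the fitted
diagnostics (regression coefficients, loadings, explained variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .scores import homa_ir, mean_arterial_pressure

logger = logging.getLogger(__name__)

Z_SUM = "z_sum"
PCA_FIRST = "pca_first_component"
PCA_WEIGHTED = "pca_weighted_sum"

#: the conventional age strata: children, young adults, adults
AGE_STRATA: tuple[tuple[float, float], ...] = (
    (0.0, 18.0), (18.0, 31.0), (31.0, float("inf")))


class ComparatorError(ValueError):
    """Degenerate data for a cohort-fitted score (too few cases,
    constant column, zero residual variance)."""


@dataclass(frozen=True)
class ComparatorSpec:
    """Fully determines one comparator score column.

    ``bp_variable`` defaults follow the published conventions: z-sum
    scores use systolic pressure, PCA scores use mean arterial pressure.
    ``log_tg`` controls the log transform of triglycerides (and is applied
    to insulin/HOMA regardless, which always enter logged).
    """

    method: str = Z_SUM
    glycemic_variable: str = "glucose"
    bp_variable: Optional[str] = None
    strata: Optional[tuple[tuple[float, float], ...]] = None
    log_tg: bool = True

    def __post_init__(self):
        if self.method not in (Z_SUM, PCA_FIRST, PCA_WEIGHTED):
            raise ValueError(f"unknown method {self.method!r}")
        if self.glycemic_variable not in ("glucose", "insulin", "homa"):
            raise ValueError(
                f"unknown glycemic variable {self.glycemic_variable!r}")
        if self.bp_variable is None:
            object.__setattr__(
                self, "bp_variable",
                "systolic" if self.method == Z_SUM else "mean_arterial")
        if self.bp_variable not in ("systolic", "mean_arterial"):
            raise ValueError(f"unknown bp variable {self.bp_variable!r}")

    @property
    def label(self) -> str:
        lab = f"{self.method}({self.glycemic_variable})"
        if self.strata:
            lab += "_stratified"
        return lab


def _component_frame(cohort: Cohort, spec: ComparatorSpec) -> pd.DataFrame:
    """Raw components + covariates, one row per subject, NaN = missing."""
    rows = []
    for s in cohort:
        bp = (s.systolic_bp if spec.bp_variable == "systolic"
              else mean_arterial_pressure(s))
        if spec.glycemic_variable == "glucose":
            gly = s.glucose
        elif spec.glycemic_variable == "insulin":
            gly = s.insulin
        else:
            gly = homa_ir(s)
        rows.append({
            "subject_id": s.subject_id,
            "age": s.age,
            "male": {"male": 1.0, "female": 0.0}[s.sex],
            "waist": s.waist,
            "bp": bp,
            "tg": s.triglycerides,
            "hdl": s.hdl,
            "glycemic": gly,
        })
    df = pd.DataFrame(rows).set_index("subject_id")
    return df.astype({c: float for c in df.columns if c != "subject_id"})


def _transform(df: pd.DataFrame, spec: ComparatorSpec) -> pd.DataFrame:
    out = df.copy()
    if spec.log_tg:
        out["tg"] = np.log(out["tg"])
    if spec.glycemic_variable in ("insulin", "homa"):
        out["glycemic"] = np.log(out["glycemic"])
    return out


_COMPONENTS = ("waist", "bp", "tg", "hdl", "glycemic")


class ComparatorModel:
    """A cohort-fitted comparator score, statsmodels-style.

    Parameters
    ----------
    cohort : Cohort
        Subjects to score (complete cases are selected per stratum).
    spec : ComparatorSpec
        Which score variant to compute.
    """

    def __init__(self, cohort: Cohort, spec: ComparatorSpec):
        self.cohort = cohort
        self.spec = spec
        raw = _component_frame(cohort, spec)
        self._data = _transform(raw, spec)

    def fit(self) -> "ComparatorResults":
        spec = self.spec
        data = self._data
        strata = spec.strata or ((-np.inf, np.inf),)
        scores = pd.Series(np.nan, index=data.index, name=spec.label)
        diagnostics: dict[str, dict] = {}

        needs_age = spec.strata is not None or spec.method == Z_SUM
        for lo, hi in strata:
            if spec.strata is None:
                in_stratum = pd.Series(True, index=data.index)
                key = "all"
            else:
                in_stratum = (data["age"] >= lo) & (data["age"] < hi)
                key = f"[{lo:g},{hi:g})"
            cols = list(_COMPONENTS) + (["age", "male"] if needs_age else [])
            sub = data.loc[in_stratum, cols].dropna()
            if len(sub) == 0:
                logger.warning("stratum %s: no complete cases; skipped", key)
                continue
            if spec.method == Z_SUM:
                vals, diag = _fit_z_sum(sub, key)
            else:
                vals, diag = _fit_pca(sub, key, spec.method)
            scores.loc[vals.index] = vals
            diagnostics[key] = diag
        if scores.notna().sum() == 0:
            raise ComparatorError(
                f"{spec.label}: no stratum produced any score")
        return ComparatorResults(self, scores, diagnostics)


def _fit_z_sum(sub: pd.DataFrame, key: str) -> tuple[pd.Series, dict]:
    n = len(sub)
    if n < 2:
        raise ComparatorError(
            f"stratum {key}: {n} complete case(s); need >= 2")
    regressors = []
    for cov in ("age", "male"):
        if sub[cov].nunique() > 1:
            regressors.append(cov)
    # keep at least one residual degree of freedom beyond the mean,
    # otherwise the fit is (near-)saturated and residuals collapse to zero
    while regressors and n < len(regressors) + 3:
        dropped = regressors.pop()
        logger.warning("stratum %s: n=%d too small to adjust for %r; "
                       "dropped from the regression", key, n, dropped)
    if not regressors:
        logger.warning("stratum %s: age and sex both constant; "
                       "falling back to centering only", key)
    X = sm.add_constant(sub[regressors]) if regressors else \
        pd.DataFrame({"const": np.ones(n)}, index=sub.index)

    z_total = pd.Series(0.0, index=sub.index)
    coefs = {}
    for comp in _COMPONENTS:
        y = sub[comp]
        res = sm.OLS(y, X).fit()
        resid = res.resid
        sd = resid.std(ddof=1)
        # relative threshold: a constant column's residuals are ~1e-16
        if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
            raise ComparatorError(
                f"stratum {key}: zero residual variance in component "
                f"{comp!r}")
        z = (resid - resid.mean()) / sd
        if comp == "hdl":
            z = -z
        z_total += z
        coefs[comp] = dict(res.params)
    diag = {"method": Z_SUM, "n": n, "coefficients": coefs,
            "regressors": regressors}
    return z_total, diag


def _fit_pca(sub: pd.DataFrame, key: str, method: str
             ) -> tuple[pd.Series, dict]:
    n = len(sub)
    k = len(_COMPONENTS)
    if n < k:
        raise ComparatorError(
            f"stratum {key}: {n} complete case(s); PCA needs >= {k}")
    X = sub[list(_COMPONENTS)].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    const = [c for c, s in zip(_COMPONENTS, sd) if s == 0]
    if const:
        raise ComparatorError(
            f"stratum {key}: constant component column(s) {const}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # sign convention: orient each component so the waist loading is
    # non-negative (fall back to triglycerides if waist loading is 0)
    for j in range(k):
        pivot = eigvecs[0, j] if eigvecs[0, j] != 0 else eigvecs[2, j]
        if pivot < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    frac = eigvals / eigvals.sum()
    pc_scores = Z @ eigvecs
    n_retained = int((eigvals > 1.0).sum())

    if method == PCA_FIRST:
        vals = pc_scores[:, 0]
    else:
        if n_retained < 2:
            warnings.warn(
                f"stratum {key}: only one factor extracted "
                f"(eigenvalues > 1); weighted sum degrades to the first "
                f"component", stacklevel=2)
            logger.warning("stratum %s: only one factor extracted", key)
            vals = pc_scores[:, 0]
        else:
            lam1, lam2 = frac[0], frac[1]
            vals = (lam1 * pc_scores[:, 0] + lam2 * pc_scores[:, 1]) / (
                lam1 + lam2)
    loadings = pd.DataFrame(
        eigvecs, index=list(_COMPONENTS),
        columns=[f"PC{j + 1}" for j in range(k)])
    diag = {"method": method, "n": n, "loadings": loadings,
            "eigenvalues": eigvals, "explained_variance_fraction": frac,
            "n_factors_retained": n_retained}
    return pd.Series(vals, index=sub.index), diag


@dataclass
class ComparatorResults:
    """Fitted comparator score: per-subject values plus diagnostics."""

    model: ComparatorModel
    scores: pd.Series
    diagnostics: dict = field(default_factory=dict)

    @property
    def spec(self) -> ComparatorSpec:
        return self.model.spec

    @property
    def n_used(self) -> int:
        return int(self.scores.notna().sum())

    def summary(self) -> str:
        lines = [f"Comparator score: {self.spec.label}",
                 f"subjects scored: {self.n_used} / {len(self.scores)}"]
        for key, diag in self.diagnostics.items():
            lines.append(f"  stratum {key}: n = {diag['n']}")
            if diag["method"] == Z_SUM:
                for comp, params in diag["coefficients"].items():
                    terms = ", ".join(f"{p}={v:.4g}" for p, v in params.items())
                    lines.append(f"    {comp}: {terms}")
            else:
                frac = diag["explained_variance_fraction"]
                lines.append(
                    f"    explained variance: "
                    + ", ".join(f"{f:.3f}" for f in frac))
                lines.append(
                    f"    factors retained (eigenvalue > 1): "
                    f"{diag['n_factors_retained']}")
        return "\n".join(lines)

    def diagnostics_frame(self) -> pd.DataFrame:
        """Loadings / explained variance / coefficients as one tidy table."""
        rows = []
        for key, diag in self.diagnostics.items():
            if diag["method"] == Z_SUM:
                for comp, params in diag["coefficients"].items():
                    for p, v in params.items():
                        rows.append({"stratum": key, "component": comp,
                                     "quantity": f"coef_{p}", "value": v})
            else:
                for j, f in enumerate(diag["explained_variance_fraction"]):
                    rows.append({"stratum": key, "component": "",
                                 "quantity": f"explained_var_PC{j + 1}",
                                 "value": f})
                for comp in _COMPONENTS:
                    for pc in ("PC1", "PC2"):
                        rows.append({
                            "stratum": key, "component": comp,
                            "quantity": f"loading_{pc}",
                            "value": diag["loadings"].loc[comp, pc]})
            rows.append({"stratum": key, "component": "", "quantity": "n",
                         "value": diag["n"]})
        return pd.DataFrame(rows)


def z_sum_score(cohort: Cohort, spec: Optional[ComparatorSpec] = None
                ) -> ComparatorResults:
    """Sum of age/gender-adjusted standardised residuals (z-sum score)."""
    if spec is None:
        spec = ComparatorSpec(method=Z_SUM)
    if spec.method != Z_SUM:
        raise ValueError("spec.method must be 'z_sum'")
    return ComparatorModel(cohort, spec).fit()


def pca_score(cohort: Cohort, spec: Optional[ComparatorSpec] = None
              ) -> ComparatorResults:
    """PCA-derived factor score (first component or weighted factor sum)."""
    if spec is None:
        spec = ComparatorSpec(method=PCA_WEIGHTED)
    if spec.method not in (PCA_FIRST, PCA_WEIGHTED):
        raise ValueError("spec.method must be a PCA method")
    return ComparatorModel(cohort, spec).fit()
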