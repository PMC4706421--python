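"""Comparator scores versus independent oracles.

The z-sum implementation (statsmodels OLS residuals) is checked against a
hand-rolled normal-equations oracle; the PCA implementation (correlation
eigendecomposition) against scikit-learn's SVD-based PCA.
"""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from simscore import (AGE_STRATA, Cohort, ComparatorError, ComparatorModel,
                      ComparatorSpec, Subject, SyntheticCohortConfig,
                      generate_cohort, pca_score, pearson, z_sum_score)
from simscore.comparators import _COMPONENTS, _component_frame, _transform

from conftest import make_subject, random_complete_cohort


# ---------------------------------------------------------------------------
# oracles


def z_sum_oracle(cohort: Cohort, spec: ComparatorSpec) -> pd.Series:
    """Normal-equations OLS + manual standardisation, fully independent of
    the statsmodels fitting path."""
    df = _transform(_component_frame(cohort, spec), spec).dropna()
    n = len(df)
    cols = [np.ones(n)]
    for cov in ("age", "male"):
        if df[cov].nunique() > 1:
            cols.append(df[cov].to_numpy())
    X = np.column_stack(cols)
    total = np.zeros(n)
    for comp in _COMPONENTS:
        y = df[comp].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        z = (resid - resid.mean()) / resid.std(ddof=1)
        total += -z if comp == "hdl" else z
    return pd.Series(total, index=df.index)


def pca_oracle(cohort: Cohort, spec: ComparatorSpec) -> dict:
    """scikit-learn SVD route, sign-aligned to the waist convention."""
    df = _transform(_component_frame(cohort, spec), spec)
    Z = df[list(_COMPONENTS)].dropna()
    Zs = (Z - Z.mean()) / Z.std(ddof=1)
    pca = SkPCA(n_components=len(_COMPONENTS))
    scores = pca.fit_transform(Zs.to_numpy())
    load = pca.components_.T  # columns = PCs
    for j in range(load.shape[1]):
        pivot = load[0, j] if load[0, j] != 0 else load[2, j]
        if pivot < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    frac = pca.explained_variance_ratio_
    return {"scores": scores, "loadings": load, "frac": frac,
            "index": Zs.index}


# ---------------------------------------------------------------------------
# z-sum


class TestZSum:
    def test_z_columns_standardised(self, synthetic_cohort_500):
        res = z_sum_score(synthetic_cohort_500)
        diag = res.diagnostics["all"]
        # the summed score of five unit-variance z's has mean 0
        vals = res.scores.dropna()
        assert vals.mean() == pytest.approx(0.0, abs=1e-8)
        assert diag["n"] == len(vals)

    def test_two_subject_cohort_gives_plus_minus_five_over_sqrt2(self):
        """With constant age and sex, residuals are centred values; a
        two-point z-score is +/- 1/sqrt(2) per component, and the HDL sign
        flip aligns all five, so scores are +/- 5/sqrt(2)."""
        worse = make_subject(subject_id="worse", age=30.0, waist=110.0,
                             systolic_bp=150.0, diastolic_bp=95.0,
                             triglycerides=3.0, hdl=0.9, glucose=7.0)
        better = make_subject(subject_id="better", age=30.0, waist=80.0,
                              systolic_bp=110.0, diastolic_bp=70.0,
                              triglycerides=1.0, hdl=1.8, glucose=4.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = z_sum_score(Cohort([worse, better]))
        expect = 5.0 / np.sqrt(2.0)
        assert res.scores["worse"] == pytest.approx(expect, abs=1e-10)
        assert res.scores["better"] == pytest.approx(-expect, abs=1e-10)

    @pytest.mark.parametrize("glycemic", ["glucose", "insulin", "homa"])
    @pytest.mark.parametrize("n", [8, 23, 50])
    def test_matches_normal_equations_oracle(self, n, glycemic):
        rng = np.random.default_rng(n * 101 + hash(glycemic) % 97)
        cohort = random_complete_cohort(rng, n)
        spec = ComparatorSpec("z_sum", glycemic)
        res = z_sum_score(cohort, spec)
        oracle = z_sum_oracle(cohort, spec)
        assert np.allclose(res.scores[oracle.index], oracle, atol=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        cohort = random_complete_cohort(rng, 30)
        res = z_sum_score(cohort)
        # rescale waist cm -> mm and shift systolic pressure
        rescaled = Cohort([
            dataclasses.replace(s, waist=s.waist * 10.0,
                                systolic_bp=s.systolic_bp + 0.0)
            for s in cohort])
        res2 = z_sum_score(rescaled)
        assert np.allclose(res.scores, res2.scores, atol=1e-10)

    def test_zero_residual_variance_names_component(self):
        subjects = [make_subject(subject_id=f"s{i}", age=20.0 + 3 * i,
                                 hdl=1.5, waist=80.0 + i * i,
                                 systolic_bp=110.0 + 7 * (i % 3),
                                 triglycerides=1.0 + 0.2 * (i % 4),
                                 glucose=4.5 + 0.3 * (i % 3))
                    for i in range(8)]
        # hdl exactly constant: its residuals on age are identically zero
        with pytest.raises(ComparatorError, match="hdl"):
            z_sum_score(Cohort(subjects))

    def test_too_few_cases(self):
        with pytest.raises(ComparatorError, match="complete case"):
            z_sum_score(Cohort([make_subject()]))


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    @pytest.mark.parametrize("method", ["pca_first_component",
                                        "pca_weighted_sum"])
    @pytest.mark.parametrize("n", [6, 19, 50])
    def test_matches_sklearn_oracle(self, n, method):
        rng = np.random.default_rng(n * 13 + len(method))
        cohort = random_complete_cohort(rng, n)
        spec = ComparatorSpec(method, "glucose")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pca_score(cohort, spec)
        oracle = pca_oracle(cohort, spec)
        diag = res.diagnostics["all"]
        assert np.allclose(diag["explained_variance_fraction"],
                           oracle["frac"], atol=1e-8)
        assert np.allclose(np.abs(diag["loadings"].to_numpy()),
                           np.abs(oracle["loadings"]), atol=1e-8)
        if method == "pca_first_component":
            expect = oracle["scores"][:, 0]
        else:
            f = oracle["frac"]
            if diag["n_factors_retained"] >= 2:
                expect = (f[0] * oracle["scores"][:, 0]
                          + f[1] * oracle["scores"][:, 1]) / (f[0] + f[1])
            else:
                expect = oracle["scores"][:, 0]
        assert np.allclose(res.scores[oracle["index"]], expect, atol=1e-8)

    def test_first_component_variance_identity(self, synthetic_cohort_500):
        """PC1 scores from a correlation-matrix PCA of 5 standardised
        columns have mean 0 and variance lambda1 * 5."""
        res = pca_score(synthetic_cohort_500,
                        ComparatorSpec("pca_first_component", "glucose"))
        vals = res.scores.dropna()
        lam1 = res.diagnostics["all"]["explained_variance_fraction"][0]
        assert vals.mean() == pytest.approx(0.0, abs=1e-6)
        assert vals.var(ddof=1) == pytest.approx(lam1 * 5.0, rel=1e-6)

    def test_perfectly_correlated_components(self):
        """If all five standardised columns are identical, PC1 explains
        everything and the score is positively proportional to the common
        column."""
        subjects = []
        raw = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for i, v in enumerate(raw):
            subjects.append(Subject(
                subject_id=f"s{i}", sex="female", age=30.0,
                height=100.0, waist=40.0 + 10 * v,
                systolic_bp=100.0 + 10 * v,
                diastolic_bp=70.0 + 10 * v,
                triglycerides=float(np.exp(v / 10)),
                hdl=3.0 - v / 3.0,  # negatively aligned raw, same |corr|
                glucose=4.0 + v))
        spec = ComparatorSpec("pca_first_component", "glucose", log_tg=True,
                              bp_variable="mean_arterial")
        res = pca_score(Cohort(subjects), spec)
        diag = res.diagnostics["all"]
        assert diag["explained_variance_fraction"][0] == pytest.approx(
            1.0, abs=1e-8)
        common = (raw - raw.mean()) / raw.std(ddof=1)
        r = np.corrcoef(res.scores.to_numpy(), common)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_single_factor_fallback_warns(self, synthetic_cohort_500):
        """A cohort driven by one latent factor retains a single
        eigenvalue > 1; the weighted sum then degrades to PC1."""
        spec = ComparatorSpec("pca_weighted_sum", "glucose")
        with pytest.warns(UserWarning, match="only one factor"):
            res = pca_score(synthetic_cohort_500, spec)
        first = pca_score(synthetic_cohort_500,
                          ComparatorSpec("pca_first_component", "glucose"))
        assert np.allclose(res.scores.dropna(), first.scores.dropna())

    def test_fewer_subjects_than_components(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ComparatorError, match="PCA needs"):
            pca_score(random_complete_cohort(rng, 4))

    def test_constant_column_named(self):
        subjects = [make_subject(subject_id=f"s{i}", age=20.0 + i,
                                 glucose=5.0, waist=80.0 + i,
                                 triglycerides=1.0 + 0.1 * i,
                                 hdl=1.0 + 0.05 * i,
                                 systolic_bp=110.0 + i)
                    for i in range(6)]
        with pytest.raises(ComparatorError, match="glycemic"):
            pca_score(Cohort(subjects),
                      ComparatorSpec("pca_first_component", "glucose"))


# ---------------------------------------------------------------------------
# cross-cutting


class TestDeterminismAndStructure:
    def test_repeated_fits_bit_identical(self, synthetic_cohort_500):
        a = z_sum_score(synthetic_cohort_500).scores
        b = z_sum_score(synthetic_cohort_500).scores
        assert (a.dropna() == b.dropna()).all()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pa = pca_score(synthetic_cohort_500).scores
            pb = pca_score(synthetic_cohort_500).scores
        assert (pa.dropna() == pb.dropna()).all()

    def test_z_sum_and_pca_agree_on_latent_factor_cohort(
            self, synthetic_cohort_500):
        z = z_sum_score(synthetic_cohort_500).scores
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = pca_score(synthetic_cohort_500).scores
        res = pearson(z.to_numpy(), p.to_numpy())
        assert res.r > 0.9

    def test_stratified_fit_scores_every_stratum(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n=400, seed=7, missingness_rates={}))
        spec = ComparatorSpec("z_sum", "glucose", strata=AGE_STRATA)
        res = ComparatorModel(cohort, spec).fit()
        assert set(res.diagnostics) == {"[0,18)", "[18,31)", "[31,inf)"}
        assert res.scores.notna().all()
        # stratified and pooled scores differ (different regressions)
        pooled = z_sum_score(cohort).scores
        assert not np.allclose(res.scores, pooled)

    def test_summary_and_diagnostics_frame(self, synthetic_cohort_500):
        res = z_sum_score(synthetic_cohort_500)
        text = res.summary()
        assert "z_sum(glucose)" in text and "n = " in text
        frame = res.diagnostics_frame()
        assert {"stratum", "component", "quantity", "value"} <= set(frame.columns)
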