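import numpy as np
import pandas as pd
import pytest

from methatlas.datamodel import ValidationError
from methatlas.preprocess import m_matrix
from methatlas.signature import (
    EwasResult,
    SignatureModel,
    cox_ewas,
    dichotomize,
    hazard_score,
    select_candidates,
    stability_select,
    truncate_horizon,
)
from methatlas.synthetic import CohortSpec, generate_cohort
from oracles import cox_newton


def _survival_fixture(n=50, effect=-0.6, seed=42):
    rng = np.random.default_rng(seed)
    mv = pd.DataFrame({"cg1": rng.normal(0, 1, n), "cg2": rng.normal(0, 1, n)},
                      index=[f"s{i}" for i in range(n)])
    cov = pd.DataFrame({"risk_high": rng.integers(0, 2, n).astype(float)},
                       index=mv.index)
    t_event = rng.exponential(30, n) * np.exp(effect * mv["cg1"].to_numpy())
    censor = rng.uniform(5, 80, n)
    t = np.minimum(t_event, censor)
    e = (t_event <= censor).astype(int)
    return mv, cov, t, e


class TestCoxEwas:
    def test_agrees_with_independent_solver(self):
        mv, cov, t, e = _survival_fixture()
        res = cox_ewas(mv, t, e, adjustment_covariates=cov, horizon=60.0)
        tt, ee = truncate_horizon(t, e, 60.0)
        for probe in ("cg1", "cg2"):
            Z = np.column_stack([mv[probe].to_numpy(), cov["risk_high"].to_numpy()])
            beta, se, _, p = cox_newton(Z, tt, ee)
            assert res.table.loc[probe, "coef"] == pytest.approx(beta[0], abs=1e-6)
            assert res.table.loc[probe, "se"] == pytest.approx(se[0], abs=1e-6)
            assert res.table.loc[probe, "p"] == pytest.approx(p[0], abs=1e-6)

    def test_single_planted_effect_recovered(self):
        # one prognostic CpG, no competing hazard sources
        spec = CohortSpec(n_samples=500, n_cpgs=300, n_subtypes=2,
                          markers_per_subtype=30, n_candidates=100,
                          n_prognostic=1, prognostic_loghr=1.0,
                          subtype_loghr_spread=0.0, missing_rate=0.0,
                          batch_shift=0.0, seed=8)
        matrix, samples, truth = generate_cohort(spec)
        mv = m_matrix(matrix)
        res = cox_ewas(mv[truth.prognostic_probes], samples["os_time"],
                       samples["os_event"])
        coef = res.table["coef"].iloc[0]
        assert coef == pytest.approx(1.0, abs=0.2)

    def test_constant_probe_flagged_non_estimable(self):
        mv, _, t, e = _survival_fixture()
        mv["flat"] = 1.5
        res = cox_ewas(mv, t, e)
        row = res.table.loc["flat"]
        assert not row["converged"] and row["p"] == 1.0

    def test_requires_complete_mvalues_and_events(self):
        mv, _, t, e = _survival_fixture()
        with pytest.raises(ValidationError, match="events"):
            cox_ewas(mv, t, np.zeros_like(e))
        mv.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="complete"):
            cox_ewas(mv, t, e)

    def test_horizon_truncation_censors_late_events(self):
        t, e = truncate_horizon([30.0, 61.0, 60.0], [1, 1, 1], 60.0)
        assert list(t) == [30.0, 60.0, 60.0]
        assert list(e) == [1, 0, 1]


class TestSelectCandidates:
    def _result(self, pvals):
        table = pd.DataFrame({"coef": 0.1, "se": 0.1, "z": 1.0,
                              "p": pvals, "converged": True},
                             index=[f"cg{i}" for i in range(len(pvals))])
        return EwasResult(table, [], 10, 5)

    def test_threshold_is_strict_and_sorted(self):
        got = select_candidates(self._result([1e-4, 1e-6, 1e-7]), alpha=1e-5)
        assert got == ["cg2", "cg1"]

    def test_boundary_tie_excluded(self):
        assert select_candidates(self._result([1e-5]), alpha=1e-5) == []

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="threshold"):
            assert select_candidates(self._result([0.5, 0.9]), alpha=1e-5) == []

    def test_alpha_validated(self):
        with pytest.raises(ValidationError):
            select_candidates(self._result([0.5]), alpha=0.0)


@pytest.fixture(scope="module")
def planted_candidates():
    spec = CohortSpec(n_samples=400, n_cpgs=500, n_subtypes=2,
                      markers_per_subtype=40, n_candidates=60, n_prognostic=4,
                      prognostic_loghr=1.2, subtype_loghr_spread=0.0,
                      missing_rate=0.0, batch_shift=0.0, seed=21)
    matrix, samples, truth = generate_cohort(spec)
    mv = m_matrix(matrix)
    return spec, mv, samples, truth


class TestStabilitySelect:
    def test_planted_probes_dominate_selection(self, planted_candidates):
        _, mv, samples, truth = planted_candidates
        sig = stability_select(mv[truth.candidate_probes], samples["os_time"],
                               samples["os_event"], n_iter=80, seed=3)
        kept = set(sig.entries.index)
        planted = set(truth.prognostic_probes)
        assert len(kept & planted) >= 3
        assert len(kept - planted) <= 1
        assert ((sig.selection_frequencies >= 0) &
                (sig.selection_frequencies <= 1)).all()

    def test_deterministic_given_seed(self, planted_candidates):
        _, mv, samples, truth = planted_candidates
        kw = dict(n_iter=30, seed=9)
        s1 = stability_select(mv[truth.candidate_probes], samples["os_time"],
                              samples["os_event"], **kw)
        s2 = stability_select(mv[truth.candidate_probes], samples["os_time"],
                              samples["os_event"], **kw)
        assert s1.entries.equals(s2.entries)
        assert s1.cutoff == s2.cutoff

    def test_strong_single_candidate_always_selected(self, planted_candidates):
        _, mv, samples, truth = planted_candidates
        cols = [truth.prognostic_probes[0], truth.candidate_probes[-1]]
        sig = stability_select(mv[cols], samples["os_time"], samples["os_event"],
                               n_iter=40, support_cap=1, seed=2)
        assert sig.selection_frequencies[cols[0]] == 1.0
        assert cols[0] in sig.entries.index

    def test_pure_noise_candidates_raise(self, rng):
        n = 200
        mv = pd.DataFrame(rng.normal(0, 1, (n, 30)),
                          columns=[f"cg{i}" for i in range(30)])
        t = rng.exponential(30, n)
        e = rng.integers(0, 2, n)
        with pytest.raises(ValidationError, match="frequency"):
            stability_select(mv, t, e, n_iter=60, seed=4)

    def test_needs_at_least_two_candidates(self, planted_candidates):
        _, mv, samples, truth = planted_candidates
        with pytest.raises(ValidationError, match="2 candidate"):
            stability_select(mv[[truth.prognostic_probes[0]]],
                             samples["os_time"], samples["os_event"])


class TestHazardScore:
    def _sig(self, coefs, cutoff=0.0):
        return SignatureModel(entries=pd.Series(coefs), cutoff=cutoff,
                              selection_frequencies=pd.Series(1.0, index=list(coefs)))

    def test_linear_combination_arithmetic(self):
        sig = self._sig({"cg1": 0.5, "cg2": -0.3})
        mv = pd.DataFrame({"cg1": [2.0, 0.0], "cg2": [1.0, 0.0]}, index=["a", "b"])
        scores = hazard_score(sig, mv)
        assert scores["a"] == pytest.approx(0.7)
        assert scores["b"] == 0.0

    def test_linearity_property(self, rng):
        sig = self._sig({"cg1": 0.4, "cg2": -1.1, "cg3": 0.2})
        m1 = pd.DataFrame(rng.normal(size=(5, 3)), columns=["cg1", "cg2", "cg3"])
        m2 = pd.DataFrame(rng.normal(size=(5, 3)), columns=["cg1", "cg2", "cg3"])
        lhs = hazard_score(sig, 2.0 * m1 + 3.0 * m2)
        rhs = 2.0 * hazard_score(sig, m1) + 3.0 * hazard_score(sig, m2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_absent_probe_named(self):
        sig = self._sig({"cg1": 0.5, "cgZ": 1.0})
        mv = pd.DataFrame({"cg1": [1.0]})
        with pytest.raises(ValidationError, match="cgZ"):
            hazard_score(sig, mv)

    def test_median_cutoff_splits_cohort_in_half(self, rng):
        scores = pd.Series(rng.normal(size=100))
        groups = dichotomize(scores, float(np.median(scores)))
        assert abs((groups == "high").sum() - (groups == "low").sum()) <= 1


class TestDichotomize:
    def test_score_above_published_style_cutoff_is_high(self):
        assert dichotomize([-2.0], -2.043).iloc[0] == "high"

    def test_boundary_goes_low(self):
        assert dichotomize([-2.043], -2.043).iloc[0] == "low"

    def test_cutoff_must_be_finite(self):
        with pytest.raises(ValidationError):
            dichotomize([0.0], np.inf)
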