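import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trophospec import (
    PreyTaxon,
    assemble_use_availability,
    fit_rspf,
    hosmer_lemeshow,
    mean_probability_of_use,
    stepwise_aic,
)
from trophospec.rspf import RSPFModel, SeparationError, UseAvailabilityTable

from conftest import make_covariates, make_diet


def synthetic_ua(n=2000, beta=(-1.0, 0.5), seed=0, extra_noise=False):
    """Used/available rows with P(use) = expit(b0 + b1 * z(svl))."""
    rng = np.random.default_rng(seed)
    svl = rng.normal(0, 1, n)
    eta = beta[0] + beta[1] * svl
    y = rng.random(n) < expit(eta)
    table = pd.DataFrame(
        {
            "response": y.astype(int),
            "taxon": "T",
            "season": "autumn",
            "site": "site1",
            "sex": rng.choice(["M", "F"], n),
            "svl": svl,
            "smi": rng.normal(0, 1, n) if extra_noise else 0.0,
            "fori": rng.normal(0, 1, n),
            "weight": 1.0,
        }
    )
    if extra_noise:
        pass
    return UseAvailabilityTable(focal_taxon=PreyTaxon("T"), table=table)


class TestAssemble:
    def test_used_rows_expand_items(self, autumn_scenario):
        diet, cov, avail = autumn_scenario
        taxon = PreyTaxon("Collembola")
        ua = assemble_use_availability(diet, avail, cov, taxon, seed=3)
        j = diet.taxa.index(taxon)
        assert ua.n_used == diet.counts[:, j].sum()
        assert ua.n_available == avail.count_for(taxon)
        # three items from one stomach share that predator's covariates
        first = np.flatnonzero(diet.counts[:, j] >= 3)[0]
        svl = cov.aligned_to(diet)["svl"].iloc[first]
        used = ua.table[ua.table["response"] == 1]
        assert (used["svl"] == svl).sum() >= 3

    def test_total_rows_near_study_size(self, autumn_scenario):
        # summed over all taxa, rows = diet items + environment items
        diet, cov, avail = autumn_scenario
        total = 0
        for t in diet.taxa:
            if diet.counts[:, diet.taxa.index(t)].sum() == 0 and \
                    avail.count_for(t) == 0:
                continue
            ua = assemble_use_availability(diet, avail, cov, t, seed=1)
            total += len(ua.table)
        assert total == diet.counts.sum() + avail.total

    def test_absent_taxon_rejected(self, autumn_scenario):
        diet, cov, avail = autumn_scenario
        with pytest.raises(ValueError, match="absent"):
            assemble_use_availability(
                diet, avail, cov, PreyTaxon("Nosuchtaxon"), seed=1
            )

    def test_mean_strategy_constant_covariates(self, autumn_scenario):
        diet, cov, avail = autumn_scenario
        ua = assemble_use_availability(
            diet, avail, cov, PreyTaxon("Acarina"), strategy="mean"
        )
        av = ua.table[ua.table["response"] == 0]
        assert av["svl"].nunique() == 1
        assert av["smi"].nunique() == 1


class TestFit:
    def test_intercept_only_closed_form(self, autumn_scenario):
        diet, cov, avail = autumn_scenario
        ua = assemble_use_availability(
            diet, avail, cov, PreyTaxon("Collembola"), seed=3
        )
        m = fit_rspf(ua, [], method="naive_logistic")
        expected = ua.n_used / (ua.n_used + ua.n_available)
        assert np.allclose(m.fitted, expected)
        mean, sd = mean_probability_of_use(m)
        assert mean == pytest.approx(expected)
        assert sd == pytest.approx(0.0)

    def test_parameter_recovery_naive(self):
        ua = synthetic_ua(n=2000, beta=(-1.0, 0.5), seed=4)
        m = fit_rspf(ua, ["svl"], method="naive_logistic")
        for est, se, true in zip(m.beta, m.se, (-1.0, 0.5)):
            assert abs(est - true) < 2 * se
        # CI brackets the estimate
        assert np.all(m.ci[:, 0] <= m.beta) and np.all(m.beta <= m.ci[:, 1])

    def test_label_flip_negates_coefficients(self):
        ua = synthetic_ua(n=800, seed=5)
        m1 = fit_rspf(ua, ["svl"], method="naive_logistic")
        flipped = UseAvailabilityTable(
            ua.focal_taxon,
            ua.table.assign(response=1 - ua.table["response"]),
        )
        m2 = fit_rspf(flipped, ["svl"], method="naive_logistic")
        assert np.allclose(m1.beta, -m2.beta, atol=1e-6)

    def test_weighted_mle_agrees_in_sign_and_recovers_slope(self):
        ua = synthetic_ua(n=2000, beta=(-1.0, 0.5), seed=6)
        naive = fit_rspf(ua, ["svl"], method="naive_logistic")
        weighted = fit_rspf(ua, ["svl"], method="weighted_mle")
        i = weighted.columns.index("svl")
        assert np.sign(weighted.beta[i]) == np.sign(naive.beta[i])
        assert abs(weighted.beta[i] - 0.5) < 2 * max(weighted.se[i], 1e-6)

    def test_weighted_mle_needs_continuous_covariate(self):
        ua = synthetic_ua(n=200, seed=7)
        with pytest.raises(ValueError, match="continuous"):
            fit_rspf(ua, ["sex"], method="weighted_mle")

    def test_complete_separation_detected(self):
        n = 100
        svl = np.concatenate([np.full(50, -2.0), np.full(50, 2.0)])
        table = pd.DataFrame(
            {
                "response": (svl > 0).astype(int),
                "taxon": "T", "season": "a", "site": "s", "sex": "M",
                "svl": svl + np.random.default_rng(0).normal(0, 0.01, n),
                "smi": 0.0, "fori": 0.0, "weight": 1.0,
            }
        )
        ua = UseAvailabilityTable(PreyTaxon("T"), table)
        with pytest.raises(SeparationError):
            fit_rspf(ua, ["svl"], method="naive_logistic")

    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (500, 2000, 8000):
            est = []
            for seed in range(4):
                ua = synthetic_ua(n=n, beta=(-1.0, 0.5), seed=100 + seed)
                m = fit_rspf(ua, ["svl"], method="naive_logistic")
                est.append(m.beta[m.columns.index("svl")])
            errs.append(abs(np.mean(est) - 0.5))
        assert errs[2] < errs[0] + 0.05
        assert errs[2] < 0.05


class TestStepwise:
    def test_best_model_has_delta_zero(self):
        ua = synthetic_ua(n=600, seed=8)
        models = stepwise_aic(ua, ["svl", "fori"])
        assert models[0].delta_aic == 0.0
        assert all(m.delta_aic >= 0 for m in models)

    def test_pure_noise_covariate_never_strongly_better(self):
        # fori is pure noise here: adding it cannot beat the svl model by > 2
        ua = synthetic_ua(n=1500, beta=(-1.0, 0.8), seed=9)
        m_svl = fit_rspf(ua, ["svl"])
        m_both = fit_rspf(ua, ["svl", "fori"])
        assert m_both.aic > m_svl.aic - 2.0

    def test_strong_effect_required_in_supported_models(self):
        ua = synthetic_ua(n=2000, beta=(-1.0, 1.5), seed=10)
        models = stepwise_aic(ua, ["svl", "fori", "sex"])
        for m in models:
            if "svl" not in m.terms:
                assert m.delta_aic > 2.0


def reference_hl(fitted, y, edges):
    """Independent Hosmer-Lemeshow oracle: plain loops over given bins."""
    stat = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (fitted > lo) & (fitted <= hi)
        if not mask.any():
            continue
        e1 = fitted[mask].sum()
        e0 = (1 - fitted[mask]).sum()
        o1 = y[mask].sum()
        o0 = mask.sum() - o1
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    return stat


class TestHosmerLemeshow:
    def _model(self, fitted, y):
        k = 1
        return RSPFModel(
            focal_taxon=PreyTaxon("T"), method="naive_logistic", terms=[],
            columns=["intercept"], beta=np.zeros(k), se=np.zeros(k),
            ci=np.zeros((k, 2)), aic=0.0, llf=0.0,
            fitted=np.asarray(fitted, float), response=np.asarray(y, float),
        )

    def test_deterministic_toy_matches_oracle(self):
        rng = np.random.default_rng(0)
        fitted = rng.uniform(0.05, 0.95, 200)
        y = (rng.random(200) < fitted).astype(float)
        model = self._model(fitted, y)
        stat, p = hosmer_lemeshow(model, g=4)
        edges = np.quantile(fitted, [0, 0.25, 0.5, 0.75, 1.0])
        edges[0] = -np.inf
        assert stat == pytest.approx(reference_hl(fitted, y, edges))
        assert 0 <= p <= 1

    def test_degenerate_group_count_rejected(self):
        model = self._model([0.2, 0.8], [0, 1])
        with pytest.raises(ValueError):
            hosmer_lemeshow(model, g=2)

    def test_calibrated_model_rejects_at_nominal_rate(self):
        # data simulated from the fitted family: HL should reject ~5% at
        # alpha = 0.05 over replicate seeds
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0, 1, 300)
            y = (rng.random(300) < expit(-0.5 + x)).astype(float)
            fitted = expit(-0.5 + x)  # true (perfectly calibrated) model
            stat, p = hosmer_lemeshow(self._model(fitted, y), g=10)
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.12
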