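"""Product-of-coefficients mediation and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from msnpipe import (
    MediationGroundTruth,
    ProductOfCoefficientsMediation,
    bootstrap_indirect,
    generate_mediation_dataset,
    mediation_paths,
    run_mediation,
)


@pytest.fixture(scope="module")
def strong_df():
    return generate_mediation_dataset(2000, MediationGroundTruth(), seed=8)


class TestPaths:
    def test_vanishing_noise_chain_recovered(self):
        # mediator noise -> 0 (exactly 0 would make M collinear with ADI)
        truth = MediationGroundTruth(noise_sd_mediator=1e-6, noise_sd_outcome=0.0,
                                     covariate_effects={})
        df = generate_mediation_dataset(100, truth, seed=0)
        p = mediation_paths(df.adi, df.mediator, df.outcome)
        assert p.a == pytest.approx(0.5, abs=1e-3)
        assert p.b == pytest.approx(0.4, abs=1e-3)
        assert p.c_prime == pytest.approx(0.2, abs=1e-3)
        assert p.indirect == pytest.approx(0.20, abs=1e-3)
        assert p.c == pytest.approx(0.40, abs=1e-6)

    def test_exactly_zero_mediator_noise_is_rank_deficient(self):
        truth = MediationGroundTruth(noise_sd_mediator=0.0, noise_sd_outcome=0.0,
                                     covariate_effects={})
        df = generate_mediation_dataset(100, truth, seed=0)
        with pytest.raises(ValueError, match="rank"):
            mediation_paths(df.adi, df.mediator, df.outcome)

    def test_effect_decomposition_identity(self, strong_df):
        df = strong_df
        p = mediation_paths(df.adi, df.mediator, df.outcome,
                            [df.age, df.sex, df.education])
        assert p.c - p.c_prime - p.indirect == pytest.approx(0.0, abs=1e-10)

    def test_null_path_when_mediator_independent(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 3000).astype(float)
        m = rng.normal(size=3000)
        y = 0.3 * x + rng.normal(size=3000)
        p = mediation_paths(x, m, y)
        assert abs(p.a) < 0.1 and abs(p.indirect) < 0.02

    def test_rank_deficiency_raises(self):
        x = np.ones(50)
        with pytest.raises(ValueError, match="rank"):
            mediation_paths(x, x * 2.0, np.random.default_rng(0).normal(size=50))


class TestBootstrap:
    def test_seed_determinism(self, strong_df):
        df = strong_df
        kw = dict(covariates=[df.age, df.sex, df.education], n_boot=500, seed=4)
        a = bootstrap_indirect(df.adi, df.mediator, df.outcome, **kw)
        b = bootstrap_indirect(df.adi, df.mediator, df.outcome, **kw)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_strong_effect_significant_and_sign_consistent(self, strong_df):
        df = strong_df
        r = bootstrap_indirect(df.adi, df.mediator, df.outcome,
                               [df.age, df.sex, df.education],
                               n_boot=1000, seed=5)
        assert r.significant
        assert r.ci_low > 0 and r.indirect > 0
        assert r.ci_low <= r.indirect <= r.ci_high

    def test_null_effect_rarely_significant(self):
        truth = MediationGroundTruth(a_true=0.0)
        sig = 0
        for i in range(30):
            df = generate_mediation_dataset(300, truth, seed=100 + i)
            r = bootstrap_indirect(df.adi, df.mediator, df.outcome,
                                   [df.age, df.sex, df.education],
                                   n_boot=300, seed=i)
            sig += int(r.significant)
        assert sig <= 5  # nominal 5% false-positive rate

    def test_bias_corrected_interval_close_to_percentile(self, strong_df):
        df = strong_df
        kw = dict(covariates=[df.age, df.sex, df.education], n_boot=2000, seed=6)
        pct = bootstrap_indirect(df.adi, df.mediator, df.outcome, method="percentile", **kw)
        bc = bootstrap_indirect(df.adi, df.mediator, df.outcome, method="bias-corrected", **kw)
        assert bc.ci_low == pytest.approx(pct.ci_low, abs=0.05)
        assert bc.significant == pct.significant

    def test_invalid_arguments(self, strong_df):
        df = strong_df
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_indirect(df.adi, df.mediator, df.outcome, n_boot=10)
        with pytest.raises(ValueError, match="method"):
            bootstrap_indirect(df.adi, df.mediator, df.outcome, n_boot=100, method="bca")

    def test_agrees_with_pingouin_cross_check(self, strong_df):
        """Independent oracle: pingouin's mediation_analysis on the same data."""
        pingouin = pytest.importorskip("pingouin")
        df = strong_df[["adi", "mediator", "outcome"]].rename(
            columns={"adi": "X", "mediator": "M", "outcome": "Y"}
        )
        pg = pingouin.mediation_analysis(data=df, x="X", m="M", y="Y",
                                         n_boot=500, seed=1)
        ours = bootstrap_indirect(df.X, df.M, df.Y, n_boot=2000, seed=2)
        ind = pg.set_index("path").loc["Indirect", "coef"]
        assert ours.indirect == pytest.approx(ind, abs=1e-8)
        direct = pg.set_index("path").loc["Direct", "coef"]
        assert ours.c_prime == pytest.approx(direct, abs=1e-8)


class TestWiring:
    def test_run_mediation_end_to_end(self, small_cohort):
        rng = np.random.default_rng(3)
        adi = small_cohort.set_index("subject_id").adi
        feats = pd.DataFrame(
            {"bc__lh-lateralorbitofrontal": rng.normal(size=len(small_cohort)) + 2.0 * adi},
            index=adi.index,
        )
        res = run_mediation(small_cohort, feats, ("bc", "lh-lateralorbitofrontal"),
                            "SMD", n_boot=300, seed=9)
        assert res.mediator == "bc__lh-lateralorbitofrontal"
        assert res.outcome == "SMD"
        assert res.ci_low <= res.ci_high
        assert set(res.to_dict()) >= {"a", "b", "c", "c_prime", "indirect",
                                      "ci_low", "ci_high", "significant"}
        assert "ADI" in res.path_diagram()

    def test_unknown_feature_rejected(self, small_cohort):
        feats = pd.DataFrame(index=small_cohort.set_index("subject_id").index)
        with pytest.raises(KeyError, match="not found"):
            run_mediation(small_cohort, feats, ("bc", "nowhere"), "SMD", n_boot=100)

    def test_estimator_interface(self, strong_df):
        est = ProductOfCoefficientsMediation(
            covariates=("age", "sex", "education"), n_boot=300, random_state=0
        ).fit(strong_df)
        assert est.indirect_ == pytest.approx(est.a_ * est.b_)
        assert est.ci_[0] <= est.indirect_ <= est.ci_[1]
        params = est.get_params()
        assert params["n_boot"] == 300
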