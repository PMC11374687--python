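import numpy as np
import pandas as pd
import pytest

from crcmetrics.errors import InsufficientDataError, ValidationError
from crcmetrics.hypoxia import (
    adjust_pvalues,
    associate,
    buffa_score,
    feature_matrix,
    residual_uniformity,
)


def _brute_force_score(expr, genes, tumour_ids):
    """One-line oracle: sign of (abundance - tumour median), summed."""
    out = {}
    for s in expr.columns:
        total = 0
        for g in genes:
            med = np.median(expr.loc[g, tumour_ids].to_numpy())
            total += 1 if expr.loc[g, s] > med else -1
        out[s] = total
    return pd.Series(out)


class TestBuffaScore:
    def test_four_tumour_worked_example(self):
        expr = pd.DataFrame(
            [[2.0, 4.0, 6.0, 8.0]], index=["g1"], columns=list("abcd")
        )
        s = buffa_score(expr, ["g1"], list("abcd"))
        assert list(s) == [-1, -1, 1, 1]

    def test_all_above_median_scores_plus_g(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        expr["winner"] = expr.max(axis=1) + 1.0
        s = buffa_score(expr, list(expr.index), [f"s{i}" for i in range(6)])
        assert s["winner"] == 10

    def test_tie_scores_minus_one(self):
        expr = pd.DataFrame(
            [[5.0, 5.0, 5.0]], index=["g1"], columns=list("abc")
        )
        s = buffa_score(expr, ["g1"], list("abc"))
        assert list(s) == [-1, -1, -1]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            expr = pd.DataFrame(
                rng.normal(size=(8, 9)),
                index=[f"g{i}" for i in range(8)],
                columns=[f"s{i}" for i in range(9)],
            )
            tum = [f"s{i}" for i in range(6)]
            got = buffa_score(expr, list(expr.index), tum)
            want = _brute_force_score(expr, list(expr.index), tum)
            assert (got == want).all()

    def test_monotone_transform_invariance(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 8)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(8)],
        )
        tum = list(expr.columns)[:5]
        base = buffa_score(expr, list(expr.index), tum)
        transformed = np.exp(expr * 2.0) + 3.0  # strictly increasing per gene
        assert (buffa_score(transformed, list(expr.index), tum) == base).all()

    def test_missing_gene_listed(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="gX"):
            buffa_score(expr, ["g1", "gX"], ["a", "b"])

    def test_parity_and_bound(self, default_cohort):
        c = default_cohort
        tum = list(c.truth.sample_id)
        s = buffa_score(c.expression, c.signature_genes, tum)
        g = len(c.signature_genes)
        assert (s.abs() <= g).all()
        assert ((s + g) % 2 == 0).all()

    def test_recovers_planted_hypoxia_groups(self, default_cohort):
        c = default_cohort
        tum = list(c.truth.sample_id)
        s = buffa_score(c.expression, c.signature_genes, tum)
        high = s[c.truth.loc[c.truth.hypoxia_group == "high", "sample_id"]]
        low = s[c.truth.loc[c.truth.hypoxia_group == "low", "sample_id"]]
        assert high.median() > low.median() + len(c.signature_genes) / 2


class TestFeatureMatrix:
    def test_counting_oracle(self):
        variants = pd.DataFrame(
            {
                "sample_id": ["s1"] * 6,
                "chrom": ["chr1"] * 6,
                "pos": range(1, 7),
                "ref": list("AAAAAA"),
                "alt": list("CCCCCC"),
                "variant_class": ["SNV"] * 5 + ["INS"],
                "region": ["coding"] * 3 + ["noncoding"] * 3,
                "nonsynonymous": [True, True, False, False, False, False],
            }
        )
        fm = feature_matrix(variants=variants)
        row = fm.metrics.loc["s1"]
        assert row["n_all"] == 6
        assert row["n_coding"] == 3
        assert row["n_nonsynonymous"] == 2
        assert row["n_snv"] == 5
        assert row["n_ins"] == 1
        assert row["n_indel"] == 1

    def test_empty_sv_table_counts_zero(self):
        svs = pd.DataFrame(columns=["sample_id", "sv_type"])
        fm = feature_matrix(svs=svs, sample_ids=["s1", "s2"])
        assert (fm.metrics.filter(like="sv_") == 0).all().all()

    def test_missing_table_leaves_metrics_absent(self):
        fm = feature_matrix(
            svs=pd.DataFrame({"sample_id": ["s1"], "sv_type": ["deletion"]})
        )
        assert not any(c.startswith("n_") for c in fm.metrics.columns)

    def test_constant_metric_flagged_degenerate(self):
        svs = pd.DataFrame({"sample_id": ["s1", "s2"], "sv_type": ["deletion"] * 2})
        with pytest.warns(UserWarning, match="constant"):
            fm = feature_matrix(svs=svs)
        assert fm.deciles["sv_deletion"].isna().all()


class TestAssociate:
    def _cov(self, n, rng):
        return pd.DataFrame(
            {
                "age": rng.normal(70, 8, n),
                "sex": rng.choice(["F", "M"], n),
                "purity": rng.uniform(0.2, 0.9, n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_perfect_predictor(self, rng):
        n = 60
        cov = self._cov(n, rng)
        feature = pd.Series(rng.normal(size=n), index=cov.index, name="f")
        scores = feature * 4.0
        r = associate(scores, feature, cov)
        assert r.p_value < 1e-12
        assert r.direction == 1

    def test_affine_rescale_same_p(self, rng):
        n = 80
        cov = self._cov(n, rng)
        feature = pd.Series(rng.normal(size=n), index=cov.index, name="f")
        scores = pd.Series(rng.normal(size=n), index=cov.index) + 0.4 * feature
        r1 = associate(scores, feature, cov)
        r2 = associate(scores, feature * 17.0 - 3.0, cov)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_constant_feature_rejected(self, rng):
        cov = self._cov(30, rng)
        with pytest.raises(ValidationError, match="constant"):
            associate(
                pd.Series(rng.normal(size=30), index=cov.index),
                pd.Series(1.0, index=cov.index),
                cov,
            )

    def test_collinear_covariates_rejected(self, rng):
        cov = self._cov(30, rng)
        cov["age2"] = cov["age"] * 2.0
        with pytest.raises(ValidationError, match="rank"):
            associate(
                pd.Series(rng.normal(size=30), index=cov.index),
                pd.Series(rng.normal(size=30), index=cov.index, name="f"),
                cov,
            )

    def test_too_few_complete_cases(self, rng):
        cov = self._cov(8, rng)
        with pytest.raises(InsufficientDataError):
            associate(
                pd.Series(rng.normal(size=8), index=cov.index),
                pd.Series(rng.normal(size=8), index=cov.index, name="f"),
                cov,
            )


class TestAdjustPvalues:
    def test_bonferroni_below_twenty(self):
        adj, method = adjust_pvalues([0.01] * 5)
        assert method == "bonferroni"
        assert adj[0] == pytest.approx(0.05)

    def test_bh_at_or_above_twenty(self):
        adj, method = adjust_pvalues([0.04] * 25)
        assert method == "fdr_bh"
        assert np.allclose(adj, 0.04)  # identical p are invariant under BH

    def test_switch_fires_exactly_at_twenty(self):
        _, m19 = adjust_pvalues([0.5] * 19)
        _, m20 = adjust_pvalues([0.5] * 20)
        assert (m19, m20) == ("bonferroni", "fdr_bh")

    def test_bh_matches_step_up_oracle(self):
        p = [0.01, 0.02, 0.03, 0.04]
        adj, _ = adjust_pvalues(p, n_tests=30)
        # direct step-up on the 4 observed p values
        m = len(p)
        ranked = sorted(p)
        raw = [ranked[i] * m / (i + 1) for i in range(m)]
        expect = np.minimum.accumulate(raw[::-1])[::-1]
        assert np.allclose(sorted(adj), expect)

    def test_adjusted_never_below_raw(self, rng):
        for n in (5, 30):
            p = rng.random(n)
            adj, _ = adjust_pvalues(p)
            assert (adj >= p - 1e-12).all()

    def test_range_check(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.2])


class TestResidualUniformity:
    def _fit(self, y, x):
        import statsmodels.api as sm

        return sm.OLS(y, sm.add_constant(x)).fit()

    def test_correct_model_rarely_rejects(self, rng):
        rejections = 0
        for i in range(20):
            x = rng.normal(size=150)
            y = 1.0 + 2.0 * x + rng.normal(size=150)
            p = residual_uniformity(self._fit(y, x), n_sim=200, seed=i)
            rejections += p < 0.05
        assert rejections <= 4

    def test_gross_heteroscedasticity_detected(self, rng):
        detected = 0
        for i in range(10):
            x = rng.uniform(1, 10, 200)
            y = x + rng.normal(scale=x**2 / 10, size=200)
            p = residual_uniformity(self._fit(y, x), n_sim=200, seed=i)
            detected += p < 0.05
        assert detected >= 6

    def test_degenerate_identical_residuals_reject(self, rng):
        x = rng.normal(size=100)
        y = 3.0 + 0.5 * x  # exact fit: all quantiles pile at ~0.5
        p = residual_uniformity(self._fit(y, x), n_sim=2000, seed=0)
        assert p < 1e-6

    def test_min_sims_enforced(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        with pytest.raises(ValidationError):
            residual_uniformity(self._fit(y, x), n_sim=10)
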