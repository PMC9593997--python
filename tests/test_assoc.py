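"""Burden test, Cauchy combination, direction voting, and the scan."""

import numpy as np
import pytest
from scipy import stats

from sumtwas.assoc import (
    associate_gene,
    burden_test,
    cauchy_combine,
    direction_vote,
    glm_association,
    transcriptome_scan,
)
from sumtwas.train import PenaltySpec, WeightModel


class TestBurdenTest:
    def test_single_snp_identity(self):
        z, p = burden_test(np.array([1.0]), np.array([3.2]), np.eye(1))
        assert z == pytest.approx(3.2)
        assert p == pytest.approx(2 * stats.norm.sf(3.2))

    def test_two_snp_hand_value(self):
        z, _ = burden_test(np.array([1.0, 1.0]), np.array([2.0, 2.0]), np.eye(2))
        assert z == pytest.approx(4 / np.sqrt(2))

    def test_scale_invariance_and_sign_flip(self, rng):
        w = rng.uniform(-1, 1, 5)
        gz = rng.standard_normal(5)
        A = rng.standard_normal((50, 5))
        V = np.corrcoef(A, rowvar=False)
        z1, _ = burden_test(w, gz, V)
        z2, _ = burden_test(7.3 * w, gz, V)
        z3, _ = burden_test(-w, gz, V)
        assert z1 == pytest.approx(z2, rel=1e-12)
        assert z3 == pytest.approx(-z1, rel=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            burden_test(np.zeros(2), np.ones(2), np.eye(2))

    def test_indefinite_v_rejected_with_guidance(self):
        V = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="shrunk"):
            burden_test(np.array([1.0, -1.0]), np.ones(2), V)


class TestCauchyCombine:
    @pytest.mark.parametrize("p", [0.5, 0.01, 1e-8, 0.999])
    def test_single_p_identity(self, p):
        assert cauchy_combine([p], [0.3]) == pytest.approx(p, rel=1e-12)

    def test_half_half_is_half(self):
        assert cauchy_combine([0.5, 0.5], [0.9, 0.1]) == pytest.approx(0.5)

    def test_hand_computed_two_model_example(self):
        # weights 0.03, 0.01 -> 0.75/0.25; T = 0.75 tan(0.49 pi) ~ 23.865
        assert cauchy_combine([0.01, 0.5], [0.03, 0.01]) == pytest.approx(0.01333, abs=2e-5)

    def test_weight_rescaling_invariance(self):
        a = cauchy_combine([0.01, 0.2, 0.7], [0.5, 0.3, 0.2])
        b = cauchy_combine([0.01, 0.2, 0.7], [5.0, 3.0, 2.0])
        assert a == pytest.approx(b, rel=1e-14)

    def test_extreme_p_tail_stable(self):
        out = cauchy_combine([1e-300, 0.5], [0.5, 0.5])
        assert 0 < out < 1e-290  # roughly 2x the smallest p
        assert out == pytest.approx(2e-300, rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.2])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            cauchy_combine([bad, 0.5], [1.0, 1.0])


class TestDirectionVote:
    @pytest.mark.parametrize(
        "signs,expected",
        [(["+", "+", "-"], "+"), (["+", "-"], "unknown"), (["-"], "-"),
         ([1, 1, -1, -1, -1], "-")],
    )
    def test_majority_and_tie(self, signs, expected):
        assert direction_vote(signs) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_vote([])


class TestGlmAssociation:
    def test_effect_recovery(self, rng):
        n, p = 10_000, 10
        x = rng.binomial(2, 0.3, (n, p)).astype(float)
        w = rng.uniform(-1, 1, p)
        xs = (x - x.mean(0)) / x.std(0)
        pred = xs @ w
        pred_std = (pred - pred.mean()) / pred.std()
        y = 0.5 * pred_std + rng.standard_normal(n)
        beta, pval = glm_association(w, x, y)
        se = 1.0 / (pred.std() * np.sqrt(n))
        assert beta * pred.std() == pytest.approx(0.5, abs=3 * se * pred.std() * 2)
        assert pval < 1e-10

    def test_null_p_uniform(self, rng):
        n, p = 300, 5
        x = rng.binomial(2, 0.3, (n, p)).astype(float)
        w = rng.uniform(-1, 1, p)
        pvals = []
        for _ in range(500):
            y = rng.standard_normal(n)
            _, pv = glm_association(w, x, y)
            pvals.append(pv)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_identity_link_matches_burden_route(self, rng):
        """Individual-level Wald z ~ summary burden z on the same sample."""
        from sumtwas.sim import make_summary
        from sumtwas.datatypes import SnpRecord

        n, p = 4000, 12
        x = rng.binomial(2, 0.35, (n, p)).astype(float)
        xs = (x - x.mean(0)) / x.std(0)
        w = rng.uniform(-0.5, 0.5, p)
        y = 0.1 * (xs @ w) + rng.standard_normal(n)
        beta, pv = glm_association(w, x, y)
        glm_z = stats.norm.isf(pv / 2) * np.sign(beta)
        recs = [SnpRecord(f"rs{i}", "1", 1000 + i, "A", "G") for i in range(p)]
        gwas = make_summary(xs, y, recs)
        V = xs.T @ xs / n
        burden_z, _ = burden_test(w, gwas.z, V)
        assert abs(glm_z - burden_z) < 0.05

    def test_collinear_covariates_rejected(self, rng):
        x = rng.binomial(2, 0.3, (100, 3)).astype(float)
        cov = np.column_stack([np.ones(100), np.ones(100)])
        with pytest.raises(ValueError, match="collinear"):
            glm_association(np.ones(3), x, rng.standard_normal(100), covariates=cov)


_GAMMAS = {"mcp": 3.0, "scad": 3.7, "mnet": 3.0}


def _model(gene, fam, w, r2):
    m = WeightModel(gene, [f"rs{i}" for i in range(len(w))], np.asarray(w, float),
                    PenaltySpec(fam, 0.1, gamma=_GAMMAS.get(fam, 0.0)), r2_tuning=r2)
    m.r2_testing = r2
    return m


class TestTranscriptomeScan:
    def test_threshold_is_alpha_over_tested_genes(self, rng):
        models = {g: [_model(g, "lasso", [1.0, 0.5], 0.1)] for g in ("g1", "g2", "g3")}
        gwas = {g: rng.standard_normal(2) for g in models}
        gwas["g3"] = np.array([])  # untested
        from sumtwas.ld import LdMatrix
        V = {g: LdMatrix(["rs0", "rs1"], np.eye(2)) for g in models}
        df = transcriptome_scan(models, gwas, V, alpha=0.05)
        assert df.attrs["n_tested"] == 2
        assert df.attrs["threshold"] == pytest.approx(0.025)
        assert (df["n_models"] == 0).sum() == 1  # untested gene recorded

    def test_single_gene_threshold_is_alpha(self, rng):
        models = {"g1": [_model("g1", "lasso", [1.0], 0.1)]}
        from sumtwas.ld import LdMatrix
        df = transcriptome_scan(models, {"g1": np.array([1.0])}, {"g1": LdMatrix(["rs0"], np.eye(1))})
        assert df.attrs["threshold"] == pytest.approx(0.05)

    def test_combined_p_under_null_ld_z(self, rng):
        """Super-uniformity of the combined p at alpha=0.05 under the null."""
        p = 8
        A = rng.standard_normal((200, p))
        V = np.corrcoef(A, rowvar=False)
        L = np.linalg.cholesky(V + 1e-8 * np.eye(p))
        models = [_model("g", f, rng.uniform(-1, 1, p), r2)
                  for f, r2 in [("lasso", 0.03), ("mcp", 0.02), ("scad", 0.01)]]
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            z = L @ rng.standard_normal(p)
            res = associate_gene("g", models, z, V)
            hits += res.combined_p < 0.05
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate < 0.05 + 3 * se
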