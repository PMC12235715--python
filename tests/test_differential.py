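"""Moderated linear modeling: OLS core, empirical-Bayes variance
shrinkage, BH adjustment, and a limma cross-check through Rscript."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from bwproteo import (
    ModeratedLinearModel,
    associate_with_zscore,
    bh_adjust,
    build_design,
    cross_visit_overlap,
    empirical_bayes_moderation,
    fit_linear_models,
    moderated_t_table,
)
from bwproteo.cohort import generate_cohort
from bwproteo.config import CohortConfig
from bwproteo.diff import trigamma_inverse
from bwproteo.preprocess import preprocess_pipeline


def _design(n, rng, extra=None):
    cols = {"intercept": np.ones(n), "grp": rng.integers(0, 2, n).astype(float)}
    if extra:
        cols.update(extra)
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


class TestOls:
    def test_hand_computable_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = 2.0 + 0.7 * x + np.array([0.1, -0.2, 0.05, 0.0, -0.05, 0.1])
        design = pd.DataFrame({"intercept": np.ones(6), "x": x}, index=[f"s{i}" for i in range(6)])
        mom = pd.DataFrame({"g0": y}, index=design.index)
        beta, v, s2, d, zero = fit_linear_models(mom, design)
        xm = np.column_stack([np.ones(6), x])
        beta_o = np.linalg.solve(xm.T @ xm, xm.T @ y)
        np.testing.assert_allclose(beta[0], beta_o, atol=1e-10)
        assert d == 4 and not zero[0]

    def test_exact_linear_protein_flagged(self, rng):
        design = _design(20, rng)
        y = 3.0 * design["grp"].to_numpy() + 1.0
        mom = pd.DataFrame({"exact": y, "noisy": y + rng.normal(0, 1, 20)}, index=design.index)
        _, _, s2, _, zero = fit_linear_models(mom, design)
        assert zero[0] and not zero[1]
        assert s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_row_permutation_equivariance(self, rng):
        design = _design(30, rng)
        mom = pd.DataFrame(rng.normal(size=(30, 5)), index=design.index,
                           columns=[f"g{j}" for j in range(5)])
        b1, _, s1, _, _ = fit_linear_models(mom, design)
        perm = rng.permutation(30)
        b2, _, s2_, _, _ = fit_linear_models(mom.iloc[perm], design.iloc[perm])
        np.testing.assert_allclose(b1, b2, atol=1e-10)
        np.testing.assert_allclose(s1, s2_, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        design = _design(20, rng)
        design["dup"] = design["grp"]
        mom = pd.DataFrame(rng.normal(size=(20, 3)), index=design.index)
        with pytest.raises(ValueError, match="rank"):
            fit_linear_models(mom, design)


class TestEmpiricalBayes:
    def test_identical_variances_posterior_unchanged(self):
        s2 = np.full(100, 0.3)
        d0, s02, post = empirical_bayes_moderation(s2, 10)
        assert np.isinf(d0)
        np.testing.assert_allclose(post, s2, rtol=1e-12)
        assert s02 == pytest.approx(0.3, rel=1e-12)

    def test_prior_recovery_from_known_scaled_invchisq(self):
        # simulate s2 under the exact model the moment matcher assumes
        errs_d0, errs_s02 = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d0t, s02t, d = 4.0, 0.05, 60
            sigma2 = d0t * s02t / rng.chisquare(d0t, 2000)
            s2 = sigma2 * rng.chisquare(d, 2000) / d
            d0, s02, _ = empirical_bayes_moderation(s2, d)
            errs_d0.append(abs(d0 - d0t) / d0t)
            errs_s02.append(abs(s02 - s02t) / s02t)
        assert np.mean(errs_d0) < 0.15
        assert np.mean(errs_s02) < 0.15

    def test_posterior_is_convex_combination(self, rng):
        d = 20
        sigma2 = 0.3 / rng.chisquare(6.0, 500) * 6.0
        s2 = sigma2 * rng.chisquare(d, 500) / d
        d0, s02, post = empirical_bayes_moderation(s2, d)
        expected = (d0 * s02 + d * s2) / (d0 + d)
        np.testing.assert_allclose(post, expected, rtol=1e-12)
        assert np.all(post >= np.minimum(s2, s02) - 1e-12)
        assert np.all(post <= np.maximum(s2, s02) + 1e-12)

    def test_trigamma_inverse_roundtrip(self):
        for x in (0.1, 0.7, 2.0, 15.0, 200.0):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-8)

    def test_too_few_variances_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            empirical_bayes_moderation(np.full(5, 0.1), 10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.031])), [0.031])

    def test_step_up_oracle(self):
        # hand-applied: q_i = min over j>=i of p_(j) * m / j
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])
        p = np.array([0.005, 0.04, 0.2, 0.9])
        m = 4
        sp = np.sort(p)
        oracle = [min(sp[j] * m / (j + 1) for j in range(i, m)) for i in range(m)]
        np.testing.assert_allclose(bh_adjust(sp), oracle)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(10)), np.ones(10))

    def test_matches_statsmodels_cross_check(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestModeratedModel:
    def test_unmoderated_fit_equals_classical_t(self, rng):
        design = _design(25, rng)
        mom = pd.DataFrame(rng.normal(size=(25, 40)), index=design.index,
                           columns=[f"g{j}" for j in range(40)])
        res = ModeratedLinearModel(mom, design, "grp").fit(moderate=False)
        x = design.to_numpy()
        xtx_inv = np.linalg.inv(x.T @ x)
        for j, prot in enumerate(mom.columns):
            y = mom[prot].to_numpy()
            beta = xtx_inv @ x.T @ y
            resid = y - x @ beta
            s2 = resid @ resid / (25 - 2)
            t_classic = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
            assert res.t[j] == pytest.approx(t_classic, abs=1e-10)

    def test_sign_flips_with_reversed_contrast(self, small_cohort):
        _, samples, rfu, _ = small_cohort
        _, _, _, mom = preprocess_pipeline(rfu, samples)
        a = moderated_t_table(mom, samples, 1, "LGA-AGA")
        # manual reversed contrast: case = AGA within the same subset
        design, idx = build_design(samples, 1, contrast="LGA-AGA")
        design_rev = design.copy()
        design_rev["LGA-AGA"] = 1.0 - design_rev["LGA-AGA"]
        b = ModeratedLinearModel(mom.loc[idx], design_rev, "LGA-AGA").fit()
        np.testing.assert_allclose(a["log2fc"].to_numpy(), -b.coef, atol=1e-10)
        np.testing.assert_allclose(a["p"].to_numpy(), b.p, atol=1e-10)

    def test_spiked_effects_recovered(self, small_cohort):
        _, samples, rfu, truth = small_cohort
        _, _, _, mom = preprocess_pipeline(rfu, samples)
        tab = moderated_t_table(mom, samples, 2, "LGA-AGA")
        flagged = truth.proteins["is_diff_lga"].to_numpy()
        assert 0.6 < tab.loc[flagged, "log2fc"].median() < 1.4
        # positive spikes only -> every significant protein has positive fc
        sig = tab["significant"].to_numpy()
        if sig.any():
            assert (tab.loc[sig, "log2fc"] > 0).all()

    def test_matches_limma_oracle(self, tmp_path):
        """Dual-route check: the moment-matched empirical-Bayes machinery
        against the reference R implementation on heterogeneous variances."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        n, p = 40, 200
        design = pd.DataFrame(
            {"intercept": 1.0, "grp": rng.integers(0, 2, n).astype(float),
             "bmi": rng.normal(24, 3, n)},
            index=[f"s{i}" for i in range(n)],
        )
        sigma2 = 5.0 * 0.04 / rng.chisquare(5.0, p)
        beta = np.where(rng.random(p) < 0.1, rng.normal(0, 0.5, p), 0.0)
        y = design["grp"].to_numpy()[:, None] * beta + rng.normal(0, 1, (n, p)) * np.sqrt(sigma2)
        mom = pd.DataFrame(y, index=design.index, columns=[f"g{j}" for j in range(p)])
        mom.T.to_csv(tmp_path / "y.csv")
        design.to_csv(tmp_path / "x.csv")
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))\n'
            f'x <- as.matrix(read.csv("{tmp_path}/x.csv", row.names=1))\n'
            "fit <- eBayes(lmFit(y, x))\n"
            'out <- data.frame(t=fit$t[,"grp"], p=fit$p.value[,"grp"],'
            " d0=fit$df.prior, s02=fit$s2.prior)\n"
            f'write.csv(out, "{tmp_path}/out.csv")\n'
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        res = ModeratedLinearModel(mom, design, "grp").fit()
        assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-9)
        assert res.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-9)
        np.testing.assert_allclose(res.t, ref["t"].to_numpy(), atol=1e-10)
        np.testing.assert_allclose(res.p, ref["p"].to_numpy(), atol=1e-10)


class TestAssociation:
    def test_constructed_slope_recovered(self, small_cohort, rng):
        _, samples, _, _ = small_cohort
        sub = samples[samples["visit"] == 1]
        z = sub["birth_weight_z"].to_numpy()
        cols = {f"g{j}": 0.5 * z + rng.normal(0, 0.3, len(z)) for j in range(15)}
        mom = pd.DataFrame(cols, index=sub.index)
        tab = associate_with_zscore(mom, samples, 1)
        est = tab["slope"].mean()
        se = tab["slope"].std(ddof=1) / np.sqrt(len(tab))
        assert abs(est - 0.5) < 4 * se + 0.05

    def test_monotone_noise_free_rho_one(self, small_cohort):
        _, samples, _, _ = small_cohort
        sub = samples[samples["visit"] == 1]
        z = sub["birth_weight_z"].to_numpy()
        cols = {f"g{j}": np.exp(z) + j * 0.1 for j in range(12)}
        mom = pd.DataFrame(cols, index=sub.index)
        tab = associate_with_zscore(mom, samples, 1)
        np.testing.assert_allclose(tab["spearman_rho"].to_numpy(), 1.0, atol=1e-12)

    def test_permuted_zscores_mostly_null(self, small_cohort):
        _, samples, rfu, _ = small_cohort
        _, _, _, mom = preprocess_pipeline(rfu, samples)
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = samples.copy()
            per_part = shuffled.drop_duplicates("participant_id")
            newz = dict(zip(per_part["participant_id"],
                            rng.permutation(per_part["birth_weight_z"].to_numpy())))
            shuffled["birth_weight_z"] = shuffled["participant_id"].map(newz)
            tab = associate_with_zscore(mom, shuffled, 1)
            fracs.append((tab["q"] < 0.05).mean())
        assert np.mean(fracs) < 0.01


class TestCrossVisitOverlap:
    def test_disjoint_identical_and_mixed(self):
        counts = cross_visit_overlap({1: {"A"}, 2: {"B"}, 3: {"C"}})
        assert counts["1&2&3"] == 0 and counts["union"] == 3
        counts = cross_visit_overlap({1: {"A", "B"}, 2: {"A", "B"}, 3: {"A", "B"}})
        assert counts["1&2&3"] == 2 and counts["1"] == 0

    def test_counts_verified_by_set_algebra_oracle(self):
        a, b, c = {"A", "B"}, {"B", "C"}, {"B"}
        counts = cross_visit_overlap({1: a, 2: b, 3: c})
        universe = a | b | c
        oracle = {"1": 0, "2": 0, "3": 0, "1&2": 0, "1&3": 0, "2&3": 0, "1&2&3": 0}
        for x in universe:
            key = "&".join(v for v, s in zip("123", (a, b, c)) if x in s)
            oracle[key] += 1
        for k, v in oracle.items():
            assert counts[k] == v
        assert counts["union"] == len(universe)
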