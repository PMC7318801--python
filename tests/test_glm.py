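"""Weighted logit models: mixed Laplace fits, LRT, quasibinomial GLMs."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from moralpd import glm


def simulate_glmm(
    n_subjects,
    beta,
    re_sd=(0.8, 0.6),
    re_corr=-0.3,
    weight=20,
    seed=0,
    group_balance=0.5,
):
    """Data generated directly from the binomial logit mixed model:
    two rows per subject (parameter D/U), one between-subjects factor."""
    rng = np.random.default_rng(seed)
    chol = np.array(
        [
            [re_sd[0], 0.0],
            [re_corr * re_sd[1], np.sqrt(1 - re_corr**2) * re_sd[1]],
        ]
    )
    u = rng.standard_normal((n_subjects, 2)) @ chol.T
    n_g1 = int(round(group_balance * n_subjects))
    group = np.array(["means"] * n_g1 + ["side_effect"] * (n_subjects - n_g1))
    rows = []
    for i in range(n_subjects):
        g = 1.0 if group[i] == "means" else 0.0
        for pu, param in ((0.0, "D"), (1.0, "U")):
            x = np.array([1.0, pu, g, pu * g])
            eta = float(x @ beta) + u[i, 0] + u[i, 1] * pu
            y = rng.binomial(weight, special.expit(eta))
            rows.append(
                {
                    "participant_id": f"s{i:04d}",
                    "parameter": param,
                    "instrumentality": group[i],
                    "successes": int(y),
                    "trials": weight,
                }
            )
    return pd.DataFrame(rows)


FULL_TERMS = ("parameter", "instrumentality", "parameter:instrumentality")


def brute_force_logit(data, terms):
    """Independent direct likelihood maximization of the plain weighted logit."""
    X, names = glm.build_design(data, terms)
    y = data["successes"].to_numpy(float)
    m = data["trials"].to_numpy(float)

    def negll(b):
        eta = X @ b
        return -(y * eta - m * np.logaddexp(0, eta)).sum()

    def grad(b):
        return -(X.T @ (y - m * special.expit(X @ b)))

    res = optimize.minimize(negll, np.zeros(X.shape[1]), jac=grad,
                            method="BFGS", options={"gtol": 1e-12})
    return pd.Series(res.x, index=names)


class TestBuildDesign:
    def test_reference_levels_and_interactions(self):
        df = pd.DataFrame(
            {
                "parameter": ["D", "U", "D", "U"],
                "instrumentality": ["means", "means", "side_effect", "side_effect"],
            }
        )
        X, names = glm.build_design(df, FULL_TERMS)
        assert names == [
            "Intercept",
            "parameter[U]",
            "instrumentality[means]",
            "parameter[U]:instrumentality[means]",
        ]
        np.testing.assert_allclose(X[1], [1, 1, 1, 1])
        np.testing.assert_allclose(X[3], [1, 1, 0, 0])


class TestMixedLogit:
    def test_null_structure_gives_null_effects(self):
        rows = []
        for i in range(30):
            g = "means" if i < 15 else "side_effect"
            for param in ("D", "U"):
                rows.append(
                    {
                        "participant_id": f"s{i}",
                        "parameter": param,
                        "instrumentality": g,
                        "successes": 10,
                        "trials": 20,
                    }
                )
        fit = glm.fit_mixed_logit(pd.DataFrame(rows), glm.ModelSpec(FULL_TERMS))
        coefs = fit.table[fit.table["term"] != "Intercept"]
        assert (coefs["b"].abs() < 1e-3).all()
        assert (coefs["z"].abs() < 0.1).all()

    def test_zero_variance_matches_direct_likelihood(self):
        data = simulate_glmm(10, beta=[0.4, -0.5, 0.8, -1.0], re_sd=(0, 0), seed=3)
        assert len(data) <= 40
        fit = glm.fit_mixed_logit(
            data, glm.ModelSpec(FULL_TERMS), fix_theta=(0, 0, 0)
        )
        oracle = brute_force_logit(data, FULL_TERMS)
        np.testing.assert_allclose(fit.params.to_numpy(), oracle.to_numpy(),
                                   atol=1e-6)

    def test_or_and_ci_are_exact_transforms(self):
        data = simulate_glmm(40, beta=[0.4, -0.5, 0.8, -1.0], seed=4)
        fit = glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS))
        t = fit.table
        np.testing.assert_allclose(t["odds_ratio"], np.exp(t["b"]), rtol=1e-12)
        np.testing.assert_allclose(
            t["ci_low"], np.exp(t["b"] - 1.96 * t["se"]), rtol=1e-12
        )

    def test_agrees_with_glmer_oracle(self, tmp_path):
        """Independent cross-check against the reference mixed-model fitter
        (lme4::glmer, Laplace approximation) on identical data."""
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH in this image"
        data = simulate_glmm(80, beta=[0.5, -0.6, 0.9, -1.2], seed=7)
        fit = glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS))
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            library(lme4)
            d <- read.csv("{csv}")
            d$pu <- as.integer(d$parameter == "U")
            d$im <- as.integer(d$instrumentality == "means")
            f <- glmer(cbind(successes, trials - successes) ~ pu * im +
                       (1 + pu | participant_id), data = d, family = binomial)
            cat(fixef(f), "\\n")
            cat(as.numeric(logLik(f)), "\\n")
        """))
        out = subprocess.run(
            [rscript, str(script)], capture_output=True, text=True, check=True
        )
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        glmer_beta = np.array([float(v) for v in lines[-2].split()])
        glmer_ll = float(lines[-1])
        np.testing.assert_allclose(fit.params.to_numpy(), glmer_beta, atol=0.02)
        assert fit.loglik == pytest.approx(glmer_ll, abs=0.05)

    def test_interaction_recovery_coverage(self):
        """The true interaction log-odds should fall inside the Wald 95% CI
        in about 95% of seeded replicates."""
        true_b = -1.0
        hits = 0
        for seed in range(50):
            data = simulate_glmm(
                40, beta=[0.3, -0.4, 0.6, true_b], re_sd=(0.7, 0.5), seed=seed
            )
            fit = glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS))
            row = fit.table.iloc[3]
            lo, hi = row["b"] - 1.96 * row["se"], row["b"] + 1.96 * row["se"]
            hits += lo <= true_b <= hi
        assert hits >= 44

    def test_bad_successes_rejected(self):
        data = simulate_glmm(5, beta=[0, 0, 0, 0], seed=0)
        data.loc[0, "successes"] = 25
        with pytest.raises(ValueError):
            glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS))


class TestLRT:
    def test_identical_models_give_zero(self):
        data = simulate_glmm(20, beta=[0.3, -0.4, 0.5, -0.8], seed=5)
        fit = glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS))
        res = glm.lrt(fit, fit)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == 1.0

    def test_detects_strong_interaction(self):
        data = simulate_glmm(60, beta=[0.3, -0.4, 0.5, -2.0], seed=6)
        full = glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS))
        red = glm.fit_mixed_logit(
            data, glm.ModelSpec(("parameter", "instrumentality"))
        )
        res = glm.lrt(full, red)
        assert res.df == 1
        assert res.chi2 > 10
        assert res.p < 0.01
        # Wald z and LRT agree in direction/decision
        wald_p = full.table.iloc[3]["p"]
        assert (wald_p < 0.05) == (res.p < 0.05)

    def test_non_nested_rejected(self):
        data = simulate_glmm(20, beta=[0.3, -0.4, 0.5, -0.8], seed=5)
        a = glm.fit_mixed_logit(data, glm.ModelSpec(("parameter",)))
        b = glm.fit_mixed_logit(data, glm.ModelSpec(("instrumentality",)))
        with pytest.raises(ValueError):
            glm.lrt(b, a)


class TestQuasibinomialGLM:
    def test_model_consistent_data_has_unit_dispersion(self):
        data = simulate_glmm(
            300, beta=[0.4, -0.5, 0.8, -1.0], re_sd=(0, 0), seed=8
        )
        flag, dispersion = glm.overdispersion_check(data, glm.ModelSpec(FULL_TERMS))
        assert not flag
        assert dispersion == pytest.approx(1.0, abs=0.2)

    def test_overdispersed_data_flagged_and_ses_inflate(self):
        data = simulate_glmm(
            150, beta=[0.4, -0.5, 0.8, -1.0], re_sd=(1.2, 0.9), seed=9
        )
        sub = data[data["parameter"] == "D"]
        terms = ("instrumentality",)
        flag, dispersion = glm.overdispersion_check(sub, glm.ModelSpec(terms))
        assert flag
        assert dispersion > 1.5
        quasi = glm.fit_glm(sub, glm.ModelSpec(terms, family="quasibinomial"))
        plain = glm.fit_glm(sub, glm.ModelSpec(terms, family="binomial"))
        np.testing.assert_allclose(
            quasi.params.to_numpy(), plain.params.to_numpy(), rtol=1e-10
        )
        assert (quasi.table["se"].to_numpy() > plain.table["se"].to_numpy()).all()
        # dispersion-threshold flag is monotone
        assert glm.overdispersion_check(sub, glm.ModelSpec(terms),
                                        threshold=dispersion + 0.1)[0] is False

    def test_two_group_odds_ratio_oracle(self):
        rows = []
        for i in range(10):
            rows.append({"participant_id": f"a{i}", "parameter": "D",
                         "instrumentality": "means", "successes": 16, "trials": 20})
            rows.append({"participant_id": f"b{i}", "parameter": "D",
                         "instrumentality": "side_effect", "successes": 12,
                         "trials": 20})
        data = pd.DataFrame(rows)
        fit = glm.fit_glm(data, glm.ModelSpec(("instrumentality",),
                                              family="quasibinomial"))
        hand_or = (0.8 / 0.2) / (0.6 / 0.4)
        got = fit.table.set_index("term").loc["instrumentality[means]", "odds_ratio"]
        assert got == pytest.approx(hand_or, rel=1e-8)

    def test_scaled_drop_term_test(self):
        data = simulate_glmm(
            100, beta=[0.4, 0.0, 1.2, 0.0], re_sd=(0.8, 0.0), seed=10
        )
        sub = data[data["parameter"] == "D"]
        spec = glm.ModelSpec(("instrumentality",), family="quasibinomial")
        full = glm.fit_glm(sub, spec)
        red = glm.fit_glm(sub, glm.ModelSpec((), family="quasibinomial"))
        res = glm.drop_term_test(full, red)
        assert res.df == 1
        assert res.chi2 > 0
        assert 0 <= res.p <= 1

    def test_three_routes_coincide_without_dispersion(self):
        data = simulate_glmm(15, beta=[0.2, -0.3, 0.5, -0.7], re_sd=(0, 0), seed=11)
        mixed = glm.fit_mixed_logit(data, glm.ModelSpec(FULL_TERMS),
                                    fix_theta=(0, 0, 0))
        quasi = glm.fit_glm(data, glm.ModelSpec(FULL_TERMS, family="quasibinomial"))
        oracle = brute_force_logit(data, FULL_TERMS)
        np.testing.assert_allclose(mixed.params.to_numpy(), quasi.params.to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(mixed.params.to_numpy(), oracle.to_numpy(),
                                   atol=1e-6)
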