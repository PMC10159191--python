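import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rayvisits.models import (
    build_design,
    collinearity_screen,
    fit_detection_glmm,
    pairwise_contrasts,
)
from rayvisits.models.glmm import PoissonGLMM


def simulate_counts(
    rng, n_tags=10, n_days=10, receivers=("R1", "R2"), diel_ratio_r1=1.0,
    sigma_u=0.4, base_rate=5.0, sex_effect=0.0,
):
    rows = []
    for tag in range(n_tags):
        u = rng.normal(0, sigma_u)
        sex = "F" if tag % 2 else "M"
        for day in range(n_days):
            for rec in receivers:
                for diel in ("day", "night"):
                    eta = np.log(base_rate) + u
                    if diel == "day" and rec == "R1":
                        eta += np.log(diel_ratio_r1)
                    if sex == "F":
                        eta += sex_effect
                    rows.append(
                        {
                            "transmitter_id": f"t{tag:02d}",
                            "receiver_id": rec,
                            "diel": diel,
                            "sex": sex,
                            "count": rng.poisson(np.exp(eta)),
                        }
                    )
    return pd.DataFrame(rows)


class TestPoissonGLMM:
    def test_matches_lme4_oracle(self, tmp_path):
        """Fixed effects and sigma_u agree with glmer (adaptive GH) to 1e-3."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(5)
        df = simulate_counts(rng, n_tags=12, n_days=8, diel_ratio_r1=1.8)
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        r_code = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(count ~ diel * receiver_id + (1 | transmitter_id),
                   data = d, family = poisson, nAGQ = 25)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), sep = "\\n")
        """
        proc = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        vals = [float(v) for v in proc.stdout.split()]
        res = fit_detection_glmm(df, factors=("diel", "receiver_id"))
        ours = [
            res.params["Intercept"],
            res.params["diel[night]"],
            res.params["receiver_id[R2]"],
            res.params["diel[night]:receiver_id[R2]"],
            res.sigma_u,
        ]
        np.testing.assert_allclose(ours, vals, atol=1e-3)

    def test_zero_random_variance_matches_plain_glm(self):
        rng = np.random.default_rng(8)
        df = simulate_counts(rng, n_tags=8, n_days=10, sigma_u=0.0, diel_ratio_r1=2.0)
        res = fit_detection_glmm(df, factors=("diel", "receiver_id"))
        x, names, _ = build_design(df, ["diel", "receiver_id"])
        glm = sm.GLM(df["count"], x, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.params.to_numpy(), glm.params, atol=1e-3)

    def test_convergence_status_reported(self):
        rng = np.random.default_rng(3)
        df = simulate_counts(rng, n_tags=6, n_days=5)
        res = fit_detection_glmm(df, factors=("diel", "receiver_id"))
        assert res.converged
        assert np.isfinite(res.loglike)
        assert res.n_groups == 6

    def test_sex_null_rarely_flags(self):
        """|z| < 2 for the sex coefficient in >= 90% of null replicates."""
        rng = np.random.default_rng(17)
        ok = 0
        n_rep = 40
        for _ in range(n_rep):
            df = simulate_counts(rng, n_tags=8, n_days=6, sex_effect=0.0)
            res = fit_detection_glmm(df, factors=("diel", "sex"), interaction=False)
            if abs(res.zvalues["sex[M]"]) < 2:
                ok += 1
        assert ok / n_rep >= 0.9


class TestPairwiseContrasts:
    @pytest.fixture(scope="class")
    def three_receiver_fit(self):
        rng = np.random.default_rng(11)
        rows = []
        rates = {"R1": 5.0, "R2": 5.0, "R3": 25.0}
        for tag in range(10):
            u = rng.normal(0, 0.3)
            for day in range(12):
                for rec, rate in rates.items():
                    rows.append(
                        {
                            "transmitter_id": f"t{tag}",
                            "receiver_id": rec,
                            "count": rng.poisson(rate * np.exp(u)),
                        }
                    )
        df = pd.DataFrame(rows)
        return fit_detection_glmm(df, factors=("receiver_id",))

    def test_contrast_count_is_k_choose_2(self, three_receiver_fit):
        out = pairwise_contrasts(three_receiver_fit, "receiver_id")
        assert len(out) == 3

    def test_identical_receivers_not_significant(self, three_receiver_fit):
        out = pairwise_contrasts(three_receiver_fit, "receiver_id").set_index("contrast")
        assert out.loc["R1 - R2", "p_adjusted"] > 0.05
        assert abs(out.loc["R1 - R2", "estimate"]) < 0.2

    def test_large_difference_is_significant(self, three_receiver_fit):
        out = pairwise_contrasts(three_receiver_fit, "receiver_id").set_index("contrast")
        assert out.loc["R1 - R3", "p_adjusted"] < 0.001

    def test_adjusted_at_least_unadjusted(self, three_receiver_fit):
        adj = pairwise_contrasts(three_receiver_fit, "receiver_id", adjust="tukey")
        raw = pairwise_contrasts(three_receiver_fit, "receiver_id", adjust="none")
        assert (adj["p_adjusted"].to_numpy() >= raw["p_adjusted"].to_numpy() - 1e-12).all()


class TestCollinearityScreen:
    def _cov(self, rng, n=200, rho=0.99):
        temp = rng.normal(25, 3, n)
        return pd.DataFrame(
            {
                "water_temp_c": temp,
                "salinity": rng.normal(28, 2, n),
                "do_mg_l": 7 - 0.05 * temp + rng.normal(0, 0.8, n),
                "o2_sat_pct": 2 * temp + rng.normal(0, 3 * np.sqrt(1 - rho**2), n),
            }
        )

    def test_collinear_o2_sat_dropped_temp_kept(self):
        rep = collinearity_screen(self._cov(np.random.default_rng(2)))
        assert rep.dropped == ["o2_sat_pct"]
        assert "water_temp_c" in rep.vif.index

    def test_orthogonal_covariates_kept(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        rep = collinearity_screen(cov)
        assert rep.dropped == []
        assert (rep.vif < 1.2).all()

    def test_duplicate_column_flagged_infinite(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=100)
        cov = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        rep = collinearity_screen(cov)
        assert "b" in rep.dropped
        assert any("infinite" in f for f in rep.flags.values())

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50),
                            "c": rng.normal(size=50)})
        rep = collinearity_screen(cov)
        assert "constant" in rep.flags["b"]
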