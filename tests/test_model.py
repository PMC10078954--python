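"""Sampler correctness: likelihood closed forms against a naive oracle,
agreement with OLS in the fixed-effects-only limit, seeded determinism,
precondition rejections, translation equivariance and posterior predictive
behaviour."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from circqpcr import model
from circqpcr.model import ModelSpec, PosteriorSamples, ct_log_density
from circqpcr.types import CohortDesign, GenotypeGroup, GroundTruth, ValidationError
from circqpcr import simulate


def _flat_truth(pm, residual=0.3):
    truth = simulate.default_truth(pm)
    truth.sd_run = truth.sd_litter = truth.sd_animal = 0.0
    truth.eta0 = math.log(residual)
    return truth


class TestLogDensity:
    PARAMS = {
        "alpha[p1]": 20.0,
        "beta[p1,hom]": 1.0,
        "gamma[p1,M]": 0.1,
        "u_run[run1]": 0.2,
        "v_litter[L1]": -0.1,
        "w_animal[a1]": 0.05,
        "eta0": 0.0,
        "eta_primer[p1]": 0.0,
        "eta_run[run1]": 0.0,
    }

    def _rec(self, ct, genotype="wt", sex="F"):
        return {"animal": "a1", "litter": "L1", "sex": sex, "genotype": genotype,
                "run": "run1", "primer": "p1", "ct": ct}

    def test_density_at_mean_with_unit_sigma(self):
        mu = 20.0 + 0.2 - 0.1 + 0.05  # wt/F at reference levels
        ld = ct_log_density(self._rec(mu), self.PARAMS)
        assert ld == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_translation_invariance(self):
        p2 = dict(self.PARAMS)
        p2["alpha[p1]"] += 3.7
        ld1 = ct_log_density(self._rec(21.0), self.PARAMS)
        ld2 = ct_log_density(self._rec(24.7), p2)
        assert ld1 == pytest.approx(ld2, abs=1e-12)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            ct_log_density(self._rec(20.0, genotype="het"), self.PARAMS)

    def test_dataset_sum_matches_naive_loop_oracle(self):
        """Summed log-density over six records equals an independently
        coded plain-arithmetic loop to 1e-10."""
        rng = np.random.default_rng(4)
        recs = [self._rec(float(ct), genotype=g, sex=s)
                for ct, g, s in zip(rng.normal(21, 1, 6),
                                    ["wt", "hom", "wt", "hom", "wt", "hom"],
                                    ["F", "M", "M", "F", "F", "M"])]
        total = sum(ct_log_density(r, self.PARAMS) for r in recs)
        oracle = 0.0
        for r in recs:
            mu = 20.0
            if r["genotype"] == "hom":
                mu += 1.0
            if r["sex"] == "M":
                mu += 0.1
            mu += 0.2 - 0.1 + 0.05
            sigma = math.exp(0.0)
            oracle += (
                -0.5 * math.log(2 * math.pi)
                - math.log(sigma)
                - 0.5 * ((r["ct"] - mu) / sigma) ** 2
            )
        assert total == pytest.approx(oracle, abs=1e-10)


class TestFit:
    def test_matches_ols_without_varying_intercepts(self, small_primer_map):
        """On balanced one-run data with a flat-variance spec, posterior
        means of the genotype effects must sit on the OLS solution."""
        design = CohortDesign(
            [GenotypeGroup("wt", 8, 4, 4), GenotypeGroup("hom", 8, 4, 4)],
            n_litters=1, n_runs=1, primers=small_primer_map, replicates_per_well=3,
        )
        df, _ = simulate.simulate_ct_dataset(design, _flat_truth(small_primer_map), seed=21)
        spec = ModelSpec(varying_intercepts=(), residual_structure="constant")
        post = model.fit(df, spec, seed=3, chains=2, draws=300, warmup=200)

        # independent OLS oracle via lstsq on the same dummy coding
        primers = sorted(df["primer"].unique())
        X = []
        for r in df.itertuples():
            row = [0.0] * (3 * len(primers))
            ip = primers.index(r.primer)
            row[ip] = 1.0
            if r.genotype == "hom":
                row[len(primers) + ip] = 1.0
            if r.sex == "M":
                row[2 * len(primers) + ip] = 1.0
            X.append(row)
        coef, *_ = np.linalg.lstsq(np.array(X), df["ct"].to_numpy(), rcond=None)
        for ip, p in enumerate(primers):
            beta_hat = post.get(f"beta[{p},hom]")
            assert abs(beta_hat.mean() - coef[len(primers) + ip]) < 3 * beta_hat.std()
            assert abs(beta_hat.mean() - coef[len(primers) + ip]) < 0.1

    def test_recovers_truth_with_zero_variance_components(self, small_primer_map):
        design = CohortDesign(
            [GenotypeGroup("wt", 8, 4, 4), GenotypeGroup("hom", 8, 4, 4)],
            n_litters=1, n_runs=1, primers=small_primer_map, replicates_per_well=3,
        )
        truth = _flat_truth(small_primer_map, residual=0.2)
        df, _ = simulate.simulate_ct_dataset(design, truth, seed=8)
        spec = ModelSpec(varying_intercepts=("animal",))
        post = model.fit(df, spec, seed=5, chains=2, draws=300, warmup=200)
        b = post.get("beta[circT,hom]")
        assert abs(b.mean() - 1.0) < 3 * b.std()

    def test_same_seed_gives_identical_draws(self, small_ct):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = model.fit(small_ct, seed=11, chains=2, draws=200, warmup=150)
            b = model.fit(small_ct, seed=11, chains=2, draws=200, warmup=150)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_single_observation_primer_rejected(self, small_ct):
        extra = small_ct.iloc[[0]].copy()
        extra["primer"] = "Lonely"
        df = pd.concat([small_ct, extra], ignore_index=True)
        with pytest.raises(ValidationError, match="Lonely"):
            model.fit(df, seed=0, chains=2, draws=200, warmup=50)

    def test_single_genotype_rejected(self, small_ct):
        df = small_ct[small_ct["genotype"] == "wt"]
        with pytest.raises(ValidationError, match="two genotypes"):
            model.fit(df, seed=0, chains=2, draws=200, warmup=50)

    def test_fallback_preserves_fixed_effects(self, small_ct):
        """Force the gate to fail: the reduced refit may drop varying
        intercepts (litter first) but never fixed-effect terms."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = model.fit(small_ct, seed=2, chains=2, draws=200, warmup=10)
        assert any(k.startswith("beta[") for k in post.params)
        assert any(k.startswith("gamma[") for k in post.params)
        if post.fallback_applied:
            assert "litter" not in post.spec.varying_intercepts
            assert "animal" in post.spec.varying_intercepts

    def test_translation_equivariance_of_posterior(self, small_ct):
        """Ct + c shifts the per-primer intercepts by c and leaves genotype
        effects unchanged within Monte-Carlo error."""
        shifted = small_ct.copy()
        shifted["ct"] = shifted["ct"] + 5.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = model.fit(small_ct, seed=13, chains=2, draws=300, warmup=250)
            b = model.fit(shifted, seed=13, chains=2, draws=300, warmup=250)
        assert b.get("alpha[circT]").mean() - a.get("alpha[circT]").mean() == pytest.approx(
            5.0, abs=0.1
        )
        assert b.get("beta[circT,hom]").mean() == pytest.approx(
            a.get("beta[circT,hom]").mean(), abs=0.1
        )

    def test_censored_nondetects_shift_estimates_upward(self, small_primer_map):
        """Upper-censoring at the ceiling must place the affected primer's
        mean above the detected-only average."""
        truth = _flat_truth(small_primer_map, residual=1.0)
        truth.baseline_ct = {"Gapdh": 18.0, "circT": 39.5, "linT": 22.0}
        design = CohortDesign(
            [GenotypeGroup("wt", 8, 4, 4), GenotypeGroup("hom", 8, 4, 4)],
            n_litters=1, n_runs=1, primers=small_primer_map, replicates_per_well=3,
        )
        df, _ = simulate.simulate_ct_dataset(design, truth, seed=17)
        assert df["ct"].isna().sum() > 3
        spec = ModelSpec(varying_intercepts=("animal",), nondetect_policy="censor")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = model.fit(df, spec, seed=1, chains=2, draws=300, warmup=200)
        detected_mean = df.loc[df["primer"] == "circT", "ct"].mean()
        assert post.get("alpha[circT]").mean() > detected_mean

    def test_too_few_total_draws_rejected(self, small_ct):
        with pytest.raises(ValidationError, match="400"):
            model.fit(small_ct, seed=0, chains=2, draws=100, warmup=50)


class TestPosteriorPredictive:
    def test_empty_statistic_list_rejected(self, small_ct, fitted_small):
        with pytest.raises(ValidationError, match="empty"):
            model.posterior_predictive_check(small_ct, fitted_small, statistics=())

    def test_well_fitting_model_mostly_unflagged(self, small_ct, fitted_small):
        ppc = model.posterior_predictive_check(small_ct, fitted_small, seed=3)
        assert ppc["flagged"].mean() <= 0.3

    def test_inflated_sigma_flags_low_sd_rank(self, small_ct, fitted_small):
        """A posterior whose residual SD is grossly inflated must place the
        observed per-primer SD in the extreme low tail."""
        params = {k: v.copy() for k, v in fitted_small.params.items()}
        params["eta0"] = params["eta0"] + math.log(20.0)
        bloated = PosteriorSamples(
            params=params, coords=fitted_small.coords, spec=fitted_small.spec
        )
        ppc = model.posterior_predictive_check(small_ct, bloated, seed=3)
        sd_rows = ppc[ppc["statistic"] == "sd_by_primer"]
        assert (sd_rows["rank_prop"] < 0.025).all()
        assert sd_rows["flagged"].all()

    def test_unknown_level_rejected(self, small_ct, fitted_small):
        alien = small_ct.copy()
        alien.loc[alien.index[:3], "run"] = "run99"
        with pytest.raises(ValidationError, match="run99"):
            model.posterior_predictive_check(alien, fitted_small)
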