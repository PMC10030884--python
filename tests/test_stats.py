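"""Survival fits, AIC selection, NB mixed model, Mann-Kendall, Hill fit."""

import itertools
import math
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from azping import (HillCurve, SurvivalCurve, SurvivalDecayModel,
                    build_survival_curve, compare_aic, fit_hill, fit_nb_glmm,
                    fit_survival, generate_count_table,
                    generate_survival_dataset, mann_kendall_trend,
                    survival_curve_from_conversions)
from azping.stats import _nb_logpmf_terms


class TestBuildSurvivalCurve:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["roi_id", "peak_frame"])

    def test_no_evoked_events_flat_at_one(self):
        curve = build_survival_curve([1, 2, 3], self._events([]), 3600)
        assert len(curve.surviving_fraction) == 3600
        assert np.all(curve.surviving_fraction == 1.0)

    def test_single_death_at_midpoint(self):
        curve = build_survival_curve([0, 1, 2, 3],
                                     self._events([(2, 1800)]), 3600)
        assert np.all(curve.surviving_fraction[:1800] == 1.0)
        assert np.all(curve.surviving_fraction[1800:] == 0.75)

    def test_second_evoked_event_does_not_decrement_again(self):
        curve = build_survival_curve([0, 1],
                                     self._events([(0, 100), (0, 900)]), 2000)
        assert curve.surviving_fraction[150] == 0.5
        assert curve.surviving_fraction[1000] == 0.5

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError, match="no spontaneously active"):
            build_survival_curve([], self._events([]), 100)

    def test_cell_average_of_two_cells(self):
        ids = {0: [0, 1], 1: [10]}
        events = pd.DataFrame({"cell_id": [0], "roi_id": [0],
                               "peak_frame": [50]})
        curve = build_survival_curve(ids, events, 100)
        assert curve.surviving_fraction[0] == 1.0
        assert curve.surviving_fraction[60] == pytest.approx(0.75)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SurvivalCurve(np.arange(3), np.array([1.0, 0.5, 0.7]))


class TestSurvivalFit:
    def test_noiseless_plateau_recovery(self):
        t = np.arange(3600)
        y = 0.79 * np.exp(-0.002 * t) + 0.21
        fit = fit_survival(SurvivalCurve(t, y), "exp_plateau")
        assert fit.K == pytest.approx(0.002, rel=0.01)
        assert fit.plateau == pytest.approx(0.21, abs=0.005)

    def test_plain_exponential_data_gives_tiny_plateau(self):
        t = np.arange(3600)
        y = np.exp(-0.002 * t)
        fit = fit_survival(SurvivalCurve(t, y), "exp_plateau")
        assert fit.plateau < 0.01

    def test_half_life_identity(self):
        t = np.arange(200)
        y = np.exp(-math.log(2) * t)
        fit = fit_survival(SurvivalCurve(t, y), "exp")
        assert fit.half_life == pytest.approx(1.0, rel=1e-6)
        assert fit.half_life * fit.K == pytest.approx(math.log(2))

    def test_plateau_model_nests_plain_exponential(self):
        t = np.arange(100, dtype=float)
        m = SurvivalDecayModel("exp_plateau")
        assert np.allclose(m._predict(t, 0.01, 0.0),
                           SurvivalDecayModel("exp")._predict(t, 0.01))

    def test_flat_curve_flags_rate_boundary(self):
        t = np.arange(500)
        fit = SurvivalDecayModel("exp").fit(t, np.ones(500))
        assert fit.boundary_flag_


class TestCompareAic:
    def _fit(self, model, rss, k, n):
        from azping.stats import SurvivalFit, _aicc
        return SurvivalFit(model=model, K=0.01, plateau=0.0, rss=rss,
                           n_params=k, n_obs=n, aic=_aicc(rss, n, k))

    def test_identical_rss_prefers_simpler_model(self):
        sel = compare_aic(self._fit("exp", 1.0, 1, 100),
                          self._fit("exp_plateau", 1.0, 2, 100))
        assert sel.winner == "exp"
        assert sel.delta_aic > 0

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="identical data"):
            compare_aic(self._fit("exp", 1.0, 1, 100),
                        self._fit("exp_plateau", 1.0, 2, 200))

    def test_plateau_data_selects_plateau_model(self):
        wins = 0
        for seed in range(20):
            df = generate_survival_dataset(K=0.002, plateau=0.21, n_az=50,
                                           n_frames=3600, n_cells=20,
                                           seed=seed)
            curve = survival_curve_from_conversions(df, 3600)
            sel = compare_aic(fit_survival(curve, "exp"),
                              fit_survival(curve, "exp_plateau"))
            wins += sel.winner == "exp_plateau"
        assert wins >= 19

    def test_exponential_data_penalty_protects_parsimony(self):
        wins = 0
        for seed in range(20):
            df = generate_survival_dataset(K=0.002, plateau=0.0, n_az=50,
                                           n_frames=3600, n_cells=20,
                                           seed=seed)
            curve = survival_curve_from_conversions(df, 3600)
            sel = compare_aic(fit_survival(curve, "exp"),
                              fit_survival(curve, "exp_plateau"))
            wins += sel.winner == "exp_plateau"
        assert wins <= 10


class TestMannKendall:
    def _oracle(self, values, s_obs):
        total = ge = 0
        for perm in itertools.permutations(values):
            v = np.asarray(perm)
            diff = v[None, :] - v[:, None]
            s = int(np.sign(np.triu(diff, 1)).sum())
            total += 1
            ge += s >= s_obs
        return ge / total

    def test_canonical_increasing_quadruple(self):
        S, p = mann_kendall_trend([1, 2, 3, 4])
        assert S == 6
        assert p == pytest.approx(1 / 24)

    def test_strictly_decreasing_extreme(self):
        n = 6
        S, p = mann_kendall_trend(list(range(n, 0, -1)))
        assert S == -n * (n - 1) // 2
        assert p > 0.99

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        values = rng.normal(size=n)
        S, p = mann_kendall_trend(values)
        assert p == pytest.approx(self._oracle(values, S), abs=1e-12)

    def test_ties_match_enumeration_oracle(self):
        values = [1.0, 2.0, 2.0, 3.0, 1.0]
        S, p = mann_kendall_trend(values)
        assert p == pytest.approx(self._oracle(values, S), abs=1e-12)

    def test_constant_series_mid_p(self):
        S, p = mann_kendall_trend([2.0, 2.0, 2.0, 2.0])
        assert S == 0 and p == 0.5

    def test_alternative_less(self):
        S, p = mann_kendall_trend([4, 3, 2, 1], alternative="less")
        assert S == -6 and p == pytest.approx(1 / 24)

    def test_large_n_normal_approximation_sane(self):
        rng = np.random.default_rng(0)
        S, p = mann_kendall_trend(np.arange(50) + rng.normal(0, 1, 50))
        assert p < 1e-6

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            mann_kendall_trend([1, 2])


class TestNbMixedModel:
    def test_parameter_recovery(self):
        table = generate_count_table(30, 200, (0.83, 1.0, 1.3, 1.77),
                                     dispersion=1.5, animal_sd=0.3, seed=2)
        model = fit_nb_glmm(table)
        assert model.converged_
        truth = np.array([0.83, 1.0, 1.3, 1.77])
        assert np.all(np.abs(model.group_means_ / truth - 1) < 0.15)
        assert model.animal_sd_ == pytest.approx(0.3, abs=0.12)
        assert model.dispersion_ == pytest.approx(1.5, rel=0.35)
        assert model.factor_test_p_ < 1e-6
        assert model.trend_p_ == pytest.approx(1 / 24)

    def test_single_animal_raises(self):
        table = generate_count_table(1, 50, (1, 1, 1, 1), 1.5, 0.0, seed=0)
        with pytest.raises(ValueError, match="one animal"):
            fit_nb_glmm(table)

    def test_poisson_limit_of_nb_logpmf(self):
        """With dispersion -> infinity the NB log-pmf matches Poisson."""
        y = np.arange(0, 15, dtype=float)
        log_mu = np.full((15, 1), math.log(2.3))
        nb = _nb_logpmf_terms(y, log_mu, theta=1e8)[:, 0]
        po = poisson.logpmf(y.astype(int), 2.3)
        assert np.allclose(nb, po, atol=1e-4)

    def test_agrees_with_glmmtmb_oracle(self, tmp_path):
        """Independent cross-check against R's glmmTMB on one table."""
        table = generate_count_table(15, 100, (0.8, 1.0, 1.3, 1.8),
                                     dispersion=1.5, animal_sd=0.3, seed=42)
        csv = tmp_path / "counts.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "nb.R"
        script.write_text(f"""
suppressMessages(library(glmmTMB))
d <- read.csv('{csv}')
d$spont_group <- factor(d$spont_group)
m <- glmmTMB(n_evoked ~ spont_group + (1|animal_id), family=nbinom2, data=d)
fe <- fixef(m)$cond
means <- exp(c(fe[1], fe[1]+fe[2], fe[1]+fe[3], fe[1]+fe[4]))
cat(means, sqrt(VarCorr(m)$cond$animal_id[1,1]), sigma(m), sep='\\n')
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.strip().splitlines()[-6:]]
        model = fit_nb_glmm(table)
        assert np.allclose(model.group_means_, vals[:4], rtol=0.01)
        assert model.animal_sd_ == pytest.approx(vals[4], rel=0.05)
        assert model.dispersion_ == pytest.approx(vals[5], rel=0.02)

    def test_missing_group_raises(self):
        table = generate_count_table(3, 30, (1, 1, 1, 1), 1.5, 0.0, seed=0)
        table = table[table["spont_group"] != 3]
        with pytest.raises(ValueError, match="groups must be present"):
            fit_nb_glmm(table)


class TestHillFit:
    CONCS = [0.4, 0.75, 1.5, 3.0, 6.0, 12.0]

    def test_identity_at_half_saturation(self):
        fit = fit_hill(self.CONCS,
                       HillCurve._model(np.array(self.CONCS), 900, 2.5, 1.8,
                                        120))
        value_at_ka = fit.predict([fit.K_A_])[0]
        assert value_at_ka == pytest.approx(fit.C_ + fit.F_max_ / 2, rel=1e-9)

    def test_parameter_recovery_with_noise(self, rng):
        x = np.array(self.CONCS)
        y = HillCurve._model(x, 1000, 3.0, 2.0, 100)
        y_noisy = y + rng.normal(0, 0.01 * y)
        fit = fit_hill(x, y_noisy)
        for got, true in [(fit.F_max_, 1000), (fit.K_A_, 3.0), (fit.h_, 2.0),
                          (fit.C_, 100)]:
            assert abs(got / true - 1) < 0.1

    def test_large_h_approaches_step(self):
        fit = HillCurve()
        fit.F_max_, fit.K_A_, fit.h_, fit.C_ = 100.0, 3.0, 50.0, 10.0
        fit.rss_ = 0.0
        below, above = fit.predict([1.5, 6.0])
        assert below == pytest.approx(10.0, abs=1e-6)
        assert above == pytest.approx(110.0, abs=1e-6)

    def test_nonpositive_concentration_raises(self):
        with pytest.raises(ValueError):
            fit_hill([0.0, 1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            fit_hill([1, 2, 3], [1, 2, 3])
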