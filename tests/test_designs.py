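"""Next-dose selection, EWOC overdose control, run-in, stopping rules."""

import numpy as np
import pytest
from scipy.special import expit, logit

from dosefind import (
    DesignConfig,
    PatientRecord,
    StoppingRule,
    TrialDesign,
    TrialHistory,
    check_stopping,
    crm_next_dose,
    crml_run_in,
    ewoc_next_dose,
    ewoc_posterior,
)

from conftest import make_history


class TestCrmNextDose:
    def test_prior_estimates_pick_anchor_level(self, skeleton):
        rec = crm_next_dose(skeleton.probs, theta=0.2, current_max_tried=6)
        assert rec.level == 3

    def test_tie_breaks_to_lower_level(self):
        rec = crm_next_dose(np.array([0.15, 0.25]), theta=0.2)
        assert rec.level == 1

    def test_no_skip_caps_escalation(self):
        est = np.array([0.01, 0.02, 0.05, 0.10, 0.20, 0.40])
        rec = crm_next_dose(est, theta=0.2, current_max_tried=2, no_skip=True)
        assert rec.level == 3 and rec.constrained_by == "no_skip"
        rec = crm_next_dose(est, theta=0.2, current_max_tried=2, no_skip=False)
        assert rec.level == 5


class TestRunIn:
    def _h(self, grid, pairs):
        return TrialHistory(tuple(
            PatientRecord(j + 1, lvl, grid.dose(lvl), outcome=y)
            for j, (lvl, y) in enumerate(pairs)
        ))

    def test_starts_at_start_level(self):
        rec = crml_run_in(TrialHistory(), start_level=3, K=6)
        assert rec.level == 3

    def test_escalates_after_non_dlt(self, crmb_design):
        h = self._h(crmb_design.grid, [(3, 0)])
        assert crml_run_in(h, 3, 6).level == 4

    def test_holds_after_dlt(self, crmb_design):
        h = self._h(crmb_design.grid, [(3, 0), (4, 1)])
        assert crml_run_in(h, 3, 6).level == 4
        assert crml_run_in(h, 3, 6, deescalate_on_dlt=True).level == 3

    def test_never_exceeds_top_level(self, crmb_design):
        h = self._h(crmb_design.grid, [(l, 0) for l in (3, 4, 5, 6)])
        assert crml_run_in(h, 3, 6).level == 6

    def test_crml_design_hands_off_to_mle(self, skeleton):
        cfg = DesignConfig(method="CRML", theta=0.2, start_level=3)
        design = TrialDesign(config=cfg, skeleton=skeleton)
        g = design.grid
        h = self._h(g, [(3, 0), (4, 1)])  # heterogeneity reached
        rec = design.recommend(h)
        assert rec.estimates is not None  # model-based, not run-in
        assert 1 <= rec.level <= 6


class TestEwocPosterior:
    def test_empty_history_marginal_is_prior(self, ewoc_design):
        grid = ewoc_design.grid
        post = ewoc_posterior(TrialHistory(), grid, theta=0.2)
        x1, xK = grid.standardized_doses[0], grid.standardized_doses[-1]
        for x in np.linspace(x1, xK, 7):
            assert post.prob_overdose(x) == pytest.approx(
                (x - x1) / (xK - x1), abs=0.01)

    def test_dlt_at_lowest_dose_leaves_mtd_marginal_flat(self, ewoc_design):
        """psi(x1) == rho0 by construction, so an outcome at the lowest dose
        informs rho0 only; with independent priors the MTD marginal stays
        the prior."""
        grid = ewoc_design.grid
        x1, xK = grid.standardized_doses[0], grid.standardized_doses[-1]
        h = TrialHistory((PatientRecord(1, 1, x1, outcome=1),))
        post = ewoc_posterior(h, grid, theta=0.2)
        for x in grid.standardized_doses[1:-1]:
            assert post.prob_overdose(x) == pytest.approx(
                (x - x1) / (xK - x1), abs=0.01)

    def test_dlt_above_lowest_dose_shifts_mtd_down(self, ewoc_design):
        grid = ewoc_design.grid
        x1, xK = grid.standardized_doses[0], grid.standardized_doses[-1]
        h = TrialHistory((PatientRecord(1, 2, grid.dose(2), outcome=1),))
        post = ewoc_posterior(h, grid, theta=0.2)
        for x in grid.standardized_doses[1:-1]:
            assert post.prob_overdose(x) > (x - x1) / (xK - x1)

    def test_matches_rejection_sampling_oracle(self, ewoc_design):
        """6-record history: gamma-marginal CDF vs a 2e5-draw MC oracle."""
        grid = ewoc_design.grid
        x = grid.standardized_doses
        pairs = [(1, 0), (2, 0), (3, 0), (4, 1), (3, 0), (4, 0)]
        h = TrialHistory(tuple(
            PatientRecord(j + 1, lvl, x[lvl - 1], outcome=y)
            for j, (lvl, y) in enumerate(pairs)
        ))
        post = ewoc_posterior(h, grid, theta=0.2)
        rng = np.random.default_rng(123)
        N = 200_000
        rho = rng.uniform(0.0, 0.2, N)
        gam = rng.uniform(x[0], x[-1], N)
        a1 = (logit(0.2) - logit(rho)) / (gam - x[0])
        a0 = logit(rho) - a1 * x[0]
        w = np.ones(N)
        for lvl, y in pairs:
            p = expit(a0 + a1 * x[lvl - 1])
            w *= p if y else (1.0 - p)
        w /= w.sum()
        for xi in x:
            ind = (gam <= xi).astype(float)
            mc = np.sum(w * ind)
            se = np.sqrt(np.sum(w**2 * (ind - mc) ** 2))
            assert abs(post.prob_overdose(xi) - mc) < max(3 * se, 1e-3)

    def test_joint_density_normalized(self, ewoc_design):
        grid = ewoc_design.grid
        h = make_history(np.random.default_rng(2), grid, 8)
        post = ewoc_posterior(h, grid, theta=0.2)
        mass = np.trapezoid(
            np.trapezoid(post.joint, post.gamma_grid, axis=1), post.rho_grid)
        assert mass == pytest.approx(1.0, abs=1e-5)
        assert np.all(np.diff(post.gamma_cdf) >= 0)
        assert post.gamma_cdf[0] >= 0 and post.gamma_cdf[-1] == pytest.approx(1.0)


class TestEwocNextDose:
    def test_uniform_marginal_alpha_quantile(self, ewoc_design):
        grid = ewoc_design.grid
        x = grid.standardized_doses
        post = ewoc_posterior(TrialHistory(), grid, theta=0.2)
        rec = ewoc_next_dose(post, alpha=0.25, grid=grid, no_skip=False)
        q = x[0] + 0.25 * (x[-1] - x[0])
        expected = int(np.searchsorted(x, q, side="right"))
        assert rec.level in (expected, expected - 1)  # grid-resolution edge

    def test_monotone_in_alpha(self, ewoc_design):
        grid = ewoc_design.grid
        rng = np.random.default_rng(31)
        for _ in range(5):
            h = make_history(rng, grid, 6)
            post = ewoc_posterior(h, grid, theta=0.2)
            levels = [
                ewoc_next_dose(post, a, grid, no_skip=False).level
                for a in (0.05, 0.10, 0.25, 0.40, 0.50)
            ]
            assert levels == sorted(levels)

    def test_falls_back_to_level_one(self, ewoc_design):
        grid = ewoc_design.grid
        h = TrialHistory(tuple(
            PatientRecord(j + 1, 1, grid.dose(1), outcome=1) for j in range(4)
        ))
        post = ewoc_posterior(h, grid, theta=0.2)
        assert ewoc_next_dose(post, 0.05, grid).level == 1

    def test_skip_cap_applied_after_overdose_control(self, ewoc_design):
        grid = ewoc_design.grid
        post = ewoc_posterior(TrialHistory(), grid, theta=0.2)
        free = ewoc_next_dose(post, 0.5, grid, no_skip=False).level
        capped = ewoc_next_dose(post, 0.5, grid, no_skip=True,
                                current_max_tried=1).level
        assert capped == min(free, 2)


class TestStopping:
    def _h(self, n, level=3):
        return TrialHistory(tuple(
            PatientRecord(j + 1, level, 0.2, outcome=0) for j in range(n)
        ))

    def test_max_n_fires_at_limit(self):
        from dosefind import DoseRecommendation

        rule = (StoppingRule("max_n", max_n=25),)
        rec = crm_next_dose(np.array([0.1, 0.2, 0.3]), 0.2)
        assert check_stopping(self._h(25), rule, rec)[0]
        assert not check_stopping(self._h(24), rule, rec)[0]

    def test_m_at_level_fires_on_recommended_level(self):
        rules = (StoppingRule("m_at_level", m=6),)
        rec = crm_next_dose(np.array([0.05, 0.2, 0.4]), 0.2)  # level 2
        assert check_stopping(self._h(6, level=2), rules, rec)[0]
        assert not check_stopping(self._h(6, level=3), rules, rec)[0]

    def test_fixed_level_scope(self):
        rules = (StoppingRule("m_at_level", m=3, level_scope=3),)
        rec = crm_next_dose(np.array([0.05, 0.2, 0.4]), 0.2)
        assert check_stopping(self._h(3, level=3), rules, rec)[0]


class TestEquivalences:
    def test_tite_crm_with_full_weights_matches_crmb(self, skeleton):
        tite = TrialDesign(
            config=DesignConfig(method="TITE_CRM", theta=0.2, start_level=3,
                                observation_window_T=12.0),
            skeleton=skeleton,
        )
        crmb = TrialDesign(
            config=DesignConfig(method="CRMB", theta=0.2, start_level=3),
            skeleton=skeleton,
        )
        rng = np.random.default_rng(77)
        for _ in range(10):
            h = make_history(rng, crmb.grid, int(rng.integers(1, 15)), T=12.0)
            assert tite.recommend(h).level == crmb.recommend(h).level

    def test_tite_ewoc_with_full_weights_matches_ewoc(self, skeleton):
        tite = TrialDesign(
            config=DesignConfig(method="TITE_EWOC", theta=0.2, alpha=0.25,
                                start_level=3, observation_window_T=12.0),
            skeleton=skeleton,
        )
        ewoc = TrialDesign(
            config=DesignConfig(method="EWOC", theta=0.2, alpha=0.25,
                                start_level=3),
            skeleton=skeleton,
        )
        rng = np.random.default_rng(78)
        for _ in range(10):
            h = make_history(rng, ewoc.grid, int(rng.integers(1, 12)), T=12.0)
            assert tite.recommend(h).level == ewoc.recommend(h).level

    def test_recommendations_always_in_range(self, skeleton):
        rng = np.random.default_rng(13)
        designs = [
            TrialDesign(config=DesignConfig(method="CRMB", theta=0.2,
                                            start_level=3), skeleton=skeleton),
            TrialDesign(config=DesignConfig(method="CRML", theta=0.2,
                                            start_level=3), skeleton=skeleton),
            TrialDesign(config=DesignConfig(method="EWOC", theta=0.2,
                                            alpha=0.25, start_level=3),
                        skeleton=skeleton),
        ]
        for design in designs:
            for _ in range(8):
                h = make_history(rng, design.grid, int(rng.integers(0, 12)),
                                 p_dlt=rng.uniform(0, 1))
                lvl = design.recommend(h).level
                assert 1 <= lvl <= skeleton.K


def test_design_config_validation():
    with pytest.raises(ValueError):
        DesignConfig(method="EWOC", theta=0.2)  # alpha missing
    with pytest.raises(ValueError):
        DesignConfig(method="CRMB", theta=0.2, alpha=0.25)
    with pytest.raises(ValueError):
        DesignConfig(method="TITE_CRM", theta=0.2)  # window missing
    with pytest.raises(ValueError):
        StoppingRule("bogus")
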