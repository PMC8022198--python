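"""Reduced costs, sensitivity scores, and the robustness scan on the
proteome-constrained toy model."""

import pytest

from pcfba.analyses import (
    Condition,
    dual_reduced_cost,
    robustness_scan,
    scaled_reduced_cost,
    scannable_parameters,
    sensitivity_score,
)
from pcfba.simulation import max_growth_rate, min_glucose_concentration


@pytest.fixture(scope="module")
def limited_condition(toy_pc):
    """Glucose-limited reference: S fixed at S_min for mu = 0.3."""
    S, _ = min_glucose_concentration(toy_pc, 0.3)
    return Condition(S=S, label="glucose-limited mu=0.3")


class TestScaledReducedCost:
    def test_slack_uptake_bound_scores_zero(self, toy_pc, limited_condition):
        """Alanine and serine are taken up only for protein synthesis; their
        bounds have slack, so relaxing them cannot raise growth."""
        for aa in ("ala", "ser"):
            rc = scaled_reduced_cost(toy_pc, limited_condition, aa)
            assert rc.R == pytest.approx(0.0, abs=1e-3)

    def test_arginine_bound_active_below_proteome_limit(
        self, toy_pc, limited_condition
    ):
        """Arginine catabolism is an ATP source: its uptake bound is active
        in the glucose-limited regime and carries a positive reduced cost."""
        rc = scaled_reduced_cost(toy_pc, limited_condition, "arg")
        assert rc.R > 0.01
        assert not rc.unscaled

    def test_unknown_compound_rejected(self, toy_pc, limited_condition):
        with pytest.raises(ValueError):
            scaled_reduced_cost(toy_pc, limited_condition, "tryptophan")

    def test_finite_difference_agrees_with_dual_route(self, toy_pc):
        """The re-solve (finite-difference) reduced cost and the LP-dual
        implicit-function estimate agree within 10% for active bounds and
        both vanish for slack bounds, at three growth rates."""
        for mu in (0.25, 0.45, 0.65):
            S, _ = min_glucose_concentration(toy_pc, mu)
            cond = Condition(S=S)
            for aa in toy_pc.uptake_bounds:
                fd = scaled_reduced_cost(toy_pc, cond, aa).R
                dual = dual_reduced_cost(toy_pc, cond, aa)
                if abs(fd) < 1e-3:
                    assert abs(dual) < 1e-3
                else:
                    assert dual == pytest.approx(fd, rel=0.10)


class TestSensitivityScore:
    def test_glucose_limited_regime_pattern(self, toy_pc, limited_condition):
        """Below the proteome-limited regime the transporter cap is the
        active constraint and the proteome budget has slack."""
        glc = sensitivity_score(toy_pc, limited_condition, "glucose_transporter")
        prot = sensitivity_score(toy_pc, limited_condition, "proteome")
        assert glc.score > 0.1
        assert prot.score == pytest.approx(0.0, abs=1e-3)

    def test_proteome_scores_positive_when_budget_binds(self, toy_pc):
        """On rich medium with a generous transporter cap the budget is the
        binding constraint and its score turns positive."""
        sc = sensitivity_score(
            toy_pc, Condition(S=None), "proteome", tol=1e-6
        )
        # the calibrated cap binds simultaneously at mu_max; relax it
        relaxed = toy_pc.copy()
        relaxed.budget.transporter_cap *= 10
        sc2 = sensitivity_score(relaxed, Condition(S=None), "proteome", tol=1e-6)
        assert sc2.score > 0.1
        assert sc.score >= -1e-6

    def test_unknown_constraint_rejected(self, toy_pc, limited_condition):
        with pytest.raises(ValueError):
            sensitivity_score(toy_pc, limited_condition, "membrane")

    def test_score_zero_iff_inactive_positive(self, toy_pc):
        """Whenever the returned solution carries inactive enzyme, the
        proteome score vanishes (slack constraint => zero shadow value)."""
        for mu in (0.2, 0.5):
            S, res = min_glucose_concentration(toy_pc, mu)
            assert res.inactive_enzyme > 0
            sc = sensitivity_score(toy_pc, Condition(S=S), "proteome")
            assert sc.score == pytest.approx(0.0, abs=1e-3)


class TestRelaxationMonotonicity:
    def test_raising_uptake_bound_never_decreases_mu(self, toy_pc):
        S, _ = min_glucose_concentration(toy_pc, 0.3)
        mu0, _ = max_growth_rate(toy_pc, S, tol=1e-5)
        pert = toy_pc.copy()
        a, b = pert.uptake_bounds["arg"]
        pert.uptake_bounds["arg"] = (a, b + 0.2)
        mu1, _ = max_growth_rate(pert, S, tol=1e-5)
        assert mu1 >= mu0 - 1e-6

    def test_tightening_never_increases_mu(self, toy_pc):
        S, _ = min_glucose_concentration(toy_pc, 0.3)
        mu0, _ = max_growth_rate(toy_pc, S, tol=1e-5)
        pert = toy_pc.copy()
        a, b = pert.uptake_bounds["arg"]
        pert.uptake_bounds["arg"] = (a * 0.5, b * 0.5)
        mu1, _ = max_growth_rate(pert, S, tol=1e-5)
        assert mu1 <= mu0 + 1e-6


@pytest.fixture(scope="module")
def scan(toy_pc):
    S, _ = min_glucose_concentration(toy_pc, 0.3)
    params = [
        ("k_cat", "E_pts:GLCpts"),
        ("k_cat", "E_ldh:LDH"),
        ("k_cat", "E_adi:ADI"),
        ("k_cat", "E_pox:POX"),
        ("machinery_rate", "ribosome"),
        ("budget", "total_modeled_fraction"),
        ("budget", "transporter_cap"),
    ]
    frame = robustness_scan(
        toy_pc,
        [Condition(S=S, label="glucose-limited")],
        parameters=params,
    )
    return frame, params


class TestRobustnessScan:
    def test_two_rows_per_parameter_per_condition(self, scan):
        frame, params = scan
        assert len(frame) == 2 * len(params)
        counts = frame.groupby("parameter").size()
        assert (counts == 2).all()

    def test_blocked_reaction_parameter_has_no_effect(self, scan):
        frame, _ = scan
        rows = frame[frame["parameter"] == "k_cat:E_pox:POX"]
        assert (rows["rel_change"].abs() < 1e-6).all()

    def test_halving_transporter_kcat_matters_when_glucose_limited(self, scan):
        """The transporter is the active constraint under glucose
        limitation, so halving its turnover number changes growth > 1%."""
        frame, _ = scan
        row = frame[
            (frame["parameter"] == "k_cat:E_pts:GLCpts")
            & (frame["direction"] == "x0.5")
        ].iloc[0]
        assert abs(row["rel_change"]) > 0.01
        assert row["flagged"]

    def test_inactive_pathway_parameters_do_not_move_growth(self, scan):
        """LDH carries no flux in the glucose-limited optimum at low mu;
        its turnover number is irrelevant there."""
        frame, _ = scan
        rows = frame[frame["parameter"] == "k_cat:E_ldh:LDH"]
        assert (rows["rel_change"].abs() < 0.01).all()

    def test_scannable_parameters_cover_model(self, toy_pc):
        params = scannable_parameters(toy_pc)
        kinds = {k for k, _ in params}
        assert kinds == {"k_cat", "k_deg", "machinery_rate", "budget", "kinetics"}
        assert ("budget", "transporter_cap") in params
        # every catalyzed reaction contributes one k_cat parameter
        n_kcat = sum(1 for k, _ in params if k == "k_cat")
        assert n_kcat == sum(len(e.catalyzed) for e in toy_pc.enzymes.values())
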