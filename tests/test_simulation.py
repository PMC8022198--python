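"""Growth-rate LP assembly, binary searches, and coupling soundness."""

import numpy as np
import pytest

from pcfba.fixtures import make_micro_model, micro_model_s_min
from pcfba.simulation import (
    GlucoseKinetics,
    GrowthInfeasibleError,
    assemble_lp,
    audit_solution,
    feasible,
    inactive_enzyme,
    max_growth_rate,
    min_glucose_concentration,
    solve_at,
)


class TestGlucoseKinetics:
    def test_saturation_limits(self):
        kin = GlucoseKinetics(k_cat=24000.0, k_m=0.2, transporter_cap=1e-3)
        assert kin.saturation(None) == 1.0  # saturating medium
        assert kin.saturation(0.0) == 0.0
        # S = K_M gives half-saturation, hence half the maximal uptake
        assert kin.saturation(0.2) == pytest.approx(0.5)
        assert kin.max_uptake(0.2) == pytest.approx(0.5 * 24000.0 * 1e-3)
        with pytest.raises(ValueError):
            kin.saturation(-1.0)

    def test_sigma_strictly_below_one_for_finite_s(self):
        kin = GlucoseKinetics(1.0, 0.2, 1.0)
        for S in (0.001, 1.0, 1000.0):
            assert 0 <= kin.saturation(S) < 1


class TestAssembly:
    def test_mu_zero_rejected(self, toy_pc):
        with pytest.raises(ValueError, match="mu"):
            assemble_lp(toy_pc, 0.0)

    def test_amino_acid_bounds_scale_with_growth_rate(self, toy_pc):
        for mu in (0.2, 0.6):
            lp = assemble_lp(toy_pc, mu)
            for compound, (a, b) in toy_pc.uptake_bounds.items():
                rid = toy_pc.uptake_reactions[compound]
                assert lp.upper[rid] == pytest.approx(max(0.0, a * mu + b))

    def test_blocked_reactions_pinned_to_zero(self, toy_pc):
        lp = assemble_lp(toy_pc, 0.5)
        for rid in toy_pc.blocked_reactions:
            assert lp.lower[rid] == lp.upper[rid] == 0.0

    def test_biomass_dilution_pinned_to_growth_rate(self, toy_pc):
        for mu in (0.25, 0.5):
            lp = assemble_lp(toy_pc, mu)
            want = mu * toy_pc.growth_pinned["BIODIL"]
            assert lp.lower["BIODIL"] == lp.upper["BIODIL"] == pytest.approx(want)


class TestFeasibility:
    def test_unreachable_growth_rate_infeasible(self, toy_pc):
        ok, _ = feasible(toy_pc, 10.0, None)
        assert not ok

    def test_no_energy_source_infeasible(self, toy_pc):
        """Maintenance demand with zero glucose and zero amino-acid uptake
        cannot be met."""
        starved = toy_pc.copy()
        starved.uptake_bounds = {aa: (0.0, 0.0) for aa in toy_pc.uptake_bounds}
        ok, _ = feasible(starved, 0.05, 0.0)
        assert not ok

    def test_modest_growth_on_rich_medium_feasible(self, toy_pc):
        ok, res = feasible(toy_pc, 0.3, None)
        assert ok
        assert res.fluxes["BIODIL"] > 0


class TestMicroModelClosedForm:
    """On a three-reaction chemostat model, the minimal glucose
    concentration has a Michaelis-Menten closed form; the bisection must
    reproduce it."""

    @pytest.mark.parametrize("mu", [0.1, 0.3, 0.55])
    def test_bisection_matches_closed_form(self, mu):
        m = make_micro_model()
        expected = micro_model_s_min(m, mu)
        S, _ = min_glucose_concentration(m, mu, tol=1e-8)
        assert S == pytest.approx(expected, rel=1e-6)

    def test_s_min_nondecreasing_in_growth_rate(self):
        m = make_micro_model()
        mus = np.linspace(0.05, 0.6, 10)
        smins = [min_glucose_concentration(m, mu, tol=1e-8)[0] for mu in mus]
        assert all(b >= a - 1e-12 for a, b in zip(smins, smins[1:]))

    def test_bisection_brackets_nest_when_tolerance_halves(self):
        m = make_micro_model()
        coarse, _ = min_glucose_concentration(m, 0.3, tol=1e-4)
        fine, _ = min_glucose_concentration(m, 0.3, tol=5e-5)
        true = micro_model_s_min(m, 0.3)
        # both are upper ends of nested brackets around the true value
        assert true <= fine <= coarse * (1 + 1e-4) + 1e-12

    def test_unreachable_rate_raises(self):
        m = make_micro_model(cap=1e-6)
        with pytest.raises(GrowthInfeasibleError, match="unreachable"):
            min_glucose_concentration(m, 1.0)


class TestToyChemostatCurve:
    def test_s_min_monotone_and_saturation_increases(self, toy_pc):
        mus = np.linspace(0.15, 1.2, 6)
        smins = []
        sigmas = []
        for mu in mus:
            S, res = min_glucose_concentration(toy_pc, mu)
            smins.append(S)
            sigmas.append(S / (toy_pc.km_glucose + S))
        assert all(b >= a - 1e-9 for a, b in zip(smins, smins[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(sigmas, sigmas[1:]))
        assert all(0 <= s < 1 for s in sigmas)

    def test_transporter_at_cap_reproduces_mm_uptake(self, toy_pc):
        """At the minimal glucose concentration the transporter is at its
        abundance cap, so uptake equals k_cat x cap x S/(K_M + S)."""
        mu = 0.5
        S, res = min_glucose_concentration(toy_pc, mu)
        cap = toy_pc.budget.transporter_cap
        conc = res.concentrations["enz_E_pts"]
        assert conc == pytest.approx(cap, rel=1e-4)
        sigma = S / (toy_pc.km_glucose + S)
        assert res.fluxes["GLCpts"] == pytest.approx(
            toy_pc.kcat_transporter * cap * sigma, rel=1e-4
        )

    def test_coupling_rows_hold_in_returned_solutions(self, toy_pc):
        for mu in (0.2, 0.8):
            S, res = min_glucose_concentration(toy_pc, mu)
            assert audit_solution(toy_pc, res, rel_tol=1e-6, abs_tol=1e-6) == []

    def test_degradation_ties_encode_steady_state(self, toy_pc):
        """Synthesis = (mu + k_deg) x concentration for every catalyst with
        turnover: checked through the mRNA pools, where degradation flux is
        k_deg x [mRNA] and dilution is mu x [mRNA]."""
        mu = 0.4
        _, res = min_glucose_concentration(toy_pc, mu)
        for species, deg_rid in toy_pc.degradation_of.items():
            if not species.startswith("mrna_"):
                continue
            kdeg = toy_pc.k_deg_of[species]
            conc = res.concentrations[species]
            assert res.fluxes[deg_rid] == pytest.approx(
                kdeg * conc, rel=1e-6, abs=1e-12
            )
            tx = res.fluxes[f"TX_{species[5:]}"]
            assert tx == pytest.approx((mu + kdeg) * conc, rel=1e-6, abs=1e-12)


class TestInactiveEnzyme:
    def test_positive_at_low_growth_zero_at_mu_max(self, toy_pc):
        _, res_low = min_glucose_concentration(toy_pc, 0.15)
        assert inactive_enzyme(res_low) > 0
        mu_max, res_top = max_growth_rate(toy_pc, None)
        assert inactive_enzyme(res_top) == pytest.approx(0.0, abs=1e-3)

    def test_accounting_identity(self, toy_pc):
        """Inactive mass = budget - active catalyst mass (the unmodeled
        share lives outside the modeled budget)."""
        _, res = min_glucose_concentration(toy_pc, 0.3)
        used = sum(
            mass * res.concentrations[sp]
            for sp, mass in toy_pc.protein_mass_of.items()
        )
        assert used + res.inactive_enzyme == pytest.approx(
            toy_pc.budget.total_modeled_fraction, rel=1e-6
        )


class TestMaxGrowthRate:
    def test_rich_medium_growth_and_proteome_closure(self, toy_pc):
        mu_max, res = max_growth_rate(toy_pc, None)
        assert 0.5 < mu_max < 2.0
        assert audit_solution(toy_pc, res, rel_tol=1e-6, abs_tol=1e-4) == []

    def test_bigger_proteome_does_not_slow_growth(self, toy_pc):
        mu0, _ = max_growth_rate(toy_pc, None)
        mu1, _ = max_growth_rate(
            toy_pc, None,
            budget_fraction=toy_pc.budget.total_modeled_fraction * 2,
        )
        assert mu1 >= mu0 - 1e-6

    def test_closed_transporter_starves_the_cell(self, toy_pc):
        """With the glucose transporter capped at (near) zero, growth must
        be sustained by amino acids alone; arginine ATP cannot drive the
        biomass reaction, which needs glucose-derived precursors."""
        with pytest.raises(GrowthInfeasibleError):
            max_growth_rate(toy_pc, None, transporter_cap=1e-12)
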