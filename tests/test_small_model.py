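"""The three-pathway small model: parameter estimation, LP vs analytic
oracle, phase structure, and sensitivities."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcfba.small_model import (
    PathwayParams,
    estimate_pathway_params,
    phase_scan,
    small_model_sensitivity,
    solve_small_model,
    solve_small_model_analytic,
    substrate_level_arginine_yield,
)


class TestPathwayParameterEstimation:
    def test_atp_yields(self, toy_params):
        y1, y2, y3 = toy_params.atp_yield
        assert y1 == pytest.approx(3.0, abs=1e-6)
        assert y2 == pytest.approx(2.0, abs=1e-6)
        # 1 substrate-level ATP + 2 protons / 3 protons-per-ATP
        assert y3 == pytest.approx(1 + 2 / 3, abs=1e-6)

    def test_substrate_level_yield_isolates_carbamate_kinase(self, toy_network):
        assert substrate_level_arginine_yield(toy_network) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_efficiency_ordering_lactate_mixed_arginine(self, toy_params):
        e1, e2, e3 = toy_params.efficiency
        assert e2 > e1 > e3

    def test_efficiency_is_yield_over_cost(self, toy_params):
        for y, p, e in zip(toy_params.atp_yield, toy_params.protein_cost,
                           toy_params.efficiency):
            assert e == pytest.approx(y / p)

    def test_infeasible_pathway_lp_names_the_pathway(self, toy_network):
        m = toy_network.copy()
        m.reactions["ADI"].upper_bound = 0.0
        with pytest.raises(RuntimeError, match="arginine"):
            estimate_pathway_params(m)


def _random_params(rng) -> tuple[PathwayParams, float]:
    y2 = rng.uniform(0.5, 4.0)
    y1 = y2 + rng.uniform(0.1, 3.0)
    y3 = rng.uniform(0.2, 4.0)
    p2 = rng.uniform(1e-3, 2e-2)
    p1 = p2 + rng.uniform(1e-4, 2e-2)
    p3 = rng.uniform(1e-3, 3e-2)
    params = PathwayParams(
        atp_yield=(y1, y2, y3),
        protein_cost=(p1, p2, p3),
        proteome_cap=rng.uniform(0.05, 0.4),
        arg_slope=rng.uniform(0.0, 1.0),
        arg_intercept=rng.uniform(0.0, 0.5),
    )
    j_glc = rng.uniform(0.0, 0.99 * params.proteome_cap / p2)
    return params, j_glc


def test_lp_matches_analytic_oracle_on_random_parameters():
    """100 random parameter sets: the LP optimum equals the hand-derived
    greedy (fill by marginal ATP per proteome) solution."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        params, j_glc = _random_params(rng)
        lp = solve_small_model(params, j_glc)
        an = solve_small_model_analytic(params, j_glc)
        assert max(abs(a - b) for a, b in zip(lp, an)) < 1e-8


def test_unbounded_proteome_gives_pure_phase_a(toy_params):
    params = dataclasses.replace(toy_params, proteome_cap=1e6,
                                 flux_profiles={})
    j1, j2, j3, _ = solve_small_model(params, 10.0)
    assert j1 == pytest.approx(10.0)
    assert j2 == pytest.approx(0.0, abs=1e-9)
    assert j3 == pytest.approx(params.arg_bound(10.0))


def test_zero_glucose_zero_intercept_all_zero(toy_params):
    params = dataclasses.replace(toy_params, arg_intercept=0.0,
                                 flux_profiles={})
    assert solve_small_model(params, 0.0) == pytest.approx((0, 0, 0, 0))


def test_infeasible_glucose_reports_maximum(toy_params):
    j_max = toy_params.proteome_cap / min(toy_params.protein_cost[:2])
    with pytest.raises(ValueError, match="maximum sustainable"):
        solve_small_model(toy_params, j_max * 1.01)


@given(st.floats(0.1, 20.0), st.floats(0.1, 20.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_atp_optimum_monotone_in_glucose_and_cap(g_lo, g_hi):
    """Relaxation monotonicity: J_ATP never decreases when glucose supply
    or the proteome cap grows."""
    params = PathwayParams(
        atp_yield=(3.0, 2.0, 5 / 3), protein_cost=(0.035, 0.0116, 0.0426),
        proteome_cap=0.30, arg_slope=0.3,
    )
    lo, hi = sorted((g_lo, g_hi))
    hi = min(hi, 0.99 * params.proteome_cap / params.protein_cost[1])
    lo = min(lo, hi)
    assert solve_small_model(params, hi)[3] >= solve_small_model(params, lo)[3] - 1e-9
    bigger = dataclasses.replace(params, proteome_cap=params.proteome_cap * 1.5)
    assert solve_small_model(bigger, lo)[3] >= solve_small_model(params, lo)[3] - 1e-9


class TestPhaseScan:
    def test_phases_contiguous_in_order(self, toy_params):
        prof = phase_scan(toy_params, np.linspace(0.01, 24.0, 150))
        blocks = [b[0] for b in prof.phase_blocks()]
        assert blocks == ["A", "B", "C"]

    def test_phase_b_starts_where_inactive_reaches_zero(self, toy_params):
        prof = phase_scan(toy_params, np.linspace(0.01, 24.0, 400))
        b_start = next(i for i, lab in enumerate(prof.labels) if lab == "B")
        # inactive enzyme positive before the onset, zero from the onset on
        assert prof.inactive[b_start - 1] > 0
        assert prof.inactive[b_start + 1 :].max() < 1e-9

    def test_arginine_declines_before_mixed_acid(self, toy_params):
        prof = phase_scan(toy_params, np.linspace(0.01, 24.0, 400))
        first_b = prof.labels.index("B")
        first_c = prof.labels.index("C")
        assert first_b < first_c
        # pathway 3 hits zero exactly when C begins
        assert prof.j3[first_c] == pytest.approx(0.0, abs=1e-9)

    def test_raised_arginine_efficiency_inverts_decline_order(self, toy_params):
        """If arginine catabolism is made more protein-efficient than mixed
        acid, the proteome squeeze sheds mixed acid first."""
        p1, p2, p3 = toy_params.protein_cost
        cheap_arg = dataclasses.replace(
            toy_params, protein_cost=(p1, p2, p3 / 8), flux_profiles={}
        )
        e = cheap_arg.efficiency
        assert e[2] > e[0]
        prof = phase_scan(cheap_arg, np.linspace(0.01, 24.0, 300))
        labels = prof.labels
        assert "C" in labels
        first_c = labels.index("C")
        # pathway 1 declines while arginine is still at its bound
        assert prof.j3[first_c] == pytest.approx(
            cheap_arg.arg_bound(prof.j_glc[first_c]), rel=1e-6
        )

    def test_non_monotone_grid_rejected(self, toy_params):
        with pytest.raises(ValueError):
            phase_scan(toy_params, [1.0, 0.5, 2.0])

    @pytest.mark.parametrize("field,factor", [
        ("protein_cost_0", 2.0), ("protein_cost_0", 0.5),
        ("protein_cost_1", 2.0), ("protein_cost_1", 0.5),
        ("protein_cost_2", 2.0), ("protein_cost_2", 0.5),
        ("proteome_cap", 2.0), ("proteome_cap", 0.5),
        ("arg_slope", 2.0), ("arg_slope", 0.5),
        ("atp_yield_2", 2.0), ("atp_yield_2", 0.5),
    ])
    def test_arginine_decline_only_in_proteome_limited_regime(
        self, toy_params, field, factor
    ):
        """Twofold one-at-a-time parameter variation: arginine catabolism
        leaves its upper bound only once the proteome cap is binding."""
        params = _vary(toy_params, field, factor)
        grid = np.linspace(0.01, 0.95 * params.proteome_cap
                           / min(params.protein_cost[:2]), 200)
        prof = phase_scan(params, grid)
        for i in range(len(grid) - 1):
            declining = prof.j3[i + 1] < prof.j3[i] - 1e-9
            if declining:
                # the cap must be binding by the end of the declining step
                # (the first such step may straddle the phase boundary)
                assert prof.inactive[i + 1] < 1e-6, (
                    f"arginine declined with proteome slack at {field} x{factor}"
                )


def _vary(params, field, factor):
    kw = {"flux_profiles": {}}
    if field.startswith(("protein_cost", "atp_yield")):
        name, idx = field.rsplit("_", 1)
        vals = list(getattr(params, name))
        vals[int(idx)] *= factor
        kw[name] = tuple(vals)
    else:
        kw[field] = getattr(params, field) * factor
    return dataclasses.replace(params, **kw)


class TestSmallModelSensitivity:
    def test_phase_a_glucose_and_arginine_score_proteome_zero(self, toy_params):
        g = 3.0  # proteome cap slack here
        assert small_model_sensitivity(toy_params, g, "glucose") > 0
        assert small_model_sensitivity(toy_params, g, "arginine") > 0
        assert small_model_sensitivity(toy_params, g, "proteome") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_phase_c_proteome_scores_positive(self, toy_params):
        g = 20.0
        assert small_model_sensitivity(toy_params, g, "proteome") > 0

    def test_scores_sum_to_one_without_intercept(self, toy_params):
        """With a zero arginine intercept the optimum is positively
        homogeneous of degree 1 in (J_glc, P, arginine bound); Euler's
        relation makes the three scaled scores sum to 1."""
        params = dataclasses.replace(toy_params, arg_intercept=0.0,
                                     flux_profiles={})
        for g in (3.0, 11.0, 20.0):
            total = sum(
                small_model_sensitivity(params, g, c)
                for c in ("glucose", "proteome", "arginine")
            )
            assert total == pytest.approx(1.0, rel=0.02)

    def test_local_linearity_of_scores(self, toy_params):
        """Scores at perturbation sizes 0.5%, 1% and 2% agree within 20%
        (away from phase boundaries)."""
        for g in (3.0, 20.0):
            scores = [
                small_model_sensitivity(toy_params, g, "glucose", delta_c=d)
                for d in (0.005, 0.01, 0.02)
            ]
            ref = scores[1]
            if abs(ref) > 1e-12:
                for s in scores:
                    assert abs(s - ref) <= 0.2 * abs(ref) + 1e-9
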