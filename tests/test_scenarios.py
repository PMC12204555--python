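"""Scenario battery: substrate screens, exchange robustness, abundance
sensitivity, the oxygen/cytochrome scan, flux summation and PCA."""

import numpy as np
import pytest

from xfba.community import solve_xfba
from xfba.scenarios import (
    CarbonSource,
    NitrogenSource,
    abundance_sensitivity,
    exchange_robustness,
    nitrogen_carbon_screen,
    oxygen_cytochrome_scan,
    pca_flux_comparison,
    summed_member_fluxes,
)
from xfba.toys import (
    ToySpec,
    configure_toy_boundaries,
    make_toy_cell,
    make_toy_community,
    make_toy_members,
)

PINS = {"EX_s[u]": -10.0}
CYTC = {"m1": "CYTC[m1]", "m2": "CYTC[m2]"}
CYTBD = {"m1": "CYTBD[m1]", "m2": "CYTBD[m2]"}


@pytest.fixture(scope="module")
def fixer_cell():
    return make_toy_cell(ToySpec(), nitrogenase_open=True)


class TestSourceScreen:
    def test_ammonia_beats_dinitrogen(self, fixer_cell):
        """NH3 as N source outgrows N2 (nitrogenase ATP burden), and the
        N-source ordering does not depend on list order."""
        s = CarbonSource("substrate", "EX_s", 4)
        pairs = [(s, NitrogenSource("NH3", "EX_nh3")),
                 (s, NitrogenSource("N2", "EX_n2"))]
        res = nitrogen_carbon_screen(fixer_cell, pairs, (4.16, 4))
        by_n = {g["n_source"]: s for g, s in zip(res.grid, res.summaries)}
        assert by_n["NH3"]["mu"] > by_n["N2"]["mu"] > 0
        res_flip = nitrogen_carbon_screen(fixer_cell, pairs[::-1], (4.16, 4))
        flip = {g["n_source"]: s for g, s in
                zip(res_flip.grid, res_flip.summaries)}
        for k in by_n:
            assert by_n[k]["mu"] == pytest.approx(flip[k]["mu"], rel=1e-9)

    def test_carbon_matched_pin_applied(self, fixer_cell):
        s8 = CarbonSource("fat_substrate", "EX_s", 8)
        res = nitrogen_carbon_screen(
            fixer_cell, [(s8, NitrogenSource("NH3", "EX_nh3"))], (4.16, 4))
        assert res.grid[0]["c_uptake"] == pytest.approx(2.08)
        sol = res.solutions[0]
        assert sol.fluxes["EX_s"] == pytest.approx(-2.08, abs=1e-9)

    def test_unknown_exchange_rejected(self, fixer_cell):
        with pytest.raises(KeyError, match="EX_nope"):
            nitrogen_carbon_screen(
                fixer_cell,
                [(CarbonSource("x", "EX_nope", 4), None)], (4.16, 4))


@pytest.fixture(scope="module")
def robustness_result():
    comm, spec = make_toy_community(ToySpec())
    grid = [-3.0, -1.0, -0.5, -0.1, 0.0, 0.5, 1.5, 3.0]
    return exchange_robustness(comm, spec, "asp", grid, fixed=PINS,
                               nitrogenase_id="NASE[m2]"), grid


class TestExchangeRobustness:
    def test_zero_pin_equals_base(self, robustness_result):
        res, grid = robustness_result
        comm, spec = make_toy_community(ToySpec())
        base = solve_xfba(comm, spec, fixed=PINS)
        at_zero = res.summaries[grid.index(0.0)]
        assert at_zero["community_growth"] == pytest.approx(
            base.members["community"]["community_growth"], rel=1e-9)

    def test_base_bounds_every_pinned_optimum(self, robustness_result):
        """Pinning only restricts the feasible set."""
        res, grid = robustness_result
        base = res.summaries[grid.index(0.0)]["community_growth"]
        for s in res.summaries:
            if s.get("community_growth") is not None:
                assert s["community_growth"] <= base + 1e-8

    def test_plateau_at_low_exchange(self, robustness_result):
        """Shipping preformed amino acid from the N-fixer substitutes
        in-member synthesis at equal cost: small transfers leave growth
        untouched."""
        res, grid = robustness_result
        base = res.summaries[grid.index(0.0)]["community_growth"]
        for value in (-1.0, -0.5, -0.1):
            got = res.summaries[grid.index(value)]["community_growth"]
            assert got == pytest.approx(base, rel=1e-9)

    def test_decline_at_high_exchange_either_direction(self, robustness_result):
        res, grid = robustness_result
        base = res.summaries[grid.index(0.0)]["community_growth"]
        for value in (-3.0, 3.0):
            got = res.summaries[grid.index(value)]["community_growth"]
            assert got < base - 1e-6


@pytest.fixture(scope="module")
def sensitivity_result():
    spec = ToySpec()
    comm, coupling = make_toy_community(spec)
    return abundance_sensitivity(
        make_toy_members(spec), coupling,
        [0.05, 0.10, 0.15, 0.20, 0.25, 0.30], fixed=PINS,
        nitrogenase_id="NASE[m2]",
        community_setup=configure_toy_boundaries)


class TestAbundanceSensitivity:
    def test_growing_member_growth_declines(self, sensitivity_result):
        mu1 = [s["m1.mu1"] for s in sensitivity_result.summaries]
        assert all(a > b for a, b in zip(mu1, mu1[1:]))

    def test_n_fixation_declines(self, sensitivity_result):
        fix = [s["m2.n2_fixation"] for s in sensitivity_result.summaries]
        assert all(a > b for a, b in zip(fix, fix[1:]))

    def test_base_fraction_reproduces_base_case(self, sensitivity_result):
        comm, spec = make_toy_community(ToySpec(), nongrowing_fraction=0.10)
        base = solve_xfba(comm, spec, fixed=PINS)
        at_10 = sensitivity_result.summaries[1]
        assert at_10["m1.mu1"] == pytest.approx(base.members["m1"]["mu1"],
                                                rel=1e-9)

    def test_ratio_and_coefficient_recomputed(self, sensitivity_result):
        rs = [g["r"] for g in sensitivity_result.grid]
        expected = [f / (1 - f) for f in
                    [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]]
        assert rs == pytest.approx(expected)
        for g, s in zip(sensitivity_result.grid, sensitivity_result.summaries):
            assert s["phb_content_nongrowing"] == pytest.approx(0.50,
                                                                abs=1e-9)


@pytest.fixture(scope="module")
def oxygen_scan_result():
    comm, spec = make_toy_community(ToySpec())
    grid = [9.0, 9.5] + list(np.round(np.arange(10.0, 30.5, 1.0), 2))
    res = oxygen_cytochrome_scan(comm, spec, grid, "EX_o2[u]", CYTC,
                                 CYTBD, fixed=PINS,
                                 nitrogenase_id="NASE[m2]")
    return res, grid


class TestOxygenScan:
    def test_infeasible_below_threshold(self, oxygen_scan_result):
        res, grid = oxygen_scan_result
        by_o2 = dict(zip(grid, res.summaries))
        assert by_o2[9.0]["status"] == "infeasible"
        assert by_o2[10.0]["status"] == "optimal"

    def test_threshold_refined_to_stoichiometric_minimum(self, oxygen_scan_result):
        """One O2 per substrate once overflow leaves as formate: the pinned
        substrate of 10 sets the threshold at exactly 10.00."""
        res, _ = oxygen_scan_result
        assert res.extras["feasibility_threshold"] == pytest.approx(10.0,
                                                                    abs=0.01)

    def test_unimodal_rise_and_fall(self, oxygen_scan_result):
        res, grid = oxygen_scan_result
        mu = [s["community_growth"] for s in res.summaries
              if s.get("community_growth") is not None]
        peak = mu.index(max(mu))
        assert 0 < peak < len(mu) - 1
        assert all(a <= b + 1e-9 for a, b in zip(mu[:peak], mu[1:peak + 1]))
        assert all(a >= b - 1e-9 for a, b in zip(mu[peak:], mu[peak + 1:]))

    def test_cytc_only_on_rising_branch(self, oxygen_scan_result):
        res, _ = oxygen_scan_result
        feasible = [s for s in res.summaries
                    if s.get("community_growth") is not None]
        peak = max(feasible, key=lambda s: s["community_growth"])
        rising = feasible[: feasible.index(peak) + 1]
        for s in rising:
            assert s["m1.cytbd"] + s["m2.cytbd"] == pytest.approx(0.0,
                                                                  abs=1e-6)

    def test_bd_takes_over_at_high_oxygen(self, oxygen_scan_result):
        res, _ = oxygen_scan_result
        feasible = [s for s in res.summaries
                    if s.get("community_growth") is not None]
        top = feasible[-1]
        bd = top["m1.cytbd"] + top["m2.cytbd"]
        cytc = top["m1.cytc"] + top["m2.cytc"]
        assert bd > cytc
        assert bd > 1.0

    def test_upper_bound_scan_is_monotone(self):
        """With O2 as an allowance (upper bound on uptake) instead of a pin,
        enlarging the allowance never lowers the optimum."""
        comm, spec = make_toy_community(ToySpec())
        last = -np.inf
        for o2 in [10.0, 14.0, 18.0, 22.0, 26.0, 30.0]:
            comm.merged.reactions["EX_o2[u]"].lower_bound = -o2
            sol = solve_xfba(comm, spec, fixed=PINS)
            assert sol.objective_value >= last - 1e-9
            last = sol.objective_value


class TestSummedMemberFluxes:
    def test_single_member_identity(self, toy_cell):
        from xfba.community import build_community

        comm = build_community([("m1", toy_cell)], {"m1": 1.0})
        sol = solve_xfba(comm, None, objective="BIOMASS[m1]", fixed=PINS)
        ref = list(toy_cell.reactions)
        vec = summed_member_fluxes(sol, comm, ref)
        for rid, got in zip(ref, vec):
            if rid.startswith("EX_"):
                expected = sol.fluxes[f"{rid}[u]"]
            else:
                expected = sol.fluxes[f"{rid}[m1]"]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_vector_length_and_single_carrier(self, toy_community):
        comm, spec = toy_community
        sol = solve_xfba(comm, spec, fixed=PINS)
        ref = list(comm.members[0][1].reactions)
        vec = summed_member_fluxes(sol, comm, ref)
        assert len(vec) == len(ref)
        # nitrogenase runs only in the fixer: summed value is its aggregate
        agg = comm.aggregate(sol.fluxes, "NASE[m2]")
        assert vec[ref.index("NASE")] == pytest.approx(agg, abs=1e-9)


class TestPCA:
    def test_identical_vectors_degenerate(self):
        res = pca_flux_comparison({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert res.degenerate
        assert res.explained_variance.size == 0

    def test_collinear_points_load_on_first_axis(self):
        res = pca_flux_comparison({"a": (0.0, 0.0), "b": (2.0, 0.0),
                                   "c": (4.0, 0.0)})
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(res.loadings[0]) == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_rank_bound_and_unit_sum(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 30))
        res = pca_flux_comparison(X)
        assert res.scores.shape[1] <= 3
        assert res.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_and_orthonormal_loadings(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 40))
        res = pca_flux_comparison(X)
        assert np.abs(res.reconstruct() - X).max() < 1e-8
        gram = res.loadings @ res.loadings.T
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_fewer_than_two_observations_rejected(self):
        with pytest.raises(ValueError):
            pca_flux_comparison({"a": [1.0, 2.0]})
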