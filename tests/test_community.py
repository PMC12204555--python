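"""Community construction, abundance scaling, coupling rows and XFBA."""

import numpy as np
import pytest

from conftest import dense_xfba_optimum
from xfba.community import (
    AbundanceVector,
    CommunityBuildError,
    CouplingSpec,
    abundance_scale,
    add_coupling_constraints,
    build_community,
    differentiation_coefficient,
    member_phb_content,
    solve_xfba,
)
from xfba.fba import solve_fba, to_cobra
from xfba.model import MetabolicModel, Reaction
from xfba.network import build_stoichiometric_matrix, compute_alpha
from xfba.toys import ToySpec, make_toy_cell, make_toy_community

PINS = {"EX_s[u]": -10.0}


class TestAbundanceVector:
    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            AbundanceVector({"m1": 1.0, "m2": 0.0})

    def test_sum_must_be_one(self):
        with pytest.raises(ValueError, match="sum"):
            AbundanceVector({"m1": 0.6, "m2": 0.3})


class TestBuildCommunity:
    def test_identity_community_preserves_optimum(self, toy_spec, toy_cell):
        single = build_community([("m1", toy_cell)], {"m1": 1.0})
        sol_c = solve_xfba(single, None, objective="BIOMASS[m1]", fixed=PINS)
        sol_s = solve_fba(toy_cell, fixed={"EX_s": -10.0})
        assert sol_c.objective_value == pytest.approx(sol_s.objective_value,
                                                      rel=1e-6)

    def test_symmetric_members_match_single_growth(self, toy_spec):
        """Two identical members at 0.5/0.5 with an equal-growth row grow
        exactly as fast as one cell on the same total substrate."""
        a = make_toy_cell(toy_spec, model_id="a")
        b = make_toy_cell(toy_spec, model_id="b")
        comm = build_community([("m1", a), ("m2", b)],
                               {"m1": 0.5, "m2": 0.5})
        cm = to_cobra(comm.scaled_model())
        r1 = cm.reactions.get_by_id("BIOMASS[m1]")
        r2 = cm.reactions.get_by_id("BIOMASS[m2]")
        cm.add_cons_vars(cm.problem.Constraint(
            r1.flux_expression - r2.flux_expression, lb=0, ub=0))
        sol = solve_fba(cm, objective="BIOMASS[m1]", fixed=PINS)
        single = solve_fba(a, fixed={"EX_s": -10.0})
        assert sol.objective_value == pytest.approx(single.objective_value,
                                                    rel=1e-6)
        # symmetric fluxes: equal member substrate shares
        assert sol.fluxes["TU_s[m1]"] == pytest.approx(sol.fluxes["TU_s[m2]"],
                                                       abs=1e-6)

    def test_member_tags_carried(self, toy_community):
        comm, _ = toy_community
        for rid, rxn in comm.merged.reactions.items():
            if rid in comm.exchange_ids:
                assert rxn.member is None
            else:
                assert rxn.member in ("m1", "m2"), rid

    def test_missing_shared_species_rejected(self, toy_spec):
        cell = make_toy_cell(toy_spec)
        with pytest.raises(CommunityBuildError, match="nope"):
            build_community([("m1", cell)], {"m1": 1.0}, shared=["nope"])


class TestAbundanceScale:
    def test_identity_for_single_member(self, toy_cell):
        S = build_stoichiometric_matrix(toy_cell)
        scaled = abundance_scale(S, {"m": 1.0}, [],
                                 {rid: "m" for rid in S.rxn_ids})
        assert (scaled.matrix != S.matrix).nnz == 0

    def test_member_columns_scaled_exactly(self, toy_community):
        comm, _ = toy_community
        S = build_stoichiometric_matrix(comm.merged)
        Sx = comm.scaled_matrix()
        dense, dense_x = S.toarray(), Sx.toarray()
        for j, rid in enumerate(S.rxn_ids):
            member = comm.merged.reactions[rid].member
            factor = comm.abundances[member] if member else 1.0
            assert np.allclose(dense_x[:, j], factor * dense[:, j])

    def test_unassigned_column_listed(self, toy_cell):
        S = build_stoichiometric_matrix(toy_cell)
        with pytest.raises(CommunityBuildError, match="CAT"):
            abundance_scale(S, {"m": 1.0}, [], {})

    def test_cross_feeding_balance(self):
        """Shared species produced by m2 at rate p and consumed by m1 at rate
        c balances iff 0.1 p = 0.9 c (two-reaction micro-model by hand)."""
        m = MetabolicModel()
        m.add_reaction(Reaction("PROD", {"x[u]": 1.0}, member="m2"))
        m.add_reaction(Reaction("CONS", {"x[u]": -1.0}, member="m1"))
        S = build_stoichiometric_matrix(m)
        Sx = abundance_scale(S, {"m1": 0.9, "m2": 0.1}, [],
                             {"PROD": "m2", "CONS": "m1"})
        row = Sx.toarray()[0]
        p, c = 9.0, 1.0
        assert row @ np.array([p, c]) == pytest.approx(0.0)  # 0.1*9 = 0.9*1


class TestDifferentiationCoefficient:
    def test_reference_values(self):
        spec = CouplingSpec(r=1 / 9, alpha=7.9303, mw_phb=86.0,
                            growth_id="g", diff_id="d", phb_flux_id="p")
        assert differentiation_coefficient(spec) == pytest.approx(0.06604,
                                                                  abs=1e-4)
        spec20 = CouplingSpec(r=1 / 4, alpha=7.9303, mw_phb=86.0,
                              growth_id="g", diff_id="d", phb_flux_id="p")
        assert differentiation_coefficient(spec20) == pytest.approx(0.14859,
                                                                    abs=1e-4)

    def test_alpha_zero_reduces_to_ratio(self):
        spec = CouplingSpec(r=0.25, alpha=0.0, growth_id="g", diff_id="d",
                            phb_flux_id="p")
        assert differentiation_coefficient(spec) == 0.25


class TestCoupling:
    def test_rows_hold_as_identities(self, toy_community):
        comm, spec = toy_community
        sol = solve_xfba(comm, spec, fixed=PINS)
        agg = comm.aggregate
        mu1 = agg(sol.fluxes, spec.growth_id)
        mu1s = agg(sol.fluxes, spec.diff_id)
        vphb = agg(sol.fluxes, spec.phb_flux_id)
        mu2 = mu1s + spec.mw_phb * vphb / 1000.0
        assert abs(vphb - spec.alpha * mu1s) < 1e-8
        assert abs(mu2 - spec.r * mu1) < 1e-8
        c = differentiation_coefficient(spec)
        assert mu1s / mu1 == pytest.approx(c, abs=1e-8)

    def test_missing_reaction_is_config_error(self, toy_community):
        comm, spec = toy_community
        bad = CouplingSpec(r=spec.r, alpha=spec.alpha, growth_id="nope",
                           diff_id=spec.diff_id, phb_flux_id=spec.phb_flux_id)
        cm = to_cobra(comm.scaled_model())
        with pytest.raises(CommunityBuildError, match="nope"):
            add_coupling_constraints(cm, comm, bad)

    def test_scaled_steady_state(self, toy_community):
        """S_x . v = 0 within 1e-6 on internal and shared rows."""
        comm, spec = toy_community
        sol = solve_xfba(comm, spec, fixed=PINS)
        Sx = comm.scaled_matrix()
        v = np.array([sol.fluxes[r] for r in Sx.rxn_ids])
        residual = Sx.matrix @ v
        # every row balances: boundary flows run through the exchange columns
        assert np.abs(residual).max() < 1e-6


class TestSolveXfba:
    def test_matches_dense_oracle(self, toy_community):
        comm, spec = toy_community
        mine = solve_xfba(comm, spec, fixed=PINS)
        oracle = dense_xfba_optimum(comm, spec, pins=PINS)
        assert mine.objective_value == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("fraction", [0.05, 0.2, 0.3])
    @pytest.mark.parametrize("alpha", [0.0, 3.0, None])
    def test_oracle_equivalence_across_parameters(self, fraction, alpha):
        comm, spec = make_toy_community(ToySpec(),
                                        nongrowing_fraction=fraction,
                                        alpha=alpha)
        mine = solve_xfba(comm, spec, fixed=PINS)
        oracle = dense_xfba_optimum(comm, spec, pins=PINS)
        assert mine.optimal and oracle is not None
        assert mine.objective_value == pytest.approx(oracle, rel=1e-6)

    def test_community_growth_is_proportional(self, toy_community):
        """With the fixed-abundance row active, mu1 + mu2 = (1+r) mu1, so
        maximizing mu1 maximizes community growth."""
        comm, spec = toy_community
        sol = solve_xfba(comm, spec, fixed=PINS)
        total = sol.members["community"]["community_growth"]
        mu1 = sol.members["m1"]["mu1"]
        assert total == pytest.approx((1 + spec.r) * mu1, rel=1e-9)

    def test_infeasible_status_returned(self, toy_community):
        comm, spec = toy_community
        sol = solve_xfba(comm, spec, fixed={**PINS, "EX_o2[u]": 0.0})
        assert sol.status == "infeasible"


class TestPhbContent:
    def test_target_reached_exactly(self, toy_community):
        """alpha from compute_alpha makes the non-growing PHB content land
        exactly on the target fraction (closed-form self-consistency)."""
        comm, spec = toy_community
        sol = solve_xfba(comm, spec, fixed=PINS)
        content = member_phb_content(sol, spec, comm)
        assert content["m2"] == pytest.approx(0.50, abs=1e-9)
        assert content["m1"] == spec.p_base

    @pytest.mark.parametrize("p_target", [0.3, 0.5, 0.6, 0.8])
    def test_content_identity_for_any_alpha(self, p_target):
        """For any top-up alpha, the realized content is
        (p_base + a)/(1 + a) with a = alpha*MW/1000; dividing the mass deficit
        by the *target* fraction makes this land exactly on the target at the
        50 % study condition."""
        comm, spec = make_toy_community(ToySpec(), p_target=p_target)
        sol = solve_xfba(comm, spec, fixed=PINS)
        a = spec.alpha * spec.mw_phb / 1000.0
        expected = (spec.p_base + a) / (1.0 + a)
        assert member_phb_content(sol, spec, comm)["m2"] == pytest.approx(
            expected, abs=1e-9)
        if p_target == 0.5:
            assert expected == pytest.approx(0.5, abs=1e-12)

    def test_alpha_zero_keeps_base_content(self):
        comm, spec = make_toy_community(ToySpec(), alpha=0.0)
        sol = solve_xfba(comm, spec, fixed=PINS)
        assert member_phb_content(sol, spec, comm)["m2"] == pytest.approx(
            spec.p_base, abs=1e-9)
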