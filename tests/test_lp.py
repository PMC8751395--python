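"""Optimization core: FBA, pFBA, FVA (plain/loopless), MOMA, deletions,
sampling."""

import numpy as np
import pytest
from scipy import optimize

from rhizoflux import (
    Metabolite,
    MetabolicModel,
    Reaction,
    fba,
    fva,
    moma,
    pfba,
    sample_fluxes,
    single_gene_deletion,
    stoichiometric_matrix,
)
from rhizoflux.synthetic import ToySpec, brute_force_essentiality, make_toy_model

TOL = 1e-6


def oracle_fba(model):
    """Independently formulated LP (direct linprog assembly)."""
    midx = {m.id: i for i, m in enumerate(model.metabolites)}
    n = len(model.reactions)
    A = np.zeros((len(model.metabolites), n))
    c = np.zeros(n)
    bounds = []
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            A[midx[mid], j] = coeff
        bounds.append((r.lower_bound, r.upper_bound))
        c[j] = -model.objective.get(r.id, 0.0)
    res = optimize.linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]),
                           bounds=bounds, method="highs")
    assert res.status == 0
    return -res.fun, A, bounds


class TestFba:
    def test_conservation_forced_chain(self, chain_model):
        sol = fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=TOL)

    def test_branched_toy_matches_independent_lp(self):
        model, _ = make_toy_model(ToySpec(seed=7, carbon_sources=2,
                                          n_decoy_branches=2))
        expected, _, _ = oracle_fba(model)
        assert fba(model).objective_value == pytest.approx(expected, abs=TOL)

    def test_infeasible_reported_as_status(self, chain_model):
        chain_model.get_reaction("BIOMASS").lower_bound = 500.0
        assert fba(chain_model).status == "infeasible"

    def test_unbounded_reported_as_status(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction(id="in", stoichiometry={"A": 1.0},
                         lower_bound=0.0, upper_bound=np.inf),
                Reaction(id="out", stoichiometry={"A": -1.0},
                         lower_bound=0.0, upper_bound=np.inf),
            ],
            objective={"out": 1.0},
        )
        assert fba(m).status == "unbounded"

    def test_cobra_agrees_on_emitted_sbml(self, tmp_path):
        """Cross-check against COBRApy as a fully independent solver path."""
        import cobra.io

        from rhizoflux import write_model

        model, optimum = make_toy_model(ToySpec(seed=19, carbon_sources=2,
                                                biomass_yield=0.7))
        path = tmp_path / "toy.xml"
        write_model(model, path)
        cm = cobra.io.read_sbml_model(str(path))
        assert cm.slim_optimize() == pytest.approx(optimum, abs=1e-5)
        assert fba(model).objective_value == pytest.approx(optimum, abs=TOL)


class TestPfba:
    def test_equals_fba_on_unique_pathway(self, chain_model):
        a, b = fba(chain_model), pfba(chain_model, 1.0)
        assert b.objective_value == pytest.approx(a.objective_value, abs=TOL)
        for rid in a.fluxes:
            assert b.fluxes[rid] == pytest.approx(a.fluxes[rid], abs=1e-5)

    def test_diamond_prefers_direct_route(self, diamond):
        sol = pfba(diamond, 1.0)
        # oracle: both vertex solutions, compare taxicab norms
        direct_cost = 10 + 10 + 10 + 10        # EX,T,DIRECT,BIOMASS
        via_cost = 10 + 10 + 10 + 10 + 10      # EX,T,VIA_C1,VIA_C2,BIOMASS
        assert direct_cost < via_cost
        assert sol.fluxes["DIRECT"] == pytest.approx(10.0, abs=1e-5)
        assert sol.fluxes["VIA_C1"] == pytest.approx(0.0, abs=1e-5)

    def test_internal_loop_carries_zero_flux(self):
        model, _ = make_toy_model(ToySpec(seed=2, with_loop=True))
        sol = pfba(model, 1.0)
        assert abs(sol.fluxes["LOOP_A"]) < 1e-5
        assert abs(sol.fluxes["LOOP_B"]) < 1e-5

    def test_taxicab_norm_not_larger_than_fba(self):
        for seed in range(5):
            model, _ = make_toy_model(ToySpec(seed=seed, n_decoy_branches=2,
                                              with_loop=True))
            va = np.abs(fba(model).flux_vector(model)).sum()
            vp = np.abs(pfba(model, 1.0).flux_vector(model)).sum()
            assert vp <= va + 1e-6


class TestFva:
    def test_unique_pathway_min_equals_max(self, chain_model):
        for r in fva(chain_model, 1.0):
            assert r.minimum == pytest.approx(r.maximum, abs=1e-6)

    def test_diamond_ranges_match_per_reaction_lp_oracle(self, diamond):
        frac = 0.95
        ranges = {r.reaction_id: r for r in fva(diamond, frac)}
        optimum, A, bounds = oracle_fba(diamond)
        c = diamond.objective_vector()
        for j, rxn in enumerate(diamond.reactions):
            for sense, key in ((1.0, "minimum"), (-1.0, "maximum")):
                obj = np.zeros(len(diamond.reactions))
                obj[j] = sense
                res = optimize.linprog(
                    obj, A_ub=(-c)[None, :], b_ub=[-frac * optimum + 1e-9],
                    A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                    method="highs")
                assert res.status == 0
                assert getattr(ranges[rxn.id], key) == pytest.approx(
                    sense * res.fun, abs=1e-5)

    def test_loopless_zeroes_internal_cycle(self):
        model, _ = make_toy_model(ToySpec(seed=4, with_loop=True))
        ranges = fva(model, 0.95, loopless=True,
                     reactions=["LOOP_A", "LOOP_B"])
        for r in ranges:
            assert r.minimum == pytest.approx(0.0, abs=1e-6)
            assert r.maximum == pytest.approx(0.0, abs=1e-6)
        plain = fva(model, 0.95, reactions=["LOOP_A"])
        assert plain[0].maximum > 100  # the loop is open without the loop law

    def test_fba_flux_within_envelope(self):
        """Structural mirror of measured-flux containment: the FBA point
        always lies inside the FVA band at the same fraction."""
        for seed in range(3):
            model, _ = make_toy_model(ToySpec(seed=seed, carbon_sources=2,
                                              n_decoy_branches=1))
            sol = fba(model)
            for r in fva(model, 1.0):
                assert r.minimum - 1e-6 <= sol.fluxes[r.reaction_id] \
                    <= r.maximum + 1e-6


class TestMoma:
    def _three_reaction_model(self):
        return MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction(id="r1", stoichiometry={"A": 1.0}, lower_bound=0,
                         upper_bound=10),
                Reaction(id="r2", stoichiometry={"A": -1.0}, lower_bound=0,
                         upper_bound=10, gpr="g2"),
                Reaction(id="r3", stoichiometry={"A": -1.0}, lower_bound=0,
                         upper_bound=10),
            ],
            genes=["g2"],
            objective={"r2": 1.0},
        )

    def test_empty_deletion_returns_wild_type_exactly(self):
        m = self._three_reaction_model()
        wt = fba(m)
        sol = moma(m, wt, set())
        assert sol.fluxes == wt.fluxes

    def test_disabling_sole_objective_feed_gives_zero_growth(self, chain_model):
        wt = fba(chain_model)
        sol = moma(chain_model, wt, {"A_to_B"})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-5)

    def test_matches_closed_form_projection(self):
        """KO of r2: feasible set is r1 = r3, r2 = 0; minimizing
        (r1-10)^2 + (r2-10)^2 + (r3-0)^2 gives r1 = r3 = 5 exactly."""
        m = self._three_reaction_model()
        wt = fba(m)
        assert (wt.fluxes["r1"], wt.fluxes["r2"]) == (10.0, 10.0)
        sol = moma(m, wt, {"r2"})
        assert sol.fluxes["r1"] == pytest.approx(5.0, abs=1e-5)
        assert sol.fluxes["r3"] == pytest.approx(5.0, abs=1e-5)
        assert sol.fluxes["r2"] == pytest.approx(0.0, abs=1e-8)

    def test_linear_variant_agrees_on_forced_knockout(self, chain_model):
        wt = fba(chain_model)
        sol = moma(chain_model, wt, {"A_to_B"}, quadratic=False)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_knockout_growth_zero(self):
        m = self._three_reaction_model()
        m.get_reaction("r1").lower_bound = 5.0  # force production
        wt = fba(m)
        sol = moma(m, wt, {"r2", "r3"})
        assert sol.status == "infeasible"
        assert sol.objective_value == 0.0


class TestSingleGeneDeletion:
    def test_gene_not_in_any_gpr_is_nonessential(self, chain_model):
        chain_model.genes.append("idle")
        res = {r.gene_id: r for r in single_gene_deletion(chain_model)}
        assert not res["idle"].essential
        assert res["idle"].growth_rate == pytest.approx(
            res["idle"].wild_type_rate)

    def test_isoenzyme_or_rule_is_nonessential(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A_e", compartment="e0"),
                         Metabolite("A_c")],
            reactions=[
                Reaction(id="EX_A", stoichiometry={"A_e": -1.0},
                         lower_bound=-10, upper_bound=0, kind="exchange"),
                Reaction(id="T", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                         lower_bound=0, upper_bound=1000, gpr="g1 or g2"),
                Reaction(id="BIOMASS", stoichiometry={"A_c": -1.0},
                         lower_bound=0, upper_bound=1000),
            ],
            genes=["g1", "g2"],
            objective={"BIOMASS": 1.0},
        )
        for r in single_gene_deletion(m):
            assert not r.essential

    def test_sole_gatekeeper_is_essential(self, chain_model):
        res = {r.gene_id: r for r in single_gene_deletion(chain_model,
                                                          threshold=0.5)}
        assert res["gT"].essential  # unique transporter gene
        assert res["g1"].essential and res["g2"].essential  # AND complex

    def test_unknown_gene_listed_in_error(self, chain_model):
        with pytest.raises(ValueError, match="ghost"):
            single_gene_deletion(chain_model, genes=["ghost"])

    @pytest.mark.parametrize("seed", range(5))
    def test_fba_mode_matches_brute_force_oracle(self, seed):
        model, _ = make_toy_model(ToySpec(seed=seed, n_decoy_branches=1,
                                          carbon_sources=1))
        oracle = brute_force_essentiality(model)
        for r in single_gene_deletion(model, method="fba"):
            assert r.essential == oracle[r.gene_id], r.gene_id

    def test_moma_mode_runs_and_flags_gatekeepers(self, chain_model):
        res = {r.gene_id: r for r in single_gene_deletion(chain_model,
                                                          method="moma")}
        assert res["gT"].essential


class TestSteadyStateInvariant:
    @pytest.mark.parametrize("seed", range(3))
    def test_all_optima_mass_balanced_and_bounded(self, seed):
        model, _ = make_toy_model(ToySpec(seed=seed, with_loop=True,
                                          n_decoy_branches=2))
        S = stoichiometric_matrix(model)
        lb, ub = model.bounds()
        for sol in (fba(model), pfba(model, 1.0),
                    moma(model, fba(model), set())):
            v = sol.flux_vector(model)
            assert np.abs(S @ v).max() < 1e-6
            assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)


class TestSampling:
    def test_singleton_polytope_returns_forced_point(self, chain_model):
        for r in chain_model.reactions:
            r.lower_bound = r.upper_bound = 10.0 if r.id != "EX_A" else -10.0
        s = sample_fluxes(chain_model, 7, seed=1)
        assert np.allclose(s.samples, s.samples[0])

    def test_uniform_interval_mean(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction(id="in", stoichiometry={"A": 1.0}, lower_bound=0,
                         upper_bound=10),
                Reaction(id="out", stoichiometry={"A": -1.0}, lower_bound=0,
                         upper_bound=10),
            ],
            objective={"out": 1.0},
        )
        s = sample_fluxes(m, 5000, seed=3, thin=5, burn_in=20)
        assert abs(s.column("out").mean() - 5.0) < 0.5

    def test_requested_sample_count(self, diamond):
        assert sample_fluxes(diamond, 500, seed=2).samples.shape[0] == 500

    def test_rows_satisfy_mass_balance_and_bounds(self, diamond):
        s = sample_fluxes(diamond, 100, seed=5)
        S = stoichiometric_matrix(diamond)
        lb, ub = diamond.bounds()
        assert np.abs(S @ s.samples.T).max() < 1e-6
        assert (s.samples >= lb - 1e-9).all() and (s.samples <= ub + 1e-9).all()

    def test_seed_reproducibility_bit_identical(self, diamond):
        a = sample_fluxes(diamond, 50, seed=11, weights={"DIRECT": 1.0})
        b = sample_fluxes(diamond, 50, seed=11, weights={"DIRECT": 1.0})
        assert np.array_equal(a.samples, b.samples)

    def test_weighting_biases_expected_flux_monotonically(self, diamond):
        heavy = sample_fluxes(diamond, 300, seed=9,
                              weights={"DIRECT": 1.0, "VIA_C1": 0.0,
                                       "VIA_C2": 0.0})
        light = sample_fluxes(diamond, 300, seed=9,
                              weights={"DIRECT": 0.0, "VIA_C1": 1.0,
                                       "VIA_C2": 1.0})
        assert np.abs(heavy.column("DIRECT")).mean() > \
            np.abs(light.column("DIRECT")).mean()
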