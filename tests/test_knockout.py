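"""Knockout reaction sets, MOMA optimality, transformation scoring, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyriflux.flux import FVAResult, InfeasibleModelError, flux_variability, optimize_biomass
from pyriflux.knockout import (
    fba_knockout,
    gene_knockout_reactions,
    moma_knockout,
    mta_score,
    rank_gene_knockouts,
)
from pyriflux.network import MetabolicModel, Metabolite, Reaction, parse_gpr
from pyriflux.simulate import (
    EffectSpec,
    ToyModelConfig,
    build_toy_pyrimidine_model,
    random_feasible_model,
)


def gpr_model(rules):
    mets = [Metabolite("A")]
    rxns = [Reaction("keep", {"A": 1}, 0, 10)]
    rxns += [Reaction(f"r{i}", {"A": -1}, 0, 10, gpr=parse_gpr(rule))
             for i, rule in enumerate(rules)]
    return MetabolicModel(mets, rxns, "keep")


class TestKnockoutReactions:
    @pytest.mark.parametrize(
        "rule,gene,disabled",
        [
            ("g1", "g1", True),
            ("g1 or g2", "g1", False),
            ("g1 and g2", "g1", True),
            ("(g1 and g2) or g3", "g1", False),
            ("(g1 or g2) and g3", "g3", True),
        ],
    )
    def test_boolean_semantics(self, rule, gene, disabled):
        m = gpr_model([rule])
        hit = gene_knockout_reactions(m, gene)
        assert ("r0" in hit) == disabled

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            gene_knockout_reactions(gpr_model(["g1"]), "nope")

    def test_gprless_reactions_never_disabled(self):
        m = gpr_model(["g1"])
        assert "keep" not in gene_knockout_reactions(m, "g1")


class TestMoma:
    def test_zero_flux_knockout_returns_reference(self, diamond_model):
        ref = {"up": 10.0, "ab": 10.0, "ac": 0.0, "bd": 10.0, "cd": 0.0, "ex": 10.0}
        pred = moma_knockout(diamond_model, ref, {"ac"})
        assert pred.distance == pytest.approx(0.0, abs=1e-9)
        assert pred.flux_vector == pytest.approx(ref)

    def test_chain_middle_knockout_zeroes_everything(self, chain_model):
        ref = {"r1": 10.0, "r2": 10.0, "r3": 10.0}
        pred = moma_knockout(chain_model, ref, {"r2"})
        assert all(abs(v) < 1e-7 for v in pred.flux_vector.values())
        assert pred.distance == pytest.approx(300.0, abs=1e-5)

    def test_diamond_reroutes_halfway(self, diamond_model):
        # knocking the loaded branch: optimum shifts half the flux to the
        # spare branch (closed form: f = 5 minimizes 2(f-10)^2 + 2f^2 + 200)
        ref = {"up": 10.0, "ab": 10.0, "ac": 0.0, "bd": 10.0, "cd": 0.0, "ex": 10.0}
        pred = moma_knockout(diamond_model, ref, {"ab"})
        assert pred.flux_vector["ac"] == pytest.approx(5.0, abs=1e-5)
        assert pred.distance == pytest.approx(300.0, abs=1e-4)

    def test_disabled_reactions_carry_zero_flux(self, diamond_model):
        ref = optimize_biomass(diamond_model).flux_vector
        pred = moma_knockout(diamond_model, ref, {"bd"})
        assert pred.flux_vector["bd"] == 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_optimality_against_polytope_sampling(self, seed):
        """MOMA distance must not exceed that of any sampled feasible point.

        Feasible samples are convex combinations of the FVA extreme points of
        the knocked model, which all satisfy mass balance and bounds.
        """
        model = random_feasible_model(n_reactions=7, seed=seed)
        sol = optimize_biomass(model)
        if not sol.optimal or not np.isfinite(sol.fmax):
            return
        ref = sol.flux_vector
        victim = model.reaction_ids[seed % len(model.reaction_ids)]
        if victim == model.objective_reaction_id:
            victim = model.reaction_ids[0]
        try:
            pred = moma_knockout(model, ref, {victim})
        except InfeasibleModelError:
            return
        knocked = model.with_bounds({victim: (0.0, 0.0)})
        # collect extreme points from per-reaction optimizations
        from scipy.optimize import linprog

        from pyriflux.network import stoichiometric_matrix

        S = stoichiometric_matrix(knocked)
        bounds = [(r.lb, r.ub) for r in knocked.reactions]
        vertices = []
        for i in range(len(knocked.reactions)):
            for sign in (1.0, -1.0):
                c = np.zeros(len(knocked.reactions))
                c[i] = sign
                res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                              method="highs")
                if res.success:
                    vertices.append(res.x)
        if not vertices:
            return
        V = np.array(vertices)
        rng = np.random.default_rng(seed)
        weights = rng.dirichlet(np.ones(len(V)), size=2000)
        samples = weights @ V
        refv = np.array([ref[r] for r in knocked.reaction_ids])
        sample_dists = np.sum((samples - refv) ** 2, axis=1)
        assert pred.distance <= sample_dists.min() + 1e-6


class TestMtaScore:
    def _fva(self, mids):
        return FVAResult({k: (v, v) for k, v in mids.items()}, 1.0, 1.0)

    def _pred(self, flux, gene="g", disabled=()):
        from pyriflux.knockout import KnockoutPrediction

        return KnockoutPrediction(gene, frozenset(disabled), flux, 0.0)

    def test_perfect_transformation_scores_one(self):
        source = self._fva({"a": 0.0, "b": 5.0})
        target = self._fva({"a": 2.0, "b": 1.0})
        score = mta_score(source, target, self._pred({"a": 2.0, "b": 1.0}), tau=0.01)
        assert score.robust_score == pytest.approx(1.0)
        assert score.n_violation == 0

    def test_no_movement_scores_only_steady_reactions(self):
        source = self._fva({"a": 0.0, "b": 5.0, "c": 3.0})
        target = self._fva({"a": 2.0, "b": 1.0, "c": 3.0})  # c is steady
        score = mta_score(source, target, self._pred({"a": 0.0, "b": 5.0, "c": 3.0}),
                          tau=0.01)
        assert score.ts_moma == pytest.approx(1.0 / 3.0)  # only c succeeds, w = 1/n

    def test_fully_adverse_movement_scores_minus_one(self):
        source = self._fva({"a": 0.0, "b": 5.0})
        target = self._fva({"a": 2.0, "b": 1.0})
        score = mta_score(source, target, self._pred({"a": -2.0, "b": 9.0}), tau=0.01)
        assert score.robust_score == pytest.approx(-1.0)
        assert score.n_success == 0

    def test_antisymmetry_of_success_and_violation(self):
        source = self._fva({"a": 0.0, "b": 5.0})
        target = self._fva({"a": 2.0, "b": 1.0})
        toward = mta_score(source, target, self._pred({"a": 2.0, "b": 1.0}), tau=0.01)
        away = mta_score(source, target, self._pred({"a": -2.0, "b": 9.0}), tau=0.01)
        assert toward.ts_moma == pytest.approx(-away.ts_moma)

    def test_robust_score_is_worst_case(self):
        source = self._fva({"a": 0.0})
        target = self._fva({"a": 2.0})
        good = self._pred({"a": 2.0})
        bad = self._pred({"a": -2.0})
        score = mta_score(source, target, good, tau=0.01, fba_prediction=bad)
        assert score.ts_moma == pytest.approx(1.0)
        assert score.ts_fba == pytest.approx(-1.0)
        assert score.robust_score == pytest.approx(-1.0)

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValueError):
            mta_score(self._fva({"a": 0.0}), self._fva({"b": 0.0}),
                      self._pred({"a": 0.0}), tau=0.01)


class TestRanking:
    @pytest.fixture
    def treated_scenario(self):
        """Toy network with salvage open; treated bounds throttle DHODH."""
        from pyriflux.expression import (
            IntegrationConfig,
            apply_expression_bounds,
            map_expression_to_reactions,
        )
        from pyriflux.simulate import simulate_expression_profiles

        model = build_toy_pyrimidine_model(ToyModelConfig(salvage_ub=5.0))
        profiles = simulate_expression_profiles(
            model, EffectSpec(effects={"DHODH": 0.2}, noise_cv=0.0, n_replicates=1)
        )
        cfg = IntegrationConfig()
        out = {}
        for p in profiles:
            rmap = map_expression_to_reactions(model, p, cfg)
            out[p.condition] = apply_expression_bounds(model, rmap, cfg)
        return out["treated"], out["control"]

    def test_ranking_matches_bruteforce_oracle(self, treated_scenario):
        treated, control = treated_scenario
        source_fva = flux_variability(treated, 1.0)
        target_fva = flux_variability(control, 1.0)
        scores, infeasible = rank_gene_knockouts(treated, source_fva, target_fva)
        assert not infeasible
        # brute force: score each gene independently and sort the same way
        ref = optimize_biomass(treated).flux_vector
        from pyriflux.knockout import default_tau

        tau = default_tau(treated)
        expected = []
        for gene in sorted(treated.genes):
            disabled = gene_knockout_reactions(treated, gene)
            moma = moma_knockout(treated, ref, disabled, gene=gene)
            fba = fba_knockout(treated, disabled, gene=gene)
            expected.append(
                mta_score(source_fva, target_fva, moma, tau, fba_prediction=fba)
            )
        expected.sort(key=lambda s: (-s.robust_score, s.gene))
        assert [s.gene for s in scores] == [s.gene for s in expected]
        for got, want in zip(scores, expected):
            assert got.robust_score == pytest.approx(want.robust_score, abs=1e-9)

    def test_empty_candidate_set(self, treated_scenario):
        treated, control = treated_scenario
        sf = flux_variability(treated, 1.0)
        tf = flux_variability(control, 1.0)
        scores, infeasible = rank_gene_knockouts(treated, sf, tf, candidate_genes=[])
        assert scores == [] and infeasible == []

    def test_deterministic_across_runs(self, treated_scenario):
        treated, control = treated_scenario
        sf = flux_variability(treated, 1.0)
        tf = flux_variability(control, 1.0)
        a, _ = rank_gene_knockouts(treated, sf, tf)
        b, _ = rank_gene_knockouts(treated, sf, tf)
        assert [(s.gene, s.robust_score) for s in a] == [
            (s.gene, s.robust_score) for s in b
        ]

    def test_gene_absent_from_gprs_moves_nothing(self, treated_scenario):
        treated, control = treated_scenario
        sf = flux_variability(treated, 1.0)
        tf = flux_variability(control, 1.0)
        ref = optimize_biomass(treated).flux_vector
        # no GPR mentions this gene: knockout disables nothing
        model2 = MetabolicModel(
            treated.metabolites, treated.reactions, treated.objective_reaction_id,
            set(treated.genes) | {"BYSTANDER"},
        )
        disabled = gene_knockout_reactions(model2, "BYSTANDER")
        assert disabled == set()
        pred = moma_knockout(model2, ref, disabled, gene="BYSTANDER")
        assert pred.flux_vector == pytest.approx(ref)
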