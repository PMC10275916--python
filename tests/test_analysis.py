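"""Media application, FBA/pFBA, GPR logic, essentiality and flux sampling."""

import cobra
import numpy as np
import pytest

from conftest import chain_model, draft_for
from gembuild.analysis import (
    InfeasibleModelError,
    evaluate_gpr,
    fba,
    pfba,
    sample_fluxes,
    single_gene_deletion,
    stoichiometric_residual,
)
from gembuild.media import MediaCondition, set_media
from oracle import total_flux_alternatives


class TestSetMedia:
    def test_complete_opens_every_exchange(self, full_draft):
        model = set_media(full_draft, MediaCondition.complete())
        for rxn in model.reactions:
            if rxn.id.startswith("EX_"):
                assert rxn.bounds == (-1000.0, 1000.0)

    def test_defined_media_sets_named_uptake_only(self, full_draft):
        media = MediaCondition("glc", {"cpd00001_e": 10.0})
        model = set_media(full_draft, media)
        for rxn in model.reactions:
            if rxn.id == "EX_cpd00001_e":
                assert rxn.bounds == (-10.0, 1000.0)
            elif rxn.id.startswith("EX_"):
                assert rxn.bounds == (0.0, 1000.0)

    def test_absent_media_metabolite_warns_and_skips(self, full_draft, caplog):
        before = {r.id: r.bounds for r in full_draft.reactions}
        with caplog.at_level("WARNING"):
            set_media(full_draft, MediaCondition("odd", {"cpd99999_e": 5.0}))
        assert "no exchange reaction" in caplog.text
        # named metabolite ignored; every other exchange closed as specified
        assert all(
            full_draft.reactions.get_by_id(r).bounds[0] == 0.0
            for r in before if r.startswith("EX_")
        )

    def test_positive_rates_enforced(self):
        with pytest.raises(ValueError):
            MediaCondition("bad", {"cpd00001_e": -1.0})


class TestFBA:
    def test_uptake_limited_chain(self):
        assert fba(chain_model(uptake=10)).objective_value == pytest.approx(10.0)

    def test_internal_bottleneck(self):
        assert fba(chain_model(internal_ub=4)).objective_value == pytest.approx(4.0)

    def test_closed_exchanges_give_zero(self):
        assert fba(chain_model(close_exchanges=True)).objective_value == (
            pytest.approx(0.0)
        )

    def test_objective_invariant_under_reaction_reordering(self, full_draft):
        reference = fba(full_draft).objective_value
        shuffled = cobra.Model("shuffled")
        shuffled.add_reactions(
            [r.copy() for r in sorted(full_draft.reactions,
                                      key=lambda r: r.id, reverse=True)]
        )
        shuffled.objective = "biomass"
        assert fba(shuffled).objective_value == pytest.approx(reference, abs=1e-9)


class TestPFBA:
    def test_unique_path_total_flux(self):
        # 10 units through each of EX, transport, conversion, biomass
        result = pfba(chain_model(uptake=10))
        assert result.objective_value == pytest.approx(10.0)
        assert result.total_flux == pytest.approx(40.0)

    def test_prefers_shorter_parallel_route(self):
        model = chain_model()
        a_c = model.metabolites.get_by_id("cpd00001_c")
        b_c = model.metabolites.get_by_id("cpd00002_c")
        x = cobra.Metabolite("cpd00010_c", compartment="c")
        y = cobra.Metabolite("cpd00011_c", compartment="c")
        r1 = cobra.Reaction("rxn00010_c", lower_bound=0, upper_bound=1000)
        r2 = cobra.Reaction("rxn00011_c", lower_bound=0, upper_bound=1000)
        r3 = cobra.Reaction("rxn00012_c", lower_bound=0, upper_bound=1000)
        model.add_reactions([r1, r2, r3])
        r1.add_metabolites({a_c: -1, x: 1})
        r2.add_metabolites({x: -1, y: 1})
        r3.add_metabolites({y: -1, b_c: 1})
        result = pfba(model)
        # all flux goes through the direct 1-step conversion, none via x/y
        assert result.fluxes["rxn00002_c"] == pytest.approx(10.0)
        assert abs(result.fluxes["rxn00010_c"]) < 1e-9

    def test_fraction_zero_closed_model_is_all_zero(self):
        result = pfba(chain_model(close_exchanges=True), fraction=0.0)
        assert result.total_flux == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.fluxes.to_numpy(), 0.0, atol=1e-9)

    def test_total_flux_not_above_any_enumerated_alternative(self):
        model = chain_model()
        z_star, totals = total_flux_alternatives(
            model, "biomass", fraction=1.0, n_directions=20, seed=11
        )
        result = pfba(model)
        assert result.objective_value == pytest.approx(z_star, abs=1e-6)
        assert all(result.total_flux <= t + 1e-6 for t in totals)


@pytest.mark.parametrize(
    "gpr, knocked, active",
    [
        ("g1 or g2", {"g1"}, True),
        ("g1 and g2", {"g1"}, False),
        ("", {"g1"}, True),
        ("(g1 and g2) or g3", {"g1"}, True),
        ("(g1 and g2) or g3", {"g2", "g3"}, False),
        ("g1", set(), True),
    ],
)
def test_evaluate_gpr(gpr, knocked, active):
    assert evaluate_gpr(gpr, knocked) is active


class TestEssentiality:
    def test_matches_seeded_ground_truth(self, simple_fixture, full_draft):
        _, gt, _ = simple_fixture
        calls = single_gene_deletion(full_draft)
        essential = {g for g, c in calls.items() if c == "essential"}
        assert essential == gt.essential_genes
        assert gt.redundant_genes <= {
            g for g, c in calls.items() if c == "nonessential"
        }

    def test_parallel_redundant_route_gene_nonessential(self, simple_fixture):
        db, gt, _ = simple_fixture
        draft = draft_for(gt, db)
        # add a genetically redundant duplicate of an essential step
        original = draft.reactions.get_by_id("rxn00002_c")
        dup = cobra.Reaction("rxn00900_c", lower_bound=0, upper_bound=1000)
        draft.add_reactions([dup])
        dup.add_metabolites({m: c for m, c in original.metabolites.items()})
        dup.gene_reaction_rule = "g_alt"
        calls = single_gene_deletion(draft)
        assert calls["g_alt"] == "nonessential"
        assert calls["g00002"] == "nonessential"  # redundancy cuts both ways

    def test_nongrowing_wild_type_rejected(self):
        with pytest.raises(InfeasibleModelError):
            single_gene_deletion(chain_model(close_exchanges=True))


class TestSampling:
    def test_samples_satisfy_steady_state_and_bounds(self, full_draft):
        samples = sample_fluxes(full_draft, 50, seed=3)
        assert len(samples) == 50
        lb = {r.id: r.lower_bound for r in full_draft.reactions}
        ub = {r.id: r.upper_bound for r in full_draft.reactions}
        for dist in samples:
            assert stoichiometric_residual(full_draft, dist.fluxes) <= 1e-6
            for rid, v in dist.fluxes.items():
                assert lb[rid] - 1e-6 <= v <= ub[rid] + 1e-6

    def test_identical_seed_is_bitwise_identical(self, full_draft):
        first = sample_fluxes(full_draft, 20, seed=1)
        second = sample_fluxes(full_draft, 20, seed=1)
        for a, b in zip(first, second):
            assert (a.fluxes.to_numpy() == b.fluxes.to_numpy()).all()

    def test_different_seeds_differ(self, full_draft):
        a = sample_fluxes(full_draft, 5, seed=1)
        b = sample_fluxes(full_draft, 5, seed=2)
        assert any((x.fluxes != y.fluxes).any() for x, y in zip(a, b))

    def test_single_point_region_returns_that_point(self):
        model = chain_model()
        for rxn in model.reactions:
            rxn.bounds = (10.0, 10.0) if not rxn.id.startswith("EX_") else (-10.0, -10.0)
        samples = sample_fluxes(model, 10, seed=5)
        for dist in samples:
            assert dist.fluxes["biomass"] == pytest.approx(10.0, abs=1e-9)

    def test_infeasible_region_raises_before_sampling(self):
        model = chain_model(close_exchanges=True)
        model.reactions.get_by_id("biomass").lower_bound = 1.0
        with pytest.raises(InfeasibleModelError):
            sample_fluxes(model, 5, seed=1)
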