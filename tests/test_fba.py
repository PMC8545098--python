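"""FBA, reaction essentiality, flux coupling and auxotrophy calls."""

import numpy as np
import pytest

from sipgrade.fba import (
    ModelError,
    ToyMetabolicModel,
    call_auxotrophy,
    coupled_to_compound,
    critical_reactions,
    essential_reactions,
    fba,
    prototrophy_count,
)
from sipgrade.synthetic import build_toy_model, generate_toy_models


def _chain_model(parallel=False):
    """EX_A(≤10 uptake) → A → B → biomass, optionally with a duplicate A→B."""
    reactions = [
        {"id": "EX_A", "stoichiometry": {"A": -1}, "lower_bound": -10, "upper_bound": 1000},
        {"id": "R_AB", "stoichiometry": {"A": -1, "B": 1}, "lower_bound": 0, "upper_bound": 1000},
        {"id": "biomass", "stoichiometry": {"B": -1}, "lower_bound": 0, "upper_bound": 1000},
    ]
    if parallel:
        reactions.insert(2, {"id": "R_AB2", "stoichiometry": {"A": -1, "B": 1},
                             "lower_bound": 0, "upper_bound": 1000})
    return ToyMetabolicModel.from_dict(
        {
            "id": "chain",
            "compounds": [{"id": "A"}, {"id": "B"}],
            "reactions": reactions,
            "biomass_reaction": "biomass",
            "exchange_reactions": ["EX_A"],
            "media": {
                "rich": {"EX_A": [-10, 1000]},
                "minimal": {"EX_A": [-10, 1000]},
                "closed": {"EX_A": [0, 1000]},
            },
            "target_compounds": ["B"],
        }
    )


class TestFba:
    def test_linear_chain_bottleneck(self):
        res = fba(_chain_model(), "minimal")
        assert res.feasible
        assert res.objective == pytest.approx(10.0)

    def test_closed_exchanges_no_growth(self):
        res = fba(_chain_model(), "closed")
        assert res.objective == pytest.approx(0.0)

    def test_parallel_duplicate_same_optimum(self):
        assert fba(_chain_model(parallel=True), "minimal").objective == pytest.approx(
            fba(_chain_model(), "minimal").objective
        )

    def test_knockout_never_exceeds_wild_type(self):
        model = _chain_model(parallel=True)
        wt = fba(model, "minimal").objective
        for rx in model.reaction_ids:
            ko = fba(model, "minimal", fixed={rx: (0.0, 0.0)})
            assert not ko.feasible or ko.objective <= wt + 1e-9


class TestEssentialReactions:
    def test_linear_chain_all_essential(self):
        assert essential_reactions(_chain_model(), "minimal") == {"EX_A", "R_AB", "biomass"}

    def test_parallel_copies_not_essential(self):
        ess = essential_reactions(_chain_model(parallel=True), "minimal")
        assert "R_AB" not in ess and "R_AB2" not in ess
        assert {"EX_A", "biomass"} <= ess

    def test_no_growth_baseline_rejected(self):
        with pytest.raises(ModelError):
            essential_reactions(_chain_model(), "closed")

    def test_matches_cobra_single_deletion_oracle(self):
        """Independent check of essentiality with the cobra toolbox."""
        cobra = pytest.importorskip("cobra")
        toy = build_toy_model("oracle", {"his": "complete", "trp": "complete", "met": "deleted"})
        model = ToyMetabolicModel.from_dict(toy)
        # rebuild in cobra under the minimal medium
        cm = cobra.Model("oracle")
        mets = {c["id"]: cobra.Metabolite(c["id"]) for c in toy["compounds"]}
        lb_min = {rx: b[0] for rx, b in toy["media"]["minimal"].items()}
        ub_min = {rx: b[1] for rx, b in toy["media"]["minimal"].items()}
        rxns = []
        for r in toy["reactions"]:
            cr = cobra.Reaction(r["id"])
            cr.lower_bound = lb_min.get(r["id"], r["lower_bound"])
            cr.upper_bound = ub_min.get(r["id"], r["upper_bound"])
            rxns.append(cr)
        cm.add_reactions(rxns)
        for r in toy["reactions"]:
            cm.reactions.get_by_id(r["id"]).add_metabolites(
                {mets[c]: v for c, v in r["stoichiometry"].items()}
            )
        cm.objective = "biomass"
        wt = cm.optimize().objective_value
        from cobra.flux_analysis import single_reaction_deletion

        deletions = single_reaction_deletion(cm)
        cobra_essential = set()
        for ids, growth in zip(deletions["ids"], deletions["growth"]):
            if np.isnan(growth) or growth < 0.01 * wt:
                cobra_essential |= ids
        assert essential_reactions(model, "minimal") == cobra_essential


class TestCoupling:
    def setup_method(self):
        self.toy = ToyMetabolicModel.from_dict(
            build_toy_model("c", {"his": "complete", "trp": "complete"})
        )

    def test_sole_pathway_coupled(self):
        assert coupled_to_compound(self.toy, "R_his_1", "his")

    def test_unrelated_branch_not_coupled(self):
        assert not coupled_to_compound(self.toy, "R_trp_1", "his")

    def test_redundant_parallel_route_not_coupled(self):
        model = _chain_model(parallel=True)
        assert not coupled_to_compound(model, "R_AB", "B", medium="minimal")
        assert coupled_to_compound(_chain_model(), "R_AB", "B", medium="minimal")

    def test_unknown_compound_rejected(self):
        with pytest.raises(ModelError):
            coupled_to_compound(self.toy, "R_his_1", "nope")


class TestCriticalReactions:
    def test_intact_pathway_critical_for_its_compound(self):
        toy = ToyMetabolicModel.from_dict(build_toy_model("t", {"his": "complete"}))
        assert critical_reactions(toy, "his") == {"R_his_1", "R_his_2"}

    def test_central_carbon_flag_excludes(self):
        d = build_toy_model("t", {"his": "complete"})
        for r in d["reactions"]:
            if r["id"].startswith("R_his"):
                r["central_carbon"] = True
        toy = ToyMetabolicModel.from_dict(d)
        assert critical_reactions(toy, "his") == set()

    def test_supplied_in_both_media_never_minimal_only(self):
        d = build_toy_model("t", {"his": "complete"})
        d["media"]["minimal"]["EX_his"] = [-10, 1000]
        toy = ToyMetabolicModel.from_dict(d)
        assert critical_reactions(toy, "his") == set()

    def test_subset_of_minimal_essentials(self):
        toy = ToyMetabolicModel.from_dict(
            build_toy_model("t", {"his": "complete", "trp": "gapfilled", "met": "deleted"})
        )
        ess_min = essential_reactions(toy, "minimal")
        for cpd in toy.target_compounds:
            assert critical_reactions(toy, cpd) <= ess_min


class TestCallAuxotrophy:
    def test_three_status_round_trip(self):
        statuses = {"his": "complete", "trp": "deleted", "met": "gapfilled"}
        toy = ToyMetabolicModel.from_dict(build_toy_model("t", statuses))
        profile = call_auxotrophy(toy)
        assert profile.auxotrophic == {"his": False, "trp": True, "met": True}
        assert profile.n_critical["trp"] == 0
        assert profile.n_gapfilled_critical["met"] > 0

    def test_monotone_in_theta(self):
        toy = ToyMetabolicModel.from_dict(build_toy_model("t", {"his": "complete"}))
        was_auxo = call_auxotrophy(toy, theta=1).auxotrophic["his"]
        for theta in (2, 3, 5):
            now = call_auxotrophy(toy, theta=theta).auxotrophic["his"]
            assert now or not was_auxo  # raising theta never flips auxo -> proto

    def test_prototrophy_count(self):
        statuses = {c: "complete" for c in ("a1", "a2", "a3")}
        statuses["a3"] = "deleted"
        toy = ToyMetabolicModel.from_dict(build_toy_model("t", statuses))
        profile = call_auxotrophy(toy)
        assert prototrophy_count(profile) == 2


class TestGeneratedToyModels:
    def test_truth_recovered_exactly(self):
        for model_dict, truth in generate_toy_models(n_models=2, n_targets=6, seed=5):
            model = ToyMetabolicModel.from_dict(model_dict)
            profile = call_auxotrophy(model)
            for cpd, status in truth.items():
                assert profile.auxotrophic[cpd] == (status != "complete"), (
                    model.id, cpd, status
                )

    def test_json_round_trip(self, tmp_path):
        import json

        model_dict, _ = generate_toy_models(n_models=1, n_targets=3, seed=1)[0]
        path = tmp_path / "m.json"
        path.write_text(json.dumps(model_dict))
        model = ToyMetabolicModel.from_json(path)
        assert fba(model, "minimal").objective > 0
        assert fba(model, "rich").objective > 0
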