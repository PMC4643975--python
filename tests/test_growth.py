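"""Constrained-growth scans, correlations, loop diagnosis."""

import numpy as np
import pytest

from gemscreen import (
    GrowthObservation,
    MetabolicModel,
    Metabolite,
    Reaction,
    constrained_growth_scan,
    diagnose_high_flux_reactions,
    generate_growth_observations,
    pearson_correlation,
    remove_reaction_and_rescan,
    solve_fba,
)
from gemscreen.growth import (
    ASPARTATE_TRANSPORT_IDS,
    resolve_aspartate_transport,
    spearman_correlation,
)


def build_o2_limited_model() -> MetabolicModel:
    """Growth needs glucose and oxygen 1:2; either can become binding."""
    mets = {m: Metabolite(id=m, compartment="c") for m in ("glc", "o2", "bio")}
    rxns = {
        "EX_glc": Reaction(id="EX_glc", stoichiometry={"glc": -1.0},
                           lower_bound=-10.0, upper_bound=0.0),
        "EX_o2": Reaction(id="EX_o2", stoichiometry={"o2": -1.0},
                          lower_bound=-10.0, upper_bound=0.0),
        "resp": Reaction(id="resp",
                         stoichiometry={"glc": -1.0, "o2": -2.0, "bio": 1.0},
                         lower_bound=0.0, upper_bound=1000.0),
        "biomass": Reaction(id="biomass", stoichiometry={"bio": -1.0},
                            lower_bound=0.0, upper_bound=1000.0),
    }
    return MetabolicModel(model_id="o2lim", metabolites=mets, reactions=rxns,
                          genes=set(), objective_reaction_id="biomass")


def build_shortcut_model() -> MetabolicModel:
    """Carbon-conserving route plus a planted shortcut that fabricates
    biomass from nothing but a cheap co-substrate — inflates the optimum."""
    mets = {m: Metabolite(id=m, compartment="c") for m in ("glc", "bio")}
    rxns = {
        "EX_glc": Reaction(id="EX_glc", stoichiometry={"glc": -1.0},
                           lower_bound=-5.0, upper_bound=0.0),
        "make": Reaction(id="make", stoichiometry={"glc": -1.0, "bio": 1.0},
                         lower_bound=0.0, upper_bound=1000.0),
        "shortcut": Reaction(id="shortcut", stoichiometry={"glc": -1.0, "bio": 3.0},
                             lower_bound=0.0, upper_bound=1000.0),
        "biomass": Reaction(id="biomass", stoichiometry={"bio": -1.0},
                            lower_bound=0.0, upper_bound=1000.0),
    }
    return MetabolicModel(model_id="shortcut", metabolites=mets, reactions=rxns,
                          genes=set(), objective_reaction_id="biomass")


class TestScan:
    def test_doubling_the_binding_constraint_doubles_optimum(self, toy):
        model, _ = toy
        obs = [
            GrowthObservation(condition=f"u{u}", uptake={"p0m0": u}, growth_rate=u)
            for u in (2.0, 4.0)
        ]
        scan = constrained_growth_scan(model, obs, which=["p0m0"])
        assert scan.predicted[1] == pytest.approx(2 * scan.predicted[0])

    def test_oxygen_ceiling_flattens_glucose_response(self):
        model = build_o2_limited_model()
        obs = [
            GrowthObservation(condition=f"g{g}", uptake={"glc": g, "o2": 8.0},
                              growth_rate=min(g, 4.0))
            for g in (2.0, 4.0, 6.0, 8.0)
        ]
        scan = constrained_growth_scan(model, obs)
        # o2 fixed at 8 -> biomass ceiling 4 regardless of extra glucose
        assert scan.predicted == pytest.approx([2.0, 4.0, 4.0, 4.0])

    def test_scan_equals_per_point_fba_oracle(self, toy):
        model, _ = toy
        obs = [
            GrowthObservation(condition=f"c{i}", uptake={"p0m0": float(i)},
                              growth_rate=float(i))
            for i in range(1, 6)
        ]
        scan = constrained_growth_scan(model, obs, which=["p0m0"])
        for o, pred in zip(obs, scan.predicted):
            manual = model.copy()
            manual.reactions["EX_p0"].lower_bound = -o.uptake["p0m0"]
            assert pred == pytest.approx(solve_fba(manual).objective_value)

    def test_unresolvable_key_is_hard_error(self, toy):
        model, _ = toy
        obs = [GrowthObservation(condition="x", uptake={"pixie": 1.0},
                                 growth_rate=0.1)]
        with pytest.raises(KeyError):
            constrained_growth_scan(model, obs)

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            GrowthObservation(condition="bad", uptake={"glc": -1.0}, growth_rate=0.1)


class TestCorrelation:
    def test_proportional_vectors(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v for v in x]) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        # r for (1..5) vs (2,1,4,3,6): cov=2, sd_x=sqrt(2), sd_y=sqrt(2.96)
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        expected = 2.0 / (np.sqrt(2.0) * np.sqrt(2.96))
        assert pearson_correlation(x, y) == pytest.approx(expected)

    def test_zero_variance_is_error_not_zero(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            pearson_correlation([1, 2], [1, 2])

    def test_spearman_monotone_nonlinear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [v**3 for v in x]
        assert spearman_correlation(x, y) == pytest.approx(1.0)
        assert pearson_correlation(x, y) < 1.0


class TestLoopDiagnosis:
    def test_forced_loop_tops_ranking(self):
        model = build_o2_limited_model()
        # plant a loop forced to carry >= 50 units
        model.metabolites["L"] = Metabolite(id="L", compartment="c")
        model.reactions["loop_f"] = Reaction(
            id="loop_f", stoichiometry={"bio": -1.0, "L": 1.0},
            lower_bound=50.0, upper_bound=1000.0,
        )
        model.reactions["loop_b"] = Reaction(
            id="loop_b", stoichiometry={"L": -1.0, "bio": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        )
        model.refresh_exchanges()
        ranked = diagnose_high_flux_reactions(model)
        assert {ranked[0][0], ranked[1][0]} == {"loop_f", "loop_b"}
        assert ranked[0][1] >= 50.0

    def test_loop_free_ranking_follows_stoichiometry(self, chain_model):
        ranked = dict(diagnose_high_flux_reactions(chain_model))
        # unique optimum: the sole internal conversion carries exactly the
        # bottleneck flux (the one-metabolite biomass drain is structurally
        # an exchange and so excluded, like EX_A)
        assert ranked == {"AtoB": pytest.approx(5.0)}

    def test_exchanges_excluded(self, chain_model):
        assert "EX_A" not in dict(diagnose_high_flux_reactions(chain_model))


class TestRemoval:
    def _obs(self):
        return [
            GrowthObservation(condition=f"g{g}", uptake={"glc": g},
                              growth_rate=g)
            for g in (1.0, 2.0, 3.0, 4.0)
        ]

    def test_removing_zero_flux_reaction_changes_nothing(self):
        model = build_o2_limited_model()
        model.metabolites["idle"] = Metabolite(id="idle", compartment="c")
        model.reactions["idle_rxn"] = Reaction(
            id="idle_rxn", stoichiometry={"glc": -1.0, "idle": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        )
        model.refresh_exchanges()
        obs = self._obs()
        cmp = remove_reaction_and_rescan(model, "idle_rxn", obs, which=["glc"])
        assert cmp.before.predicted == pytest.approx(cmp.after.predicted)

    def test_planted_shortcut_removal_lowers_optimum(self):
        model = build_shortcut_model()
        obs = self._obs()
        cmp = remove_reaction_and_rescan(model, "shortcut", obs, which=["glc"])
        assert all(
            a < b for a, b in zip(cmp.after.predicted, cmp.before.predicted)
        )
        assert cmp.after.predicted == pytest.approx([1.0, 2.0, 3.0, 4.0])

    def test_soft_and_hard_removal_agree(self):
        model = build_shortcut_model()
        soft = model.copy()
        soft.reactions["shortcut"].lower_bound = 0.0
        soft.reactions["shortcut"].upper_bound = 0.0
        hard = model.copy()
        del hard.reactions["shortcut"]
        hard.refresh_exchanges()
        assert solve_fba(soft).objective_value == pytest.approx(
            solve_fba(hard).objective_value
        )

    def test_unknown_reaction_lists_near_matches(self):
        model = build_shortcut_model()
        with pytest.raises(KeyError, match="near matches.*shortcut"):
            remove_reaction_and_rescan(model, "shortcat", self._obs(), ["glc"])

    def test_aspartate_transport_lookup_per_model(self):
        assert resolve_aspartate_transport("Yeast 4") == "r_1163"
        assert resolve_aspartate_transport("Yeast 6") == "r_1117"
        assert resolve_aspartate_transport("Yeast 7") == "r_1117"
        assert resolve_aspartate_transport("iAZ900") == "ASSPt2M"
        assert resolve_aspartate_transport("iMM904") == "ASPt2m"
        assert "iFF708" not in ASPARTATE_TRANSPORT_IDS
        with pytest.raises(KeyError, match="known models"):
            resolve_aspartate_transport("iFF708")


class TestGeneratedObservations:
    def test_noiseless_grid_gives_perfect_correlation(self, toy):
        model, _ = toy
        grid = [{"p0m0": float(u)} for u in range(1, 8)]
        obs = generate_growth_observations(model, grid, noise_sd=0.0, seed=0)
        scan = constrained_growth_scan(model, obs, which=["p0m0"])
        assert scan.correlation() == pytest.approx(1.0)

    def test_limitation_switch_produces_breakpoint(self):
        model = build_o2_limited_model()
        grid = [{"glc": float(g), "o2": 8.0} for g in range(1, 9)]
        obs = generate_growth_observations(model, grid, noise_sd=0.0, seed=0)
        rates = [o.growth_rate for o in obs]
        assert rates[:4] == pytest.approx([1.0, 2.0, 3.0, 4.0])
        assert rates[4:] == pytest.approx([4.0, 4.0, 4.0, 4.0])

    def test_moderate_noise_keeps_high_mean_correlation(self, toy):
        """20-point scans at 5% multiplicative noise: mean r over 100
        seeds stays above 0.9."""
        model, _ = toy
        grid = [{"p0m0": 0.5 * (i + 1)} for i in range(20)]
        base = constrained_growth_scan(
            model,
            generate_growth_observations(model, grid, noise_sd=0.0, seed=0),
            which=["p0m0"],
        )
        rs = []
        rng_truth = base.predicted
        rng = np.random.default_rng(123)
        for seed in rng.integers(0, 2**31 - 1, size=100):
            obs = generate_growth_observations(
                model, grid, noise_sd=0.05, seed=int(seed)
            )
            rs.append(
                pearson_correlation(rng_truth, [o.growth_rate for o in obs])
            )
        assert np.mean(rs) > 0.9
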