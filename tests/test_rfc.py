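"""Scenario simulation: first choice, RFC perturbation, uptake reporting."""

import numpy as np
import pytest

from latentchoice.cohort import study_fixture_classes
from latentchoice.design import DesignConfig, NONE_LABEL, validate_profile
from latentchoice.rfc import (
    Scenario,
    SimulationConfig,
    first_choice_shares,
    fixture_individuals,
    rfc_shares,
    scenario_sets,
    scenario_utilities,
    uptake_report,
)
from latentchoice.utilities import IndividualUtilities


def _make_ind(attributes, n=1, none=None, rng=None):
    total = sum(a.n_levels for a in attributes)
    levels = np.zeros((n, total)) if rng is None else rng.normal(size=(n, total))
    none = np.full(n, -50.0) if none is None else np.asarray(none, dtype=float)
    return IndividualUtilities(
        attributes=attributes,
        respondent_ids=np.arange(1, n + 1),
        levels=levels,
        none=none,
    )


def _set_level(ind, attr, level, value, row=0):
    offset = 0
    for a in ind.attributes:
        if a.name == attr:
            ind.levels[row, offset + a.levels.index(level)] = value
            return
        offset += a.n_levels
    raise KeyError(attr)


WALKIN = {
    "test_type": "PCR",
    "venue": "Walk-in community testing site",
    "turnaround": "48 hours",
}


class TestScenarioSets:
    def test_counts(self):
        set1, set2 = scenario_sets()
        assert len(set1) == 3 and len(set2) == 6
        assert sum(s.is_none for s in set1) == 1
        assert sum(s.is_none for s in set2) == 1

    def test_at_home_scenario_levels(self):
        _, set2 = scenario_sets()
        at_home = next(s for s in set2 if s.label == "At-home testing")
        assert at_home.levels["specimen_type"] == "Shallow nasal swab"
        assert at_home.levels["venue"] == "Home collection, return by mail"
        assert at_home.levels["turnaround"] == "Within 5 days"

    def test_dual_testing_levels(self):
        _, set2 = scenario_sets()
        dual = next(s for s in set2 if s.label == "Dual testing")
        assert dual.levels["test_type"] == "PCR and serology"
        assert dual.levels["specimen_type"] == "Finger prick"

    def test_scenarios_are_design_valid(self):
        cfg = DesignConfig()
        _, set2 = scenario_sets()
        for s in set2:
            if not s.is_none:
                ok, _ = validate_profile(dict(s.levels), cfg.prohibitions, cfg.attributes)
                assert ok, s.label


class TestFirstChoice:
    def test_argmax_winner(self, attributes):
        ind = _make_ind(attributes, none=[-10.0])
        _set_level(ind, "specimen_type", "Saliva", 5.0)
        _set_level(ind, "specimen_type", "Cheek swab", 3.0)
        a = Scenario("a", {**WALKIN, "specimen_type": "Saliva"})
        b = Scenario("b", {**WALKIN, "specimen_type": "Cheek swab"})
        out = first_choice_shares(ind, [a, b, Scenario(NONE_LABEL)])
        shares = out.set_index("scenario")["share"]
        assert shares["a"] == 1.0 and shares["b"] == 0.0 and shares[NONE_LABEL] == 0.0

    def test_tie_split(self, attributes):
        ind = _make_ind(attributes, none=[-10.0])
        a = Scenario("a", {**WALKIN, "specimen_type": "Saliva"})
        b = Scenario("b", {**WALKIN, "specimen_type": "Cheek swab"})
        out = first_choice_shares(ind, [a, b]).set_index("scenario")["share"]
        assert out["a"] == 0.5 and out["b"] == 0.5

    def test_brute_force_ten_respondents(self, attributes):
        rng = np.random.default_rng(14)
        ind = _make_ind(attributes, n=10, none=rng.normal(size=10), rng=rng)
        set1, _ = scenario_sets()
        totals = scenario_utilities(ind, set1)
        expected = np.zeros(3)
        for i in range(10):  # exhaustive tabulation
            expected[np.argmax(totals[i])] += 1
        expected /= 10
        out = first_choice_shares(ind, set1)
        got = out[out.stratum == "overall"]["share"].to_numpy()
        np.testing.assert_allclose(got, expected)

    def test_shares_normalized_per_stratum(self, attributes):
        rng = np.random.default_rng(3)
        ind = _make_ind(attributes, n=30, none=rng.normal(size=30), rng=rng)
        assignment = rng.integers(0, 3, size=30)
        _, set2 = scenario_sets()
        out = first_choice_shares(ind, set2, assignment)
        for _, grp in out.groupby("stratum"):
            assert grp["share"].sum() == pytest.approx(1.0, abs=1e-9)


class TestRFC:
    def test_zero_perturbation_equals_first_choice(self, attributes):
        rng = np.random.default_rng(4)
        ind = _make_ind(attributes, n=25, none=rng.normal(size=25), rng=rng)
        _, set2 = scenario_sets()
        cfg = SimulationConfig(n_draws=10, attribute_error_scale=0.0,
                               option_error_scale=0.0, seed=1)
        fc = first_choice_shares(ind, set2)
        sim = rfc_shares(ind, set2, cfg)
        np.testing.assert_array_equal(fc["share"].to_numpy(), sim["share"].to_numpy())

    def test_symmetric_scenarios_split_half(self, attributes):
        ind = _make_ind(attributes)
        a = Scenario("a", {**WALKIN, "specimen_type": "Saliva"})
        b = Scenario("b", {**WALKIN, "specimen_type": "Cheek swab"})
        cfg = SimulationConfig(n_draws=100_000, attribute_error_scale=0.0,
                               option_error_scale=1.0, seed=9)
        out = rfc_shares(ind, [a, b], cfg).set_index("scenario")
        se = out.loc["a", "mc_se"]
        assert abs(out.loc["a", "share"] - 0.5) <= 3 * se

    def test_gumbel_option_error_logit_limit(self, attributes):
        """With pure Gumbel option errors of scale 1, a utility gap of ln 2
        yields shares (2/3, 1/3) — the closed-form logit limit."""
        ind = _make_ind(attributes)
        _set_level(ind, "specimen_type", "Saliva", np.log(2.0))
        a = Scenario("a", {**WALKIN, "specimen_type": "Saliva"})
        b = Scenario("b", {**WALKIN, "specimen_type": "Cheek swab"})
        cfg = SimulationConfig(n_draws=100_000, attribute_error_scale=0.0,
                               option_error_scale=1.0, seed=10)
        out = rfc_shares(ind, [a, b], cfg).set_index("scenario")
        assert abs(out.loc["a", "share"] - 2 / 3) <= 3 * out.loc["a", "mc_se"]

    def test_seeded_reproducibility(self, attributes):
        rng = np.random.default_rng(6)
        ind = _make_ind(attributes, n=8, none=rng.normal(size=8), rng=rng)
        set1, _ = scenario_sets()
        cfg = SimulationConfig(n_draws=500, seed=77)
        out1 = rfc_shares(ind, set1, cfg)
        out2 = rfc_shares(ind, set1, SimulationConfig(n_draws=500, seed=77))
        assert out1.equals(out2)

    def test_adding_scenarios_never_raises_none_share(self, attributes):
        rng = np.random.default_rng(12)
        ind = _make_ind(attributes, n=40, none=rng.normal(0, 2, size=40), rng=rng)
        set1, set2 = scenario_sets()
        fc1 = first_choice_shares(ind, set1).set_index("scenario")["share"]
        fc2 = first_choice_shares(ind, set2).set_index("scenario")["share"]
        assert fc2[NONE_LABEL] <= fc1[NONE_LABEL] + 1e-12
        cfg = SimulationConfig(n_draws=4000, seed=2)
        r1 = rfc_shares(ind, set1, cfg).set_index("scenario")
        r2 = rfc_shares(ind, set2, SimulationConfig(n_draws=4000, seed=3)).set_index("scenario")
        tol = 3 * np.hypot(r1.loc[NONE_LABEL, "mc_se"], r2.loc[NONE_LABEL, "mc_se"])
        assert r2.loc[NONE_LABEL, "share"] <= r1.loc[NONE_LABEL, "share"] + tol


class TestUptake:
    def test_complement_and_delta(self, attributes):
        ind, assignment, weights = fixture_individuals(study_fixture_classes())
        set1, set2 = scenario_sets()
        s1 = first_choice_shares(ind, set1, assignment, weights)
        s2 = first_choice_shares(ind, set2, assignment, weights)
        report = uptake_report(s1, s2)
        none1 = s1[(s1.scenario == NONE_LABEL) & (s1.stratum == "overall")]["share"].iloc[0]
        overall = report[report.stratum == "overall"].iloc[0]
        assert overall["uptake_sim1_pct"] == pytest.approx(100 * (1 - none1), abs=0.05)

    def test_uptake_arithmetic(self):
        import pandas as pd

        s1 = pd.DataFrame({"scenario": ["x", NONE_LABEL], "stratum": ["overall"] * 2,
                           "share": [0.816, 0.184], "mc_se": [0, 0]})
        s2 = pd.DataFrame({"scenario": ["x", NONE_LABEL], "stratum": ["overall"] * 2,
                           "share": [0.98, 0.02], "mc_se": [0, 0]})
        report = uptake_report(s1, s2)
        row = report.iloc[0]
        assert row["uptake_sim1_pct"] == 81.6
        assert row["uptake_sim2_pct"] == 98.0
        assert row["delta_pp"] == 16.4

    def test_missing_none_is_error(self):
        import pandas as pd

        s = pd.DataFrame({"scenario": ["x"], "stratum": ["overall"],
                          "share": [1.0], "mc_se": [0.0]})
        with pytest.raises(ValueError, match="NONE"):
            uptake_report(s, s)
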