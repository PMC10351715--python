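"""Model posteriors, confidence sets, hypothesis posteriors, BMA, consolidation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesmmi.mmi import (
    BMADistribution,
    HypothesisQuery,
    bma_distribution,
    compare_groups,
    confidence_set,
    consolidate,
    hypothesis_posterior,
    model_posteriors,
    odds_band,
    posterior_odds,
)


class FakeModel:
    def __init__(self, key, tags=()):
        self.identity_key = key
        self.tags = set(tags)


class TestModelPosteriors:
    def test_equal_evidence_is_uniform(self):
        mp = model_posteriors({"a": -3.0, "b": -3.0, "c": -3.0})
        assert np.allclose(mp.posteriors, 1 / 3)

    def test_bayes_factor_ten(self):
        mp = model_posteriors({"a": math.log(10.0), "b": 0.0})
        assert mp["a"] == pytest.approx(10 / 11, abs=1e-4)
        assert mp["b"] == pytest.approx(1 / 11, abs=1e-4)

    def test_sum_to_one(self, rng):
        logz = {f"m{i}": float(z) for i, z in enumerate(rng.normal(0, 50, size=40))}
        mp = model_posteriors(logz)
        assert abs(mp.posteriors.sum() - 1.0) < 1e-10

    def test_nonuniform_priors(self):
        mp = model_posteriors({"a": 0.0, "b": 0.0}, priors={"a": 0.9, "b": 0.1})
        assert mp["a"] == pytest.approx(0.9)

    def test_nonfinite_evidence_rejected(self):
        with pytest.raises(ValueError):
            model_posteriors({"a": float("-inf"), "b": 0.0})


class TestConfidenceSet:
    def test_cumulative_mass_keeps_all_when_needed(self):
        mp = model_posteriors(
            {"a": math.log(0.6), "b": math.log(0.3), "c": math.log(0.1)}
        )
        assert confidence_set(mp, "percent95") == ["a", "b", "c"]

    def test_single_model(self):
        mp = model_posteriors({"a": 1.0})
        assert confidence_set(mp, "percent95") == ["a"]
        assert confidence_set(mp, "relative_likelihood") == ["a"]

    def test_relative_likelihood_cutoff(self):
        mp = model_posteriors(
            {"a": math.log(0.5), "b": math.log(0.2), "c": math.log(0.05)}
        )
        # ratios 1 and 2.5 pass the sqrt(10) cutoff; ratio 10 does not
        assert confidence_set(mp, "relative_likelihood") == ["a", "b"]

    def test_percent95_is_minimal_prefix(self, rng):
        logz = {f"m{i}": float(z) for i, z in enumerate(rng.normal(0, 2, size=25))}
        mp = model_posteriors(logz)
        chosen = confidence_set(mp, "percent95")
        mass = {m: mp[m] for m in mp.model_ids}
        total = sum(mass[m] for m in chosen)
        assert total >= 0.95
        assert total - mass[chosen[-1]] < 0.95  # dropping the last breaks it


class TestHypothesisPosterior:
    def _run(self, evidences, with_models, without_models, **kw):
        models = [FakeModel(k, ("in",)) for k in with_models] + [
            FakeModel(k) for k in without_models
        ]
        hyps = [
            HypothesisQuery("in", lambda m: "in" in m.tags, 0.5),
            HypothesisQuery("out", lambda m: "in" not in m.tags, 0.5),
        ]
        return hypothesis_posterior(models, evidences, hyps, **kw)

    def test_worked_two_model_example(self):
        # evidences 3 and 1 at equal hypothesis priors: posterior 0.75
        df = self._run({"m1": math.log(3.0), "m2": 0.0}, ["m1"], ["m2"])
        assert df.loc[df.hypothesis == "in", "posterior"].iloc[0] == pytest.approx(0.75)

    def test_bias_avoidance_under_equal_evidence(self, rng):
        # unequal member counts with identical evidence: posterior == prior
        for n_in, n_out in [(1, 9), (3, 7), (5, 5), (8, 2)]:
            names_in = [f"i{k}" for k in range(n_in)]
            names_out = [f"o{k}" for k in range(n_out)]
            evid = {m: -4.2 for m in names_in + names_out}
            df = self._run(evid, names_in, names_out)
            assert df["posterior"].to_numpy() == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_partition_posteriors_sum_to_one(self, rng):
        names_in = [f"i{k}" for k in range(4)]
        names_out = [f"o{k}" for k in range(11)]
        evid = {m: float(rng.normal(0, 5)) for m in names_in + names_out}
        df = self._run(evid, names_in, names_out)
        assert abs(df["posterior"].sum() - 1.0) < 1e-10

    def test_hypothesis_covering_every_model(self):
        models = [FakeModel("a"), FakeModel("b")]
        hyps = [HypothesisQuery("all", lambda m: True, 1.0)]
        df = hypothesis_posterior(models, {"a": 0.0, "b": 1.0}, hyps)
        assert df["posterior"].iloc[0] == pytest.approx(1.0)

    def test_empty_member_set_rejected(self):
        models = [FakeModel("a")]
        hyps = [
            HypothesisQuery("yes", lambda m: True, 0.5),
            HypothesisQuery("never", lambda m: False, 0.5),
        ]
        with pytest.raises(ValueError):
            hypothesis_posterior(models, {"a": 0.0}, hyps)

    def test_normalized_variant_agrees_at_equal_priors(self, rng):
        names_in = [f"i{k}" for k in range(3)]
        names_out = [f"o{k}" for k in range(6)]
        evid = {m: float(rng.normal(0, 3)) for m in names_in + names_out}
        verbatim = self._run(evid, names_in, names_out)
        normalized = self._run(
            evid, names_in, names_out, normalized_conditional_prior=True
        )
        assert np.allclose(verbatim["posterior"], normalized["posterior"])


class TestPosteriorOdds:
    @pytest.mark.parametrize(
        "p, expected", [(0.75, 3.0), (0.5, 1.0), (0.09, 0.09 / 0.91)]
    )
    def test_values(self, p, expected):
        assert posterior_odds(p) == pytest.approx(expected)

    def test_certainty_is_infinite(self):
        assert math.isinf(posterior_odds(1.0))

    @given(st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=50, derandomize=True)
    def test_monotone(self, p):
        assert posterior_odds(p + 0.001) > posterior_odds(p)

    @pytest.mark.parametrize(
        "p, band",
        [
            (0.8, "substantial"),
            (0.2, "substantial"),
            (0.7, "notable"),
            (0.3, "notable"),
            (0.5, "uninformed"),
            (0.61, "uninformed"),
        ],
    )
    def test_bands(self, p, band):
        assert odds_band(p) == band


def _posterior_and_samples(posteriors, sample_sets):
    ids = list(posteriors)
    logz = {m: math.log(posteriors[m]) if posteriors[m] > 0 else -745.0 for m in ids}
    mp = model_posteriors(logz)
    samples = {m: pd.DataFrame({"k": np.asarray(v, dtype=float)}) for m, v in sample_sets.items()}
    return mp, samples


class TestBMA:
    def test_single_model_unit_weights(self):
        mp, samples = _posterior_and_samples({"a": 1.0}, {"a": [1.0, 2.0, 3.0]})
        dist = bma_distribution(mp, samples, "k")
        assert dist.total_mass == pytest.approx(1.0)
        assert dist.mean() == pytest.approx(2.0)

    def test_equal_posteriors_average(self):
        mp, samples = _posterior_and_samples(
            {"a": 0.5, "b": 0.5}, {"a": [0.0], "b": [1.0]}
        )
        dist = bma_distribution(mp, samples, "k")
        assert dist.mean() == pytest.approx(0.5, abs=1e-6)

    def test_zero_posterior_contributes_nothing(self):
        mp, samples = _posterior_and_samples(
            {"a": 1.0, "b": 1e-300}, {"a": [0.0, 0.0], "b": [100.0]}
        )
        dist = bma_distribution(mp, samples, "k")
        assert dist.quantile(0.999) < 1.0

    def test_expectation_is_posterior_weighted_mean(self, rng):
        post = {"a": 0.2, "b": 0.3, "c": 0.5}
        sets = {m: rng.normal(i, 0.1, size=50) for i, m in enumerate(post)}
        mp, samples = _posterior_and_samples(post, sets)
        dist = bma_distribution(mp, samples, "k")
        expected = sum(mp[m] * sets[m].mean() for m in post)
        assert dist.mean() == pytest.approx(expected, rel=1e-9)

    def test_parameter_absent_everywhere_rejected(self):
        mp, samples = _posterior_and_samples({"a": 1.0}, {"a": [1.0]})
        with pytest.raises(ValueError):
            bma_distribution(mp, samples, "other")

    def test_sample_cap(self):
        mp, samples = _posterior_and_samples({"a": 1.0}, {"a": np.arange(5000.0)})
        dist = bma_distribution(mp, samples, "k", max_samples_per_model=1000)
        assert dist.values.size == 1000
        assert dist.values.max() == 999.0  # the *first* 1000 samples


def _dist(values, weights=None):
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) / v.size if weights is None else np.asarray(weights)
    return BMADistribution(parameter="k", values=v, weights=w)


class TestCompareGroups:
    def test_identical_groups_not_different(self, rng):
        vals = rng.normal(0, 1, size=500)
        res = compare_groups({"g1": _dist(vals), "g2": _dist(vals)}, seed=3)
        assert not res["different"].any()

    def test_separated_groups_different_every_iteration(self, rng):
        res = compare_groups(
            {
                "lo": _dist(rng.normal(0, 1, size=500)),
                "hi": _dist(rng.normal(10, 1, size=500)),
            },
            seed=3,
        )
        assert res["different"].all()
        assert (res["significant_iterations"] == res["iterations"]).all()

    def test_seeded_runs_reproduce(self, rng):
        groups = {
            "a": _dist(rng.normal(0, 1, size=300)),
            "b": _dist(rng.normal(0.5, 1, size=300)),
        }
        r1 = compare_groups(groups, seed=9)
        r2 = compare_groups(groups, seed=9)
        assert r1.equals(r2)

    def test_degenerate_groups_short_circuit(self):
        res = compare_groups({"a": _dist([2.0, 2.0]), "b": _dist([2.0, 2.0])}, seed=0)
        assert not res["different"].any()

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            compare_groups({"only": _dist([1.0, 2.0])})


class TestConsolidate:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.709, 0.626], 0.626),
            ([0.5, 0.9], 0.5),
            ([0.3, 0.45], 0.45),
            ([0.7], 0.7),
        ],
    )
    def test_closest_to_half_wins(self, values, expected):
        selected, _ = consolidate(values)
        assert selected == pytest.approx(expected)

    def test_tie_breaks_to_smaller(self):
        selected, _ = consolidate([0.6, 0.4])
        assert selected == 0.4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consolidate([])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    @settings(max_examples=100, derandomize=True)
    def test_selected_minimizes_distance_to_prior(self, values):
        selected, idx = consolidate(values)
        assert selected == values[idx]
        assert all(abs(selected - 0.5) <= abs(v - 0.5) + 1e-15 for v in values)


class TestConsolidatedEdgeList:
    def test_transition_and_behavior_rows(self):
        from bayesmmi.mmi import consolidated_edge_list

        df = consolidated_edge_list({"tr_A_N": [0.709, 0.626], "div_Y": [0.8, 0.9]})
        tr = df[df["feature"] == "tr_A_N"].iloc[0]
        assert tr["from_subtype"] == "A" and tr["to_subtype_or_behavior"] == "N"
        assert tr["posterior"] == 0.626
        dv = df[df["feature"] == "div_Y"].iloc[0]
        assert dv["posterior"] == 0.8
        assert dv["band"] == "substantial"
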