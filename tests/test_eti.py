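"""Composite index: tabulation, scoring, ranking and time series."""

import numpy as np
import pandas as pd
import pytest

from ecotraits.errors import ConfigError, ValidationError
from ecotraits.eti import (
    DEFAULT_KAPPA,
    ETIConfig,
    eti_rank,
    eti_score,
    eti_timeseries,
    relb_category,
    tabulate,
)
from ecotraits.foodweb import FoodWeb, Link, Species, WebSeries
from ecotraits.greenband import GreenBandModel, classify_species
from ecotraits.synth import SynthConfig, default_scenario, depletion_sweep, generate_web


@pytest.fixture
def config():
    return ETIConfig()


def counts_frame(config, cells):
    """N_ij frame from {(rating, band, class): count}."""
    index = pd.MultiIndex.from_tuples(config.combinations, names=["rating", "relb"])
    N = pd.DataFrame(0, index=index, columns=["vulnerable", "hub", "target", "byproduct", "other"])
    for (rating, band, cls), count in cells.items():
        N.loc[(rating, band), cls] = count
    return N


class TestRelbCategory:
    def test_reference_level_is_top_band(self, config):
        assert relb_category(1.0, 1.0, config) == "healthy"

    def test_zero_biomass_is_bottom_band(self, config):
        assert relb_category(0.0, 1.0, config) == "collapsed"

    def test_interior_boundary_goes_to_upper_band(self, config):
        assert relb_category(0.4, 1.0, config) == "intermediate"

    def test_above_reference_stays_in_top_band(self, config):
        assert relb_category(3.0, 1.0, config) == "healthy"

    def test_nonpositive_reference_rejected(self, config):
        with pytest.raises(ValidationError):
            relb_category(1.0, 0.0, config)


class TestConfig:
    def test_default_has_ten_rank_bands(self, config):
        assert len(config.rank_labels) == 10
        assert len(set(config.rank_labels)) == 10

    def test_yaml_roundtrip(self, config, tmp_path):
        config.to_yaml(tmp_path / "config.yaml")
        back = ETIConfig.from_yaml(tmp_path / "config.yaml")
        assert back.kappa == config.kappa
        assert back.weights == config.weights
        assert back.relb_bands == config.relb_bands
        assert back.rank_bands == config.rank_bands
        assert back.resilience == config.resilience

    def test_missing_section_names_it(self):
        with pytest.raises(ConfigError, match="kappa"):
            ETIConfig.from_dict({"relb_bands": [], "weights": {}, "rank_bands": []})

    @pytest.mark.parametrize(
        "mutation, fragment",
        [
            ({"weights": {"hub": 0.5, "other": 0.6}}, "sum to 1"),
            ({"kappa": {("Fail", "healthy"): 1.5}}, "0, 1"),
        ],
    )
    def test_invalid_values_rejected(self, config, mutation, fragment):
        kwargs = {
            "relb_bands": config.relb_bands,
            "kappa": dict(config.kappa),
            "weights": dict(config.weights),
            "rank_bands": config.rank_bands,
        }
        for key, value in mutation.items():
            if isinstance(value, dict) and key == "kappa":
                kwargs["kappa"].update(value)
            else:
                kwargs[key] = value
        with pytest.raises(ConfigError, match=fragment):
            ETIConfig(**kwargs)


class TestTabulate:
    def _web(self, specs):
        species = [
            Species(
                id=f"s{i}",
                species_class=cls,
                biomass=b,
                production=1.0,
                catch=y,
                reference_biomass=1.0,
            )
            for i, (cls, b, y) in enumerate(specs)
        ]
        return FoodWeb(species=species, links=[Link("s0", "s0", 1.0)])

    model = GreenBandModel(a=1.0, intercept=0.0, resid_sd=0.0, delta=0.01)

    def test_single_cell(self, config):
        web = self._web([("target", 1.0, 0.3)] * 4)  # within band, healthy
        statuses = classify_species(web, self.model)
        N = tabulate(statuses, web, config)
        assert N.loc[("Acceptable", "healthy"), "target"] == 4
        assert N.to_numpy().sum() == 4

    def test_marginals_equal_class_sizes(self, config):
        web = self._web(
            [("target", 1.0, 0.3), ("target", 0.3, 0.3), ("other", 0.05, 0.0), ("vulnerable", 1.0, 0.6)]
        )
        statuses = classify_species(web, self.model)
        N = tabulate(statuses, web, config)
        assert dict(N.sum(axis=0)[lambda s: s > 0]) == {
            "vulnerable": 1,
            "target": 2,
            "other": 1,
        }

    def test_hub_override_reclassifies(self, config):
        web = self._web([("target", 1.0, 0.3), ("other", 1.0, 0.3)])
        statuses = classify_species(web, self.model)
        N = tabulate(statuses, web, config, hub_ids={"s1"})
        assert N["hub"].sum() == 1
        assert N["other"].sum() == 0


class TestScore:
    def test_perfect_single_class(self, config):
        N = counts_frame(config, {("Acceptable", "healthy", "target"): 5})
        result = eti_score(N, config, R=1.0)
        assert result.score == pytest.approx(1.0)
        assert result.rank_label == "Close to pristine"

    def test_all_zero_kappa_scores_zero(self, config):
        N = counts_frame(config, {("Fail", "collapsed", "target"): 5})
        assert eti_score(N, config, R=1.0).score == 0.0

    def test_worked_two_class_example(self):
        # W = {0.6, 0.4}; class 1 all kappa=1; class 2 half kappa=0.5,
        # half kappa=1.0; R = 0.8  =>  0.8*(0.6*1 + 0.4*0.75) = 0.72
        config = ETIConfig(
            weights={"target": 0.6, "other": 0.4, "vulnerable": 0.0, "hub": 0.0, "byproduct": 0.0}
        )
        N = counts_frame(
            config,
            {
                ("Acceptable", "healthy", "target"): 3,
                ("Acceptable", "healthy", "other"): 2,
                ("Fail", "healthy", "other"): 2,
            },
        )
        result = eti_score(N, config, R=0.8)
        assert result.score == pytest.approx(0.72, abs=1e-12)

    def test_linear_in_r_and_bounded(self, config, rng):
        for _ in range(10):
            cells = {}
            for comb in config.combinations:
                for cls in ("target", "other"):
                    cells[(comb[0], comb[1], cls)] = int(rng.integers(0, 4))
            N = counts_frame(config, cells)
            if N.to_numpy().sum() == 0:
                continue
            r = float(rng.uniform(0.25, 1.0))
            full = eti_score(N, config, R=1.0).score
            damped = eti_score(N, config, R=r).score
            assert damped == pytest.approx(r * full, rel=1e-12)
            assert 0.0 <= damped <= r

    def test_moving_species_to_lower_kappa_never_raises_score(self, config):
        N = counts_frame(
            config,
            {("Acceptable", "healthy", "target"): 3, ("Acceptable", "healthy", "hub"): 2},
        )
        base = eti_score(N, config, R=1.0).score
        worse = N.copy()
        worse.loc[("Acceptable", "healthy"), "target"] -= 1
        worse.loc[("Fail", "depleted"), "target"] += 1
        assert eti_score(worse, config, R=1.0).score < base

    def test_empty_classes_dropped_with_renormalisation(self, config):
        # only 'other' occupied (weight 0.1): renormalised to weight 1
        N = counts_frame(config, {("Acceptable", "healthy", "other"): 2})
        assert eti_score(N, config, R=1.0).score == pytest.approx(1.0)

    def test_all_empty_raises(self, config):
        with pytest.raises(ValidationError):
            eti_score(counts_frame(config, {}), config, R=1.0)


class TestRank:
    def test_extremes(self, config):
        assert eti_rank(1.0, config) == "Close to pristine"
        assert eti_rank(0.0, config) == "Collapsed"

    def test_band_edges_belong_to_upper_band(self, config):
        assert eti_rank(0.9, config) == "Close to pristine"
        assert eti_rank(0.8999999, config) == "High integrity"

    def test_out_of_range_rejected(self, config):
        with pytest.raises(ValidationError):
            eti_rank(1.2, config)


class TestTimeseries:
    def test_constant_series_constant_scores(self, config):
        web = generate_web(SynthConfig(n_species=20, seed=3))
        snaps = []
        for t in (1, 2, 3):
            snap = FoodWeb(species=web.species, links=web.links, timestamp=t)
            snaps.append(snap)
        results = eti_timeseries(WebSeries(snaps), web, config)
        assert len({round(r.score, 12) for r in results}) == 1

    def test_recovery_raises_score_after_change_point(self, config):
        web = generate_web(SynthConfig(n_species=25, seed=11))
        scenario = default_scenario(web, g_schedule=(2.0, 2.0, 1.0, 0.5))
        from ecotraits.synth import apply_fishing

        snaps = []
        for t, g in enumerate(scenario.g_schedule):
            snap = apply_fishing(web, g, scenario)
            snap.timestamp = t
            snaps.append(snap)
        results = eti_timeseries(WebSeries(snaps), web, config)
        scores = [r.score for r in results]
        assert scores[2] >= scores[1]
        assert scores[3] >= scores[2]

    def test_permutation_of_species_within_class_is_irrelevant(self, config):
        # swapping the identities of two same-class species with identical
        # state must not change the score
        species = [
            Species(id=i, species_class="target", biomass=1, production=1, catch=0.3, reference_biomass=1)
            for i in ("a", "b")
        ] + [
            Species(id="c", species_class="other", biomass=4, production=4, catch=0.3, reference_biomass=4)
        ]
        links = [Link("a", "c", 1.0), Link("b", "c", 1.0)]
        web = FoodWeb(species=species, links=links, timestamp=0)
        swapped = FoodWeb(species=[species[1], species[0], species[2]], links=links, timestamp=0)
        r1 = eti_timeseries(WebSeries([web]), web, config)[0]
        r2 = eti_timeseries(WebSeries([swapped]), swapped, config)[0]
        assert r1.score == pytest.approx(r2.score, rel=1e-12)
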