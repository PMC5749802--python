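"""Synthetic-data generator: determinism, ground truth, recovery hooks."""

import numpy as np
import pandas as pd
import pytest

from planktivore import SyntheticScenario
from planktivore.growth import estimate_k, fit_weight_at_day
from planktivore.species import DEFAULT_SPECIES, Species
from planktivore.synthetic import (
    generate_assessment,
    generate_fish_samples,
    generate_temperature_fields,
    load_k_table,
)
from planktivore.temperature import ambient_temperature


class TestDeterminism:
    def test_fields_bit_identical_across_reruns(self):
        sc = SyntheticScenario(seed=5)
        a = generate_temperature_fields(sc, Species.HERRING, 2005)
        b = generate_temperature_fields(sc, Species.HERRING, 2005)
        for period in ("May", "July"):
            pd.testing.assert_frame_equal(a[period][0].data, b[period][0].data)
            pd.testing.assert_frame_equal(a[period][1].data, b[period][1].data)

    def test_different_seeds_differ(self):
        a = generate_temperature_fields(SyntheticScenario(seed=1), Species.HERRING, 2005)
        b = generate_temperature_fields(SyntheticScenario(seed=2), Species.HERRING, 2005)
        assert not a["May"][0].data["value"].equals(b["May"][0].data["value"])

    def test_samples_and_assessment_reproducible(self):
        sc = SyntheticScenario(seed=5)
        s1, w1 = generate_fish_samples(sc, Species.MACKEREL)
        s2, w2 = generate_fish_samples(sc, Species.MACKEREL)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(w1, w2)
        n1, b1 = generate_assessment(sc, Species.MACKEREL)
        n2, b2 = generate_assessment(sc, Species.MACKEREL)
        pd.testing.assert_frame_equal(n1, n2)
        pd.testing.assert_frame_equal(b1, b2)


class TestTemperatureFields:
    def test_weighted_temperature_near_level_with_no_association(self):
        sc = SyntheticScenario(
            seed=3, temp_cell_sd=0.0, fish_temperature_association=0.0
        )
        fields = generate_temperature_fields(sc, Species.HERRING, 2005)
        temps, dens = fields["May"]
        at = ambient_temperature(temps, dens)
        level = sc.temperature_levels[Species.HERRING][0]
        # zero spatial noise: any weighting stays within the vertical gradient
        assert at == pytest.approx(level, abs=0.5)

    def test_association_pulls_towards_warm_cells(self):
        base = dict(seed=11, n_cells=25, temp_cell_sd=0.5)
        cold = SyntheticScenario(fish_temperature_association=0.0, **base)
        warm = SyntheticScenario(fish_temperature_association=2.0, **base)
        ats = {}
        for name, sc in (("cold", cold), ("warm", warm)):
            temps, dens = generate_temperature_fields(sc, Species.HERRING, 2005)["May"]
            ats[name] = ambient_temperature(temps, dens)
        assert ats["warm"] > ats["cold"]

    def test_mackerel_density_is_single_depth_cpue(self):
        fields = generate_temperature_fields(
            SyntheticScenario(seed=1), Species.MACKEREL, 2005
        )
        _, dens = fields["July"]
        assert dens.kind == "cpue"
        assert dens.data["depth_mid_m"].nunique() == 1


class TestGroundTruthEncoding:
    def test_true_weight_matches_coefficient_expansion(self):
        sc = SyntheticScenario(seed=0)
        for sp in Species:
            p = DEFAULT_SPECIES[sp]
            a, b, c = sc.true_weight_coefficients(sp, 30)
            days = np.arange(p.feeding_start, p.feeding_end + 1)
            poly = a * days**2 + b * days + c
            assert np.allclose(poly, sc.true_weight(sp, 30, days), rtol=1e-12)

    def test_noiseless_samples_recover_true_quadratic(self):
        sc = SyntheticScenario(seed=2, seasonal_weight_cv=0.0)
        seasonal, _ = generate_fish_samples(sc, Species.HERRING)
        fit = fit_weight_at_day(seasonal, 30, window=(91, 258))
        assert fit.coefficients == pytest.approx(
            sc.true_weight_coefficients(Species.HERRING, 30), rel=1e-6
        )

    def test_noiseless_winter_samples_recover_k_exactly(self):
        sc = SyntheticScenario(seed=2, winter_length_sd=1e-9)
        _, winter = generate_fish_samples(sc, Species.HERRING)
        means = (
            winter.groupby(["year", "age"])["length_cm"]
            .mean()
            .rename("mean_length_cm")
            .reset_index()
        )
        ks = estimate_k(means, DEFAULT_SPECIES[Species.HERRING].lmax)
        assert ks[2005] == pytest.approx(sc.true_k(Species.HERRING, 2005), abs=1e-6)

    def test_packaged_k_table_has_all_species_years(self):
        tbl = load_k_table()
        assert set(tbl["species"]) == {s.value for s in Species}
        counts = tbl.groupby("species")["year"].count()
        assert (counts == 6).all()


class TestAssessment:
    def test_weight_at_age_consistent_with_length_means(self):
        sc = SyntheticScenario(seed=4)
        naa, _ = generate_assessment(sc, Species.HERRING)
        means = sc.winter_mean_lengths(Species.HERRING).set_index(["year", "age"])
        p = DEFAULT_SPECIES[Species.HERRING]
        for _, r in naa.iterrows():
            L = means.loc[(r["year"], r["age"]), "mean_length_cm"]
            assert r["mean_weight_g"] == pytest.approx(p.weight_from_length(L))

    def test_unperturbed_biomass_gives_unit_scale_factor(self):
        """With consistent biomass, the rescaling applies a factor of ~1."""
        from planktivore.population import build_length_distribution, scale_to_biomass

        sc = SyntheticScenario(seed=4)
        sp = Species.HERRING
        p = DEFAULT_SPECIES[sp]
        naa, biomass = generate_assessment(sc, sp)
        sd = {int(a): sc.winter_length_sd for a in naa["age"].unique()}
        dist = build_length_distribution(naa, sd, p, year=2005)
        scaled = scale_to_biomass(
            dist,
            float(biomass["biomass_tonnes"].iloc[0]),
            lambda L: sc.true_weight(sp, L, 91.0),
        )
        assert np.allclose(scaled.abundance, dist.abundance, rtol=1e-9)

    def test_perturbed_biomass_scales_all_abundances(self):
        from planktivore.population import build_length_distribution, scale_to_biomass

        sc1 = SyntheticScenario(seed=4)
        sc2 = SyntheticScenario(seed=4, biomass_perturbation=2.0)
        sp = Species.HERRING
        p = DEFAULT_SPECIES[sp]
        naa, b1 = generate_assessment(sc1, sp)
        _, b2 = generate_assessment(sc2, sp)
        sd = {int(a): sc1.winter_length_sd for a in naa["age"].unique()}
        dist = build_length_distribution(naa, sd, p, year=2005)
        w = lambda L: sc1.true_weight(sp, L, 91.0)
        s1 = scale_to_biomass(dist, float(b1["biomass_tonnes"].iloc[0]), w)
        s2 = scale_to_biomass(dist, float(b2["biomass_tonnes"].iloc[0]), w)
        assert np.allclose(s2.abundance, 2 * s1.abundance, rtol=1e-12)


class TestEndToEnd:
    def test_species_rate_ordering_on_small_scenario(self, small_results):
        """Surface feeders out-consume the gadoid per gram: the cross-species
        ordering of mean daily rates is mackerel > herring > blue whiting."""
        rates = small_results.mean_specific_rates()
        assert rates["mackerel"] > rates["herring"] > rates["blue_whiting"]

    def test_rates_within_sanity_envelope(self, small_results):
        for rate in small_results.mean_specific_rates().values():
            assert 0.0 < rate < 0.2
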