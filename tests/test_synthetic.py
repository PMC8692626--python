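"""Synthetic campaign generator: contracts, determinism, recoverability."""

import dataclasses

import numpy as np
import pytest

from calanus_diapause.biometry import validate_individuals
from calanus_diapause.hydrography import mean_temperature, temperature_at_depth
from calanus_diapause.metabolism import assess_table
from calanus_diapause.population import capable_fraction, depth_integrated_abundance
from calanus_diapause.synthetic import (
    GeneratorConfig,
    generate_catch_table,
    generate_ctd,
    generate_population,
)


def test_ctd_matches_archetype(gen_config):
    for station, arch in gen_config.stations.items():
        prof = generate_ctd(gen_config, station)
        assert mean_temperature(prof, 0.0, 125.0) == pytest.approx(
            arch.surface_mean_C, abs=0.1
        )
        assert temperature_at_depth(prof, 900.0) == pytest.approx(
            arch.deep_temp_C, abs=0.2
        )
        assert np.all(np.diff(prof.depth_m) > 0)


def test_ctd_deterministic(gen_config):
    a = generate_ctd(gen_config, "S2")
    b = generate_ctd(gen_config, "S2")
    np.testing.assert_array_equal(a.temperature_C, b.temperature_C)


def test_population_deterministic_and_valid(gen_config):
    rec1, truth1 = generate_population(gen_config, "S1", compute_truth=False)
    rec2, _ = generate_population(gen_config, "S1", compute_truth=False)
    assert rec1.equals(rec2)
    accepted, rejections = validate_individuals(rec1)
    assert rejections.empty
    # no generated record can violate the carbon partition (M = m + w > w)
    prof, excl = assess_table(
        accepted,
        truth1.latent["assigned_temp_C"].to_numpy(),
        gen_config.allometry,
        gen_config.params,
    )
    assert excl.empty
    # the biometric chain inverts the generator's latent lipid carbon
    np.testing.assert_allclose(
        prof["lipid_carbon_ug"], truth1.latent["lipid_carbon_ug"], rtol=1e-9
    )
    np.testing.assert_allclose(
        prof["diapause_days"], truth1.latent["diapause_days"], rtol=1e-9
    )


def test_saturated_fullness_gives_capable_deep_population():
    config = GeneratorConfig(
        seed=3,
        stage_mix={"CV": 1.0},
        fullness_alpha=200.0,
        fullness_beta=1.0,
        n_truth_mc=20_000,
    )
    _, truth = generate_population(config, "S3", n=400)
    assert truth.true_deep_capable_fraction > 0.99
    mid = (truth.latent["stratum_upper_m"] + truth.latent["stratum_lower_m"]) / 2
    deep = truth.latent[mid > config.params.deep_cutoff_m]
    frac, _, _ = capable_fraction(deep["capable"])
    assert frac > 0.95


def test_near_empty_sacs_give_no_capability():
    config = GeneratorConfig(seed=4, fullness_alpha=0.05, fullness_beta=50.0,
                             n_truth_mc=5_000)
    _, truth = generate_population(config, "S1", n=300)
    assert truth.true_capable_fraction == 0.0
    assert not truth.latent["capable"].any()
    # reserves this small cannot come close to the capability threshold
    assert truth.latent["diapause_days"].max() < 0.5 * config.params.duration_threshold_days
    assert truth.latent["diapause_days"].median() < 1.0


def test_catch_table_deterministic_and_zero_where_empty(gen_config):
    a = generate_catch_table(gen_config, "S3")
    b = generate_catch_table(gen_config, "S3")
    assert a.equals(b)
    # an archetype with no mass below 630 m yields zero counts there
    arch = gen_config.stations["S1"]
    bands = tuple(
        dataclasses.replace(band, weight=w)
        for band, w in zip(arch.depth_bands, (0.6, 0.28, 0.12, 0.0, 0.0))
    )
    config = dataclasses.replace(gen_config)
    config.stations = dict(gen_config.stations)
    config.stations["S1"] = dataclasses.replace(arch, depth_bands=bands)
    catch = generate_catch_table(config, "S1")
    empty = catch[catch["stratum_upper_m"] >= 630.0]
    assert (empty["count"] == 0).all()


def test_catch_estimate_recovers_configured_total(gen_config):
    """Depth-integrated estimate from Poisson counts is unbiased (50 replicates)."""
    truth_total = gen_config.stations["S3"].abundance_m2["CV"]
    estimates = [
        depth_integrated_abundance(
            generate_catch_table(gen_config, "S3", seed=seed),
            gen_config.taxon, "CV", 5.0, 1000.0,
        )
        for seed in range(50)
    ]
    assert np.mean(estimates) == pytest.approx(truth_total, rel=0.05)


def test_pipeline_recovers_capable_fraction_single_seed(gen_config):
    """At n = 2000 the assessed fraction sits close to the Monte-Carlo truth."""
    prof = generate_ctd(gen_config, "S3")
    records, truth = generate_population(gen_config, "S3", profile=prof, n=2000)
    accepted, _ = validate_individuals(records)
    mid = (accepted["stratum_upper_m"] + accepted["stratum_lower_m"]) / 2
    temps = temperature_at_depth(prof, mid.to_numpy())
    profiles, _ = assess_table(accepted, temps, gen_config.allometry, gen_config.params)
    frac, _, n = capable_fraction(profiles)
    se = np.sqrt(truth.true_capable_fraction * (1 - truth.true_capable_fraction) / n)
    assert abs(frac - truth.true_capable_fraction) < 4 * se + 1e-3


def test_config_invariants():
    with pytest.raises(ValueError):
        GeneratorConfig(stage_mix={"CV": 0.5})
    with pytest.raises(ValueError):
        GeneratorConfig(fullness_alpha=0.0)
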