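"""SSI computation: strike ratio, density, formula, floor and regression."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, strategies as st

from birdrisk.io_model import AirbaseProfile, CountSurvey, MovementEntry, SpeciesProfile, StrikeRecord, filter_strikes
from birdrisk.ssi import (
    DegenerateRegressionError,
    SSIConfig,
    SSIEntry,
    build_ssi_table,
    compute_ssi,
    fit_mass_power_regression,
    mean_density,
    strike_ratio,
)
from oracles import brute_force_ssi_table

BASE = AirbaseProfile("a", 500.0, date(2020, 1, 1), date(2020, 12, 31))


@pytest.mark.parametrize("n,mov,expected", [
    (0, 100_000, 0.0),
    (5, 100_000, 0.5),
    (1, 2_857_143, 0.0035),  # the floor ratio corresponds to ~2.86M movements
])
def test_strike_ratio_closed_form(n, mov, expected):
    assert strike_ratio(n, mov) == pytest.approx(expected, rel=1e-4)


def test_strike_ratio_zero_movements_errors():
    with pytest.raises(ValueError):
        strike_ratio(1, 0)


def test_mean_density_counts_absent_occasions_as_zero():
    surveys = [
        CountSurvey(date(2020, 1, 1), "a", "sp001", 10),
        CountSurvey(date(2020, 1, 2), "a", "sp002", 7),  # sp001 absent -> 0
        CountSurvey(date(2020, 1, 3), "a", "sp001", 20),
    ]
    # counts 10, 0, 20 over three occasions at 500 ha -> mean 10 birds -> 0.2 / 10 ha
    assert mean_density("sp001", surveys, [BASE]) == pytest.approx(0.2)


def test_mean_density_single_survey():
    surveys = [CountSurvey(date(2020, 1, 1), "a", "sp001", 50)]
    assert mean_density("sp001", surveys, [BASE]) == pytest.approx(1.0)


def test_mean_density_never_seen_is_zero():
    surveys = [CountSurvey(date(2020, 1, 1), "a", "sp002", 50)]
    assert mean_density("sp001", surveys, [BASE]) == 0.0


def test_mean_density_without_occasions_errors():
    with pytest.raises(ValueError):
        mean_density("sp001", [], [BASE])


@pytest.mark.parametrize("ratio,density,mass,expected", [
    (0.0, 0.5, 2.0, 0.0),
    (1.0, 1.0, 1.0, math.log(2.0)),
    (0.7, 0.1, 0.95, math.log(8.0) * 0.95),  # = 1.9756
])
def test_compute_ssi_hand_values(ratio, density, mass, expected):
    assert compute_ssi(ratio, density, mass) == pytest.approx(expected)


def test_compute_ssi_rejects_nonpositive_density():
    with pytest.raises(ValueError):
        compute_ssi(1.0, 0.0, 1.0)


@given(
    ratio=st.floats(0.001, 10.0),
    density=st.floats(0.01, 10.0),
    mass=st.floats(0.01, 15.0),
    bump=st.floats(0.01, 5.0),
)
def test_compute_ssi_monotonicity(ratio, density, mass, bump):
    base = compute_ssi(ratio, density, mass)
    assert compute_ssi(ratio + bump, density, mass) > base
    assert compute_ssi(ratio, density + bump, mass) < base
    assert compute_ssi(ratio, density, mass + bump) > base
    assert compute_ssi(0.0, density, mass) == 0.0  # zero iff no strikes


# --- mass power regression ------------------------------------------------

def _entry(mass, ssi, method="observed"):
    return SSIEntry("x", "x", mass, 1, 0.1, 0.1, ssi, method)


def test_regression_recovers_exact_power_law():
    masses = [0.02, 0.1, 0.5, 2.0, 8.0]
    entries = [_entry(m, 2.0 * m**0.5) for m in masses]
    reg = fit_mass_power_regression(entries)
    assert reg.coefficient == pytest.approx(2.0)
    assert reg.exponent == pytest.approx(0.5)
    assert reg.r_squared == pytest.approx(1.0)
    assert reg.n_species == 5


def test_regression_equal_masses_is_degenerate():
    entries = [_entry(1.0, s) for s in (0.5, 1.0, 2.0)]
    with pytest.raises(DegenerateRegressionError):
        fit_mass_power_regression(entries)


def test_regression_too_few_points_errors():
    with pytest.raises(DegenerateRegressionError):
        fit_mass_power_regression([_entry(1.0, 1.0), _entry(2.0, 2.0)])


def test_regression_excludes_regression_entries():
    good = [_entry(m, 3.0 * m**0.8) for m in (0.1, 1.0, 10.0)]
    bad = [_entry(5.0, 1e6, method="regression")]
    reg = fit_mass_power_regression(good + bad)
    assert reg.n_species == 3
    assert reg.exponent == pytest.approx(0.8)


def test_regression_noisy_power_law_recovery():
    """Seeded noisy power law at the field-typical sample size (97 species)."""
    rng = np.random.default_rng(42)
    masses = rng.lognormal(np.log(0.3), 1.2, 97)
    true_a, true_b, sigma = 1.5, 0.6, 0.5
    ssi = true_a * masses**true_b * np.exp(rng.normal(0, sigma, 97))
    entries = [_entry(m, s) for m, s in zip(masses, ssi)]
    reg = fit_mass_power_regression(entries)
    # OLS standard error of the slope on the log-log scale
    x = np.log(masses)
    se_b = sigma / math.sqrt(((x - x.mean()) ** 2).sum())
    assert abs(reg.exponent - true_b) < 2.5 * se_b
    assert 0.0 < reg.r_squared < 1.0


# --- full table -----------------------------------------------------------

def _one_species_inputs():
    species = [SpeciesProfile("sp001", "Test bird", 1.0)]
    movements = [MovementEntry("a", 2020, 10_000)]
    surveys = [CountSurvey(date(2020, 1, 1), "a", "sp001", 50)]  # density 1.0
    strikes = [StrikeRecord(date(2020, 6, 1), "a", "sp001", "landing")]
    return strikes, surveys, movements, species, [BASE]


def test_build_table_single_observed_species():
    entries, _ = build_ssi_table(*_one_species_inputs())
    (e,) = entries
    assert e.method == "observed"
    assert e.bs_ratio == pytest.approx(1.0)
    assert e.ssi == pytest.approx(math.log(2.0))


def test_build_table_floor_entry_uses_configured_floor():
    strikes, surveys, movements, species, airbases = _one_species_inputs()
    entries, _ = build_ssi_table([], surveys, movements, species, airbases)
    (e,) = entries
    assert e.method == "floor"
    assert e.bs_ratio == 0.0035
    assert e.ssi == pytest.approx(math.log(0.0035 / 1.0 + 1.0) * 1.0)


def test_build_table_floor_from_movements_mode():
    strikes, surveys, movements, species, airbases = _one_species_inputs()
    cfg = SSIConfig(floor_mode="from_movements")
    entries, _ = build_ssi_table([], surveys, movements, species, airbases, cfg)
    assert entries[0].bs_ratio == pytest.approx(10_000.0 / 10_000.0)


def test_build_table_struck_species_without_mass_errors():
    strikes, surveys, movements, _, airbases = _one_species_inputs()
    other = [SpeciesProfile("sp999", "Other", 1.0)]
    with pytest.raises(ValueError, match="sp001"):
        build_ssi_table(strikes, surveys, movements, other, airbases)


def test_build_table_matches_brute_force_oracle(scenario):
    kept, _ = filter_strikes(scenario.strikes)
    entries, _ = build_ssi_table(
        kept, scenario.surveys, scenario.movements, scenario.species, scenario.airbases
    )
    oracle = brute_force_ssi_table(
        kept, scenario.surveys, scenario.movements, scenario.species, scenario.airbases
    )
    by_id = {e.species_id: e for e in entries}
    assert set(by_id) == set(oracle)
    for sid, (n, ratio, density, ssi, method) in oracle.items():
        e = by_id[sid]
        assert e.method == method
        assert e.n_strikes == n
        assert e.density == pytest.approx(density, abs=1e-12)
        if ssi is not None:
            assert e.bs_ratio == pytest.approx(ratio)
            assert e.ssi == pytest.approx(ssi)
    # sorted by descending SSI
    ssis = [e.ssi for e in entries]
    assert ssis == sorted(ssis, reverse=True)


def test_doubling_survey_counts_weakly_decreases_observed_ssi(scenario):
    kept, _ = filter_strikes(scenario.strikes)
    entries, _ = build_ssi_table(
        kept, scenario.surveys, scenario.movements, scenario.species, scenario.airbases
    )
    doubled = [
        CountSurvey(s.date, s.airbase, s.species_id, 2 * s.count)
        for s in scenario.surveys
    ]
    entries2, _ = build_ssi_table(
        kept, doubled, scenario.movements, scenario.species, scenario.airbases
    )
    a = {e.species_id: e for e in entries if e.method == "observed"}
    b = {e.species_id: e for e in entries2 if e.method == "observed"}
    for sid in a:
        assert b[sid].density == pytest.approx(2.0 * a[sid].density)
        assert b[sid].ssi <= a[sid].ssi + 1e-12


def test_proneness_ranking_recovered_at_high_exposure():
    """With many movements, observed bs_ratio/density ranks by true proneness."""
    rng = np.random.default_rng(3)
    movements = [MovementEntry("a", 2020, 5_000_000)]
    proneness = {"sp001": 5.0, "sp002": 1.0, "sp003": 0.2}
    density = 1.0  # identical density for all species
    species = [SpeciesProfile(s, s, 1.0) for s in proneness]
    surveys = [CountSurvey(date(2020, 1, 1), "a", s, 50) for s in proneness]
    scale = 2e-5
    strikes = []
    for sid, p in proneness.items():
        n = rng.poisson(scale * p * density * 5_000_000)
        strikes += [StrikeRecord(date(2020, 6, 1), "a", sid, "landing")] * int(n)
    entries, _ = build_ssi_table(strikes, surveys, movements, species, [BASE])
    sens = {e.species_id: e.bs_ratio / e.density for e in entries}
    assert sens["sp001"] > sens["sp002"] > sens["sp003"]
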