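"""Synthetic multi-airbase bird-monitoring scenarios with known ground truth.

Emulates the statistical structure of the four monitoring streams so that
every pipeline stage can be exercised end to end without field data:

* each species gets a latent body mass (log-normal), a mean airfield
  density with a sinusoidal seasonal cycle, and a strike proneness (its
  relative per-encounter collision probability);
* transect surveys draw negative-binomial counts around the seasonal mean
  density times airfield area — birds flock, so counts are overdispersed
  relative to Poisson, which stresses the class binning and the BSRI tail;
* runway inspections draw counts from the runway subpopulation (a fixed
  fraction of the airfield density, more strongly overdispersed) and bin
  them into the fixed count classes;
* strikes are Poisson with per-species rate proportional to
  proneness x density x total movements; a configurable fraction is
  recorded with an unidentified species or a non-local flight phase, which
  the strike filter later removes;
* each inspection's observer status is the status implied by the true BSRI
  (computed from ground-truth SSI, thresholds calibrated at the configured
  quantiles over the generated set), flipped to an adjacent status with the
  configured noise probability.

The seed fixes the whole dataset byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .bsri import DEFAULT_CLASS_MIDDLES, assign_status, calibrate_thresholds
from .io_model import (
    COUNT_CLASSES,
    UNKNOWN_SPECIES,
    AirbaseProfile,
    CountSurvey,
    InspectionRecord,
    MovementEntry,
    SpeciesProfile,
    StrikeRecord,
    write_table,
)

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario"]

# lower bounds of the count classes; a count falls in class i when
# bounds[i] <= count < bounds[i+1]
_CLASS_LOWER = np.array([1, 3, 6, 11, 26, 51, 101, 251, 501, 1001])

_LOCAL_PHASE_PROBS = {
    "final_approach": 0.08,
    "landing": 0.42,
    "touch_and_go": 0.06,
    "takeoff": 0.42,
    "climb": 0.02,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a generated scenario.

    Defaults mirror a six-airbase monitoring programme: transect counts
    twice a week, four runway inspections a day, and yearly movements in the
    low tens of thousands per airbase.  The record length defaults to five
    years, a scaled-down span that keeps a full scenario fast to generate
    and analyse while every rate and noise level retains its field-realistic
    magnitude.
    """

    n_airbases: int = 6
    n_species: int = 25
    years: int = 5
    seed: int = 0
    start_year: int = 2018
    surveys_per_week: int = 2
    inspections_per_day: int = 4
    #: chance an observer logs a status adjacent to the one the true BSRI implies
    observer_noise: float = 0.10
    #: fraction of strike records with unidentifiable species remains
    unknown_species_rate: float = 0.09
    #: fraction of strike records from non-local flight phases ("other")
    nonlocal_phase_rate: float = 0.05
    #: expected strikes per unit proneness, per (bird/10 ha), per movement
    strike_scale: float = 3.5e-4
    #: fraction of the airfield bird density present in the runway area
    runway_fraction: float = 0.25
    #: negative-binomial dispersion for transect counts (smaller = flockier)
    survey_dispersion: float = 2.0
    #: negative-binomial dispersion for runway inspection counts
    inspection_dispersion: float = 0.6
    movements_per_year_range: tuple[int, int] = (10_000, 35_000)
    alert_quantile: float = 0.80
    critical_quantile: float = 0.95

    def __post_init__(self):
        if self.n_airbases < 1 or self.n_species < 1 or self.years < 1:
            raise ValueError("need at least one airbase, one species and one year")
        for name in ("observer_noise", "unknown_species_rate", "nonlocal_phase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class Scenario:
    """A generated dataset plus the latent parameters that produced it."""

    config: ScenarioConfig
    species: list[SpeciesProfile]
    surveys: list[CountSurvey]
    inspections: list[InspectionRecord]
    strikes: list[StrikeRecord]
    movements: list[MovementEntry]
    airbases: list[AirbaseProfile]
    ground_truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.species, out / "species.csv", "species")
        write_table(self.surveys, out / "surveys.csv", "surveys")
        write_table(self.inspections, out / "inspections.csv", "inspections")
        write_table(self.strikes, out / "strikes.csv", "strikes")
        write_table(self.movements, out / "movements.csv", "movements")
        write_table(self.airbases, out / "airbases.csv", "airbases")
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion ``k`` (gamma-Poisson)."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def _seasonal(doy: np.ndarray, amp: float, phase: float) -> np.ndarray:
    return 1.0 + amp * np.sin(2.0 * np.pi * doy / 365.25 + phase)


def generate_scenario(config: ScenarioConfig = ScenarioConfig()) -> Scenario:
    """Generate a complete scenario; see the module docstring for the model."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    species_ids = [f"sp{i + 1:03d}" for i in range(cfg.n_species)]
    masses = rng.lognormal(np.log(0.3), 1.1, cfg.n_species)
    densities = rng.lognormal(np.log(0.08), 1.4, cfg.n_species)  # birds / 10 ha
    amplitudes = rng.uniform(0.0, 0.7, cfg.n_species)
    phases = rng.uniform(0.0, 2.0 * np.pi, cfg.n_species)
    proneness = rng.lognormal(0.0, 1.0, cfg.n_species)
    species = [
        SpeciesProfile(sid, f"Synthetic species {i + 1}", float(masses[i]))
        for i, sid in enumerate(species_ids)
    ]

    start = date(cfg.start_year, 1, 1)
    end = date(cfg.start_year + cfg.years, 1, 1) - timedelta(days=1)
    base_names = [f"base{b + 1:02d}" for b in range(cfg.n_airbases)]
    areas = rng.uniform(120.0, 680.0, cfg.n_airbases)
    airbases = [
        AirbaseProfile(base_names[b], float(areas[b]), start, end)
        for b in range(cfg.n_airbases)
    ]
    yearly = rng.integers(*cfg.movements_per_year_range, cfg.n_airbases)
    movements = [
        MovementEntry(base_names[b], cfg.start_year + y, int(yearly[b]))
        for b in range(cfg.n_airbases)
        for y in range(cfg.years)
    ]
    total_movements = int(sum(m.movements for m in movements))

    # --- transect surveys -------------------------------------------------
    weekdays = [0, 3, 1, 4, 2][: max(1, cfg.surveys_per_week)]  # Mon, Thu, ...
    all_days = pd.date_range(start, end, freq="D")
    survey_days = all_days[np.isin(all_days.weekday, weekdays)]
    doy = survey_days.dayofyear.to_numpy()
    surveys: list[CountSurvey] = []
    mean_seasonal = np.empty(cfg.n_species)
    for i in range(cfg.n_species):
        mean_seasonal[i] = _seasonal(doy, amplitudes[i], phases[i]).mean()
    for b, base in enumerate(base_names):
        # mean count per survey = density x seasonal x (area / 10 ha)
        mu = (
            densities[None, :]
            * np.stack([_seasonal(doy, amplitudes[i], phases[i]) for i in range(cfg.n_species)], axis=1)
            * (areas[b] / 10.0)
        )
        counts = _nb_draw(rng, mu, cfg.survey_dispersion)
        occ_idx, sp_idx = np.nonzero(counts)
        for o, sp in zip(occ_idx, sp_idx):
            surveys.append(
                CountSurvey(
                    survey_days[o].date(), base, species_ids[sp], int(counts[o, sp])
                )
            )

    # --- strikes ----------------------------------------------------------
    lam = cfg.strike_scale * proneness * densities * total_movements
    n_events = rng.poisson(lam)
    base_share = yearly / yearly.sum()
    phase_names = list(_LOCAL_PHASE_PROBS)
    phase_probs = np.array(list(_LOCAL_PHASE_PROBS.values()))
    n_days = (end - start).days + 1
    strikes: list[StrikeRecord] = []
    for i, sid in enumerate(species_ids):
        for _ in range(int(n_events[i])):
            b = rng.choice(cfg.n_airbases, p=base_share)
            d = start + timedelta(days=int(rng.integers(0, n_days)))
            if rng.random() < cfg.nonlocal_phase_rate:
                ph = "other"
            else:
                ph = phase_names[rng.choice(len(phase_names), p=phase_probs)]
            sp = UNKNOWN_SPECIES if rng.random() < cfg.unknown_species_rate else sid
            strikes.append(StrikeRecord(d, base_names[b], sp, ph))
    strikes.sort(key=lambda s: (s.date, s.airbase, s.species_id, s.flight_phase))

    # --- ground-truth SSI -------------------------------------------------
    lam_local_known = lam * (1.0 - cfg.nonlocal_phase_rate) * (1.0 - cfg.unknown_species_rate)
    true_ratio = lam_local_known / total_movements * 10_000.0
    true_density = densities * mean_seasonal  # expectation of the pooled survey mean
    true_ssi = np.log(true_ratio / true_density + 1.0) * masses
    ssi_lookup = dict(zip(species_ids, true_ssi))

    # --- runway inspections ----------------------------------------------
    hours = np.linspace(7, 17, cfg.inspections_per_day).astype(int)
    insp_times = pd.DatetimeIndex(
        [
            pd.Timestamp(d) + pd.Timedelta(hours=int(h))
            for d in all_days
            for h in hours
        ]
    )
    insp_doy = insp_times.dayofyear.to_numpy()
    middles = np.array([DEFAULT_CLASS_MIDDLES[c] for c in COUNT_CLASSES])
    inspections: list[InspectionRecord] = []
    true_bsri_all: list[np.ndarray] = []
    obs_per_insp: list[list[dict[str, str]]] = []
    meta: list[tuple[pd.Timestamp, str]] = []
    for b, base in enumerate(base_names):
        mu = (
            cfg.runway_fraction
            * densities[None, :]
            * np.stack(
                [_seasonal(insp_doy, amplitudes[i], phases[i]) for i in range(cfg.n_species)],
                axis=1,
            )
            * (areas[b] / 10.0)
        )
        counts = _nb_draw(rng, mu, cfg.inspection_dispersion)
        cls_idx = np.digitize(counts, _CLASS_LOWER[1:])  # 0..9 for counts >= 1
        n_mid = np.where(counts > 0, middles[cls_idx], 0.0)
        tb = np.log((n_mid * true_ssi[None, :]).sum(axis=1) + 1.0)
        true_bsri_all.append(tb)
        for j in range(len(insp_times)):
            obs = {
                species_ids[i]: COUNT_CLASSES[cls_idx[j, i]]
                for i in np.nonzero(counts[j])[0]
            }
            obs_per_insp.append([obs])
            meta.append((insp_times[j], base))

    true_bsri = np.concatenate(true_bsri_all)
    thresholds = calibrate_thresholds(
        true_bsri.tolist(), cfg.alert_quantile, cfg.critical_quantile
    )
    true_status = np.array([assign_status(v, thresholds) for v in true_bsri])
    observer_status = _flip_statuses(true_status, cfg.observer_noise, rng)
    for k, (ts, base) in enumerate(meta):
        inspections.append(
            InspectionRecord(
                ts.to_pydatetime(), base, obs_per_insp[k][0], str(observer_status[k])
            )
        )

    ground_truth = {
        "config": dataclasses.asdict(cfg),
        "total_movements": total_movements,
        "thresholds": {
            "alert_value": thresholds.alert_value,
            "critical_value": thresholds.critical_value,
        },
        "species": {
            sid: {
                "body_mass_kg": float(masses[i]),
                "mean_density_per_10ha": float(densities[i]),
                "pooled_density_expectation": float(true_density[i]),
                "seasonal_amplitude": float(amplitudes[i]),
                "seasonal_phase": float(phases[i]),
                "strike_proneness": float(proneness[i]),
                "expected_strikes_total": float(lam[i]),
                "expected_strikes_local_known": float(lam_local_known[i]),
                "true_bs_ratio": float(true_ratio[i]),
                "true_ssi": float(true_ssi[i]),
            }
            for i, sid in enumerate(species_ids)
        },
    }
    return Scenario(
        config=cfg,
        species=species,
        surveys=surveys,
        inspections=inspections,
        strikes=strikes,
        movements=movements,
        airbases=airbases,
        ground_truth=ground_truth,
    )


def _flip_statuses(
    true_status: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each status to an adjacent one with probability ``noise``.

    normal <-> alert, critical <-> alert; from alert the flip goes up or
    down with equal chance.
    """
    out = true_status.copy()
    flip = rng.random(len(out)) < noise
    up = rng.random(len(out)) < 0.5
    for i in np.nonzero(flip)[0]:
        s = out[i]
        if s == "normal":
            out[i] = "alert"
        elif s == "critical":
            out[i] = "alert"
        else:
            out[i] = "critical" if up[i] else "normal"
    return out
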