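"""Species Strike Impact (SSI): per-species bird strike risk.

SSI combines the probability and severity of a strike with one individual of
a species present on the airfield:

    SSI_i = ln(BS_ratio_i / density_i + 1) * mass_i

where ``BS_ratio_i`` is the species' strikes per 10,000 aircraft movements,
``density_i`` its mean abundance in birds per 10 ha over all transect counts
(absent-species occasions count as zero), and ``mass_i`` its mean body mass
in kg.  The log(x+1) transform normalises the heavily skewed count data.

Species seen on the airfield but never struck get a floor strike ratio
(fewer than one strike over the whole movement record); species struck but
never counted have an undefined ratio/density quotient and receive an SSI
estimated from a power regression of SSI on body mass fitted to the directly
quantified species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AirbaseProfile,
    CountSurvey,
    MovementEntry,
    SpeciesProfile,
    StrikeRecord,
    UNKNOWN_SPECIES,
)

__all__ = [
    "SSIConfig",
    "SSIEntry",
    "MassRegression",
    "DegenerateRegressionError",
    "strike_ratio",
    "mean_density",
    "density_table",
    "compute_ssi",
    "fit_mass_power_regression",
    "build_ssi_table",
    "ssi_entries_to_frame",
]


@dataclass(frozen=True)
class SSIConfig:
    """Tunables for SSI estimation.

    floor_ratio
        Strike ratio assigned to species counted on the airfield but never
        struck: "fewer than one strike per total movements", expressed per
        10,000 movements.  The default 0.0035 corresponds to roughly 2.9
        million movements of exposure.
    density_eligibility
        Minimum mean density (birds/10 ha) for a never-struck species to be
        assigned the floor; rarer species are left out entirely.
    floor_mode
        ``constant`` uses ``floor_ratio`` as is; ``from_movements`` derives
        the floor as 10,000 / total movements of the supplied ledger.
    """

    floor_ratio: float = 0.0035
    density_eligibility: float = 0.001
    floor_mode: str = "constant"

    def __post_init__(self):
        if self.floor_ratio <= 0:
            raise ValueError("floor_ratio must be > 0")
        if self.density_eligibility <= 0:
            raise ValueError("density_eligibility must be > 0")
        if self.floor_mode not in ("constant", "from_movements"):
            raise ValueError(f"unknown floor_mode {self.floor_mode!r}")


@dataclass(frozen=True)
class SSIEntry:
    species_id: str
    common_name: str
    body_mass_kg: float
    n_strikes: int
    bs_ratio: float
    density: float
    ssi: float
    method: str  # observed | floor | regression


@dataclass(frozen=True)
class MassRegression:
    """Power-law fit SSI = coefficient * mass ** exponent (log-log OLS)."""

    coefficient: float
    exponent: float
    r_squared: float
    n_species: int

    def predict(self, body_mass_kg: float) -> float:
        return self.coefficient * body_mass_kg ** self.exponent


class DegenerateRegressionError(ValueError):
    """Mass regression cannot be fitted (too few species or no mass spread)."""


def strike_ratio(n_strikes: int, total_movements: int) -> float:
    """Strikes per 10,000 aircraft movements."""
    if total_movements <= 0:
        raise ValueError("total_movements must be > 0")
    if n_strikes < 0:
        raise ValueError("n_strikes must be >= 0")
    return n_strikes / total_movements * 10_000.0


def _occasion_areas(
    surveys: Sequence[CountSurvey], airbases: Sequence[AirbaseProfile]
) -> pd.Series:
    """Area (ha) per distinct survey occasion (date x airbase)."""
    area = {a.airbase: a.area_ha for a in airbases}
    occ: dict[tuple, float] = {}
    for s in surveys:
        if s.airbase not in area:
            raise ValueError(f"survey references unprofiled airbase {s.airbase!r}")
        occ[(s.date, s.airbase)] = area[s.airbase]
    if not occ:
        raise ValueError("no survey occasions")
    return pd.Series(occ)


def mean_density(
    species_id: str,
    surveys: Sequence[CountSurvey],
    airbases: Sequence[AirbaseProfile],
) -> float:
    """Mean density of one species in birds per 10 ha.

    Averaged over ALL survey occasions pooled across airbases; occasions on
    which the species was not recorded contribute zero.
    """
    areas = _occasion_areas(surveys, airbases)
    counts = pd.Series(0.0, index=areas.index)
    for s in surveys:
        if s.species_id == species_id:
            counts[(s.date, s.airbase)] += s.count
    return float((counts / areas * 10.0).mean())


def density_table(
    surveys: Sequence[CountSurvey],
    airbases: Sequence[AirbaseProfile],
    species_ids: Sequence[str],
) -> pd.Series:
    """Vectorised :func:`mean_density` for many species at once."""
    areas = _occasion_areas(surveys, airbases)
    n_occ = len(areas)
    # sum over occasions of count/area, per species; absent occasions are 0
    totals = pd.Series(0.0, index=pd.Index(species_ids, name="species_id"))
    for s in surveys:
        if s.species_id in totals.index:
            totals[s.species_id] += s.count / areas[(s.date, s.airbase)] * 10.0
    return totals / n_occ


def compute_ssi(bs_ratio: float, density: float, body_mass_kg: float) -> float:
    """ln(strike ratio / density + 1) x body mass; zero iff no strikes."""
    if density <= 0:
        raise ValueError("density must be > 0 (no SSI without count data)")
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    if bs_ratio < 0:
        raise ValueError("bs_ratio must be >= 0")
    return math.log(bs_ratio / density + 1.0) * body_mass_kg


def fit_mass_power_regression(entries: Sequence[SSIEntry]) -> MassRegression:
    """Fit SSI = a * mass^b by least squares on the log-log scale.

    Only directly quantified entries (method ``observed`` or ``floor``) with
    positive SSI enter the fit, so regression-filled species cannot feed back
    into their own predictor.
    """
    pts = [
        (e.body_mass_kg, e.ssi)
        for e in entries
        if e.method in ("observed", "floor") and e.ssi > 0
    ]
    if len(pts) < 3:
        raise DegenerateRegressionError(
            f"need >= 3 directly quantified species with SSI > 0, got {len(pts)}"
        )
    x = np.log([p[0] for p in pts])
    y = np.log([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("all body masses equal; exponent undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return MassRegression(
        coefficient=float(np.exp(intercept)),
        exponent=float(slope),
        r_squared=r2,
        n_species=len(pts),
    )


def build_ssi_table(
    strikes: Sequence[StrikeRecord],
    surveys: Sequence[CountSurvey],
    movements: Sequence[MovementEntry],
    species_profiles: Sequence[SpeciesProfile],
    airbases: Sequence[AirbaseProfile],
    config: SSIConfig = SSIConfig(),
) -> tuple[list[SSIEntry], MassRegression | None]:
    """Compute the full per-species SSI table on the pooled dataset.

    Inputs are expected to be pre-filtered to local, species-identified
    strikes.  Species fall into three methods:

    * ``observed`` — at least one strike and a positive density;
    * ``floor``    — no strikes but density at or above the eligibility
      cutoff; the strike ratio is the configured floor;
    * ``regression`` — strikes but zero density (never counted, e.g. owls);
      SSI is predicted from the mass power regression.

    Never-struck species below the eligibility density are omitted.  Returns
    entries sorted by descending SSI plus the fitted regression (``None``
    when no species needed it and fewer than 3 points were available).
    """
    total_movements = sum(m.movements for m in movements)
    if total_movements <= 0:
        raise ValueError("total movements must be > 0")

    profile = {p.species_id: p for p in species_profiles}
    strike_counts: dict[str, int] = {}
    for s in strikes:
        if s.species_id == UNKNOWN_SPECIES:
            raise ValueError("strikes must be filtered to known species first")
        strike_counts[s.species_id] = strike_counts.get(s.species_id, 0) + 1
    missing = sorted(set(strike_counts) - set(profile))
    if missing:
        raise ValueError(f"struck species missing from species profiles: {missing}")

    densities = density_table(surveys, airbases, list(profile))
    floor = (
        config.floor_ratio
        if config.floor_mode == "constant"
        else 10_000.0 / total_movements
    )

    direct: list[SSIEntry] = []
    needs_regression: list[tuple[str, int]] = []
    for sp_id, prof in profile.items():
        n = strike_counts.get(sp_id, 0)
        dens = float(densities[sp_id])
        if n > 0 and dens > 0:
            ratio = strike_ratio(n, total_movements)
            direct.append(
                SSIEntry(
                    sp_id, prof.common_name, prof.body_mass_kg, n, ratio, dens,
                    compute_ssi(ratio, dens, prof.body_mass_kg), "observed",
                )
            )
        elif n == 0 and dens >= config.density_eligibility:
            direct.append(
                SSIEntry(
                    sp_id, prof.common_name, prof.body_mass_kg, 0, floor, dens,
                    compute_ssi(floor, dens, prof.body_mass_kg), "floor",
                )
            )
        elif n > 0:
            needs_regression.append((sp_id, n))
        # else: never struck, too rare to count -> no SSI

    regression: MassRegression | None = None
    entries = list(direct)
    if needs_regression:
        regression = fit_mass_power_regression(direct)
        for sp_id, n in needs_regression:
            prof = profile[sp_id]
            entries.append(
                SSIEntry(
                    sp_id, prof.common_name, prof.body_mass_kg, n,
                    strike_ratio(n, total_movements), 0.0,
                    regression.predict(prof.body_mass_kg), "regression",
                )
            )
    else:
        try:
            regression = fit_mass_power_regression(direct)
        except DegenerateRegressionError:
            regression = None

    entries.sort(key=lambda e: (-e.ssi, e.species_id))
    return entries, regression


def ssi_entries_to_frame(entries: Sequence[SSIEntry]) -> pd.DataFrame:
    """SSI table as a DataFrame matching the ssi_table.csv layout."""
    return pd.DataFrame(
        [
            {
                "species_id": e.species_id,
                "common_name": e.common_name,
                "body_mass_kg": e.body_mass_kg,
                "n_strikes": e.n_strikes,
                "bs_ratio": e.bs_ratio,
                "density": e.density,
                "ssi": e.ssi,
                "method": e.method,
            }
            for e in entries
        ]
    )
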