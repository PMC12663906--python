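"""Independent brute-force recomputations used as test oracles.

Deliberately written as plain nested loops over record lists, separate from
the vectorised/grouped implementations in the package, so agreement between
the two routes is meaningful.
"""

import math

from birdrisk.io_model import UNKNOWN_SPECIES
from birdrisk.bsri import DEFAULT_CLASS_MIDDLES


def brute_force_ssi_table(
    strikes, surveys, movements, species_profiles, airbases,
    floor_ratio=0.0035, density_eligibility=0.001,
):
    """Per-species n_strikes, bs_ratio, density and SSI by direct loops.

    Returns {species_id: (n_strikes, bs_ratio, density, ssi, method)} for
    directly quantifiable species only (regression-filled species are
    reported with ssi=None).
    """
    total_movements = 0
    for m in movements:
        total_movements += m.movements

    area_by_base = {}
    for a in airbases:
        area_by_base[a.airbase] = a.area_ha
    occasions = sorted({(s.date, s.airbase) for s in surveys})

    out = {}
    for prof in species_profiles:
        n = 0
        for st in strikes:
            if st.species_id == prof.species_id:
                n += 1
        dens_sum = 0.0
        for (d, base) in occasions:
            count = 0
            for s in surveys:
                if s.date == d and s.airbase == base and s.species_id == prof.species_id:
                    count += s.count
            dens_sum += count / area_by_base[base] * 10.0
        density = dens_sum / len(occasions)
        ratio = n / total_movements * 10_000.0
        if n > 0 and density > 0:
            ssi = math.log(ratio / density + 1.0) * prof.body_mass_kg
            out[prof.species_id] = (n, ratio, density, ssi, "observed")
        elif n == 0 and density >= density_eligibility:
            ssi = math.log(floor_ratio / density + 1.0) * prof.body_mass_kg
            out[prof.species_id] = (0, floor_ratio, density, ssi, "floor")
        elif n > 0:
            out[prof.species_id] = (n, ratio, 0.0, None, "regression")
    return out


def brute_force_bsri(inspection, ssi_by_species, middles=None):
    """Direct summation BSRI for one inspection."""
    middles = middles or DEFAULT_CLASS_MIDDLES
    total = 0.0
    for sp, cls in inspection.observations.items():
        total += middles[cls] * ssi_by_species[sp]
    return math.log(total + 1.0)


def brute_force_filter_partition(records, phases, require_species):
    """Partition strike records by drop reason with explicit loops."""
    kept, by_phase, unknown = [], 0, 0
    for r in records:
        if r.flight_phase not in phases:
            by_phase += 1
        elif require_species and r.species_id == UNKNOWN_SPECIES:
            unknown += 1
        else:
            kept.append(r)
    return kept, by_phase, unknown
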