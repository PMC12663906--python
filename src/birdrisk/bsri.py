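"""Bird Strike Risk Index (BSRI): per-inspection aggregate risk.

Each runway inspection records birds in abundance classes; BSRI folds those
counts and the per-species SSI into a single number,

    BSRI = ln(sum_i n_i * SSI_i + 1)

with ``n_i`` the class middle of the recorded count class.  Operational
statuses are assigned against thresholds calibrated as empirical quantiles
of a reference BSRI distribution: by default the 80% quantile triggers
"alert" and the 95% quantile "critical".  Where no local calibration set
exists, the published reference values 3.1 and 3.7 can be used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_model import COUNT_CLASSES, InspectionRecord, normalize_count_class

__all__ = [
    "DEFAULT_CLASS_MIDDLES",
    "DEFAULT_THRESHOLDS",
    "ClassMiddleMap",
    "ThresholdConfig",
    "BSRIResult",
    "class_middle",
    "compute_bsri",
    "compute_bsri_batch",
    "calibrate_thresholds",
    "assign_status",
    "bsri_results_to_frame",
]

#: Default class middles: arithmetic midpoint of the class bounds.  The open
#: top class ">1000" has no upper bound; its representative value of 1500 is
#: a declared convention, overridable through :class:`ClassMiddleMap`.
DEFAULT_CLASS_MIDDLES: dict[str, float] = {
    "1-2": 1.5,
    "3-5": 4.0,
    "6-10": 8.0,
    "11-25": 18.0,
    "26-50": 38.0,
    "51-100": 75.5,
    "101-250": 175.5,
    "251-500": 375.5,
    "501-1000": 750.5,
    ">1000": 1500.0,
}


@dataclass(frozen=True)
class ClassMiddleMap:
    """Mapping from count-class label to its representative count."""

    middles: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIDDLES)
    )

    def __post_init__(self):
        missing = [c for c in COUNT_CLASSES if c not in self.middles]
        if missing:
            raise ValueError(f"class middles missing for {missing}")
        ordered = [self.middles[c] for c in COUNT_CLASSES]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("class middles must be strictly increasing")
        if ordered[0] <= 0:
            raise ValueError("class middles must be positive")

    def __getitem__(self, label: str) -> float:
        return self.middles[normalize_count_class(label)]


def class_middle(label: str, middles: ClassMiddleMap | None = None) -> float:
    """Representative count for a count-class label."""
    return (middles or ClassMiddleMap())[label]


@dataclass(frozen=True)
class ThresholdConfig:
    """Alert/critical thresholds and the quantiles they were calibrated at."""

    alert_quantile: float = 0.80
    critical_quantile: float = 0.95
    alert_value: float = 3.1
    critical_value: float = 3.7

    def __post_init__(self):
        if not (0.0 < self.alert_quantile < self.critical_quantile < 1.0):
            raise ValueError("need 0 < alert_quantile < critical_quantile < 1")
        if self.alert_value > self.critical_value:
            raise ValueError("alert_value must be <= critical_value")


#: Published reference thresholds (3.1 / 3.7), for use when no local
#: calibration set is available.
DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass
class BSRIResult:
    timestamp: object
    airbase: str
    bsri: float
    contributions: list[tuple[str, float]]  # (species_id, n_i * SSI_i), descending
    status: str | None = None
    observer_status: str = "unknown"


def compute_bsri(
    inspection: InspectionRecord,
    ssi_by_species: Mapping[str, float],
    middles: ClassMiddleMap | None = None,
) -> BSRIResult:
    """BSRI for one inspection; every observed species needs an SSI value."""
    middles = middles or ClassMiddleMap()
    missing = sorted(set(inspection.observations) - set(ssi_by_species))
    if missing:
        raise KeyError(f"species without SSI entries observed at inspection: {missing}")
    contributions = [
        (sp, middles[cls] * ssi_by_species[sp])
        for sp, cls in inspection.observations.items()
    ]
    contributions.sort(key=lambda c: (-c[1], c[0]))
    total = sum(c for _, c in contributions)
    return BSRIResult(
        timestamp=inspection.timestamp,
        airbase=inspection.airbase,
        bsri=math.log(total + 1.0),
        contributions=contributions,
        observer_status=inspection.observer_status,
    )


def compute_bsri_batch(
    inspections: Sequence[InspectionRecord],
    ssi_by_species: Mapping[str, float],
    middles: ClassMiddleMap | None = None,
    thresholds: ThresholdConfig | None = None,
) -> list[BSRIResult]:
    """BSRI for many inspections; assigns statuses when thresholds given."""
    middles = middles or ClassMiddleMap()
    results = [compute_bsri(i, ssi_by_species, middles) for i in inspections]
    if thresholds is not None:
        for r in results:
            r.status = assign_status(r.bsri, thresholds)
    return results


def empirical_quantile(values: Sequence[float], q: float) -> float:
    """Order-statistic quantile: smallest value v with #{x <= v} >= q*n.

    Inverse empirical CDF (no interpolation), so the result is always an
    element of ``values`` and reproducible across sample sizes.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    ordered = sorted(values)
    k = math.ceil(q * len(ordered))  # 1-based rank
    return float(ordered[k - 1])


def calibrate_thresholds(
    bsri_values: Sequence[float],
    alert_q: float = 0.80,
    critical_q: float = 0.95,
    min_values: int = 20,
) -> ThresholdConfig:
    """Derive alert/critical thresholds as empirical quantiles of a pooled
    reference distribution of BSRI values."""
    if len(bsri_values) < min_values:
        raise ValueError(
            f"need >= {min_values} BSRI values to calibrate, got {len(bsri_values)}"
        )
    return ThresholdConfig(
        alert_quantile=alert_q,
        critical_quantile=critical_q,
        alert_value=empirical_quantile(bsri_values, alert_q),
        critical_value=empirical_quantile(bsri_values, critical_q),
    )


def assign_status(bsri: float, thresholds: ThresholdConfig = DEFAULT_THRESHOLDS) -> str:
    """Local bird status for a BSRI value.

    Strictly-greater comparisons, so a value sitting exactly on a threshold
    keeps the lower status and at least the calibration quantile fraction of
    the reference set classifies at or below that status.
    """
    if bsri > thresholds.critical_value:
        return "critical"
    if bsri > thresholds.alert_value:
        return "alert"
    return "normal"


def bsri_results_to_frame(results: Sequence[BSRIResult]) -> pd.DataFrame:
    """Results as a DataFrame matching the bsri.csv layout."""
    return pd.DataFrame(
        [
            {
                "timestamp": r.timestamp,
                "airbase": r.airbase,
                "bsri": r.bsri,
                "status": r.status,
                "observer_status": r.observer_status,
                "top_contributing_species": (
                    r.contributions[0][0] if r.contributions else ""
                ),
            }
            for r in results
        ]
    )
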