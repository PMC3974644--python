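"""Bioactivity normalization, activity classes, efficiency indices.

Measured potencies (Ki, Kd, IC50, EC50) are mapped onto a common negative
log molar scale (pActivity).  A 6-log-unit cutoff (1 uM) separates active
from inactive; records that cannot be normalized (qualified values,
unconvertible types) or that carry only an assay comment are classified
from the comment text or fall into class "other".  Ligand efficiency
indices normalize pActivity by heavy atoms, molecular weight, polar
surface area or polar atom count.  Set-level summaries use the median and
the unscaled median absolute deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_THRESHOLD",
    "NormalizedActivity",
    "EfficiencyIndices",
    "PromiscuityCounts",
    "normalize_activity",
    "classify_activity",
    "efficiency_indices",
    "promiscuity",
    "median_mad",
    "normalize_table",
]

#: pActivity cutoff (log units) separating active from inactive.
ACTIVITY_THRESHOLD = 6.0

#: Standard types that convert to pActivity when the qualifier is "=".
_CONVERTIBLE = {"Ki", "Kd", "IC50", "EC50"}

#: Unit -> factor converting a value to mol/L.
_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

_ACTIVE_COMMENTS = {"active", "potent", "agonist", "inhibitor active"}
_INACTIVE_COMMENTS = {"inactive", "not active", "no activity", "no inhibition"}


class UnitConversionError(ValueError):
    pass


@dataclass
class NormalizedActivity:
    pactivity: float | None
    activity_class: str  # active | inactive | other
    standard_type: str


@dataclass
class EfficiencyIndices:
    """LE in kcal/mol per heavy atom; the rest are pActivity ratios/logs."""

    le: float | None
    bei: float | None
    sei: float | None
    nbei: float | None
    nsei: float | None
    nbei_log: float | None  # nBEI = pActivity + log10(HA)
    mbei_log: float | None  # mBEI = pActivity + log10(MW)

    def as_dict(self) -> dict:
        return {
            "LE": self.le,
            "BEI": self.bei,
            "SEI": self.sei,
            "NBEI": self.nbei,
            "NSEI": self.nsei,
            "nBEI": self.nbei_log,
            "mBEI": self.mbei_log,
        }


@dataclass
class PromiscuityCounts:
    targets_annotated: int
    targets_active: int
    targets_inactive: int
    targets_other: int


def _comment_class(comment) -> str | None:
    if comment is None or (isinstance(comment, float) and math.isnan(comment)):
        return None
    text = str(comment).strip().lower()
    if text in _ACTIVE_COMMENTS:
        return "active"
    if text in _INACTIVE_COMMENTS:
        return "inactive"
    return None


def to_molar(value: float, units: str) -> float:
    try:
        return float(value) * _UNIT_TO_MOLAR[str(units)]
    except KeyError:
        raise UnitConversionError(f"unknown concentration unit: {units!r}") from None


def normalize_activity(record) -> NormalizedActivity:
    """Convert one activity record to pActivity + activity class.

    ``record`` is a mapping (or pandas row) with keys standard_type,
    standard_value, standard_units, qualifier, activity_comment.  Only
    unqualified ("=") Ki/Kd/IC50/EC50 measurements yield a pActivity;
    everything else is classified from its comment or lands in "other".
    """
    stype = record.get("standard_type", "other")
    value = record.get("standard_value", None)
    units = record.get("standard_units", None)
    qualifier = record.get("qualifier", "=")
    if qualifier is None or (isinstance(qualifier, float) and math.isnan(qualifier)):
        qualifier = "="
    has_value = value is not None and not (
        isinstance(value, float) and math.isnan(value)
    )

    pact = None
    if stype in _CONVERTIBLE and has_value and qualifier == "=":
        molar = to_molar(value, units)
        if molar > 0:
            pact = -math.log10(molar)
    cls = classify_activity(pact, record.get("activity_comment", None))
    return NormalizedActivity(pactivity=pact, activity_class=cls,
                              standard_type=str(stype))


def classify_activity(pactivity: float | None, comment=None) -> str:
    """Active iff pActivity >= 6 log units (or comment says so); inactive
    iff pActivity < 6 (or comment); otherwise "other"."""
    if pactivity is not None and math.isfinite(pactivity):
        return "active" if pactivity >= ACTIVITY_THRESHOLD else "inactive"
    from_comment = _comment_class(comment)
    return from_comment if from_comment is not None else "other"


def efficiency_indices(pactivity: float, heavy_atoms: int, mw: float,
                       psa: float, npol: int) -> EfficiencyIndices:
    """Efficiency-index panel for one measurement.

    LE = 1.37 * pActivity / HA (kcal/mol per heavy atom, 1.37 = 2.303 RT
    at ~300 K); BEI = pActivity / (MW/1000); SEI = pActivity / (PSA/100);
    NBEI = pActivity / HA; NSEI = pActivity / NPOL (NPOL = N+O count);
    nBEI = pActivity + log10(HA); mBEI = pActivity + log10(MW).  Indices
    with a non-positive denominator are reported as None.
    """
    if pactivity is None or not math.isfinite(pactivity):
        raise ValueError("efficiency indices require a finite pActivity")

    def ratio(den):
        return pactivity / den if den and den > 0 else None

    return EfficiencyIndices(
        le=1.37 * pactivity / heavy_atoms if heavy_atoms > 0 else None,
        bei=ratio(mw / 1000.0),
        sei=ratio(psa / 100.0),
        nbei=ratio(float(heavy_atoms)),
        nsei=ratio(float(npol)),
        nbei_log=pactivity + math.log10(heavy_atoms) if heavy_atoms > 0 else None,
        mbei_log=pactivity + math.log10(mw) if mw > 0 else None,
    )


def promiscuity(compound_records: pd.DataFrame) -> PromiscuityCounts:
    """Distinct-target counts per activity class for one compound.

    Expects deduplicated records (one row per target) with columns
    target_id and activity_class.
    """
    if len(compound_records) == 0:
        return PromiscuityCounts(0, 0, 0, 0)
    per_target = compound_records.drop_duplicates("target_id")
    counts = per_target["activity_class"].value_counts()
    active = int(counts.get("active", 0))
    inactive = int(counts.get("inactive", 0))
    other = int(counts.get("other", 0))
    return PromiscuityCounts(active + inactive + other, active, inactive, other)


def median_mad(values) -> tuple[float, float]:
    """Median and unscaled median absolute deviation (no 1.4826 factor)."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("median_mad requires at least one finite value")
    med = float(np.median(arr))
    return med, float(np.median(np.abs(arr - med)))


def normalize_table(activities: pd.DataFrame) -> pd.DataFrame:
    """Vectorized convenience: add pActivity and activity_class columns."""
    out = activities.copy()
    normalized = [normalize_activity(row) for row in
                  activities.to_dict("records")]
    out["pactivity"] = [n.pactivity for n in normalized]
    out["activity_class"] = [n.activity_class for n in normalized]
    return out
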