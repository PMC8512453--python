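"""Criterion lab arm: breath-by-breath gas exchange to MVPA and net AEE.

The chain is: time-weighted epoch aggregation of breath VO2 rates ->
individualized 1-MET baseline from the resting period -> MET per epoch ->
intensity classes (SED <= 1.5 < LPA < 3.0 <= MPA < 6.0 <= VPA) -> MVPA
minutes (transitions excluded) and net activity energy expenditure
(active-segment kilocalories at 4.867 kcal per litre O2, minus the
Schofield basal rate over the active minutes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (
    LPA,
    MPA,
    SED,
    VPA,
    LabResult,
    ProtocolSegment,
    RestingRate,
    SubjectProfile,
)

KCAL_PER_L_O2 = 4.867

# Schofield (1985) weight-based BMR coefficients, kcal/day, child and
# adolescent bands: bmr = slope * weight_kg + intercept.
SCHOFIELD_COEFFS = {
    ("male", "3-10"): (22.7, 495.0),
    ("male", "10-18"): (17.5, 651.0),
    ("female", "3-10"): (22.5, 499.0),
    ("female", "10-18"): (12.2, 746.0),
}


def aggregate_breaths(
    breaths: pd.DataFrame,
    epoch_s: float = 60.0,
    session_start_s: float = 0.0,
    max_interval_s: float = 30.0,
) -> pd.DataFrame:
    """Time-weighted epoch means of the breath-rate step function.

    Each breath's timestamp ends the interval that began at the previous
    breath (the first interval begins at ``session_start_s``), over which
    its ``vo2_ml_min`` is taken as constant. A breath never covers more
    than ``max_interval_s`` seconds back, so recording gaps leave epochs
    uncovered; an epoch's value is the overlap-weighted mean of intervals
    intersecting it, and epochs with no coverage are NaN (missing), never
    zero.
    """
    if breaths.empty:
        raise ValueError("breath series is empty")
    if epoch_s <= 0:
        raise ValueError("epoch length must be positive")
    t = breaths["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"breath times not strictly increasing at row {i}")
    rate = breaths["vo2_ml_min"].to_numpy(dtype=float)

    starts = np.maximum(np.concatenate([[session_start_s], t[:-1]]), t - max_interval_s)
    ends = t
    n_epochs = int(np.ceil((t[-1] - session_start_s) / epoch_s))
    epoch_starts = session_start_s + epoch_s * np.arange(n_epochs)
    values = np.full(n_epochs, np.nan)
    for k, e0 in enumerate(epoch_starts):
        e1 = e0 + epoch_s
        overlap = np.clip(np.minimum(ends, e1) - np.maximum(starts, e0), 0.0, None)
        total = overlap.sum()
        if total > 0:
            values[k] = float(np.dot(rate, overlap) / total)
    return pd.DataFrame({"epoch_start_s": epoch_starts, "vo2_ml_min": values})


def assign_segments(
    epochs: pd.DataFrame, protocol: list[ProtocolSegment], epoch_s: float = 60.0
) -> pd.DataFrame:
    """Label each epoch with the protocol segment covering most of it.

    Ties go to the earlier segment; epochs not overlapping any segment get
    an empty category and are excluded downstream.
    """
    cats = []
    for e0 in epochs["epoch_start_s"].to_numpy(dtype=float):
        e1 = e0 + epoch_s
        best, best_overlap = "", 0.0
        for seg in protocol:
            ov = min(seg.end_s, e1) - max(seg.start_s, e0)
            if ov > best_overlap + 1e-9:
                best, best_overlap = seg.category, ov
        cats.append(best)
    out = epochs.copy()
    out["segment_category"] = cats
    return out


def compute_resting_met(
    epochs: pd.DataFrame,
    protocol: list[ProtocolSegment],
    weight_kg: float,
    epoch_s: float = 60.0,
) -> RestingRate:
    """Mean VO2/kg over epochs fully inside the rest segment = the 1-MET rate."""
    rest = [s for s in protocol if s.category == "rest"]
    if not rest:
        raise ValueError("protocol has no rest segment")
    seg = rest[0]
    e0 = epochs["epoch_start_s"].to_numpy(dtype=float)
    inside = (e0 >= seg.start_s - 1e-9) & (e0 + epoch_s <= seg.end_s + 1e-9)
    vals = epochs.loc[inside, "vo2_ml_min"].dropna()
    if vals.empty:
        raise ValueError("rest segment not covered by any complete epoch")
    return RestingRate(float(vals.mean()) / weight_kg, int(vals.size))


def mets_from_vo2(
    epochs: pd.DataFrame, resting: RestingRate, weight_kg: float
) -> pd.DataFrame:
    """MET = (VO2 rate / weight) / individualized resting VO2 per kg."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    out = epochs.copy()
    out["vo2_per_kg"] = out["vo2_ml_min"] / weight_kg
    out["met"] = out["vo2_per_kg"] / resting.vo2_per_kg_1met
    return out


def classify_met_intensity(met: float) -> str:
    """SED <= 1.5 < LPA < 3.0 <= MPA < 6.0 <= VPA.

    The printed anchors 1.5, 3.0 and 6.0 are preserved and the gaps of the
    discrete bands (1.5-1.6, 5.9-6.0) are closed half-open so every
    non-negative MET maps to exactly one class.
    """
    if met < 0:
        raise ValueError("MET must be non-negative")
    if met <= 1.5:
        return SED
    if met < 3.0:
        return LPA
    if met < 6.0:
        return MPA
    return VPA


def classify_epochs(epochs: pd.DataFrame) -> pd.DataFrame:
    out = epochs.copy()
    out["intensity"] = [
        classify_met_intensity(m) if np.isfinite(m) else None for m in out["met"]
    ]
    return out


def mvpa_minutes(epochs: pd.DataFrame, epoch_s: float = 60.0) -> float:
    """Minutes of epochs classified MPA or VPA, transitions excluded."""
    usable = epochs[epochs["vo2_ml_min"].notna()]
    if "intensity" not in usable.columns or usable["intensity"].isna().any():
        raise ValueError("epochs must be classified before counting MVPA")
    mask = usable["intensity"].isin([MPA, VPA]) & (
        usable["segment_category"] != "transition"
    )
    return float(mask.sum()) * epoch_s / 60.0


def vo2_to_kcal(vo2_liters: float) -> float:
    """Caloric equivalent of oxygen: 4.867 kcal per litre O2."""
    if np.any(np.asarray(vo2_liters) < 0):
        raise ValueError("VO2 volume must be non-negative")
    return KCAL_PER_L_O2 * vo2_liters


def gross_active_aee(epochs: pd.DataFrame, epoch_s: float = 60.0):
    """(gross kcal, active minutes) over ``activity``-category epochs only.

    Rest, sedentary and transition epochs are removed first; each remaining
    epoch contributes kcal = 4.867 * (VO2 in L/min) * epoch minutes. VO2
    rates arrive in mL/min and are divided by 1000.
    """
    active = epochs[
        (epochs["segment_category"] == "activity") & epochs["vo2_ml_min"].notna()
    ]
    epoch_min = epoch_s / 60.0
    kcal = vo2_to_kcal(active["vo2_ml_min"].to_numpy(dtype=float) / 1000.0) * epoch_min
    return float(np.sum(kcal)), float(len(active)) * epoch_min


def schofield_bmr(subject: SubjectProfile) -> float:
    """Predicted basal metabolic rate (kcal/day), Schofield weight equations."""
    if subject.weight_kg <= 0:
        raise ValueError("weight must be positive")
    if not (3.0 <= subject.age_years < 18.0):
        raise ValueError("Schofield child bands cover ages [3, 18)")
    band = "3-10" if subject.age_years < 10.0 else "10-18"
    slope, intercept = SCHOFIELD_COEFFS[(subject.sex, band)]
    return slope * subject.weight_kg + intercept


def net_aee(gross_aee_kcal: float, bmr_kcal_day: float, active_minutes: float) -> float:
    """Gross active kcal minus the basal rate accrued over active minutes."""
    if gross_aee_kcal < 0 or bmr_kcal_day < 0 or active_minutes < 0:
        raise ValueError("inputs must be non-negative")
    net = gross_aee_kcal - (bmr_kcal_day / 1440.0) * active_minutes
    if net < 0:
        warnings.warn(
            f"net AEE is negative ({net:.2f} kcal); basal rate exceeds "
            "measured active expenditure",
            stacklevel=2,
        )
    return net


def process_lab_session(
    subject: SubjectProfile,
    breaths: pd.DataFrame,
    protocol: list[ProtocolSegment],
    epoch_s: float = 60.0,
):
    """Full criterion arm for one session -> (epoch table, LabResult)."""
    epochs = aggregate_breaths(breaths, epoch_s=epoch_s,
                               session_start_s=protocol[0].start_s)
    epochs = assign_segments(epochs, protocol, epoch_s=epoch_s)
    resting = compute_resting_met(epochs, protocol, subject.weight_kg, epoch_s=epoch_s)
    epochs = mets_from_vo2(epochs, resting, subject.weight_kg)
    epochs = classify_epochs(epochs)
    mvpa = mvpa_minutes(epochs, epoch_s=epoch_s)
    gross, active_min = gross_active_aee(epochs, epoch_s=epoch_s)
    bmr = schofield_bmr(subject)
    net = net_aee(gross, bmr, active_min)
    result = LabResult(
        mvpa_min=mvpa,
        gross_aee_kcal=gross,
        bmr_kcal_day=bmr,
        active_minutes=active_min,
        net_aee_kcal=net,
    )
    return epochs, result
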