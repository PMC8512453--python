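"""Free-living criterion arm: raw tri-axial acceleration to daily MVPA.

Pipeline: autocalibration against the 1-g gravity reference on stationary
windows -> per-minute ENMO (Euclidean norm minus one, per-sample negative
truncation) -> Hildebrand cut-point intensity classes -> Choi run-length
non-wear detection plus parent-log exclusion -> daily MVPA with a minimum
wear-time rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import LPA, MPA, SED, VPA, AccelStream, CalibrationModel, CutPoints

# ENMO intensity thresholds (milli-g) for wrist-worn devices in children,
# transcribed from the Hildebrand calibration studies; data, not logic.
CUTPOINT_SETS = {
    "hildebrand_children_wrist": CutPoints(lpa_mg=35.6, mpa_mg=201.4, vpa_mg=707.0),
}

STATIONARY_SD_MG = 13.0
ORIENTATION_MIN_ANGLE_DEG = 30.0


def autocalibrate(
    stream: AccelStream,
    window_s: float = 10.0,
    sd_threshold_mg: float = STATIONARY_SD_MG,
    min_orientations: int = 3,
    max_iter: int = 100,
) -> CalibrationModel:
    """Fit per-axis offset and gain so stationary norms approach 1 g.

    Stationary windows (per-axis SD below ``sd_threshold_mg`` over
    ``window_s``) are collected; if they do not span at least
    ``min_orientations`` distinct orientations (pairwise separated by more
    than 30 degrees) an identity model flagged non-converged is returned.
    Otherwise offset and gain are fitted iteratively: each round regresses
    the raw window means onto their unit-normalized calibrated versions,
    axis by axis — a simplified version of the closest-point sphere fit
    used for raw accelerometry calibration.
    """
    if stream.n_samples == 0:
        raise ValueError("acceleration series is empty")
    if stream.n_samples / stream.rate_hz < 600.0:
        raise ValueError("calibration requires at least 10 minutes of data")

    w = max(1, round(window_s * stream.rate_hz))
    n_win = stream.n_samples // w
    xyz = stream.xyz[: n_win * w].reshape(n_win, w, 3).astype(np.float64)
    sds = xyz.std(axis=1)
    means = xyz.mean(axis=1)
    stationary = np.all(sds < sd_threshold_mg / 1000.0, axis=1)
    M = means[stationary]
    k = int(M.shape[0])
    if k < min_orientations:
        return CalibrationModel.identity(k)
    if k > 2000:  # cap the fit size; evenly spaced windows keep all postures
        M = M[np.linspace(0, k - 1, 2000).astype(int)]

    norms = np.linalg.norm(M, axis=1)
    units = M / norms[:, None]
    cos_min = np.cos(np.deg2rad(ORIENTATION_MIN_ANGLE_DEG))
    reps: list[np.ndarray] = []
    for u in units:
        if all(abs(float(u @ r)) < cos_min for r in reps):
            reps.append(u)
    if len(reps) < min_orientations:
        return CalibrationModel.identity(k)

    offset = np.zeros(3)
    gain = np.ones(3)
    for _ in range(max_iter):
        cal = (M - offset) / gain
        target = cal / np.linalg.norm(cal, axis=1)[:, None]
        new_offset = np.empty(3)
        new_gain = np.empty(3)
        for a in range(3):
            g, o = np.polyfit(target[:, a], M[:, a], 1)
            new_gain[a], new_offset[a] = g, o
        if np.max(np.abs(new_offset - offset)) < 1e-10 and np.max(
            np.abs(new_gain - gain)
        ) < 1e-10:
            offset, gain = new_offset, new_gain
            break
        offset, gain = new_offset, new_gain
    if np.any(gain <= 0.5) or np.any(gain >= 2.0):
        return CalibrationModel.identity(k)
    return CalibrationModel(offset, gain, k, converged=True)


def compute_enmo(
    stream: AccelStream,
    epoch_s: float = 60.0,
    calibration: CalibrationModel | None = None,
) -> pd.DataFrame:
    """Per-epoch ENMO in milli-g.

    Per sample, e = max(0, sqrt(x^2 + y^2 + z^2) - 1) in g; the truncation
    at zero happens before averaging (the two do not commute). Epochs are
    the mean of e over their samples, scaled to milli-g; an epoch with any
    missing samples is NaN, and a trailing partial epoch is dropped.
    """
    if epoch_s <= 0:
        raise ValueError("epoch length must be positive")
    xyz = stream.xyz
    if calibration is not None:
        xyz = calibration.apply(xyz)
    norm = np.sqrt(np.einsum("ij,ij->i", xyz.astype(np.float64), xyz.astype(np.float64)))
    e = np.maximum(0.0, norm - 1.0)
    per_epoch = round(epoch_s * stream.rate_hz)
    n_epochs = e.size // per_epoch
    vals = e[: n_epochs * per_epoch].reshape(n_epochs, per_epoch).mean(axis=1) * 1000.0
    starts = stream.start_s + epoch_s * np.arange(n_epochs)
    return pd.DataFrame({"minute_start_s": starts, "enmo_mg": vals})


def classify_enmo(records: pd.DataFrame, cuts: CutPoints) -> pd.DataFrame:
    """Left-closed cut-point bands: SED < LPA-cut <= LPA < MPA-cut <= MPA < VPA-cut <= VPA."""
    e = records["enmo_mg"].to_numpy(dtype=float)
    intensity = np.select(
        [e < cuts.lpa_mg, e < cuts.mpa_mg, e < cuts.vpa_mg],
        [SED, LPA, MPA],
        default=VPA,
    ).astype(object)
    intensity[~np.isfinite(e)] = None
    out = records.copy()
    out["intensity"] = intensity
    return out


def _runs(mask: np.ndarray):
    """(start, length) of each maximal True run."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends - starts))


def detect_nonwear(
    minute_values: np.ndarray,
    window_min: int = 90,
    spike_tolerance_min: int = 2,
    flank_min: int = 30,
    zero_threshold_mg: float = 1.0,
) -> np.ndarray:
    """Choi run-length non-wear mask; returns True where the monitor is worn.

    A minute is non-wear when it lies in a run of at least ``window_min``
    zero-activity minutes, tolerating interruptions of up to
    ``spike_tolerance_min`` consecutive non-zero minutes provided each
    interruption has at least ``flank_min`` zero minutes immediately on
    both sides. Originally defined on activity counts; here "zero" means
    per-minute ENMO below ``zero_threshold_mg`` (missing minutes count as
    zero). Series shorter than the window are entirely wear.
    """
    v = np.asarray(minute_values, dtype=float)
    n = v.size
    if n < window_min:
        return np.ones(n, dtype=bool)
    nonzero = np.where(np.isfinite(v), v >= zero_threshold_mg, False)

    # Zero out tolerated spikes: short non-zero runs flanked by long zeros.
    effective = nonzero.copy()
    for start, length in _runs(nonzero):
        if length > spike_tolerance_min:
            continue
        zeros_before = 0
        i = start - 1
        while i >= 0 and not nonzero[i]:
            zeros_before += 1
            i -= 1
        zeros_after = 0
        i = start + length
        while i < n and not nonzero[i]:
            zeros_after += 1
            i += 1
        if zeros_before >= flank_min and zeros_after >= flank_min:
            effective[start : start + length] = False

    nonwear = np.zeros(n, dtype=bool)
    for start, length in _runs(~effective):
        if length >= window_min:
            nonwear[start : start + length] = True
    return ~nonwear


def apply_logs(
    minute_starts_s: np.ndarray, log: pd.DataFrame, epoch_s: float = 60.0
) -> np.ndarray:
    """True for minutes overlapping any logged sleep/non-wear interval."""
    t0 = np.asarray(minute_starts_s, dtype=float)
    excluded = np.zeros(t0.size, dtype=bool)
    if log is None or len(log) == 0:
        return excluded
    for _, row in log.iterrows():
        s, e = float(row["start_s"]), float(row["end_s"])
        if e <= s:
            raise ValueError(f"malformed log interval: [{s}, {e}]")
        excluded |= (t0 < e) & (t0 + epoch_s > s)
    return excluded


def daily_mvpa(
    minutes: pd.DataFrame,
    min_wear_min: float = 600.0,
    day_s: float = 86400.0,
):
    """Per-day summaries and the across-day mean of daily MVPA.

    A minute counts toward wear when worn, not log-excluded and not
    missing. Days with wear below ``min_wear_min`` are dropped; partial
    first/last days are retained only if they meet the same minimum.
    """
    req = {"minute_start_s", "enmo_mg", "intensity", "wear", "excluded"}
    missing = req - set(minutes.columns)
    if missing:
        raise ValueError(f"minute table lacks columns: {sorted(missing)}")
    m = minutes.copy()
    m["day"] = (m["minute_start_s"] // day_s).astype(int)
    ok = m["wear"] & ~m["excluded"] & m["enmo_mg"].notna()
    rows = []
    for day, grp in m.groupby("day"):
        worn = grp[ok.loc[grp.index]]
        wear_min = float(len(worn))
        mvpa = float(worn["intensity"].isin([MPA, VPA]).sum())
        total_pa = float(worn["intensity"].isin([LPA, MPA, VPA]).sum())
        rows.append(
            {"day": int(day), "mvpa_min": mvpa, "total_pa_min": total_pa,
             "wear_min": wear_min, "retained": wear_min >= min_wear_min}
        )
    daily = pd.DataFrame(rows)
    retained = daily[daily["retained"]]
    if retained.empty:
        raise ValueError("no days meet the minimum wear time")
    return daily, float(retained["mvpa_min"].mean())


def process_free_living(
    stream: AccelStream,
    log: pd.DataFrame | None = None,
    cuts: CutPoints | str = "hildebrand_children_wrist",
    epoch_s: float = 60.0,
    calibrate: bool = True,
    window_min: int = 90,
    spike_tolerance_min: int = 2,
    flank_min: int = 30,
    min_wear_min: float = 600.0,
):
    """Full free-living arm -> (minute table, daily table, mean daily MVPA, calibration)."""
    if isinstance(cuts, str):
        cuts = CUTPOINT_SETS[cuts]
    calibration = None
    if calibrate:
        calibration = autocalibrate(stream)
        if not calibration.converged:
            warnings.warn(
                "autocalibration did not converge; using identity model",
                stacklevel=2,
            )
    minutes = compute_enmo(stream, epoch_s=epoch_s, calibration=calibration)
    minutes = classify_enmo(minutes, cuts)
    minutes["wear"] = detect_nonwear(
        minutes["enmo_mg"].to_numpy(),
        window_min=window_min,
        spike_tolerance_min=spike_tolerance_min,
        flank_min=flank_min,
    )
    minutes["excluded"] = apply_logs(
        minutes["minute_start_s"].to_numpy(), log, epoch_s=epoch_s
    )
    daily, mean_mvpa = daily_mvpa(minutes, min_wear_min=min_wear_min)
    return minutes, daily, mean_mvpa, calibration
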