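"""Synthetic cohorts, lab protocols and signal generators.

Everything downstream (the calorimetry arm, the accelerometry arm, the
agreement statistics) is tested against data produced here, where the ground
truth — programmed MVPA minutes, net activity energy expenditure, device
bias — is known exactly. With all noise knobs at zero the generators are
designed so both processing arms recover the programmed truth exactly:
segments are whole minutes (aligning with 60-s epochs), breath records never
straddle segment boundaries, and the per-minute ENMO of a worn segment
averages exactly to its target.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    AccelStream,
    DeviceSummary,
    ProtocolSegment,
    SimulationParams,
    SubjectProfile,
    TruthRecord,
    split_rng,
    validate_protocol,
)

# Cohort-level generator targets: the study population is elementary-school
# children (mean age 9.7 y, SD 1.9, range clipped to 7-13; height/weight
# consistent with the cohort's anthropometrics).
AGE_MEAN = 9.7
AGE_SD = 1.9
AGE_LO, AGE_HI = 7.0, 13.0
HEIGHT_AT_MEAN_AGE_CM = 138.3
HEIGHT_SLOPE_CM_PER_Y = 5.8
HEIGHT_RESID_SD_CM = 6.5
BMI_MEAN = 16.3
BMI_SD = 2.7
BMI_MIN = 12.0

# Default 14-station lab protocol: compendium-style MET targets spanning
# sedentary through vigorous play, light stations 3 min / MVPA stations
# 2 min, so rest (3) + 14 transitions (1 each) + activities (33) = 50 min.
DEFAULT_ACTIVITY_METS = (
    1.3, 1.5, 1.8, 2.3, 2.8, 3.3, 3.8, 4.3, 4.8, 5.3, 5.8, 6.3, 6.8, 7.3,
)
TRANSITION_MET = 2.0  # walking between stations
REST_MET = 1.0

MOVEMENT_HZ = 1.0  # fundamental of the synthetic movement waveform
RER = 0.85  # fixed VCO2/VO2 ratio for the carried (unused) VCO2 channel


@lru_cache(maxsize=8)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation location whose truncated-normal mean equals target."""

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return optimize.brentq(f, lo, hi)


def make_subject(seed: int) -> SubjectProfile:
    """Draw one child with cohort-consistent anthropometrics.

    Deterministic given ``seed``. Ages come from a normal truncated to
    [7, 13] whose location is solved numerically so the truncated mean is
    exactly the cohort mean; height is age-linked and weight follows from a
    BMI draw, so all covariates have positive support.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = split_rng(seed, "subject")
    loc = _truncnorm_loc(AGE_MEAN, AGE_SD, AGE_LO, AGE_HI)
    a, b = (AGE_LO - loc) / AGE_SD, (AGE_HI - loc) / AGE_SD
    age = float(stats.truncnorm.rvs(a, b, loc=loc, scale=AGE_SD, random_state=rng))
    sex = "female" if rng.random() < 0.5 else "male"
    height = HEIGHT_AT_MEAN_AGE_CM + HEIGHT_SLOPE_CM_PER_Y * (age - AGE_MEAN)
    height += rng.normal(0.0, HEIGHT_RESID_SD_CM)
    height = max(height, 100.0)
    bmi = max(rng.normal(BMI_MEAN, BMI_SD), BMI_MIN)
    weight = bmi * (height / 100.0) ** 2
    return SubjectProfile(
        subject_id=f"S{seed:05d}",
        sex=sex,
        age_years=age,
        height_cm=height,
        weight_kg=weight,
    )


def make_cohort(n: int, seed: int) -> list[SubjectProfile]:
    """n subjects with ids/draws derived from ``seed`` (offset sub-seeds)."""
    base = int(np.random.SeedSequence(entropy=seed).generate_state(1)[0] % (2**20))
    return [make_subject(base * 1000 + i) for i in range(n)]


def make_lab_protocol(
    n_activities: int = 14,
    rest_min: float = 3.0,
    transition_min: float = 1.0,
    activity_min: float | None = None,
    activity_mets: tuple | None = None,
) -> list[ProtocolSegment]:
    """Rest, then ``n_activities`` stations each preceded by a transition.

    With the defaults the session is the 50-min protocol: 3-min rest, 14
    stations spanning sedentary through vigorous intensities, 1-min
    transitions. Stations at <=1.5 MET are category ``sedentary`` (they are
    excluded from AEE but still classified); all others are ``activity``.
    """
    if n_activities < 1:
        raise ValueError("n_activities must be >= 1")
    if rest_min <= 0 or transition_min <= 0:
        raise ValueError("durations must be positive")
    if activity_min is not None and activity_min <= 0:
        raise ValueError("durations must be positive")

    if activity_mets is None:
        if n_activities == len(DEFAULT_ACTIVITY_METS):
            mets = DEFAULT_ACTIVITY_METS
        else:
            spanning = (1.3, 2.0, 3.3, 4.8, 6.3)
            mets = tuple(spanning[i % len(spanning)] for i in range(n_activities))
    else:
        mets = tuple(activity_mets)
        if len(mets) != n_activities:
            raise ValueError("activity_mets length must equal n_activities")

    segments = [
        ProtocolSegment("rest", 0.0, rest_min * 60.0, "rest", REST_MET)
    ]
    t = rest_min * 60.0
    for i, met in enumerate(mets):
        segments.append(
            ProtocolSegment(f"transition_{i + 1}", t, t + transition_min * 60.0,
                            "transition", TRANSITION_MET)
        )
        t += transition_min * 60.0
        if activity_min is not None:
            dur = activity_min
        elif mets == DEFAULT_ACTIVITY_METS:
            dur = 3.0 if met < 3.0 else 2.0  # 50-min default session
        else:
            dur = 2.0
        category = "sedentary" if met <= 1.5 else "activity"
        segments.append(
            ProtocolSegment(f"activity_{i + 1}", t, t + dur * 60.0, category, met)
        )
        t += dur * 60.0
    validate_protocol(segments)
    return segments


# ---------------------------------------------------------------------------
# Ground truth


def lab_truth(
    subject: SubjectProfile,
    protocol: list[ProtocolSegment],
    params: SimulationParams,
) -> TruthRecord:
    """Programmed MVPA minutes and net AEE implied by the protocol targets.

    Mirrors the criterion arm's definitions: MVPA is the summed duration of
    segments at >= 3.0 MET; net AEE converts the target VO2 of ``activity``
    segments to kilocalories and subtracts the Schofield basal rate over the
    active minutes.
    """
    from .calorimetry import schofield_bmr  # local import avoids a cycle

    true_mvpa = sum(s.duration_min for s in protocol if s.target_met >= 3.0)
    active = [s for s in protocol if s.category == "activity"]
    active_min = sum(s.duration_min for s in active)
    gross = 0.0
    for s in active:
        vo2_l_min = s.target_met * params.resting_vo2_per_kg * subject.weight_kg / 1000.0
        gross += vo2_l_min * 4.867 * s.duration_min
    bmr = schofield_bmr(subject)
    net = gross - (bmr / 1440.0) * active_min
    return TruthRecord(
        subject_id=subject.subject_id,
        true_mvpa_min=true_mvpa,
        true_net_aee_kcal=net,
        segment_mets={s.label: s.target_met for s in protocol},
    )


# ---------------------------------------------------------------------------
# Gas exchange


def _mean_and_exit(m0: float, target: float, dt: float, tau: float):
    """Mean of a first-order approach over dt, and the state at its end."""
    if tau <= 1e-12 or dt <= 0:
        return target, target
    decay = math.exp(-dt / tau)
    mean = target + (m0 - target) * tau * (1.0 - decay) / dt
    return mean, target + (m0 - target) * decay


def simulate_gas_exchange(
    subject: SubjectProfile,
    protocol: list[ProtocolSegment],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Breath-by-breath VO2/VCO2 for one lab session.

    Each row is one breath: its timestamp marks the END of the breath
    interval and ``vo2_ml_min`` is the mean metabolic rate over that
    interval (the backward-interval convention the epoch aggregator
    assumes). The underlying rate tracks each segment's target MET through
    a first-order on-kinetics filter with time constant ``onkinetics_tau_s``
    and is scaled by the subject's resting VO2 (``resting_vo2_per_kg`` x
    weight); multiplicative lognormal noise has unit mean and coefficient
    of variation ``vo2_noise_cv``. Breaths are emitted segment by segment,
    with the last breath of a segment exactly at its end.
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    validate_protocol(protocol)
    if rng is None:
        rng = split_rng(params.seed, "gas", subject.subject_id)

    resting_rate = params.resting_vo2_per_kg * subject.weight_kg  # mL/min at 1 MET
    tau = params.onkinetics_tau_s
    cv = params.vo2_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    times, mets = [], []
    m = protocol[0].target_met  # start at steady state of the first segment
    for seg in protocol:
        dur = seg.duration_s
        n = max(1, round(dur / params.breath_interval_mean_s))
        # jittered spacings rescaled so the segment is tiled exactly
        raw = rng.gamma(25.0, 1.0, size=n)
        edges = seg.start_s + dur * np.cumsum(raw) / raw.sum()
        edges[-1] = seg.end_s
        t_prev = seg.start_s
        for t in edges:
            mean_met, m = _mean_and_exit(m, seg.target_met, t - t_prev, tau)
            times.append(t)
            mets.append(mean_met)
            t_prev = t

    vo2 = np.asarray(mets) * resting_rate
    if sigma > 0:
        vo2 = vo2 * rng.lognormal(-0.5 * sigma * sigma, sigma, size=vo2.size)
    return pd.DataFrame(
        {"time_s": np.asarray(times), "vo2_ml_min": vo2, "vco2_ml_min": RER * vo2}
    )


# ---------------------------------------------------------------------------
# Raw acceleration


def met_to_enmo_mg(met: float, params: SimulationParams) -> float:
    """Affine MET -> expected per-minute ENMO map, floored at zero."""
    return max(0.0, params.met_to_enmo_intercept + params.met_to_enmo_slope * (met - 1.0))


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_raw_accel(
    schedule: list[ProtocolSegment],
    params: SimulationParams,
    rate_hz: float = 30.0,
    rng: np.random.Generator | None = None,
) -> AccelStream:
    """Fixed-rate tri-axial acceleration (g) over a wear/sleep schedule.

    Worn segments superimpose a movement waveform along a per-segment
    gravity direction: the per-sample excess magnitude is
    ``e * (1 - cos(2*pi*t))`` with ``e`` the MET-mapped ENMO target, whose
    mean over any whole second is exactly ``e``; optional multiplicative
    lognormal noise (``enmo_noise_cv``) perturbs each sample. Non-wear
    segments are a constant unit gravity vector plus per-axis uniform noise
    bounded by ``accel_noise_floor_mg``.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    validate_protocol(schedule)
    if rng is None:
        rng = split_rng(params.seed, "accel")

    floor_g = params.accel_noise_floor_mg / 1000.0
    cv = params.enmo_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    chunks = []
    for seg in schedule:
        n = round(seg.duration_s * rate_hz)
        if n == 0:
            continue
        g_dir = _unit_vector(rng)
        e_g = met_to_enmo_mg(seg.target_met, params) / 1000.0 if seg.worn else 0.0
        if not seg.worn or e_g == 0.0:
            xyz = np.tile(g_dir, (n, 1))
            if floor_g > 0:
                xyz = xyz + rng.uniform(-floor_g, floor_g, size=(n, 3))
        else:
            t_local = np.arange(n) / rate_hz
            a = e_g * (1.0 - np.cos(2.0 * np.pi * MOVEMENT_HZ * t_local))
            if sigma > 0:
                a = a * rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)
            xyz = g_dir[None, :] * (1.0 + a)[:, None]
        chunks.append(xyz.astype(np.float32))

    xyz = np.concatenate(chunks, axis=0)
    return AccelStream(rate_hz=rate_hz, xyz=xyz, start_s=schedule[0].start_s)


# ---------------------------------------------------------------------------
# Black-box device model


def simulate_device_summary(
    truth: TruthRecord,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> DeviceSummary:
    """Device estimate: truth scaled by a proportional bias plus noise.

    ``mvpa = max(0, true * (1 + bias) + Normal(0, sd))`` and analogously for
    AEE. Deterministic given the global seed and the subject id.
    """
    if rng is None:
        rng = split_rng(params.seed, "device", truth.subject_id)
    mvpa = truth.true_mvpa_min * (1.0 + params.device_mvpa_bias)
    if params.device_mvpa_sd_min > 0:
        mvpa += rng.normal(0.0, params.device_mvpa_sd_min)
    aee = truth.true_net_aee_kcal * (1.0 + params.device_aee_bias)
    if params.device_aee_sd_kcal > 0:
        aee += rng.normal(0.0, params.device_aee_sd_kcal)
    return DeviceSummary(truth.subject_id, max(0.0, mvpa), max(0.0, aee))


# ---------------------------------------------------------------------------
# Free-living weeks

DAY_S = 86400.0


def make_free_living_schedule(
    days: int = 7,
    daily_mvpa_min: float | list = 53,
) -> list[ProtocolSegment]:
    """Multi-day schedule with sleep, one >=90-min non-wear bout and bouts of
    known intensity each day.

    The day template (minutes from midnight): sleep 0-420 and 1290-1440,
    a 100-min non-wear bout at 960, MVPA bouts (4.0 MET) at 540 and 780
    totalling the programmed minutes (up to 120/day), with light (2.0 MET)
    and sedentary (1.3 MET) filler. All block edges are whole minutes.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if np.isscalar(daily_mvpa_min):
        daily = [float(daily_mvpa_min)] * days
    else:
        daily = [float(m) for m in daily_mvpa_min]
        if len(daily) != days:
            raise ValueError("daily_mvpa_min must have one entry per day")

    segments: list[ProtocolSegment] = []
    for d, m_total in enumerate(daily):
        if not (0 <= m_total <= 120):
            raise ValueError("daily MVPA must lie in [0, 120] minutes")
        base = d * DAY_S

        def add(label, start_min, end_min, category, met, worn=True):
            if end_min > start_min:
                segments.append(
                    ProtocolSegment(f"d{d}_{label}", base + start_min * 60.0,
                                    base + end_min * 60.0, category, met, worn)
                )

        m1 = min(m_total, 60.0)
        m2 = m_total - m1
        add("sleep_am", 0, 420, "sleep", 0.9)
        add("sed_am", 420, 480, "sedentary", 1.3)
        add("lpa_am", 480, 540, "activity", 2.0)
        add("mvpa_am", 540, 540 + m1, "activity", 4.0)
        add("sed_mid", 540 + m1, 720, "sedentary", 1.3)
        add("lpa_noon", 720, 780, "activity", 2.0)
        add("mvpa_pm", 780, 780 + m2, "activity", 4.0)
        add("sed_pm", 780 + m2, 960, "sedentary", 1.3)
        add("nonwear", 960, 1060, "nonwear", 0.9, worn=False)
        add("lpa_eve", 1060, 1140, "activity", 2.0)
        add("sed_eve", 1140, 1290, "sedentary", 1.3)
        add("sleep_pm", 1290, 1440, "sleep", 0.9)
    validate_protocol(segments)
    return segments


def schedule_log(schedule: list[ProtocolSegment]) -> pd.DataFrame:
    """Parent-report log: one row per sleep or non-wear segment."""
    rows = [
        {"start_s": s.start_s, "end_s": s.end_s,
         "kind": "sleep" if s.category == "sleep" else "nonwear"}
        for s in schedule
        if s.category in ("sleep", "nonwear")
    ]
    return pd.DataFrame(rows, columns=["start_s", "end_s", "kind"])


def schedule_daily_truth(schedule: list[ProtocolSegment]) -> pd.DataFrame:
    """Ground-truth MVPA minutes per calendar day (worn segments >= 3 MET)."""
    n_days = int(math.ceil(max(s.end_s for s in schedule) / DAY_S))
    truth = np.zeros(n_days)
    for s in schedule:
        if s.worn and s.target_met >= 3.0:
            truth[int(s.start_s // DAY_S)] += s.duration_min
    return pd.DataFrame({"day": np.arange(n_days), "true_mvpa_min": truth})


def simulate_free_living_week(
    subject: SubjectProfile,
    params: SimulationParams,
    days: int = 7,
    rate_hz: float = 30.0,
    daily_mvpa_min: float | list = 53,
):
    """One subject's free-living wear: raw stream, device days, log, truth.

    Returns ``(stream, device_daily, log, truth_daily)`` where
    ``device_daily`` has one device MVPA estimate per day (truth passed
    through the black-box device model) and ``truth_daily`` the programmed
    minutes.
    """
    schedule = make_free_living_schedule(days, daily_mvpa_min)
    rng = split_rng(params.seed, "accel", subject.subject_id)
    stream = simulate_raw_accel(schedule, params, rate_hz=rate_hz, rng=rng)
    log = schedule_log(schedule)
    truth = schedule_daily_truth(schedule)

    dev_rng = split_rng(params.seed, "device", subject.subject_id)
    rows = []
    for day, t in zip(truth["day"], truth["true_mvpa_min"]):
        rec = TruthRecord(subject.subject_id, float(t), 0.0)
        dev = simulate_device_summary(rec, params, rng=dev_rng)
        rows.append({"day": int(day), "device_mvpa_min": dev.mvpa_min})
    device_daily = pd.DataFrame(rows)
    return stream, device_daily, log, truth
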