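"""Agreement and equivalence statistics for paired device-vs-criterion data.

Implements the mean absolute percent error, the paired mean bias with its
t test, Bland-Altman limits of agreement, the two-sided 90% confidence
interval of the device estimates, and the minimal relative equivalence
zone: the narrowest symmetric percent band around the criterion mean that
contains the device 90% CI.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .types import AgreementResult, EquivalenceResult, PairedMeasurements

CRITERION_MINUS_DEVICE = "criterion_minus_device"
DEVICE_MINUS_CRITERION = "device_minus_criterion"


def _differences(pairs: PairedMeasurements, direction: str) -> np.ndarray:
    c = np.asarray(pairs.criterion, dtype=float)
    d = np.asarray(pairs.device, dtype=float)
    if direction == CRITERION_MINUS_DEVICE:
        return c - d
    if direction == DEVICE_MINUS_CRITERION:
        return d - c
    raise ValueError(f"unknown direction {direction!r}")


def mape(pairs: PairedMeasurements) -> float:
    """Mean of |(criterion - device) / criterion| * 100 over participants."""
    c = np.asarray(pairs.criterion, dtype=float)
    d = np.asarray(pairs.device, dtype=float)
    if np.any(c == 0):
        raise ValueError("MAPE undefined: zero criterion value present")
    return float(np.mean(np.abs((c - d) / c)) * 100.0)


def mean_bias(pairs: PairedMeasurements, direction: str = CRITERION_MINUS_DEVICE):
    """(bias, se, p) of the paired differences in the requested direction.

    p is the two-sided paired t test with n-1 degrees of freedom; when the
    differences have zero variance and zero mean, p = 1.
    """
    diffs = _differences(pairs, direction)
    n = diffs.size
    if n < 2:
        raise ValueError("mean bias requires at least 2 pairs")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    se = sd / math.sqrt(n)
    if se == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        tstat = bias / se
        p = float(2.0 * sps.t.sf(abs(tstat), df=n - 1))
    return bias, se, p


def bland_altman(
    pairs: PairedMeasurements, direction: str = CRITERION_MINUS_DEVICE
) -> AgreementResult:
    """Mean bias, 95% limits of agreement and the systematic-bias decision.

    LoA = bias +/- 1.96 * SD(differences); the bias 95% CI uses the t
    quantile, and systematic bias is flagged when that CI excludes the line
    of equality (zero difference).
    """
    diffs = _differences(pairs, direction)
    n = diffs.size
    if n < 3:
        raise ValueError("Bland-Altman requires at least 3 pairs")
    bias, se, p = mean_bias(pairs, direction)
    mape_pct = (
        mape(pairs) if not np.any(np.asarray(pairs.criterion) == 0) else float("nan")
    )
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tq = float(sps.t.ppf(0.975, df=n - 1))
    ci = (bias - tq * se, bias + tq * se)
    systematic = not (ci[0] <= 0.0 <= ci[1])
    return AgreementResult(
        metric_name=pairs.metric_name,
        direction=direction,
        mean_bias=bias,
        se_bias=se,
        p_paired=p,
        mape_pct=mape_pct,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci95=ci,
        systematic_bias=systematic,
    )


def ci90(values: np.ndarray) -> tuple[float, float]:
    """Two-sided 90% t interval: mean +/- t(0.95, n-1) * sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("confidence interval requires at least 2 values")
    m = float(v.mean())
    half = float(sps.t.ppf(0.95, df=n - 1)) * float(v.std(ddof=1)) / math.sqrt(n)
    return (m - half, m + half)


def minimal_equivalence_zone(
    device_ci90: tuple[float, float], criterion_mean: float
) -> tuple[float, tuple[float, float]]:
    """Narrowest symmetric percent band around the criterion mean containing the CI.

    ez% = 100 * max(mean - ci_low, ci_high - mean) / mean, rounded UP to one
    decimal so the containment ``ci90 within bounds`` still holds after the
    reporting rounding; bounds = mean * (1 -/+ ez/100).
    """
    if criterion_mean <= 0:
        raise ValueError("criterion mean must be positive")
    lo, hi = float(device_ci90[0]), float(device_ci90[1])
    if hi < lo:
        raise ValueError("invalid interval")
    half = max(criterion_mean - lo, hi - criterion_mean)
    raw_pct = 100.0 * half / criterion_mean
    ez_pct = math.ceil(raw_pct * 10.0 - 1e-9) / 10.0
    ez_pct = max(ez_pct, 0.0)
    bounds = (
        criterion_mean * (1.0 - ez_pct / 100.0),
        criterion_mean * (1.0 + ez_pct / 100.0),
    )
    return ez_pct, bounds


def equivalence_decision(
    device_ci90: tuple[float, float], ez_bounds: tuple[float, float]
) -> bool:
    """Closed inclusion of the device CI in the equivalence bounds."""
    tol = 1e-9
    return (
        device_ci90[0] >= ez_bounds[0] - tol and device_ci90[1] <= ez_bounds[1] + tol
    )


def evaluate_equivalence(pairs: PairedMeasurements) -> EquivalenceResult:
    """Device 90% CI vs the minimal equivalence zone of the criterion mean."""
    interval = ci90(pairs.device)
    criterion_mean = float(np.mean(pairs.criterion))
    ez_pct, bounds = minimal_equivalence_zone(interval, criterion_mean)
    return EquivalenceResult(
        metric_name=pairs.metric_name,
        device_ci90=interval,
        criterion_mean=criterion_mean,
        ez_pct=ez_pct,
        ez_bounds=bounds,
        equivalent_within_ez=equivalence_decision(interval, bounds),
    )
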