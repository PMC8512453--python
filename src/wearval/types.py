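"""Shared domain types for the validation pipeline.

Containers are deliberately light: raw signal series live in pandas
DataFrames / numpy arrays for speed, while per-entity records (subjects,
protocol segments, results) are dataclasses with explicit units in their
field names.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

# Intensity classes used by both processing arms.
SED = "SED"
LPA = "LPA"
MPA = "MPA"
VPA = "VPA"
INTENSITY_CLASSES = (SED, LPA, MPA, VPA)

# Protocol / schedule segment categories. The lab protocol uses the first
# four; free-living schedules additionally use sleep (worn, stationary) and
# nonwear (device off wrist).
SEGMENT_CATEGORIES = ("rest", "sedentary", "activity", "transition", "sleep", "nonwear")


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics for one child; drives Schofield BMR and VO2 scaling."""

    subject_id: str
    sex: str  # "male" | "female"
    age_years: float
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (3.0 <= self.age_years < 18.0):
            raise ValueError(f"age must be in [3, 18) years, got {self.age_years}")
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("height and weight must be positive")


@dataclass(frozen=True)
class ProtocolSegment:
    """A labeled time interval with a target metabolic intensity.

    ``worn`` is True for every lab segment; free-living schedules set it
    False for non-wear bouts.
    """

    label: str
    start_s: float
    end_s: float
    category: str
    target_met: float
    worn: bool = True

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"segment {self.label!r}: end must exceed start")
        if self.category not in SEGMENT_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.target_met < 0.9:
            raise ValueError(f"target MET must be >= 0.9, got {self.target_met}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


def validate_protocol(segments: list[ProtocolSegment]) -> None:
    """Check that segments are ordered and non-overlapping."""
    for a, b in zip(segments, segments[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValueError(f"segments {a.label!r} and {b.label!r} overlap")


@dataclass
class SimulationParams:
    """Ground-truth knobs for every stochastic generator.

    One integer ``seed`` drives all draws through a documented splitting
    scheme (see :func:`split_rng`), so each generator can be re-run
    independently and reproducibly.
    """

    breath_interval_mean_s: float = 2.0
    vo2_noise_cv: float = 0.1
    onkinetics_tau_s: float = 20.0
    resting_vo2_per_kg: float = 5.0  # mL O2/kg/min; children's resting uptake
    accel_noise_floor_mg: float = 2.0
    met_to_enmo_slope: float = 110.5  # mg per MET above 1
    met_to_enmo_intercept: float = -19.7  # mg at 1 MET (floored at 0)
    enmo_noise_cv: float = 0.25
    device_mvpa_bias: float = 0.0  # proportional
    device_mvpa_sd_min: float = 2.0  # additive, minutes
    device_aee_bias: float = 0.0
    device_aee_sd_kcal: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.breath_interval_mean_s < 10.0):
            raise ValueError("breath_interval_mean_s must lie in (0.5, 10)")
        for name in (
            "vo2_noise_cv",
            "onkinetics_tau_s",
            "resting_vo2_per_kg",
            "accel_noise_floor_mg",
            "met_to_enmo_slope",
            "enmo_noise_cv",
            "device_mvpa_sd_min",
            "device_aee_sd_kcal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def split_rng(seed: int, *labels) -> np.random.Generator:
    """Derive an independent generator from the global seed and string labels.

    The spawn key is the CRC32 of each label, so e.g. ``split_rng(seed,
    "gas", subject_id)`` is stable across runs and independent of every
    other labeled stream.
    """
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class TruthRecord:
    """Programmed ground truth for one subject's lab session."""

    subject_id: str
    true_mvpa_min: float
    true_net_aee_kcal: float
    segment_mets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.true_mvpa_min) or self.true_mvpa_min < 0:
            raise ValueError("true_mvpa_min must be finite and non-negative")
        if not np.isfinite(self.true_net_aee_kcal):
            raise ValueError("true_net_aee_kcal must be finite")


@dataclass(frozen=True)
class DeviceSummary:
    """Black-box device output for one session or day."""

    subject_id: str
    mvpa_min: float
    aee_kcal: float


@dataclass(frozen=True)
class RestingRate:
    """Individualized 1-MET baseline from the resting period."""

    vo2_per_kg_1met: float  # mL/kg/min
    n_epochs_used: int

    def __post_init__(self) -> None:
        if self.vo2_per_kg_1met <= 0:
            raise ValueError("resting VO2/kg must be positive")


@dataclass(frozen=True)
class LabResult:
    """Criterion-arm summary for one lab session."""

    mvpa_min: float
    gross_aee_kcal: float
    bmr_kcal_day: float
    active_minutes: float
    net_aee_kcal: float


@dataclass(frozen=True)
class CutPoints:
    """ENMO intensity thresholds in milli-g."""

    lpa_mg: float
    mpa_mg: float
    vpa_mg: float

    def __post_init__(self) -> None:
        if not (0 < self.lpa_mg < self.mpa_mg < self.vpa_mg):
            raise ValueError("cut-points must satisfy 0 < LPA < MPA < VPA")


@dataclass
class CalibrationModel:
    """Per-axis sensor error model: raw = gain * true + offset (in g).

    ``apply`` inverts it, mapping stationary norms toward 1 g.
    """

    offset_g: np.ndarray
    gain: np.ndarray
    n_stationary_windows: int
    converged: bool

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (xyz - self.offset_g) / self.gain

    @classmethod
    def identity(cls, n_stationary_windows: int = 0, converged: bool = False):
        return cls(np.zeros(3), np.ones(3), n_stationary_windows, converged)


@dataclass(frozen=True)
class AccelStream:
    """Fixed-rate tri-axial acceleration in g, starting at ``start_s``."""

    rate_hz: float
    xyz: np.ndarray  # (n, 3)
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-participant (criterion, device) value pairs for one metric."""

    metric_name: str
    subject_ids: tuple
    criterion: np.ndarray
    device: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.subject_ids) == len(self.criterion) == len(self.device)):
            raise ValueError("subject_ids, criterion and device must align")

    @property
    def n(self) -> int:
        return len(self.criterion)


@dataclass(frozen=True)
class AgreementResult:
    metric_name: str
    direction: str  # "criterion_minus_device" | "device_minus_criterion"
    mean_bias: float
    se_bias: float
    p_paired: float
    mape_pct: float
    loa_low: float
    loa_high: float
    bias_ci95: tuple
    systematic_bias: bool


@dataclass(frozen=True)
class EquivalenceResult:
    metric_name: str
    device_ci90: tuple
    criterion_mean: float
    ez_pct: float
    ez_bounds: tuple
    equivalent_within_ez: bool
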