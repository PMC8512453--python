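"""File formats, run configuration and end-to-end orchestration.

Delimited text is comma-separated UTF-8 with mandatory headers and "."
decimals. The two validation drivers tie the generators to the processing
arms and the agreement statistics, producing a JSON report that is
byte-identical for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelerometry import process_free_living
from .calorimetry import process_lab_session
from .stats import (
    CRITERION_MINUS_DEVICE,
    DEVICE_MINUS_CRITERION,
    bland_altman,
    evaluate_equivalence,
)
from .synthetic import (
    lab_truth,
    make_cohort,
    make_lab_protocol,
    simulate_device_summary,
    simulate_free_living_week,
    simulate_gas_exchange,
)
from .types import AccelStream, PairedMeasurements, SimulationParams

BREATH_COLUMNS = ["time_s", "vo2_ml_min", "vco2_ml_min"]
ACCEL_COLUMNS = ["time_s", "x_g", "y_g", "z_g"]
LOG_COLUMNS = ["date", "start_hms", "end_hms", "kind"]
_LOG_BASE_DATE = np.datetime64("2021-06-07")  # day 0 of simulated schedules


# ---------------------------------------------------------------------------
# Tables


def write_breath_table(breaths: pd.DataFrame, path) -> None:
    breaths.to_csv(path, index=False, columns=BREATH_COLUMNS)


def read_breath_table(path) -> pd.DataFrame:
    """Validated breath records; strictly increasing times required."""
    df = pd.read_csv(path)
    missing = set(BREATH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: breath table is empty")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time_s not strictly increasing at row {int(bad[0]) + 1}"
        )
    if (df["vo2_ml_min"] < 0).any():
        raise ValueError(f"{path}: negative VO2 rate")
    return df[BREATH_COLUMNS]


def write_accel_table(stream: AccelStream, path) -> None:
    """Raw acceleration as text; the fixed rate lives in a header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate_hz={stream.rate_hz} start_s={stream.start_s}\n")
        fh.write(",".join(ACCEL_COLUMNS) + "\n")
        t = stream.times()
        for i in range(stream.n_samples):
            x, y, z = stream.xyz[i]
            fh.write(f"{t[i]:.6f},{x:.6f},{y:.6f},{z:.6f}\n")


def read_accel_table(path):
    """-> (AccelStream, missing_spans). Gaps longer than 1.5 sample periods
    are reported as (start_s, end_s) missing spans; a measured rate deviating
    more than 2% from the declared one triggers a warning."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("#") or "rate_hz=" not in header:
        raise ValueError(f"{path}: missing '# rate_hz=...' header")
    fields = dict(
        tok.split("=") for tok in header.lstrip("# ").split() if "=" in tok
    )
    rate = float(fields["rate_hz"])
    start_s = float(fields.get("start_s", 0.0))
    df = pd.read_csv(path, skiprows=1)
    missing = set(ACCEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    spans = [
        (float(t[i]), float(t[i + 1]))
        for i in np.flatnonzero(dt > 1.5 / rate)
    ]
    if dt.size:
        measured = 1.0 / float(np.median(dt))
        if abs(measured - rate) / rate > 0.02:
            warnings.warn(
                f"{path}: declared rate {rate} Hz but measured {measured:.2f} Hz",
                stacklevel=2,
            )
    xyz = df[["x_g", "y_g", "z_g"]].to_numpy(dtype=np.float32)
    return AccelStream(rate_hz=rate, xyz=xyz, start_s=start_s), spans


def write_log_table(log: pd.DataFrame, path) -> None:
    """Sleep/non-wear log as date,start_hms,end_hms,kind rows."""
    rows = []
    for _, r in log.iterrows():
        day = int(r["start_s"] // 86400)
        date = str(_LOG_BASE_DATE + np.timedelta64(day, "D"))

        def hms(sec):
            sec = int(round(sec)) % 86400
            return f"{sec // 3600:02d}:{(sec % 3600) // 60:02d}:{sec % 60:02d}"

        end_in_day = r["end_s"] - day * 86400
        end_str = "24:00:00" if end_in_day == 86400 else hms(r["end_s"])
        rows.append(
            {"date": date, "start_hms": hms(r["start_s"]), "end_hms": end_str,
             "kind": r["kind"]}
        )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def read_log_table(path) -> pd.DataFrame:
    """-> log with absolute start_s/end_s (seconds from day 0) and kind."""
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        day = int((np.datetime64(r["date"]) - _LOG_BASE_DATE) // np.timedelta64(1, "D"))

        def secs(hms):
            h, m, s = (int(x) for x in str(hms).split(":"))
            return h * 3600 + m * 60 + s

        start = day * 86400 + secs(r["start_hms"])
        end = day * 86400 + secs(r["end_hms"])
        if end <= start:
            raise ValueError(f"{path}: malformed interval {r['start_hms']}-{r['end_hms']}")
        rows.append({"start_s": float(start), "end_s": float(end), "kind": r["kind"]})
    return pd.DataFrame(rows, columns=["start_s", "end_s", "kind"])


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Everything a validation run needs; serializable to/from flat JSON."""

    seed: int = 0
    n_subjects_lab: int = 20
    n_subjects_freeliving: int = 5
    days: int = 7
    rate_hz: float = 30.0
    epoch_s: float = 60.0
    cutpoints: str = "hildebrand_children_wrist"
    choi_window_min: int = 90
    choi_spike_min: int = 2
    choi_flank_min: int = 30
    min_wear_min: float = 600.0
    daily_mvpa_min: float = 53.0
    lab_direction: str = CRITERION_MINUS_DEVICE
    freeliving_direction: str = DEVICE_MINUS_CRITERION
    sim: dict = field(default_factory=dict)  # SimulationParams overrides
    output_dir: str = "wearval_out"

    def params(self) -> SimulationParams:
        return SimulationParams(seed=self.seed, **self.sim)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.hash(),
        "seed": config.seed,
        "wearval_version": __version__,
    }


def _metric_block(pairs: PairedMeasurements, direction: str) -> dict:
    agreement = bland_altman(pairs, direction=direction)
    equivalence = evaluate_equivalence(pairs)
    return {
        "n": pairs.n,
        "criterion_mean": float(np.mean(pairs.criterion)),
        "criterion_sd": float(np.std(pairs.criterion, ddof=1)),
        "device_mean": float(np.mean(pairs.device)),
        "device_sd": float(np.std(pairs.device, ddof=1)),
        "agreement": dataclasses.asdict(agreement),
        "equivalence": dataclasses.asdict(equivalence),
    }


# ---------------------------------------------------------------------------
# Drivers


def run_lab_validation(config: RunConfig) -> dict:
    """Simulated lab cohort -> criterion arm vs device -> agreement report."""
    if config.n_subjects_lab < 2:
        raise ValueError("lab validation requires at least 2 subjects")
    params = config.params()
    protocol = make_lab_protocol()
    ids, crit_mvpa, crit_aee, dev_mvpa, dev_aee = [], [], [], [], []
    for subject in make_cohort(config.n_subjects_lab, config.seed):
        breaths = simulate_gas_exchange(subject, protocol, params)
        _, lab = process_lab_session(subject, breaths, protocol, epoch_s=config.epoch_s)
        truth = lab_truth(subject, protocol, params)
        device = simulate_device_summary(truth, params)
        ids.append(subject.subject_id)
        crit_mvpa.append(lab.mvpa_min)
        crit_aee.append(lab.net_aee_kcal)
        dev_mvpa.append(device.mvpa_min)
        dev_aee.append(device.aee_kcal)

    pairs_mvpa = PairedMeasurements(
        "mvpa_min", tuple(ids), np.asarray(crit_mvpa), np.asarray(dev_mvpa)
    )
    pairs_aee = PairedMeasurements(
        "net_aee_kcal", tuple(ids), np.asarray(crit_aee), np.asarray(dev_aee)
    )
    return {
        "arm": "lab",
        "metrics": {
            "mvpa_min": _metric_block(pairs_mvpa, config.lab_direction),
            "net_aee_kcal": _metric_block(pairs_aee, config.lab_direction),
        },
        "provenance": _provenance(config),
    }


def run_freeliving_validation(config: RunConfig) -> dict:
    """Simulated free-living weeks -> accelerometry arm vs device daily MVPA."""
    if config.n_subjects_freeliving < 1:
        raise ValueError("free-living validation requires at least 1 subject")
    params = config.params()
    ids, crit, dev = [], [], []
    for subject in make_cohort(config.n_subjects_freeliving, config.seed + 1):
        stream, device_daily, log, _truth = simulate_free_living_week(
            subject, params, days=config.days, rate_hz=config.rate_hz,
            daily_mvpa_min=config.daily_mvpa_min,
        )
        _, daily, mean_mvpa, _cal = process_free_living(
            stream, log, cuts=config.cutpoints, epoch_s=config.epoch_s,
            window_min=config.choi_window_min,
            spike_tolerance_min=config.choi_spike_min,
            flank_min=config.choi_flank_min,
            min_wear_min=config.min_wear_min,
        )
        retained_days = set(daily.loc[daily["retained"], "day"])
        dev_days = device_daily[device_daily["day"].isin(retained_days)]
        ids.append(subject.subject_id)
        crit.append(mean_mvpa)
        dev.append(float(dev_days["device_mvpa_min"].mean()))

    pairs = PairedMeasurements(
        "daily_mvpa_min", tuple(ids), np.asarray(crit), np.asarray(dev)
    )
    return {
        "arm": "freeliving",
        "metrics": {
            "daily_mvpa_min": _metric_block(pairs, config.freeliving_direction)
        },
        "provenance": _provenance(config),
    }


def report_to_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_table(report: dict) -> pd.DataFrame:
    """Delimited-text summary mirroring the usual validation-table layout:
    criterion mean (SD), device mean (SD), mean diff (SE), MAPE."""
    rows = []
    for metric, block in report["metrics"].items():
        agr = block["agreement"]
        rows.append(
            {
                "metric": metric,
                "criterion_mean": round(block["criterion_mean"], 1),
                "criterion_sd": round(block["criterion_sd"], 1),
                "device_mean": round(block["device_mean"], 1),
                "device_sd": round(block["device_sd"], 1),
                "mean_diff": round(agr["mean_bias"], 1),
                "diff_se": round(agr["se_bias"], 1),
                "mape_pct": round(agr["mape_pct"], 1),
                "ez_pct": round(block["equivalence"]["ez_pct"], 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figures


def bland_altman_figure(pairs: PairedMeasurements, direction: str, path) -> None:
    """Scatter of per-pair means vs differences with the line of equality,
    mean bias, its 95% CI and the limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs, direction=direction)
    from .stats import _differences

    diffs = _differences(pairs, direction)
    means = (np.asarray(pairs.criterion) + np.asarray(pairs.device)) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, color="k", s=20)
    ax.axhline(0.0, color="b", ls=":", label="line of equality")
    ax.axhline(res.mean_bias, color="k", label="mean bias")
    for b in res.bias_ci95:
        ax.axhline(b, color="r", ls=":", label="bias 95% CI")
    for b in (res.loa_low, res.loa_high):
        ax.axhline(b, color="gray", ls="--", label="95% LoA")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=7)
    ax.set_xlabel(f"mean of criterion and device ({pairs.metric_name})")
    ax.set_ylabel(f"difference ({direction.replace('_', ' ')})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def equivalence_figure(result, path) -> None:
    """Device 90% CI bar against the minimal equivalence-zone bounds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 2.5))
    lo, hi = result.device_ci90
    ax.plot([lo, hi], [1, 1], lw=6, color="tab:blue", label="device 90% CI")
    for b in result.ez_bounds:
        ax.axvline(b, color="k", ls="--")
    ax.axvline(result.criterion_mean, color="k")
    ax.set_yticks([])
    ax.set_title(
        f"{result.metric_name}: EZ ±{result.ez_pct}% "
        f"({'equivalent' if result.equivalent_within_ez else 'not equivalent'})"
    )
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_outputs(report: dict, config: RunConfig) -> Path:
    """Persist report JSON + summary table under the configured directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    arm = report["arm"]
    report_to_json(report, out / f"{arm}_report.json")
    report_table(report).to_csv(out / f"{arm}_table.csv", index=False)
    return out
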