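"""File formats and configuration: series CSV, truth/fit JSON, reports.

Series travel as long-format CSV with columns animal_id, group, phase,
timestamp, temperature_c.  Timestamps are ISO 8601 (clock time is needed to
assign noise regimes); numeric values are accepted as minutes since phase
start provided a phase-start clock hour is supplied.  Ground-truth
parameters and fit results serialise to JSON; comparison reports emit JSON
plus a small human-readable text table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    FullModelParams,
    NoiseParams,
    TrendParams,
    VanDerPolParams,
)
from .simulate import STUDY_EPOCH, TemperatureSeries

__all__ = [
    "REQUIRED_COLUMNS",
    "read_series",
    "write_series",
    "write_truth",
    "read_truth",
    "fits_to_summary",
    "write_fits_json",
    "report_to_dict",
    "format_report_text",
    "config_hash",
    "load_config",
]

logger = logging.getLogger("circavdp")

REQUIRED_COLUMNS = ("animal_id", "group", "phase", "timestamp", "temperature_c")


def write_series(series_list, path) -> None:
    """Write series as long CSV (6-decimal temperatures, ISO timestamps)."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "phase": s.phase,
                    "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "temperature_c": np.round(s.temperature, 6),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def _series_from_frame(key, frame, dt_expected=None) -> TemperatureSeries:
    animal, phase = key
    frame = frame.sort_values("timestamp")
    ts = frame["timestamp"]
    if ts.duplicated().any():
        raise ValueError(
            f"duplicate timestamps for animal {animal!r}, phase {phase!r}"
        )
    diffs = ts.diff().dropna().dt.total_seconds() / 60.0
    dt = float(np.median(diffs)) if len(diffs) else (dt_expected or 3.0)
    if len(diffs) and not np.allclose(diffs, dt):
        n_gaps = int(np.sum(~np.isclose(diffs, dt)))
        logger.warning(
            "animal %s phase %s: %d non-uniform sampling gaps (median dt %.3g min)",
            animal, phase, n_gaps, dt,
        )
    return TemperatureSeries(
        animal_id=str(animal),
        group=str(frame["group"].iloc[0]),
        phase=str(phase),
        temperature=frame["temperature_c"].to_numpy(dtype=float),
        start=ts.iloc[0],
        dt_minutes=dt,
    )


def read_series(path, start_hour: float = 6.0) -> list:
    """Read and validate a long-format series CSV.

    Rows with missing temperature are dropped (count logged); rows are
    canonicalised to timestamp order.  Numeric timestamps are interpreted
    as minutes since phase start beginning at ``start_hour`` o'clock.
    Returns one :class:`TemperatureSeries` per (animal, phase), sorted.
    """
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    n_nan = int(df["temperature_c"].isna().sum())
    if n_nan:
        logger.warning("%s: dropping %d rows with missing temperature", path, n_nan)
        df = df.dropna(subset=["temperature_c"])
    if df.empty:
        raise ValueError(f"{path}: no usable rows")
    raw_ts = df["timestamp"]
    numeric = pd.to_numeric(raw_ts, errors="coerce")
    if numeric.notna().all():
        base = STUDY_EPOCH.normalize() + pd.Timedelta(hours=start_hour)
        df = df.assign(timestamp=base + pd.to_timedelta(numeric, unit="m"))
    else:
        parsed = pd.to_datetime(raw_ts, errors="coerce", format="ISO8601")
        if parsed.isna().any():
            bad = raw_ts[parsed.isna()].iloc[0]
            raise ValueError(f"{path}: unparseable timestamp {bad!r}")
        df = df.assign(timestamp=parsed)
    out = [
        _series_from_frame(key, frame)
        for key, frame in df.groupby(["animal_id", "phase"], sort=True)
    ]
    return out


def _params_to_dict(p: FullModelParams) -> dict:
    return {
        "a0": p.vdp.a0,
        "gamma": p.vdp.gamma,
        "epsilon": p.vdp.epsilon,
        "psi": p.vdp.psi,
        "tau": p.vdp.tau,
        "c0": p.trend.c0,
        "c1": p.trend.c1,
        "var_day1": p.noise.var_day1,
        "var_day2": p.noise.var_day2,
        "var_night": p.noise.var_night,
    }


def _params_from_dict(d: dict) -> FullModelParams:
    return FullModelParams(
        vdp=VanDerPolParams(
            a0=d["a0"], gamma=d["gamma"], epsilon=d["epsilon"],
            psi=d["psi"], tau=d.get("tau", 24.0),
        ),
        trend=TrendParams(c0=d["c0"], c1=d["c1"]),
        noise=NoiseParams(
            var_day1=d["var_day1"], var_day2=d["var_day2"], var_night=d["var_night"]
        ),
    )


def write_truth(param_table, groups, path) -> None:
    """Ground-truth sidecar JSON for a simulated study."""
    payload = {
        "groups": dict(groups),
        "params": {
            animal: {phase: _params_to_dict(p) for phase, p in phases.items()}
            for animal, phases in param_table.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path):
    """Inverse of :func:`write_truth`: returns (param_table, groups)."""
    payload = json.loads(Path(path).read_text())
    table = {
        animal: {phase: _params_from_dict(d) for phase, d in phases.items()}
        for animal, phases in payload["params"].items()
    }
    return table, payload["groups"]


def fits_to_summary(fits) -> pd.DataFrame:
    """Flat one-row-per-(animal, phase) summary of fits (full precision)."""
    rows = []
    for f in fits:
        p = f.params
        rows.append(
            {
                "animal_id": f.animal_id,
                "group": f.group,
                "phase": f.phase,
                **_params_to_dict(p),
                "a_T": f.a_at_T,
                "nll": f.negloglik,
                "aic": f.aic,
                "n_obs": f.n_obs,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


def write_fits_json(fits, path) -> None:
    """Full fit records (estimates, bounds, initials, diagnostics) as JSON."""
    records = []
    for f in fits:
        records.append(
            {
                "animal_id": f.animal_id,
                "group": f.group,
                "phase": f.phase,
                "params": _params_to_dict(f.params),
                "a_at_T": f.a_at_T,
                "duration_hours": f.duration_hours,
                "negloglik": f.negloglik,
                "aic": f.aic,
                "n_obs": f.n_obs,
                "converged": f.converged,
                "bounds": {k: list(v) for k, v in f.bounds.items()},
                "initial": f.initial,
                "n_free_params": f.n_free_params,
                "time_unit": f.time_unit,
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def report_to_dict(report: dict) -> dict:
    """Comparison report (from :func:`circavdp.inference.compare_study`) as JSON-ready dict."""
    out: dict = {"mean_diff_P2_P3": {}}
    for group, res in report["mean_diff_P2_P3"].items():
        out["mean_diff_P2_P3"][group] = res.to_dict()
    out["ratio_noninferiority"] = report["ratio_noninferiority"].to_dict()
    return out


def _fmt_ci(lo: float, hi: float) -> str:
    left = "(-inf" if lo == -float("inf") else f"({lo:.4f}"
    right = "inf)" if hi == float("inf") else f"{hi:.4f}]"
    return f"{left}, {right}"


def format_report_text(report: dict) -> str:
    """Human-readable report table (4-decimal, Tables-style layout)."""
    lines = ["Mean differences gamma_P2 - gamma_P3 (one-sided bootstrap CI)", ""]
    lines.append(f"{'group':<12}{'estimate':>10}  CI")
    for group, res in report["mean_diff_P2_P3"].items():
        lines.append(
            f"{group:<12}{res.estimate:>10.4f}  {_fmt_ci(res.ci_lower, res.ci_upper)}"
        )
    r = report["ratio_noninferiority"]
    lines += [
        "",
        "Reconstruction-ratio non-inferiority test "
        f"(margin {r.margin}, alpha {r.alpha})",
        "",
        f"{'estimator':<24}{'estimate':>10}  CI{'':<18}p",
        f"{'median(ref)-median(test)':<24}{r.estimate:>10.4f}  "
        f"{_fmt_ci(r.ci_lower, r.ci_upper):<20}{r.p_value:.4f}",
        f"H0 (difference >= {r.margin}) {'rejected' if r.reject else 'not rejected'}",
    ]
    return "\n".join(lines) + "\n"


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (key order irrelevant)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> dict:
    """Load a YAML (or JSON — valid YAML) run configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
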