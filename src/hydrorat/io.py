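"""Writing and re-reading simulation outputs (CSV series, JSON summaries)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from .config import params_to_dict
from .engine import SimulationSummary, TimeSeries

__all__ = ["write_series_csv", "read_series_csv", "write_summary_json",
           "summary_to_dict"]

_UNITS_COMMENT = (
    "# units: t_min [min], na_conc [mmol/L], ecf_v/icf_v/stomach_v/intestine_v [ml], "
    "avp/avp_base [pg/ml], urine_flow/intake_ml [ml/min and ml], urine_na/intake_na [mmol], "
    "cumulative columns [ml or mmol]; minute 0 = 08:00"
)


def write_series_csv(series: TimeSeries, path: str | Path) -> Path:
    """Write the per-minute series as an RFC-4180-style CSV with a units comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = series.frame.copy()
    frame.insert(4, "clock", [f"{tod // 60:02d}:{tod % 60:02d}"
                              for tod in frame["time_of_day"]])
    with path.open("w") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        frame.to_csv(fh, index=False)
    return path


def read_series_csv(path: str | Path) -> pd.DataFrame:
    """Re-read a series CSV written by :func:`write_series_csv`."""
    return pd.read_csv(path, comment="#")


def summary_to_dict(summary: SimulationSummary) -> dict[str, Any]:
    out: dict[str, Any] = {
        "means": summary.means,
        "sds": summary.sds,
        "sleeping": summary.sleeping,
        "waking": summary.waking,
        "daily": summary.daily.reset_index().to_dict(orient="list"),
    }
    if summary.phases is not None:
        out["phases"] = {
            "restoration_onset_min": summary.phases.restoration_onset,
            "maintenance_onset_min": summary.phases.maintenance_onset,
            "maintenance_threshold_pg_ml": summary.phases.maintenance_threshold,
        }
    if summary.config:
        out["config"] = summary.config
    return out


def write_summary_json(summary: SimulationSummary, series: TimeSeries,
                       path: str | Path) -> Path:
    """Write the run summary as JSON, echoing the configuration used."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = summary_to_dict(summary)
    payload["config"] = {
        "params": params_to_dict(series.params),
        "protocol": series.protocol.name,
        "days": series.days,
        "seed": series.seed,
    }
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return path
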