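"""CSV/JSON writers for simulation outputs.

All outputs are plain text: an RFC-4180 time-series CSV, a line-per-event
log CSV and a JSON metadata file carrying the fully resolved configuration
and seeds, so any run can be reproduced from its own outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

from .engine import SimulationResult

__all__ = ["write_timeseries", "write_events", "write_metadata", "write_run"]

#: float formatting: 15 significant digits, enough to round-trip to ~1e-15.
_FLOAT_FMT = "%.15g"


def write_timeseries(result: SimulationResult, path: str | Path) -> Path:
    """Write the uniform-grid trajectories as CSV (header always present)."""
    path = Path(path)
    result.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_events(result: SimulationResult, path: str | Path) -> Path:
    """Write the event log, one line per discrete event, sorted by time."""
    path = Path(path)
    result.events_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_metadata(result: SimulationResult, path: str | Path) -> Path:
    """Write the fully resolved run configuration as JSON."""
    path = Path(path)
    path.write_text(json.dumps(result.metadata, indent=2, sort_keys=True) + "\n")
    return path


def write_run(result: SimulationResult, out_dir: str | Path, stem: str = "run") -> dict[str, Path]:
    """Write time series, events and metadata side by side under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "timeseries": write_timeseries(result, out / f"{stem}_timeseries.csv"),
        "events": write_events(result, out / f"{stem}_events.csv"),
        "metadata": write_metadata(result, out / f"{stem}_metadata.json"),
    }
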