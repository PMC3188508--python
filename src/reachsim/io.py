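"""Tabular output, run provenance and canned paradigm fixtures.

Every run writes `trials.csv` (one row per movement, all angles in degrees),
`metrics.json`, the fully resolved `config_resolved.yaml` and a small run log
recording the seed and package versions, so any figure or number can be traced
back to exact constants.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig, save_config
from .protocols import PARADIGMS, TrialRecord, records_to_frame

__all__ = ["write_outputs", "generate_fixtures", "FIXTURE_NAMES"]

# the six figure paradigms plus a tiny smoke schedule
FIXTURE_NAMES = (
    "washout_retest",
    "long_term_savings",
    "aba_interference",
    "gradual",
    "error_clamp",
    "rebound",
    "smoke",
)


def write_outputs(
    records: list[TrialRecord],
    metrics: dict,
    out_dir: str | FsPath,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, FsPath]:
    """Write trials.csv, metrics.json, config_resolved.yaml and run.log."""
    out = FsPath(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    files: dict[str, FsPath] = {}
    df = records_to_frame(records)
    files["trials"] = out / "trials.csv"
    df.to_csv(files["trials"], index=False, float_format="%.12g")

    files["metrics"] = out / "metrics.json"
    files["metrics"].write_text(json.dumps(metrics, indent=2, default=_jsonify))

    if cfg is not None:
        files["config"] = out / "config_resolved.yaml"
        save_config(cfg, files["config"])

    files["log"] = out / "run.log"
    lines = [
        f"time: {datetime.now(timezone.utc).isoformat()}",
        f"seed: {seed}",
        f"python: {platform.python_version()}",
        f"numpy: {np.__version__}",
        f"pandas: {pd.__version__}",
        f"n_trials: {len(records)}",
    ]
    files["log"].write_text("\n".join(lines) + "\n")
    return files


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def generate_fixtures(out_dir: str | FsPath) -> dict[str, FsPath]:
    """Emit one ready-to-run config per figure paradigm plus a 5-trial smoke
    schedule for quick end-to-end checks."""
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, FsPath] = {}
    base = RunConfig().model_dump(mode="json")
    for name in FIXTURE_NAMES:
        cfg = dict(base)
        meta = {"paradigm": name if name != "smoke" else "abrupt"}
        if name == "smoke":
            cfg = dict(base)
            cfg["protocol"] = dict(base["protocol"])
            cfg["protocol"]["adapt_trials"] = 4
            cfg["protocol"]["intersession_washout"] = 0
            meta["overrides"] = {"baseline_trials": 1}
        path = out / f"{name}.yaml"
        payload = {"config": cfg, **meta}
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        written[name] = path
    return written


def load_fixture(path: str | FsPath) -> tuple[RunConfig, str, dict]:
    """Read a fixture file back into (config, paradigm name, overrides)."""
    data = yaml.safe_load(FsPath(path).read_text())
    cfg = RunConfig(**data["config"])
    return cfg, data["paradigm"], data.get("overrides", {})
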