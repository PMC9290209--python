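"""Run manifests and result-table emission.

Outputs are diff-able text: CSV tables written with a fixed column order
and 10-significant-digit floats, plus a JSON manifest tying every output
of a run to its configuration hash and master seed, so a run can be
reproduced byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__ as _version

FLOAT_FORMAT = "%.10g"


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    package_version: str = _version
    scenario_runtimes: dict[str, float] = field(default_factory=dict)
    flagged_replicates: dict[str, int] = field(default_factory=dict)
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @staticmethod
    def hash_config(payload) -> str:
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def emit_report(metrics: pd.DataFrame, manifest: RunManifest, out_dir: str | Path,
                records: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write metrics.csv (+ optional records.csv) and manifest.json.

    Refuses empty metrics before touching the filesystem, so a failed run
    leaves no partial output behind.
    """
    if metrics is None or metrics.empty:
        raise ValueError("metrics table is empty; nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format=FLOAT_FORMAT)
    written["metrics"] = metrics_path
    if records is not None and not records.empty:
        records_path = out / "records.csv"
        records.to_csv(records_path, index=False, float_format=FLOAT_FORMAT)
        written["records"] = records_path
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    return written
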