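"""Result output: per-trial CSV, summary JSON, optional events JSONL
and trajectory CSV.  Every file embeds the config hash and seed so runs
are traceable and byte-identical under the same (config, seed)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import WorldConfig


def write_outputs(
    cfg: WorldConfig,
    seed: int,
    trials: pd.DataFrame,
    summary: dict,
    out_dir: str | Path,
    events: Optional[pd.DataFrame] = None,
    trajectory: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Write protocol outputs under out_dir; returns the file map."""
    if trials is None or len(trials) == 0:
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    written: dict[str, Path] = {}

    trials = trials.copy()
    trials.insert(0, "config_hash", chash)
    trials.insert(1, "seed", seed)
    p = out / "trials.csv"
    trials.to_csv(p, index=False, lineterminator="\n")
    written["trials"] = p

    payload = {"config_hash": chash, "seed": seed, **summary}
    p = out / "summary.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written["summary"] = p

    if events is not None:
        p = out / "events.jsonl"
        with open(p, "w") as fh:
            for rec in events.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
        written["events"] = p

    if trajectory is not None:
        p = out / "trajectory.csv"
        traj = trajectory.copy()
        traj.insert(0, "config_hash", chash)
        traj.to_csv(p, index=False, lineterminator="\n")
        written["trajectory"] = p

    return written
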