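"""Output helpers shared by the CLI and the analysis drivers.

Monetary amounts are reported to the nearest pound (internal arithmetic is
full precision); every output directory receives a run manifest with a
checksum of the canonicalised configuration so a run can be reproduced
exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .cea import ArmResult, Comparison
from .params import ParameterSet

__all__ = [
    "RunManifest",
    "config_checksum",
    "write_manifest",
    "write_json",
    "arm_results_frame",
    "comparisons_frame",
]


class RunManifest(BaseModel):
    tool_version: str
    config_checksum: str
    seed: int | None
    timestamp: str
    subcommand: str


def config_checksum(params: ParameterSet) -> str:
    canonical = json.dumps(params.raw, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_manifest(
    out_dir: Path, subcommand: str, params: ParameterSet, seed: int | None = None
) -> RunManifest:
    manifest = RunManifest(
        tool_version=__version__,
        config_checksum=config_checksum(params),
        seed=seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        subcommand=subcommand,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(manifest.model_dump_json(indent=2) + "\n")
    return manifest


def _round_money(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _round_money(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_money(v) for v in obj]
    return obj


def write_json(path: Path, payload: dict[str, Any]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def arm_results_frame(results: dict[str, ArmResult]) -> pd.DataFrame:
    rows = []
    for arm, r in results.items():
        row: dict[str, Any] = {
            "arm": arm,
            "total_cost_gbp": round(r.total_cost),
            "total_qalys": round(r.total_qalys, 3),
        }
        row.update({f"cost_{k}_gbp": round(v) for k, v in r.cost_by_category.items()})
        row.update({f"cost_state_{k}_gbp": round(v) for k, v in r.cost_by_state.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_frame(comparisons: dict[str, Comparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons.values():
        rows.append(
            {
                "reference": c.reference,
                "comparator": c.comparator,
                "delta_cost_gbp": round(c.delta_cost),
                "delta_qalys": round(c.delta_qalys, 3),
                "icer_gbp_per_qaly": (
                    None if c.icer is None else round(c.icer)
                ),
                "classification": c.classification.value,
                "nmb_difference_gbp": round(c.nmb_difference),
            }
        )
    return pd.DataFrame(rows)
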