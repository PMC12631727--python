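"""Result records: the oscillator table plus everything needed to reproduce it.

A :class:`ResultRecord` bundles the estimated oscillator table (amplitudes,
phases, frequencies, dampings, uncertainties, multiplet membership and purge
status), the grid geometry, the regions analysed, the processing settings and
full provenance (seeds, filter settings, regularizer weight, threshold,
package version).  On disk it is a JSON metadata file next to a plain CSV
table readable by any generic tool.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpInfo, Oscillator2D

__all__ = ["ResultRecord", "write_result", "read_result", "SCHEMA_VERSION", "build_table"]

SCHEMA_VERSION = 1

TABLE_COLUMNS = [
    "index",
    "a",
    "a_err",
    "phi",
    "phi_err",
    "f1",
    "f1_err",
    "f2",
    "f2_err",
    "pure_shift_freq",
    "eta1",
    "eta2",
    "multiplet_id",
    "purged",
    "purge_reason",
]


def build_table(
    oscillators: list[Oscillator2D],
    errors: np.ndarray | None = None,
    multiplet_ids: list[int] | None = None,
    purged_flags: list[bool] | None = None,
    purge_reasons: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the canonical oscillator table.

    ``pure_shift_freq`` always equals ``f2 - f1``; purged rows carry
    ``multiplet_id = -1`` and a reason.
    """
    m = len(oscillators)
    if errors is None:
        errors = np.full((m, 6), np.nan)
    errors = np.asarray(errors, dtype=float).reshape(m, 6) if m else np.empty((0, 6))
    rows = []
    for i, osc in enumerate(oscillators):
        rows.append(
            {
                "index": i,
                "a": osc.amplitude,
                "a_err": errors[i, 0],
                "phi": osc.phase,
                "phi_err": errors[i, 1],
                "f1": osc.f1,
                "f1_err": errors[i, 2],
                "f2": osc.f2,
                "f2_err": errors[i, 3],
                "pure_shift_freq": osc.f2 - osc.f1,
                "eta1": osc.eta1,
                "eta2": osc.eta2,
                "multiplet_id": multiplet_ids[i] if multiplet_ids is not None else -1,
                "purged": bool(purged_flags[i]) if purged_flags is not None else False,
                "purge_reason": purge_reasons[i] if purge_reasons is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@dataclass
class ResultRecord:
    table: pd.DataFrame
    expinfo: ExpInfo
    regions: list[tuple[float, float]] = field(default_factory=list)
    processing: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"oscillator table missing required column(s): {missing}")

    def oscillators(self, include_purged: bool = False) -> list[Oscillator2D]:
        rows = self.table if include_purged else self.table[~self.table["purged"]]
        return [
            Oscillator2D(r.a, r.phi, r.f1, r.f2, r.eta1, r.eta2)
            for r in rows.itertuples(index=False)
        ]


def _expinfo_to_dict(info: ExpInfo) -> dict:
    d = dataclasses.asdict(info)
    d["points"] = list(d["points"])
    d["dwell"] = list(d["dwell"])
    d["offset"] = list(d["offset"])
    return d


def _expinfo_from_dict(d: dict) -> ExpInfo:
    return ExpInfo(
        points=tuple(d["points"]),
        dwell=tuple(d["dwell"]),
        offset=tuple(d.get("offset", (0.0, 0.0))),
        sfo=d.get("sfo"),
    )


def write_result(record: ResultRecord, path: str | Path) -> Path:
    """Write ``<path>.json`` (metadata) and ``<path>.csv`` (oscillator table)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record.table.to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "expinfo": _expinfo_to_dict(record.expinfo),
        "regions": [list(r) for r in record.regions],
        "processing": record.processing,
        "provenance": record.provenance,
        "table_file": path.with_suffix(".csv").name,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return path.with_suffix(".json")


def read_result(path: str | Path) -> ResultRecord:
    """Inverse of :func:`write_result` (fields round-trip up to float printing)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"result schema version mismatch: file has {version}, reader supports {SCHEMA_VERSION}"
        )
    table = pd.read_csv(
        path.with_suffix(".json").parent / meta["table_file"],
        dtype={"purge_reason": str},
        keep_default_na=False,
        na_values=[""],
    )
    table["purge_reason"] = table["purge_reason"].fillna("")
    return ResultRecord(
        table=table,
        expinfo=_expinfo_from_dict(meta["expinfo"]),
        regions=[tuple(r) for r in meta.get("regions", [])],
        processing=meta.get("processing", {}),
        provenance=meta.get("provenance", {}),
    )
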