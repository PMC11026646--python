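"""Ground-truth records for synthetic scenes.

Every rendered object (mitochondrion, calibration patch, bouton terminus,
synapse overlap, spike) gets exactly one record, so parameter-recovery tests
can compare pipeline output against the simulation truth.  Records are kept
in a single long-form DataFrame with a ``kind`` column; per-scene scalars
(geometry, calibrations, couplings) live in ``meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GroundTruth:
    objects: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "kind" not in self.objects.columns:
            raise ValueError("ground truth needs a 'kind' column")
        for col in ("speed_um_s", "lag_ms"):
            if col in self.objects.columns:
                vals = self.objects[col].dropna().to_numpy(dtype=float)
                if vals.size and not np.all(np.isfinite(vals)):
                    raise ValueError(f"non-finite values in truth column {col}")
        if "lag_ms" in self.objects.columns:
            lags = self.objects["lag_ms"].dropna()
            if len(lags) and (lags.abs() > 100).any():
                raise ValueError("coupling lags must lie within [-100, 100] ms")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.objects[self.objects["kind"] == kind].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.objects)

    def to_csv(self, path) -> None:
        self.objects.to_csv(path, index=False)

    def to_json(self, path) -> None:
        """Sidecar with the scene metadata (not the per-object table)."""
        with open(path, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return str(obj)


def empty_truth(columns: tuple[str, ...] = ("kind",), meta: dict | None = None) -> GroundTruth:
    cols = ("kind",) + tuple(c for c in columns if c != "kind")
    return GroundTruth(pd.DataFrame({c: [] for c in cols}), meta or {})
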