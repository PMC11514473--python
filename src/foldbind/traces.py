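"""Time-resolved fluorescence traces and their on-disk form.

A trace is a (time, signal) record with the experimental conditions
attached: total protein concentration and denaturant for refolding
relaxations, dimer / competitor concentrations for DNA-binding
experiments.  On disk a trace is a two-column CSV (``time_s,signal``)
with a JSON sidecar holding the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

MIN_POINTS = 10


@dataclass
class RelaxationTrace:
    """One time-resolved fluorescence record plus conditions.

    Parameters
    ----------
    time : array of float
        Time in seconds, strictly increasing.
    signal : array of float
        Fluorescence in arbitrary units, same length as ``time``.
    protein_total : float, optional
        Total monomer concentration P_T (molar); required for
        dimerization relaxation fits, must be positive when given.
    urea : float, optional
        Final denaturant concentration (molar).
    meta : dict
        Free-form condition metadata (dimer_conc_M, competitor_M, seed,
        ground truth ...).
    """

    time: np.ndarray
    signal: np.ndarray
    protein_total: float | None = None
    urea: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays")
        if self.time.size != self.signal.size:
            raise ValueError(
                f"time and signal lengths differ ({self.time.size} vs {self.signal.size})"
            )
        if self.time.size < MIN_POINTS:
            raise ValueError(f"trace needs >= {MIN_POINTS} points, got {self.time.size}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.protein_total is not None and self.protein_total <= 0:
            raise ValueError(f"protein_total must be positive, got {self.protein_total}")

    def __len__(self) -> int:
        return int(self.time.size)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> Path:
        """Write ``time_s,signal`` CSV plus a ``.meta.json`` sidecar."""
        path = Path(path)
        pd.DataFrame({"time_s": self.time, "signal": self.signal}).to_csv(
            path, index=False, float_format="%.17g")
        sidecar = {
            "protein_total_M": self.protein_total,
            "urea_M": self.urea,
            **_jsonable(self.meta),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "RelaxationTrace":
        path = Path(path)
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"{path}: malformed trace CSV: {exc}") from exc
        for col in ("time_s", "signal"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        bad = df.index[df[["time_s", "signal"]].isna().any(axis=1)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: non-numeric or missing value at line {bad[0] + 2}")
        meta: dict[str, Any] = {}
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            time=df["time_s"].to_numpy(),
            signal=df["signal"].to_numpy(),
            protein_total=meta.pop("protein_total_M", None),
            urea=meta.pop("urea_M", None),
            meta=meta,
        )


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and dataclass-likes."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
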