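"""Flow-cytometry computations: singlet gating, cell concentrations,
storage-compound gating, and intensity summaries.

Event tables carry scatter (FSC-H, SSC-H) and fluorescence channels
(BL1-H/BL1-A for SYBR Green / BODIPY, BL3-H for propidium iodide, RL1-H
for the SYTO 62 nucleic-acid counterstain) plus acquisition metadata
(recorded volume, dilution).  Stain intensity is treated as a linear
proxy for content, so medians of gated intensities are the reported
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

CHANNELS = ("FSC-H", "SSC-H", "BL1-H", "BL1-A", "BL3-H", "RL1-H")


class CytometryError(ValueError):
    """Raised for invalid event tables or gate parameters."""


@dataclass
class EventTable:
    """Per-event channel intensities plus acquisition metadata."""

    events: pd.DataFrame
    volume_ml: float = 0.075  # default: 75 uL recorded volume
    dilution: float = 1.0
    panel: str = "SG"

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise CytometryError(f"non-positive recorded volume {self.volume_ml}")
        if self.dilution < 1:
            raise CytometryError(f"dilution factor {self.dilution} < 1")
        present = [c for c in CHANNELS if c in self.events.columns]
        if len(self.events) and present:
            vals = self.events[present].to_numpy(dtype=float)
            if (vals < 0).any():
                raise CytometryError("negative channel intensities")

    def __len__(self) -> int:
        return len(self.events)

    def require(self, *channels: str) -> None:
        missing = [c for c in channels if c not in self.events.columns]
        if missing:
            raise CytometryError(f"missing channel(s): {missing}")


@dataclass
class GateResult:
    """Boolean per-event mask with the gate's name and parameters."""

    mask: np.ndarray
    name: str
    params: dict = field(default_factory=dict)

    def count(self) -> int:
        return int(self.mask.sum())


def gate_singlets(
    events: EventTable, r_lo: float = 0.7, r_hi: float = 1.3
) -> GateResult:
    """Discriminate singlets from aggregates on the primary fluorescence
    channel's area/height ratio.

    An event is kept iff its BL1-A/BL1-H ratio, normalized by the
    population median ratio, lies within [r_lo, r_hi].  Doublets (summed
    area, near-single height) sit near twice the median and are rejected
    at the defaults.
    """
    events.require("BL1-H", "BL1-A")
    n = len(events)
    params = {"r_lo": r_lo, "r_hi": r_hi}
    if n == 0:
        return GateResult(mask=np.zeros(0, dtype=bool), name="singlets", params=params)
    height = events.events["BL1-H"].to_numpy(dtype=float)
    area = events.events["BL1-A"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(height > 0, area / np.where(height > 0, height, 1.0), np.inf)
    med = float(np.median(ratio[np.isfinite(ratio)])) if np.isfinite(ratio).any() else 1.0
    rel = ratio / med if med > 0 else ratio
    mask = (rel >= r_lo) & (rel <= r_hi)
    params["median_ratio"] = med
    return GateResult(mask=mask, name="singlets", params=params)


def cell_concentration(
    events: EventTable,
    gate: GateResult | None = None,
    threshold_bl1: float = 0.0,
    pi_threshold: float | None = None,
) -> dict[str, float]:
    """Cell concentrations (cells/mL) from gated, stain-positive events.

    concentration = qualifying events / recorded volume (mL) x dilution.
    With a propidium-iodide threshold (SGPI panel) the qualifying events
    are split into intact (BL3-H <= threshold) and damaged, with
    damaged = total - intact exactly.
    """
    events.require("BL1-H")
    if gate is None:
        gate = gate_singlets(events)
    bl1 = events.events["BL1-H"].to_numpy(dtype=float)
    qualify = gate.mask & (bl1 > threshold_bl1)
    scale = events.dilution / events.volume_ml
    out = {"total_per_ml": float(qualify.sum()) * scale}
    if pi_threshold is not None:
        events.require("BL3-H")
        bl3 = events.events["BL3-H"].to_numpy(dtype=float)
        intact = qualify & (bl3 <= pi_threshold)
        out["intact_per_ml"] = float(intact.sum()) * scale
        out["damaged_per_ml"] = out["total_per_ml"] - out["intact_per_ml"]
    return out


def pha_positive(
    events: EventTable,
    ssc_thresh: float,
    syto62_thresh: float,
    bodipy_thresh: float,
) -> tuple[GateResult, float]:
    """Triple-threshold gate for storage-polymer-positive cells.

    Applied in order: low SSC-H threshold, SYTO 62 (RL1-H) threshold to
    select nucleic-acid-containing cells, then the minor BODIPY (BL1-H)
    threshold.  Returns the gate (with per-stage retained counts logged)
    and the positive fraction of all events.
    """
    if min(ssc_thresh, syto62_thresh, bodipy_thresh) < 0:
        raise CytometryError("thresholds must be >= 0")
    events.require("SSC-H", "RL1-H", "BL1-H")
    df = events.events
    stage1 = df["SSC-H"].to_numpy(dtype=float) > ssc_thresh
    stage2 = stage1 & (df["RL1-H"].to_numpy(dtype=float) > syto62_thresh)
    stage3 = stage2 & (df["BL1-H"].to_numpy(dtype=float) > bodipy_thresh)
    n = len(events)
    gate = GateResult(
        mask=stage3,
        name="pha_positive",
        params={
            "ssc_thresh": ssc_thresh,
            "syto62_thresh": syto62_thresh,
            "bodipy_thresh": bodipy_thresh,
            "retained_per_stage": [int(stage1.sum()), int(stage2.sum()), int(stage3.sum())],
        },
    )
    fraction = float(stage3.sum()) / n if n else 0.0
    return gate, fraction


def intensity_summary(
    events: EventTable, gate: GateResult, channel: str
) -> float:
    """Median channel intensity (A.U.) over gated events.

    The median is used because fluorescence distributions are heavy-
    tailed; intensity is assumed linear in content, so the median scales
    with it.  An empty gate yields NaN with a warning.
    """
    events.require(channel)
    vals = events.events.loc[gate.mask, channel].to_numpy(dtype=float)
    if vals.size == 0:
        warnings.warn(f"empty gate {gate.name!r}; no {channel} summary", stacklevel=2)
        return float("nan")
    return float(np.median(vals))


def valley_threshold(values: np.ndarray) -> float:
    """Auto-threshold at the minimum-density valley between the two
    largest KDE modes of a (log-scaled) intensity distribution."""
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size < 10:
        raise CytometryError("too few positive events for valley estimation")
    logv = np.log10(values)
    kde = stats.gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), 512)
    dens = kde(grid)
    # local maxima, two largest
    peaks = [i for i in range(1, 511) if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]]
    if len(peaks) < 2:
        raise CytometryError("fewer than two density modes; set threshold manually")
    top2 = sorted(sorted(peaks, key=lambda i: -dens[i])[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(10 ** grid[valley])


# ---------------------------------------------------------------------------
# I/O: CSV event table with JSON sidecar metadata.

def read_events(csv_path: str | Path, meta_path: str | Path | None = None) -> EventTable:
    import json

    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta: Mapping = {}
    if meta_path is None:
        candidate = csv_path.with_suffix(".json")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    return EventTable(
        events=df,
        volume_ml=float(meta.get("volume_mL", 0.075)),
        dilution=float(meta.get("dilution_factor", 1.0)),
        panel=str(meta.get("panel", "SG")),
    )


def write_events(table: EventTable, csv_path: str | Path) -> None:
    import json

    csv_path = Path(csv_path)
    table.events.to_csv(csv_path, index=False)
    meta = {
        "volume_mL": table.volume_ml,
        "dilution_factor": table.dilution,
        "panel": table.panel,
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
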