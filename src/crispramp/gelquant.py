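"""Quantification of in vitro DNA cleavage from gel densitometry.

Band intensities exported from any densitometry tool (one row per lane)
are normalised within each series to the time-zero lane:

    I_rel = intensity / intensity(t0)        (so I_rel(t0) = 1)
    % digestion = (1 - I_rel) * 100

Noise can make a lane brighter than its t0 reference, giving a negative
% digestion; the raw value is always retained and a clamped-to-[0, 100]
display column is reported alongside. Time-lapse series (variable delay
between inhibitor addition and substrate addition, in seconds) are
summarised per condition as mean +/- SD over replicates. Image analysis
itself is out of scope — input is a tidy intensity table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, NormalizationError, ValidationError

INTENSITY_COLUMNS = ["assay_id", "condition", "time_or_delay_s", "lane", "intensity"]


@dataclass(frozen=True)
class DigestionMeasurement:
    assay_id: str
    condition: str
    time_or_delay_s: float
    intensity: float
    i_rel: float

    @property
    def pct_digestion(self) -> float:
        return pct_digestion(self.i_rel)

    @property
    def pct_digestion_display(self) -> float:
        """Raw value clamped to [0, 100] for display."""
        return float(np.clip(self.pct_digestion, 0.0, 100.0))


def relative_intensity(lane_intensity: float, t0_intensity: float) -> float:
    """Substrate remaining relative to the time-zero lane."""
    if t0_intensity <= 0:
        raise NormalizationError(
            f"t0 intensity must be positive, got {t0_intensity}"
        )
    return lane_intensity / t0_intensity


def pct_digestion(i_rel: float) -> float:
    """Fraction of substrate digested, as a percentage."""
    if i_rel < 0:
        raise ValidationError(f"relative intensity must be >= 0, got {i_rel}")
    return (1.0 - i_rel) * 100.0


def predict_fragments(
    substrate_length: int, cut_position: int
) -> tuple[int, int]:
    """Fragment lengths produced by a single blunt cut; conserves
    total length."""
    if not 0 < cut_position < substrate_length:
        raise ValidationError(
            f"cut position {cut_position} not strictly inside "
            f"(0, {substrate_length})"
        )
    return cut_position, substrate_length - cut_position


def quantify_series(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise an intensity table to per-series t0 lanes.

    Each (assay_id, condition) pair is one series and must contain a
    lane at time/delay 0; every lane is expressed relative to it.
    Output adds ``i_rel``, ``pct_digestion`` (raw) and
    ``pct_digestion_display`` (clamped) columns.
    """
    missing = [c for c in INTENSITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"intensity table missing columns: {missing}")
    out = []
    for (assay, cond), grp in table.groupby(["assay_id", "condition"]):
        t0 = grp[grp["time_or_delay_s"] == 0]
        if t0.empty:
            raise NormalizationError(
                f"series ({assay}, {cond}) has no time-zero lane"
            )
        t0_intensity = float(t0["intensity"].iloc[0])
        g = grp.copy()
        g["i_rel"] = [
            relative_intensity(v, t0_intensity) for v in g["intensity"]
        ]
        g["pct_digestion"] = [pct_digestion(v) for v in g["i_rel"]]
        g["pct_digestion_display"] = np.clip(g["pct_digestion"], 0.0, 100.0)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def summarize_timelapse(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, delay) mean +/- SD of % digestion over replicate
    assays; a single replicate leaves the SD empty (NaN). Raw rows are
    left untouched — this returns a separate summary table."""
    if measurements.empty:
        return pd.DataFrame(
            columns=["condition", "time_or_delay_s", "n", "mean_pct", "sd_pct"]
        )
    if "pct_digestion" not in measurements.columns:
        raise ValidationError("run quantify_series first")
    for (cond, delay), grp in measurements.groupby(
        ["condition", "time_or_delay_s"]
    ):
        if grp["assay_id"].duplicated().any():
            raise ConsistencyError(
                f"series ({cond}, {delay}): duplicate assay ids — mixed "
                "series in one cell"
            )
    summary = (
        measurements.groupby(["condition", "time_or_delay_s"], as_index=False)
        .agg(
            n=("pct_digestion", "size"),
            mean_pct=("pct_digestion", "mean"),
            sd_pct=("pct_digestion", lambda v: v.std(ddof=1)),
        )
    )
    return summary


def load_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read a lane-intensity TSV (columns: assay_id, condition,
    time_or_delay_s, lane, intensity)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"intensity table missing columns: {missing}")
    return df
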