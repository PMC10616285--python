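"""Quantification of organoid swelling, size, and immunofluorescence staining.

Forskolin-induced swelling (FIS): total organoid area per well is imaged
every 15 min for 2 h, normalized to t = 0 with the baseline set at 100%, and
summarized as the area under the (percent - 100) curve at t = 120 min, so a
non-swelling control integrates to exactly 0 %*min. Organoid size comes from
detector bounding boxes under a disk-shape assumption (inscribed ellipse,
pi * w * h / 4), averaged per culture well. Staining is quantified as the
fraction of pixels above a fixed threshold shared across compared images.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd


@dataclass
class SwellingSeries:
    well_id: str
    condition: str
    timepoints: np.ndarray  # minutes, strictly increasing from 0
    total_area: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.total_area = np.asarray(self.total_area, dtype=float)
        if len(self.timepoints) != len(self.total_area):
            raise ValueError("timepoints and areas differ in length")
        if self.timepoints[0] != 0:
            raise ValueError("series must start at t = 0")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class NormalizedSwelling:
    well_id: str
    condition: str
    timepoints: np.ndarray
    percent_area: np.ndarray  # 100 * area(t) / area(0)
    auc: float = float("nan")


@dataclass
class OrganoidBox:
    well_id: str
    width: float
    height: float

    @property
    def estimated_area(self) -> float:
        return box_disk_area(self.width, self.height)


def normalize_swelling(series: SwellingSeries) -> NormalizedSwelling:
    """percent_area(t) = 100 * area(t) / area(0); baseline is 100% exactly."""
    a0 = series.total_area[0]
    if a0 <= 0:
        raise ValueError(f"well {series.well_id}: non-positive area at t = 0")
    return NormalizedSwelling(
        well_id=series.well_id,
        condition=series.condition,
        timepoints=series.timepoints.copy(),
        percent_area=100.0 * series.total_area / a0,
    )


def swelling_auc(
    norm: NormalizedSwelling, t_end: float = 120.0, step: float = 15.0
) -> float:
    """Trapezoidal integral of (percent_area - 100) over [0, t_end] in %*min.

    Requires the full 15-min grid up to t_end; gaps are an error rather than
    being interpolated. Shrinkage below baseline gives a negative AUC.
    """
    expected = np.arange(0.0, t_end + step / 2, step)
    present = set(norm.timepoints.tolist())
    gaps = [t for t in expected if t not in present]
    if gaps:
        raise ValueError(f"well {norm.well_id}: missing timepoints {gaps}")
    sel = np.isin(norm.timepoints, expected)
    t = norm.timepoints[sel]
    y = norm.percent_area[sel] - 100.0
    auc = float(np.trapezoid(y, t))
    norm.auc = auc
    return auc


def box_disk_area(width: float, height: float) -> float:
    """Disk/ellipse area inscribed in a (width x height) bounding box."""
    if width <= 0 or height <= 0:
        raise ValueError("bounding-box dimensions must be positive")
    return math.pi * width * height / 4.0


def mean_well_area(boxes: Sequence[OrganoidBox]) -> Dict[str, float]:
    """Arithmetic mean of estimated organoid areas per well."""
    by_well: Dict[str, List[float]] = {}
    for b in boxes:
        by_well.setdefault(b.well_id, []).append(b.estimated_area)
    return {w: float(np.mean(a)) for w, a in sorted(by_well.items())}


def stain_area_fraction(image: np.ndarray, threshold: float) -> float:
    """Fraction of pixels strictly above `threshold` (arbitrary units).

    The same threshold must be applied to every image of a comparison.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    return float(np.mean(image > threshold))


# ---------------------------------------------------------------------------
# Tabular entry points (tidy CSV in, tidy frames out)


def read_swelling_csv(path) -> List[SwellingSeries]:
    """CSV columns: well_id, condition, t_min, total_area."""
    df = pd.read_csv(path)
    required = {"well_id", "condition", "t_min", "total_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: List[SwellingSeries] = []
    for (well, cond), grp in df.groupby(["well_id", "condition"], sort=True):
        grp = grp.sort_values("t_min")
        out.append(
            SwellingSeries(
                str(well), str(cond), grp["t_min"].to_numpy(), grp["total_area"].to_numpy()
            )
        )
    return out


def read_boxes_csv(path) -> List[OrganoidBox]:
    """CSV columns: well_id, width, height (OrgaQuant-style detections)."""
    df = pd.read_csv(path)
    required = {"well_id", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        OrganoidBox(str(r.well_id), float(r.width), float(r.height))
        for r in df.itertuples()
    ]


def fis_table(series: Sequence[SwellingSeries], t_end: float = 120.0) -> pd.DataFrame:
    """Per-well normalized curves and AUC as one tidy frame."""
    rows = []
    for s in series:
        norm = normalize_swelling(s)
        auc = swelling_auc(norm, t_end=t_end)
        for t, pct in zip(norm.timepoints, norm.percent_area):
            rows.append(
                {
                    "well_id": s.well_id,
                    "condition": s.condition,
                    "t_min": t,
                    "percent_area": pct,
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)


def well_area_table(boxes: Sequence[OrganoidBox]) -> pd.DataFrame:
    counts: Dict[str, int] = {}
    for b in boxes:
        counts[b.well_id] = counts.get(b.well_id, 0) + 1
    means = mean_well_area(boxes)
    if not means:
        warnings.warn("no wells with organoids; empty means table")
    return pd.DataFrame(
        [
            {"well_id": w, "n_organoids": counts[w], "mean_area": a}
            for w, a in means.items()
        ]
    )
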