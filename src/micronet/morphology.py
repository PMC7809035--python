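"""Microglial morphometrics from segmented immunofluorescence images.

Cells are connected components of a binary mask; each cell's *compactness*
is the variance of its pixels' radial distances from the centroid divided
by its area, so a round soma scores low and a ramified, branched cell
scores high. Marker positivity (e.g. VASP among TMEM119+ microglia) is
called per cell from a global Otsu threshold on the marker channel.
Compactness is compared between marker groups with a subject-level
random-intercept model, and the per-subject positive fraction is regressed
on ordinal pathology stage scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "CellRecord",
    "segment_cells",
    "compactness",
    "call_positivity",
    "cells_to_frame",
    "compare_compactness",
    "positivity_vs_stage",
]

logger = logging.getLogger(__name__)


@dataclass
class CellRecord:
    subject_id: str
    cell_id: int
    pixels: np.ndarray  # (n, 2) 0-based (row, col)
    centroid: tuple
    area: int
    compactness: float
    channel_means: dict = field(default_factory=dict)
    positive: dict = field(default_factory=dict)


def compactness(pixels: np.ndarray) -> float:
    """Variance of pixel-to-centroid radial distances divided by area.

    Population variance; coordinates are pixel centers, so a single pixel
    has compactness 0 and the statistic is invariant to translation and to
    90-degree rotation.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 2 or len(pixels) == 0:
        raise ValueError("pixel set must be a nonempty (n, 2) array")
    centroid = pixels.mean(axis=0)
    r = np.hypot(*(pixels - centroid).T)
    return float(r.var()) / len(pixels)


def segment_cells(
    mask: np.ndarray,
    subject_id: str = "",
    min_area: int = 5,
    connectivity: int = 2,
) -> list[CellRecord]:
    """Connected components (8-connectivity) of a binary or labeled mask."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D image")
    labeled = label(mask > 0, connectivity=connectivity)
    cells, discarded = [], 0
    for region in regionprops(labeled):
        if region.area < min_area:
            discarded += 1
            continue
        pixels = region.coords
        cells.append(
            CellRecord(
                subject_id=subject_id,
                cell_id=len(cells),
                pixels=pixels,
                centroid=tuple(pixels.mean(axis=0)),
                area=int(region.area),
                compactness=compactness(pixels),
            )
        )
    if discarded:
        logger.info("subject %s: discarded %d components below %d px", subject_id, discarded, min_area)
    return cells


def call_positivity(
    cells: list[CellRecord],
    channel: np.ndarray,
    marker: str,
    positive_fraction: float = 0.10,
) -> list[CellRecord]:
    """Flag cells positive for a marker from a global Otsu threshold.

    A cell is positive iff at least ``positive_fraction`` of its pixels
    exceed the per-image Otsu threshold of the channel. Mutates and returns
    the same records (adds channel mean and the positivity flag).
    """
    channel = np.asarray(channel)
    if channel.min() == channel.max():
        raise ValueError("constant-intensity channel: threshold undefined")
    threshold = threshold_otsu(channel)
    for cell in cells:
        vals = channel[cell.pixels[:, 0], cell.pixels[:, 1]]
        cell.channel_means[marker] = float(vals.mean())
        cell.positive[marker] = bool((vals > threshold).mean() >= positive_fraction)
    return cells


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Per-cell tidy table (one row per cell, flag columns per marker)."""
    rows = []
    for c in cells:
        row = {
            "subject_id": c.subject_id,
            "cell_id": c.cell_id,
            "area": c.area,
            "compactness": c.compactness,
        }
        for marker, mean in c.channel_means.items():
            row[f"{marker}_mean"] = mean
        for marker, flag in c.positive.items():
            row[f"{marker}_positive"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def compare_compactness(
    compactness_values,
    group,
    subject_ids,
    standardize: bool = True,
) -> tuple[float, float, float]:
    """Marker-group effect on compactness with a per-subject random intercept.

    Fits compactness ~ group with a random intercept per subject (the
    between-subject random-effects model); returns (beta, se, p) for the
    group indicator. Compactness is z-scored by default so beta is in SD
    units. With a single subject the model degenerates to OLS (warned).
    """
    data = pd.DataFrame(
        {
            "compactness": np.asarray(compactness_values, dtype=float),
            "group": np.asarray(group, dtype=float),
            "subject_id": np.asarray(subject_ids),
        }
    ).dropna()
    groups_present = set(data["group"].unique())
    if len(groups_present) < 2:
        raise ValueError("both marker groups must be present")
    if standardize:
        y = data["compactness"]
        data["compactness"] = (y - y.mean()) / y.std(ddof=1)
    exog = sm.add_constant(data[["group"]])
    if data["subject_id"].nunique() < 2:
        warnings.warn("single subject: falling back to OLS", stacklevel=2)
        fit = sm.OLS(data["compactness"], exog).fit()
        return float(fit.params["group"]), float(fit.bse["group"]), float(fit.pvalues["group"])
    model = sm.MixedLM(data["compactness"], exog, groups=data["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    return float(fit.fe_params["group"]), float(fit.bse["group"]), float(fit.pvalues["group"])


def positivity_vs_stage(positive_fraction, stage) -> tuple[float, float]:
    """OLS slope of per-subject marker-positive fraction on an ordinal stage.

    Stage scores (e.g. Braak 0-6) are treated as numeric. Requires at least
    4 subjects with a non-missing stage and non-constant stage values.
    """
    data = pd.DataFrame(
        {
            "fraction": np.asarray(positive_fraction, dtype=float),
            "stage": np.asarray(stage, dtype=float),
        }
    ).dropna()
    if len(data) < 4:
        raise ValueError("need at least 4 subjects with a stage score")
    if data["stage"].nunique() < 2:
        raise ValueError("constant stage score")
    fit = sm.OLS(data["fraction"], sm.add_constant(data[["stage"]])).fit()
    return float(fit.params["stage"]), float(fit.pvalues["stage"])
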