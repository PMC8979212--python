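"""Segmentation evaluation: DSC, PPR (PPV), SEN, ASSD and HD95.

Overlap metrics compare the voxel sets of the ground truth ``G`` and the
automatic delineation ``A``:

    DSC = 2|G n A| / (|G| + |A|)      PPR = |G n A| / |A|      SEN = |G n A| / |G|

Distance metrics act on the surface voxel sets ``G_s`` and ``A_s``
(foreground voxels with a 6-connected background or out-of-bounds
neighbour), with distances measured between voxel centres in physical mm:

    ASSD = 1/2 { mean_{g in G_s} min_{a in A_s} d(a, g)
               + mean_{a in A_s} min_{g in G_s} d(a, g) }
    HD95 = max( d95(G_s, A_s), d95(A_s, G_s) )

where ``d95`` is the 95th percentile (linear interpolation between order
statistics) of the directed nearest-neighbour distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import BinaryMask

__all__ = ["CaseReport", "overlap_metrics", "extract_surface", "assd", "hd95",
           "evaluate_case", "cohort_report"]

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class CaseReport:
    """Per-case metric record; distance metrics are None when undefined
    (empty prediction)."""

    case_id: str
    dsc: float
    ppr: float
    sen: float
    assd_mm: float | None
    hd95_mm: float | None

    def as_row(self) -> dict:
        return {
            "case": self.case_id,
            "DSC_pct": 100.0 * self.dsc,
            "PPR_pct": 100.0 * self.ppr,
            "SEN_pct": 100.0 * self.sen,
            "ASSD_mm": self.assd_mm,
            "HD95_mm": self.hd95_mm,
        }


def _check_grids(g: BinaryMask, a: BinaryMask) -> None:
    if tuple(g.shape) != tuple(a.shape):
        raise ValueError(f"grid mismatch: {g.shape} vs {a.shape}")
    if not np.allclose(g.spacing, a.spacing):
        raise ValueError(f"spacing mismatch: {g.spacing} vs {a.spacing}")


def overlap_metrics(g: BinaryMask, a: BinaryMask) -> tuple[float, float, float]:
    """(DSC, PPR, SEN); PPR is reported as 0 for an empty prediction."""
    _check_grids(g, a)
    n_g = g.n_foreground
    n_a = a.n_foreground
    if n_g == 0:
        raise ValueError("ground truth mask is empty")
    inter = int(np.logical_and(g.data, a.data).sum())
    dsc = 2.0 * inter / (n_g + n_a)
    if n_a == 0:
        warnings.warn("empty prediction: PPR reported as 0 by convention")
        ppr = 0.0
    else:
        ppr = inter / n_a
    sen = inter / n_g
    return dsc, ppr, sen


def extract_surface(m: BinaryMask) -> np.ndarray:
    """(N, 3) voxel indices of foreground voxels with at least one
    face-adjacent background or out-of-bounds neighbour."""
    fg = m.data.astype(bool)
    if not fg.any():
        raise ValueError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(fg, structure=_CROSS, border_value=0)
    return np.argwhere(fg & ~interior)


def _directed_distances(src: np.ndarray, dst: np.ndarray,
                        spacing: tuple[float, float, float]) -> np.ndarray:
    sp = np.asarray(spacing)
    tree = cKDTree(dst * sp)
    d, _ = tree.query(src * sp, k=1)
    return d


def assd(g: BinaryMask, a: BinaryMask,
         spacing: tuple[float, float, float] | None = None) -> float | None:
    """Average symmetric surface distance in mm; None if either mask is
    empty (undefined, reported as missing)."""
    _check_grids(g, a)
    if g.n_foreground == 0 or a.n_foreground == 0:
        warnings.warn("ASSD undefined for an empty mask; reporting missing")
        return None
    sp = tuple(spacing) if spacing is not None else g.spacing
    gs, as_ = extract_surface(g), extract_surface(a)
    d_ga = _directed_distances(gs, as_, sp)
    d_ag = _directed_distances(as_, gs, sp)
    return 0.5 * (float(d_ga.mean()) + float(d_ag.mean()))


def hd95(g: BinaryMask, a: BinaryMask,
         spacing: tuple[float, float, float] | None = None) -> float | None:
    """95th-percentile symmetric Hausdorff surface distance in mm."""
    _check_grids(g, a)
    if g.n_foreground == 0 or a.n_foreground == 0:
        warnings.warn("HD95 undefined for an empty mask; reporting missing")
        return None
    sp = tuple(spacing) if spacing is not None else g.spacing
    gs, as_ = extract_surface(g), extract_surface(a)
    d_ga = _directed_distances(gs, as_, sp)
    d_ag = _directed_distances(as_, gs, sp)
    return float(max(np.percentile(d_ga, 95), np.percentile(d_ag, 95)))


def evaluate_case(g: BinaryMask, a: BinaryMask, case_id: str = "case") -> CaseReport:
    dsc, ppr, sen = overlap_metrics(g, a)
    if a.n_foreground == 0:
        return CaseReport(case_id, dsc, ppr, sen, None, None)
    return CaseReport(case_id, dsc, ppr, sen, assd(g, a), hd95(g, a))


def cohort_report(reports: list[CaseReport]) -> pd.DataFrame:
    """Per-case rows plus mean and sample-SD (n-1) summary rows.

    Distance metrics of empty-prediction cases are excluded from the means
    and counted in ``n_empty_predictions``; with a single case the SD is
    reported as 0.
    """
    if not reports:
        raise ValueError("no case reports to summarize")
    df = pd.DataFrame([r.as_row() for r in reports])
    metric_cols = ["DSC_pct", "PPR_pct", "SEN_pct", "ASSD_mm", "HD95_mm"]
    mean_row = {"case": "mean"}
    sd_row = {"case": "sd"}
    for col in metric_cols:
        vals = df[col].dropna().to_numpy(dtype=float)
        mean_row[col] = float(vals.mean()) if vals.size else None
        sd_row[col] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    out = pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
    out.attrs["n_empty_predictions"] = int(df["ASSD_mm"].isna().sum())
    out.attrs["n_cases"] = len(reports)
    return out
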