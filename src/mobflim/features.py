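"""Cell segmentation and the five metabolic optical biomarkers (MOBs).

Per cell: optical redox ratio ORR = FAD/(FAD + NAD(P)H); alpha_bound and
tau_bound from the pooled-phasor two-component decomposition; the
edge/center NAD(P)H intensity ratio (peripheral band vs eroded center);
and polarity, the distance between the intensity-weighted ("mass") and
geometric centroids normalized by the equivalent radius sqrt(area/pi).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, measure, morphology

from . import phasor as ph
from .config import AcquisitionConfig

__all__ = [
    "segment_cells",
    "compute_orr",
    "edge_center_ratio",
    "polarity",
    "extract_mob_table",
    "paired_delta",
    "MOB_COLUMNS",
]

MOB_COLUMNS = [
    "cell_id", "population", "orr", "alpha_bound", "tau_bound_ns",
    "edge_center_ratio", "polarity", "area_px", "mean_nadph", "mean_fad",
    "timepoint", "hoxb5",
]

MOB_FEATURES = ["orr", "alpha_bound", "tau_bound_ns", "edge_center_ratio", "polarity"]

DEFAULT_MIN_AREA = 12        # px; components below are discarded
DEFAULT_BAND_FRACTION = 0.3  # edge band depth as a fraction of the equivalent radius
DEFAULT_SUM_THRESHOLD = 1.0  # min FAD+NAD(P)H per pixel for a valid ORR pixel


def segment_cells(intensity: np.ndarray, min_area: int = DEFAULT_MIN_AREA,
                  threshold: float | None = None,
                  method: str = "triangle") -> np.ndarray:
    """Threshold + connected components segmentation into a label mask.

    Global threshold (``method`` in {"triangle", "otsu", "li"}; an absolute
    ``threshold`` overrides), 8-connected components, holes filled,
    components below ``min_area`` discarded, labels renumbered 1..K in
    raster order of centroid. The triangle default suits the
    background-dominated histograms of autofluorescence fields, where Otsu
    is pulled into the foreground mode and clips the dim side of polarized
    cells. Cells are imaged as isolated singles, so no splitting of
    touching objects is attempted.
    """
    img = np.asarray(intensity, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("intensity must be a 2-D non-negative image")
    if not np.any(img > 0):
        return np.zeros(img.shape, dtype=np.uint16)
    if threshold is None:
        pickers = {"triangle": filters.threshold_triangle,
                   "otsu": filters.threshold_otsu,
                   "li": filters.threshold_li}
        if method not in pickers:
            raise ValueError(f"unknown threshold method {method!r}")
        thr = pickers[method](img)
    else:
        thr = threshold
    fg = ndimage.binary_fill_holes(img > thr)
    labels = measure.label(fg, connectivity=2)
    # discard components with area < min_area
    keep = morphology.remove_small_objects(labels > 0, max_size=min_area - 1)
    labels = labels * keep
    props = measure.regionprops(labels)
    # renumber in raster order of centroid
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros(img.shape, dtype=np.uint16)
    for new_id, p in enumerate(order, start=1):
        out[labels == p.label] = new_id
    return out


def compute_orr(fad: np.ndarray, nadph: np.ndarray, mask: np.ndarray,
                sum_threshold: float = DEFAULT_SUM_THRESHOLD) -> dict[int, float]:
    """Per-cell mean of the pixel-wise optical redox ratio FAD/(FAD+NAD(P)H).

    Pixels whose summed signal falls below ``sum_threshold`` are excluded;
    a cell with no valid pixel maps to NaN.
    """
    fad = np.asarray(fad, dtype=float)
    nadph = np.asarray(nadph, dtype=float)
    if fad.shape != nadph.shape or fad.shape != mask.shape:
        raise ValueError("fad, nadph and mask shapes must match")
    total = fad + nadph
    valid = total >= sum_threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, fad / np.where(total > 0, total, 1.0), np.nan)
    out: dict[int, float] = {}
    for cid in np.unique(mask[mask > 0]):
        sel = (mask == cid) & valid
        out[int(cid)] = float(np.mean(ratio[sel])) if sel.any() else float("nan")
    return out


def _equivalent_radius(area: int) -> float:
    return math.sqrt(area / math.pi)


def edge_center_ratio(nadph: np.ndarray, cell_mask: np.ndarray,
                      band_fraction: float = DEFAULT_BAND_FRACTION) -> float:
    """Mean intensity in the peripheral band over the eroded center.

    The center is the mask eroded by ``d = round(band_fraction * r_eq)``
    pixels (Euclidean distance transform); the edge is the remainder. When
    erosion empties the center the single most-interior pixel is used.
    Returns NaN when the center mean is zero.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    img = np.asarray(nadph, dtype=float)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty cell mask")
    d = round(band_fraction * _equivalent_radius(area))
    dist = ndimage.distance_transform_edt(mask)
    center = dist > d
    if not center.any():
        center = np.zeros_like(mask)
        center[np.unravel_index(np.argmax(dist), dist.shape)] = True
    edge = mask & ~center
    if not edge.any():
        return 1.0
    center_mean = float(img[center].mean())
    if center_mean == 0:
        return float("nan")
    return float(img[edge].mean() / center_mean)


def polarity(nadph: np.ndarray, cell_mask: np.ndarray) -> float:
    """Distance between intensity-weighted and geometric centroids / r_eq."""
    mask = np.asarray(cell_mask, dtype=bool)
    img = np.asarray(nadph, dtype=float)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty cell mask")
    w = img[mask]
    if w.sum() <= 0:
        return float("nan")
    coords = np.argwhere(mask).astype(float)
    gc = coords.mean(axis=0)
    mc = (coords * w[:, None]).sum(axis=0) / w.sum()
    return float(np.linalg.norm(mc - gc) / _equivalent_radius(area))


def extract_mob_table(
    stack: ph.DecayStack,
    fad: np.ndarray,
    mask: np.ndarray,
    acq: AcquisitionConfig | None = None,
    tau_free: float = ph.DEFAULT_TAU_FREE,
    band_fraction: float = DEFAULT_BAND_FRACTION,
    populations: dict[int, str] | None = None,
    count_threshold: int = ph.DEFAULT_COUNT_THRESHOLD,
    timepoint: float | None = None,
    harmonic: int = 1,
    calibration: ph.PhasorCalibration | None = None,
) -> pd.DataFrame:
    """Compute all five MOBs per segmented cell.

    Returns one row per cell id in ascending order with the fixed
    :data:`MOB_COLUMNS` header; missing values (e.g. tau_bound for a
    pure-free cell) propagate as NaN rather than dropping the row.
    """
    mask = np.asarray(mask)
    if mask.shape != stack.counts.shape[1:]:
        raise ValueError("mask shape does not match the decay stack")
    if acq is not None:
        omega = acq.omega
        expect = 2.0 * math.pi * harmonic / stack.laser_period
        if not math.isclose(omega, expect, rel_tol=1e-9):
            raise ValueError("acquisition metadata (omega) inconsistent with the stack")
    phimg = ph.phasor_transform(stack, harmonic=harmonic, calibration=calibration)
    nadph = stack.total_counts.astype(float)
    orr_by_cell = compute_orr(fad, nadph, mask)
    rows = []
    for cid in sorted(int(c) for c in np.unique(mask[mask > 0])):
        cell = mask == cid
        area = int(cell.sum())
        try:
            gs = ph.cell_phasor(phimg, cell, count_threshold=count_threshold)
            fit = ph.decompose_fixed_free(gs, tau_free=tau_free, omega=phimg.omega)
            alpha, tau_b = fit.alpha_bound, fit.tau_bound
        except ValueError:
            alpha, tau_b = float("nan"), float("nan")
        rows.append({
            "cell_id": cid,
            "population": (populations or {}).get(cid),
            "orr": orr_by_cell.get(cid, float("nan")),
            "alpha_bound": alpha,
            "tau_bound_ns": tau_b,
            "edge_center_ratio": edge_center_ratio(nadph, cell, band_fraction),
            "polarity": polarity(nadph, cell),
            "area_px": area,
            "mean_nadph": float(nadph[cell].mean()),
            "mean_fad": float(np.asarray(fad, dtype=float)[cell].mean()),
            "timepoint": timepoint,
            "hoxb5": None,
        })
    return pd.DataFrame(rows, columns=MOB_COLUMNS)


def paired_delta(pre: pd.DataFrame, post: pd.DataFrame,
                 value: str = "tau_bound_ns") -> tuple[pd.DataFrame, dict]:
    """Pair pre/post tables by cell id and regress the change on the initial value.

    Returns the paired table (columns ``pre``, ``post``, ``delta``) and a
    dict with the least-squares ``slope``, ``intercept`` and Pearson ``r``
    of delta vs the initial value.
    """
    a = pre.set_index("cell_id")[value]
    b = post.set_index("cell_id")[value]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("pre and post tables share no cell ids")
    paired = pd.DataFrame({"pre": a.loc[shared], "post": b.loc[shared]})
    paired["delta"] = paired["post"] - paired["pre"]
    ok = paired.dropna()
    if len(ok) >= 2 and ok["pre"].nunique() > 1 and ok["delta"].nunique() > 1:
        res = stats.linregress(ok["pre"], ok["delta"])
        fit = {"slope": float(res.slope), "intercept": float(res.intercept),
               "pearson_r": float(res.rvalue), "n": int(len(ok))}
    else:
        slope = 0.0 if len(ok) and ok["delta"].nunique() <= 1 else float("nan")
        fit = {"slope": slope, "intercept": float(ok["delta"].mean()) if len(ok) else float("nan"),
               "pearson_r": float("nan"), "n": int(len(ok))}
    return paired, fit
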