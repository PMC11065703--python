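"""Imaging-mass-cytometry quantification: QC trimming, marker positivity,
cluster-level senescent proportions and peri-plaque classification.

Peri-plaque microglia are cells within 10 um of an amyloid-plaque object
(inclusive at exactly 10.0 um).  Two classification modes are provided:
``centroid`` computes the continuous distance from each cell centroid to
the nearest plaque boundary (0 inside a plaque); ``mask`` reproduces the
raster procedure of dilating the plaque label mask by the radius with a
disk structuring element and testing centroid pixels.  On disk-shaped
plaques the two agree up to pixelisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImagingCellTable, PlaqueSet, mask_to_disks
from .stats import EffectResult

logger = logging.getLogger("senescape")

DEFAULT_SENESCENCE_CHANNELS = ["GLB1", "p16", "p21", "gH2AX"]
DEFAULT_CELL_TYPE_CHANNELS = ["Iba1", "GFAP", "OLIG2", "MAP2", "GLUT1"]


# ---------------------------------------------------------------------------
# QC trimming
# ---------------------------------------------------------------------------

def _lower_quantile_cutoff(values: np.ndarray, frac: float) -> float:
    """Inclusive lower-tail cutoff: the 'lower'-interpolated quantile.

    With n distinct values and frac = 0.01, removal of values <= cutoff
    drops exactly floor(frac * (n-1)) + 1 records, i.e. one ROI out of
    100 at the 1% trim.
    """
    return float(np.quantile(np.asarray(values, dtype=float), frac, method="lower"))


@dataclass
class TrimRecord:
    """Frozen cutoffs and removal counts from a qc_trim pass."""

    roi_cutoff: float | None
    cell_cutoffs: dict = field(default_factory=dict)  # roi_id -> cutoff
    n_rois_removed: int = 0
    n_cells_removed: int = 0


def qc_trim(
    cells: ImagingCellTable,
    senescence_channels=None,
    cell_type_channels=None,
    trim_frac: float = 0.01,
    frozen: TrimRecord | None = None,
) -> tuple[ImagingCellTable, TrimRecord]:
    """Two-stage lowest-quantile QC trim.

    Stage 1 removes ROIs whose mean senescence-marker expression (mean of
    ``senescence_channels`` over cells) falls in the lowest ``trim_frac``
    quantile across all ROIs.  Stage 2 removes, within each remaining
    ROI, cells in the lowest ``trim_frac`` quantile of their defining
    cell-type-marker intensity (the maximum over ``cell_type_channels``).
    Ties at a cutoff are removed inclusively.  ``trim_frac = 0`` is the
    identity.  Passing the returned ``TrimRecord`` back as ``frozen``
    re-applies the first pass's cutoffs, making the operation idempotent.
    """
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must be in [0, 0.5)")
    sen = senescence_channels or [c for c in DEFAULT_SENESCENCE_CHANNELS if c in cells.channels]
    cty = cell_type_channels or [c for c in DEFAULT_CELL_TYPE_CHANNELS if c in cells.channels]
    if not sen or not cty:
        raise ValueError("need at least one senescence and one cell-type channel")
    df = cells.table.copy()
    record = TrimRecord(roi_cutoff=None)
    if trim_frac == 0 and frozen is None:
        return ImagingCellTable(table=df, channels=cells.channels), record

    roi_means = df.groupby("roi_id")[sen].mean().mean(axis=1)
    if frozen is not None:
        roi_cut = frozen.roi_cutoff
    else:
        roi_cut = _lower_quantile_cutoff(roi_means.to_numpy(), trim_frac)
    if roi_cut is not None:
        keep_rois = roi_means.index[roi_means > roi_cut]
        record.n_rois_removed = int(len(roi_means) - len(keep_rois))
        if len(keep_rois) == 0:
            raise ValueError("QC trim removed all ROIs")
        df = df[df["roi_id"].isin(keep_rois)]
    record.roi_cutoff = roi_cut

    defining = df[cty].max(axis=1).to_numpy()
    df = df.assign(_defining=defining)
    kept = []
    n_removed = 0
    for roi, grp in df.groupby("roi_id"):
        if frozen is not None:
            cut = frozen.cell_cutoffs.get(roi, -np.inf)
        else:
            cut = _lower_quantile_cutoff(grp["_defining"].to_numpy(), trim_frac)
        record.cell_cutoffs[roi] = cut
        keep = grp["_defining"] > cut
        n_removed += int((~keep).sum())
        kept.append(grp[keep])
    record.n_cells_removed = n_removed
    out = pd.concat(kept).drop(columns="_defining").reset_index(drop=True)
    logger.info("qc_trim: removed %d ROI(s), %d cell(s)", record.n_rois_removed, n_removed)
    return ImagingCellTable(table=out, channels=cells.channels), record


# ---------------------------------------------------------------------------
# Marker positivity
# ---------------------------------------------------------------------------

def call_markers(cells: ImagingCellTable, rules: dict) -> pd.DataFrame:
    """Boolean positivity per channel per cell.

    ``rules`` maps channel -> rule, where a rule is
    ``("fixed", threshold)``, ``("quantile", q)`` (per-ROI quantile of
    that channel), or ``("otsu",)`` (Otsu's threshold on log1p
    intensities, computed across all cells).  A cell is positive when
    its intensity is strictly greater than the threshold.  The applied
    rule and threshold are recorded in ``DataFrame.attrs["rules"]``.
    """
    df = cells.table
    out = df[["cell_id", "roi_id", "sample_id"]].copy()
    applied = {}
    for channel, rule in rules.items():
        if channel not in cells.channels:
            raise ValueError(f"unknown channel '{channel}'")
        kind = rule[0]
        vals = df[channel].to_numpy(dtype=float)
        if kind == "fixed":
            thr = np.full(len(df), float(rule[1]))
            applied[channel] = ("fixed", float(rule[1]))
        elif kind == "quantile":
            q = float(rule[1])
            per_roi = df.groupby("roi_id")[channel].transform(lambda s: s.quantile(q))
            thr = per_roi.to_numpy(dtype=float)
            applied[channel] = ("quantile", q)
        elif kind == "otsu":
            from skimage.filters import threshold_otsu

            t = float(np.expm1(threshold_otsu(np.log1p(vals))))
            thr = np.full(len(df), t)
            applied[channel] = ("otsu", t)
        else:
            raise ValueError(f"unknown rule type '{kind}' for channel '{channel}'")
        out[f"{channel}_pos"] = vals > thr
    out.attrs["rules"] = applied
    return out


def senescent_proportion_per_cluster(
    marker_calls: pd.DataFrame,
    cluster_labels: pd.Series | np.ndarray,
    cluster_markers: dict,
    senescence_channels=None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-(sample, cluster) senescent proportions from marker calls.

    For each cluster, the denominator is the cells positive for the
    cluster's defining cell-type marker (``cluster_markers`` maps
    cluster label -> channel); the numerator is those also positive for
    at least one senescence marker.  ROI-level counts are summed to the
    sample level; (sample, cluster) entries with fewer than ``min_cells``
    denominator cells are flagged excluded.
    """
    sen = senescence_channels or DEFAULT_SENESCENCE_CHANNELS
    sen_cols = [f"{c}_pos" for c in sen if f"{c}_pos" in marker_calls.columns]
    if not sen_cols:
        raise ValueError("no senescence-marker positivity columns present")
    df = marker_calls.copy()
    df["cluster_label"] = np.asarray(cluster_labels)
    df["_sen_any"] = df[sen_cols].any(axis=1)
    rows = []
    for (sample, cluster), grp in df.groupby(["sample_id", "cluster_label"], observed=True):
        marker = cluster_markers.get(cluster)
        if marker is None:
            continue
        col = f"{marker}_pos"
        if col not in grp.columns:
            raise ValueError(f"no positivity column for marker '{marker}'")
        denom_mask = grp[col]
        n_cells = int(denom_mask.sum())
        n_sen = int((denom_mask & grp["_sen_any"]).sum())
        excluded = n_cells < min_cells
        rows.append(
            {
                "sample_id": sample, "cluster_label": cluster,
                "n_cells": n_cells, "n_senescent": n_sen,
                "excluded": excluded,
                "reason": f"fewer than {min_cells} cells" if excluded else "",
                "proportion": np.nan if excluded else (n_sen / n_cells if n_cells else np.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peri-plaque classification
# ---------------------------------------------------------------------------

def _centroid_distances(x, y, disks: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points to nearest disk boundary (0 inside)."""
    n = len(x)
    dist = np.full(n, np.inf)
    nearest = np.full(n, -1, dtype=object)
    for _, row in disks.iterrows():
        d = np.hypot(x - row["cx_um"], y - row["cy_um"]) - row["radius_um"]
        d = np.maximum(d, 0.0)
        closer = d < dist
        dist[closer] = d[closer]
        nearest[closer] = row["plaque_id"]
    return dist, nearest


def _mask_distances(x_um, y_um, mask: np.ndarray, scale: float):
    """EDT-based distance (um) to nearest mask object and its label."""
    from scipy import ndimage

    dist_px, (iy, ix) = ndimage.distance_transform_edt(mask == 0, return_indices=True)
    px = np.clip((np.asarray(x_um) / scale).astype(int), 0, mask.shape[1] - 1)
    py = np.clip((np.asarray(y_um) / scale).astype(int), 0, mask.shape[0] - 1)
    dist = dist_px[py, px] * scale
    labels = mask[iy[py, px], ix[py, px]]
    return dist, labels


def _rasterize_disks(disks: pd.DataFrame, shape: tuple[int, int], scale: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    # pixel centres in um
    cx_px = (xx + 0.5) * scale
    cy_px = (yy + 0.5) * scale
    for _, row in disks.iterrows():
        inside = np.hypot(cx_px - row["cx_um"], cy_px - row["cy_um"]) <= row["radius_um"]
        mask[inside] = int(row["plaque_id"])
    return mask


def classify_peri_plaque(
    cells: ImagingCellTable,
    plaques: PlaqueSet,
    radius_um: float = 10.0,
    mode: str = "centroid",
    roi_shape_um: tuple[float, float] = (500.0, 500.0),
    scale_um_per_px: float = 1.0,
) -> pd.DataFrame:
    """Classify each cell as peri-plaque or not, per ROI.

    Returns (cell_id, roi_id, sample_id, nearest_plaque_id, distance_um,
    peri_plaque).  ``peri_plaque`` is inclusive at exactly ``radius_um``.
    ROIs without plaques yield distance = +inf and all-false calls.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if mode not in {"centroid", "mask"}:
        raise ValueError(f"unknown mode '{mode}'")
    df = cells.table
    results = []
    for roi, grp in df.groupby("roi_id"):
        x = grp["x_um"].to_numpy(dtype=float)
        y = grp["y_um"].to_numpy(dtype=float)
        has_mask = plaques.masks is not None and roi in plaques.masks
        disks = (
            plaques.disks[plaques.disks["roi_id"] == roi]
            if plaques.disks is not None
            else pd.DataFrame()
        )
        if not has_mask and len(disks) == 0:
            dist = np.full(len(grp), np.inf)
            nearest = np.full(len(grp), None, dtype=object)
            peri = np.zeros(len(grp), dtype=bool)
        elif mode == "centroid":
            if has_mask and len(disks) == 0:
                mask, scale = plaques.masks[roi]
                dist, nearest = _mask_distances(x, y, mask, scale)
                dist = np.where(mask[
                    np.clip((y / scale).astype(int), 0, mask.shape[0] - 1),
                    np.clip((x / scale).astype(int), 0, mask.shape[1] - 1),
                ] > 0, 0.0, dist)
            else:
                dist, nearest = _centroid_distances(x, y, disks)
            peri = dist <= radius_um
        else:  # mask mode
            if has_mask:
                mask, scale = plaques.masks[roi]
            else:
                scale = scale_um_per_px
                shape = (int(round(roi_shape_um[1] / scale)), int(round(roi_shape_um[0] / scale)))
                mask = _rasterize_disks(disks, shape, scale)
            from skimage.morphology import dilation, disk as disk_se

            r_px = int(round(radius_um / scale))
            dilated = dilation(mask > 0, disk_se(r_px))
            px = np.clip((x / scale).astype(int), 0, mask.shape[1] - 1)
            py = np.clip((y / scale).astype(int), 0, mask.shape[0] - 1)
            peri = dilated[py, px]
            dist, nearest = _mask_distances(x, y, mask, scale)
        results.append(
            pd.DataFrame(
                {
                    "cell_id": grp["cell_id"].to_numpy(),
                    "roi_id": roi,
                    "sample_id": grp["sample_id"].to_numpy(),
                    "nearest_plaque_id": nearest if len(grp) else [],
                    "distance_um": dist,
                    "peri_plaque": peri,
                }
            )
        )
    return pd.concat(results, ignore_index=True)


def peri_vs_nonplaque_contrast(
    proximity: pd.DataFrame,
    marker_calls: pd.DataFrame,
    cell_type_channel: str = "Iba1",
    senescence_channels=("GLB1",),
) -> tuple[pd.DataFrame, dict]:
    """Per-sample senescence-marker positivity among peri- vs non-plaque
    cells of one type, with a paired Wilcoxon signed-rank test.

    Only cells positive for ``cell_type_channel`` (e.g. Iba1+ microglia)
    enter; for each sample the proportion positive for each senescence
    channel (and for all of them jointly, ``double``) is computed in the
    peri-plaque and non-plaque compartments.  Samples lacking either
    compartment are dropped; with no peri-plaque cells anywhere the
    contrast is skipped with a reason.
    """
    col = f"{cell_type_channel}_pos"
    if col not in marker_calls.columns:
        raise ValueError(f"no positivity column for channel '{cell_type_channel}'")
    merged = marker_calls.merge(
        proximity[["cell_id", "roi_id", "peri_plaque"]], on=["cell_id", "roi_id"], how="inner"
    )
    merged = merged[merged[col]]
    sen_cols = [f"{c}_pos" for c in senescence_channels]
    merged["double_pos"] = merged[sen_cols].all(axis=1)
    rows = []
    for sample, grp in merged.groupby("sample_id"):
        peri = grp[grp["peri_plaque"]]
        non = grp[~grp["peri_plaque"]]
        if len(peri) == 0 or len(non) == 0:
            continue
        for label, cols in [*[(c, f"{c}_pos") for c in senescence_channels], ("double", "double_pos")]:
            rows.append(
                {
                    "sample_id": sample, "marker": label,
                    "n_peri": len(peri), "n_non": len(non),
                    "prop_peri": float(peri[cols].mean()),
                    "prop_non": float(non[cols].mean()),
                }
            )
    props = pd.DataFrame(rows)
    tests: dict = {}
    if props.empty:
        tests["skipped"] = "no sample has both peri-plaque and non-plaque cells"
        return props, tests
    from scipy.stats import wilcoxon

    for marker, grp in props.groupby("marker"):
        diff = grp["prop_peri"] - grp["prop_non"]
        if len(grp) < 2 or np.allclose(diff, 0):
            tests[marker] = {"p_value": 1.0, "n_samples": len(grp),
                             "note": "degenerate (all differences zero or < 2 samples)"}
            continue
        stat, p = wilcoxon(grp["prop_peri"], grp["prop_non"], zero_method="wilcox")
        tests[marker] = {"statistic": float(stat), "p_value": float(p), "n_samples": len(grp)}
    return props, tests
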