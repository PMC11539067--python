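"""Axon morphometry in spinal-cord cross sections, with operator blinding.

Bright axon profiles inside a polygonal region of interest are counted
and sized (equivalent diameter from component area). Sample identifiers
can be replaced by opaque pseudonyms before quantification so the
operator never sees the genotype; the inverse map is kept sealed for
unblinding after measurement. Group summaries are compared with the
permutation test and BH-corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.measure import label, regionprops

from .stats import bh_fdr, permutation_test

__all__ = ["detect_axons", "blind_labels", "unblind", "axon_summary"]


def detect_axons(
    image: np.ndarray,
    roi_polygon: np.ndarray,
    threshold: float = 100.0,
    min_area_px: int = 9,
    um_per_px: float = 1.0,
) -> pd.DataFrame:
    """Detect axon profiles inside the ROI.

    Pixels above ``threshold`` within the ROI are grouped into connected
    components; components smaller than ``min_area_px`` are discarded;
    the equivalent diameter is ``2 sqrt(area / pi)`` scaled to microns.
    Returns a frame with columns ``row``, ``col``, ``area_px``,
    ``diameter_um``.
    """
    image = np.asarray(image)
    roi_polygon = np.asarray(roi_polygon, dtype=float)
    roi = polygon2mask(image.shape, roi_polygon)
    if not roi.any():
        raise ValueError("ROI polygon covers no pixels of the image")
    fg = (image > threshold) & roi
    lab = label(fg)
    rows = []
    for p in regionprops(lab):
        if p.area < min_area_px:
            continue
        d_px = 2.0 * np.sqrt(p.area / np.pi)
        rows.append({"row": p.centroid[0], "col": p.centroid[1],
                     "area_px": int(p.area), "diameter_um": d_px * um_per_px})
    return pd.DataFrame(rows, columns=["row", "col", "area_px", "diameter_um"])


def blind_labels(sample_ids: list[str], seed: int = 0) -> tuple[dict, dict]:
    """Replace sample identifiers by opaque codes.

    Returns ``(pseudonym_map, sealed_inverse)``: a seeded permutation of
    codes ``S001..Snnn`` so the code order carries no information about
    the input order, and the inverse map to be stored separately from
    the measurement workflow.
    """
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample ids must be unique")
    rng = np.random.default_rng(seed)
    codes = [f"S{i + 1:03d}" for i in range(len(sample_ids))]
    order = rng.permutation(len(sample_ids))
    mapping = {sid: codes[k] for sid, k in zip(sample_ids, order)}
    inverse = {code: sid for sid, code in mapping.items()}
    return mapping, inverse


def unblind(code: str, sealed_inverse: dict) -> str:
    return sealed_inverse[code]


def axon_summary(
    detections: dict[str, pd.DataFrame],
    group_labels: dict[str, str],
    n_resamples: int = 200_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group axon count and diameter summary with permutation tests.

    ``detections`` maps sample id to its detection table;
    ``group_labels`` maps sample id to its group. Samples with no
    detections are flagged and excluded. Per-sample statistics (count,
    median diameter) are compared between the two groups by permutation
    test on the per-sample values, BH-corrected across the two measures.
    With a single group only the summary is returned (empty test table).
    """
    rows = []
    for sid, det in detections.items():
        if det.empty:
            rows.append({"sample": sid, "group": group_labels[sid],
                         "n_axons": 0, "median_diameter_um": np.nan,
                         "excluded": True})
            continue
        rows.append({"sample": sid, "group": group_labels[sid],
                     "n_axons": len(det),
                     "median_diameter_um": float(det["diameter_um"].median()),
                     "excluded": False})
    summary = pd.DataFrame(rows)
    usable = summary[~summary["excluded"]]
    groups = sorted(usable["group"].unique())
    if len(groups) < 2:
        return summary, pd.DataFrame(columns=["measure", "p_value", "p_adjusted"])
    if len(groups) > 2:
        raise ValueError("permutation comparison supports exactly 2 groups")
    g0 = usable[usable["group"] == groups[0]]
    g1 = usable[usable["group"] == groups[1]]
    pvals = {}
    for measure in ("n_axons", "median_diameter_um"):
        res = permutation_test(g0[measure].to_numpy(), g1[measure].to_numpy(),
                               n_resamples=n_resamples, seed=seed)
        pvals[measure] = res.p_value
    tests = pd.DataFrame({"measure": list(pvals), "p_value": list(pvals.values())})
    tests["p_adjusted"] = bh_fdr(tests["p_value"].to_numpy())
    return summary, tests
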