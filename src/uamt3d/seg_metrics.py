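"""Overlap and surface-distance segmentation metrics plus reporting.

Conventions:

* A surface voxel is a mask voxel with at least one face-adjacent
  (6-connectivity) background voxel; everything outside the array counts as
  background, so mask voxels on the array border are surface voxels.
* ``hd95``/``asd`` use the symmetric pooled construction: directed
  nearest-surface distances are computed in both directions and pooled before
  taking the 95th percentile (linear interpolation) or the mean.  This is the
  field-standard symmetric variant.
* Both masks empty: overlap metrics are 1, distance metrics 0.  One mask
  empty: overlap is 0 and distance metrics raise ``EmptyMaskError`` (reported
  as missing by ``evaluate``).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError

__all__ = ["dsc", "jaccard", "hd95", "asd", "relative_change",
           "surface_voxels", "MetricReport", "evaluate", "improvement_report"]


def _check_pair(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A.B| / (|A|+|B|); both-empty -> 1."""
    a, b = _check_pair(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard(a, b) -> float:
    """Jaccard index |A.B| / |AuB|; both-empty -> 1."""
    a, b = _check_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def surface_voxels(mask) -> np.ndarray:
    """Coordinates (n, 3) of 6-connectivity surface voxels of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros((0, mask.ndim), dtype=np.int64)
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def _pooled_surface_distances(a, b, spacing) -> np.ndarray:
    a, b = _check_pair(a, b)
    if not a.any() and not b.any():
        return np.zeros(1)
    if not a.any() or not b.any():
        raise EmptyMaskError("surface distance undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    sa = surface_voxels(a) * spacing
    sb = surface_voxels(b) * spacing
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return np.concatenate([d_ab, d_ba])


def hd95(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled directed surface distances (robust Hausdorff)."""
    return float(np.percentile(_pooled_surface_distances(a, b, spacing), 95))


def asd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance: mean of the pooled directed
    nearest-surface distances (both directions, normalised by |S(A)|+|S(B)|)."""
    return float(np.mean(_pooled_surface_distances(a, b, spacing)))


def relative_change(reference: float, proposed: float) -> float:
    """Percent change (proposed - reference) / reference * 100 (+ = increase)."""
    if reference == 0:
        raise ValueError("relative change undefined for a zero reference")
    return (proposed - reference) / reference * 100.0


# -- reporting ---------------------------------------------------------------

@dataclass
class CaseMetrics:
    case_id: str
    dsc: float
    jaccard: float
    hd95: float | None
    asd: float | None


@dataclass
class MetricReport:
    per_case: list = field(default_factory=list)
    units: str = "mm"

    def aggregate(self) -> dict:
        out = {}
        for name in ("dsc", "jaccard", "hd95", "asd"):
            vals = [getattr(c, name) for c in self.per_case
                    if getattr(c, name) is not None and math.isfinite(getattr(c, name))]
            out[name] = {"mean": float(np.mean(vals)) if vals else float("nan"),
                         "sd": float(np.std(vals)) if vals else float("nan"),
                         "n": len(vals)}
        return out

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "per_case.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["case_id", "dsc", "jaccard", "hd95", "asd"])
            for c in self.per_case:
                w.writerow([c.case_id, f"{c.dsc:.6f}", f"{c.jaccard:.6f}",
                            "" if c.hd95 is None else f"{c.hd95:.6f}",
                            "" if c.asd is None else f"{c.asd:.6f}"])
        with open(out_dir / "summary.json", "w") as fh:
            json.dump({"units": self.units, "aggregate": self.aggregate(),
                       "per_case": [asdict(c) for c in self.per_case]}, fh, indent=1)


def case_metrics(case_id: str, pred, truth, spacing, units: str = "mm") -> CaseMetrics:
    sp = spacing if units == "mm" else (1.0, 1.0, 1.0)
    try:
        h, a_ = hd95(pred, truth, sp), asd(pred, truth, sp)
    except EmptyMaskError:
        h, a_ = None, None
    return CaseMetrics(case_id, dsc(pred, truth), jaccard(pred, truth), h, a_)


def evaluate(network, manifest: dict, data_dir, *, units: str = "mm",
             window=None, split: str = "test") -> MetricReport:
    """Sliding-window inference on a manifest split, scored against ground
    truth.  Cases without a mask file are skipped with a warning entry."""
    import warnings

    from .io_inference import (SlidingWindowPlan, load_volume,
                               normalize_intensity, sliding_window_predict,
                               label_from_proba)

    data_dir = Path(data_dir)
    plan = SlidingWindowPlan(window_shape=window) if window else SlidingWindowPlan(
        window_shape=tuple(manifest["spec"]["volume_shape"]))
    report = MetricReport(units=units)
    for entry in manifest["cases"]:
        if entry["split"] != split:
            continue
        mask_path = data_dir / entry["paths"].get("mask", "")
        if not mask_path.exists():
            warnings.warn(f"{entry['case_id']}: no ground truth, skipped")
            continue
        vol, spacing, _ = load_volume(data_dir / entry["paths"]["degraded"])
        truth, _, _ = load_volume(mask_path)
        probs = sliding_window_predict(network, normalize_intensity(vol), plan)
        pred = label_from_proba(probs)
        report.per_case.append(case_metrics(entry["case_id"], pred > 0,
                                            truth > 0, spacing, units))
    return report


def improvement_report(table_csv, *, reference_methods=None,
                       proposed: str = "ours") -> dict:
    """Recompute relative-change percentages from a benchmark-values CSV.

    The CSV has columns setting,method,dsc,jaccard,hd95,asd.  For every
    setting, each non-proposed method is compared against the proposed row:
    positive percentages mean the proposed method's value is higher.
    """
    rows = []
    with open(table_csv) as fh:
        for row in csv.DictReader(fh):
            rows.append(row)
    settings = sorted({r["setting"] for r in rows})
    out: dict[str, dict] = {}
    for setting in settings:
        sub = [r for r in rows if r["setting"] == setting]
        ours = next((r for r in sub if r["method"] == proposed), None)
        if ours is None:
            continue
        out[setting] = {}
        for r in sub:
            if r["method"] == proposed:
                continue
            if reference_methods and r["method"] not in reference_methods:
                continue
            out[setting][r["method"]] = {
                m: relative_change(float(r[m]), float(ours[m]))
                for m in ("dsc", "jaccard", "hd95", "asd")}
    return out
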