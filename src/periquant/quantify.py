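"""Voxel-based volume and surface-area quantification of compartment masks.

Volume of a compartment is its voxel count times the physical voxel size
``dx * dy * dz`` (cm^3).  Surface area is the sum of areas of compartment
voxel faces that face non-compartment voxels: an exposed x-facing side
contributes ``dy * dz``, a y-facing side ``dx * dz`` and a z-facing side
``dx * dy`` (cm^2).  Faces on the grid boundary count as exposed (a
compartment clipped at the scan edge exposes the cut face; pad the mask if
that is not wanted).

Per-label surface areas count faces toward *other* labels as exposed on both
sides; the total surface area is therefore computed on the union (label > 0)
mask so that internal interfaces between touching compartments are not
double-counted.  No mesh smoothing is applied — the voxel-face sum is the
definition, not an approximation to be corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_io import CompartmentMask

__all__ = [
    "LabelMetrics",
    "CompartmentMetrics",
    "compartment_volume",
    "compartment_surface_area",
    "metrics",
    "average_duplicate_scans",
]


@dataclass(frozen=True)
class LabelMetrics:
    label: int
    volume_cm3: float
    surface_area_cm2: float
    sa_to_v_ratio: float  # per cm


@dataclass(frozen=True)
class CompartmentMetrics:
    per_label: tuple[LabelMetrics, ...]
    total_volume_cm3: float
    total_surface_area_cm2: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": m.label,
                "volume_cm3": m.volume_cm3,
                "surface_area_cm2": m.surface_area_cm2,
                "sa_v_ratio": m.sa_to_v_ratio,
            }
            for m in self.per_label
        ]
        rows.append(
            {
                "label": "TOTAL",
                "volume_cm3": self.total_volume_cm3,
                "surface_area_cm2": self.total_surface_area_cm2,
                "sa_v_ratio": (
                    self.total_surface_area_cm2 / self.total_volume_cm3
                    if self.total_volume_cm3 > 0
                    else 0.0
                ),
            }
        )
        return pd.DataFrame(rows)


def _exposed_face_area(binary: np.ndarray, spacing) -> float:
    """Total area of faces of True voxels adjacent to False or out-of-bounds."""
    dx, dy, dz = spacing
    face_area = (dy * dz, dx * dz, dx * dy)
    b = binary.astype(np.int8)
    total = 0.0
    for axis, area in enumerate(face_area):
        padded = np.pad(b, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        exposed = int(np.abs(np.diff(padded, axis=axis)).sum())
        total += exposed * area
    return total


def compartment_volume(mask: CompartmentMask) -> tuple[dict[int, float], float]:
    """Per-label and total volume in cm^3 (voxel count x dx x dy x dz)."""
    voxel = mask.spacing[0] * mask.spacing[1] * mask.spacing[2]
    counts = np.bincount(mask.labels.ravel())
    per_label = {k: float(counts[k]) * voxel for k in mask.label_ids}
    return per_label, float(sum(per_label.values()))


def compartment_surface_area(mask: CompartmentMask) -> tuple[dict[int, float], float]:
    """Per-label and total surface area in cm^2 by voxel-face summation.

    The total is measured on the union mask; it equals the sum of per-label
    areas whenever no two labels touch.
    """
    per_label = {
        k: _exposed_face_area(mask.labels == k, mask.spacing) for k in mask.label_ids
    }
    total = _exposed_face_area(mask.labels > 0, mask.spacing)
    return per_label, total


def metrics(mask: CompartmentMask) -> CompartmentMetrics:
    """Aggregate per-compartment and total volume, surface area and SA:V."""
    vols, total_v = compartment_volume(mask)
    areas, total_sa = compartment_surface_area(mask)
    per_label = tuple(
        LabelMetrics(
            label=k,
            volume_cm3=vols[k],
            surface_area_cm2=areas[k],
            sa_to_v_ratio=areas[k] / vols[k],
        )
        for k in sorted(vols)
    )
    return CompartmentMetrics(
        per_label=per_label,
        total_volume_cm3=total_v,
        total_surface_area_cm2=total_sa,
    )


def average_duplicate_scans(metrics_list) -> tuple[float, float]:
    """Mean total volume and surface area across repeat peritoneograms.

    Patients scanned more than once contribute the arithmetic mean of their
    scans' totals to the analysis dataset.
    """
    ms = list(metrics_list)
    if not ms:
        raise ValueError("metrics_list must be non-empty")
    vols = [m.total_volume_cm3 for m in ms]
    areas = [m.total_surface_area_cm2 for m in ms]
    return float(np.mean(vols)), float(np.mean(areas))
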