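"""Semi-automated segmentation of contrast-filled intraperitoneal compartments.

Workflow: a user draws a region of interest (ROI) on a single axial slice
enclosing all contrast-filled compartments; :func:`segment_seed_slice` finds
the compartments on that slice by an intensity band plus connected-component
analysis; :func:`propagate` carries the result to neighboring slices
iteratively until no more slices accept anything; manual corrections are
applied through :func:`apply_edits`.

Contrast (diluted iohexol) is brighter than soft tissue but darker than
cortical bone, so the "higher density" criterion is realized as a two-sided
intensity band ``[hu_low, hu_high]``.  Slice-to-slice acceptance uses a
fractional-overlap rule; components with no direct overlap can still be
admitted if they are diagonally contiguous in 3D with accepted voxels.
Segmentation itself is fully deterministic.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .ct_io import CompartmentMask, CTVolume

__all__ = [
    "ROI",
    "SegmentationParams",
    "MaskEdit",
    "segment_seed_slice",
    "propagate",
    "segment_compartments",
    "apply_edits",
    "canonical_relabel",
]


# ---------------------------------------------------------------------------
# parameter and ROI types
# ---------------------------------------------------------------------------

_STRUCT_2D = {4: ndimage.generate_binary_structure(2, 1), 8: ndimage.generate_binary_structure(2, 2)}
_STRUCT_3D = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the threshold-plus-propagation scheme.

    hu_low / hu_high:
        Intensity band accepted as contrast.  The default [100, 600] admits
        diluted iodinated contrast while excluding soft tissue below and
        bone-like densities above.
    connectivity_2d / connectivity_3d:
        Pixel/voxel adjacency for component analysis (8 and 26 by default:
        thin fluid films often connect diagonally).
    min_component_voxels:
        In-plane components smaller than this are treated as noise.
    overlap_fraction:
        A 2D component on a neighboring slice is accepted when its pixelwise
        overlap with the already-accepted mask is at least this fraction of
        the smaller of the two areas.
    max_slice_gap:
        Number of consecutive slices that may accept nothing before
        propagation in that direction halts (0 = strict contiguity).
    """

    hu_low: float = 100.0
    hu_high: float = 600.0
    connectivity_2d: int = 8
    connectivity_3d: int = 26
    min_component_voxels: int = 10
    overlap_fraction: float = 0.2
    max_slice_gap: int = 0

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError("hu_low must be < hu_high")
        if self.connectivity_2d not in _STRUCT_2D:
            raise ValueError("connectivity_2d must be 4 or 8")
        if self.connectivity_3d not in _STRUCT_3D:
            raise ValueError("connectivity_3d must be 6, 18, or 26")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1]")
        if self.max_slice_gap < 0:
            raise ValueError("max_slice_gap must be >= 0")

    @classmethod
    def from_file(cls, path) -> "SegmentationParams":
        """Read parameters from a JSON object or ``key=value`` lines."""
        text = open(path).read()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = float(val) if "." in val else int(val)
        ints = {"connectivity_2d", "connectivity_3d", "min_component_voxels", "max_slice_gap"}
        kwargs = {k: (int(v) if k in ints else float(v)) for k, v in raw.items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class ROI:
    """A rectangular region on one axial slice enclosing all compartments.

    ``box`` is ``(x0, y0, x1, y1)`` with inclusive bounds.
    """

    slice_index: int
    box: tuple[int, int, int, int]

    def validate(self, vol: CTVolume) -> None:
        nx, ny, nz = vol.shape
        if not 0 <= self.slice_index < nz:
            raise ValueError(f"ROI slice {self.slice_index} outside volume depth {nz}")
        x0, y0, x1, y1 = self.box
        if not (0 <= x0 <= x1 < nx and 0 <= y0 <= y1 < ny):
            raise ValueError(f"ROI box {self.box} outside slice extent {(nx, ny)}")

    def mask2d(self, vol: CTVolume) -> np.ndarray:
        self.validate(vol)
        m = np.zeros(vol.shape[:2], dtype=bool)
        x0, y0, x1, y1 = self.box
        m[x0 : x1 + 1, y0 : y1 + 1] = True
        return m


# ---------------------------------------------------------------------------
# labeling helpers
# ---------------------------------------------------------------------------


def canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by descending voxel count.

    Ties are broken by the component's minimum coordinate, compared
    lexicographically axis by axis, so output labeling is deterministic.
    """
    out = np.zeros_like(labels, dtype=np.int32)
    ids = [int(k) for k in np.unique(labels) if k != 0]
    if not ids:
        return out
    keys = []
    for k in ids:
        where = labels == k
        size = int(where.sum())
        mins = tuple(int(idx.min()) for idx in np.nonzero(where))
        keys.append((-size, mins, k))
    for new, (_, _, old) in enumerate(sorted(keys), start=1):
        out[labels == old] = new
    return out


def _label_slice(band2d: np.ndarray, params: SegmentationParams) -> tuple[np.ndarray, int]:
    """2D components of a thresholded slice, small ones removed."""
    lab, n = ndimage.label(band2d, structure=_STRUCT_2D[params.connectivity_2d])
    if n == 0:
        return lab, 0
    sizes = np.bincount(lab.ravel())
    small = np.flatnonzero(sizes < params.min_component_voxels)
    small = small[small != 0]
    if small.size:
        lab[np.isin(lab, small)] = 0
    return lab, n


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def segment_seed_slice(vol: CTVolume, roi: ROI, params: SegmentationParams) -> np.ndarray:
    """Localize and segment the compartments inside the ROI on one slice.

    Returns a 2D labeled array (same in-plane shape as the volume); labels
    are 1..K ordered by descending component size.  If nothing in the ROI
    falls inside the intensity band an empty mask is returned with a warning.
    """
    inroi = roi.mask2d(vol)
    sl = vol.intensities[:, :, roi.slice_index]
    band = inroi & (sl >= params.hu_low) & (sl <= params.hu_high)
    lab, _ = _label_slice(band, params)
    lab = canonical_relabel(lab)
    if lab.max() == 0:
        warnings.warn(
            "no pixel inside the ROI falls in the contrast intensity band; "
            "returning an empty seed mask",
            stacklevel=2,
        )
    return lab


def _touch_structure_2d(connectivity_3d: int) -> np.ndarray | None:
    """In-plane dilation footprint equivalent to cross-slice adjacency.

    Under 6-connectivity a voxel only touches the voxel directly above or
    below (no dilation); 18-connectivity adds edge neighbors (4-neighborhood);
    26-connectivity adds corners (8-neighborhood).
    """
    if connectivity_3d == 6:
        return None
    return _STRUCT_2D[4] if connectivity_3d == 18 else _STRUCT_2D[8]


def propagate(
    vol: CTVolume,
    seed_mask: np.ndarray,
    seed_slice: int,
    params: SegmentationParams,
) -> CompartmentMask:
    """Iteratively propagate a seed-slice segmentation through the volume.

    A slice worklist is processed to a fixpoint: whenever the accepted set on
    a slice grows, its neighbors are re-examined, so compartments connected
    only through distant slices are still recovered.  A candidate 2D
    component is accepted if its overlap with the nearest non-empty accepted
    slice within ``max_slice_gap + 1`` is at least ``overlap_fraction`` of
    the smaller of the two areas; zero-overlap components diagonally
    contiguous (in 3D) with an adjacent accepted slice are also admitted.
    Final labels are 3D connected components of all accepted voxels,
    renumbered 1..K by descending size.
    """
    seed_mask = np.asarray(seed_mask)
    if seed_mask.shape != vol.shape[:2]:
        raise ValueError("seed mask shape does not match the volume's in-plane shape")
    if not (seed_mask > 0).any():
        raise ValueError("seed mask is empty")
    nz = vol.shape[2]
    if not 0 <= seed_slice < nz:
        raise ValueError("seed slice outside volume")

    band = (vol.intensities >= params.hu_low) & (vol.intensities <= params.hu_high)
    # per-slice candidate components, computed lazily and cached
    comp_cache: dict[int, np.ndarray] = {}

    def candidates(z: int) -> np.ndarray:
        if z not in comp_cache:
            comp_cache[z], _ = _label_slice(band[:, :, z], params)
        return comp_cache[z]

    accepted = np.zeros(vol.shape, dtype=bool)
    accepted[:, :, seed_slice] = seed_mask > 0
    accepted_comp_ids: dict[int, set[int]] = {z: set() for z in range(nz)}
    nonempty = {seed_slice}
    touch = _touch_structure_2d(params.connectivity_3d)
    reach = params.max_slice_gap + 1

    queue: deque[int] = deque()
    for z in (seed_slice - 1, seed_slice + 1):
        if 0 <= z < nz:
            queue.append(z)
    queued = set(queue)

    while queue:
        z = queue.popleft()
        queued.discard(z)
        refs = []
        for step in range(1, reach + 1):
            if z - step in nonempty:
                refs.append(z - step)
                break
        for step in range(1, reach + 1):
            if z + step in nonempty:
                refs.append(z + step)
                break
        if not refs:
            continue
        ref_union = np.zeros(vol.shape[:2], dtype=bool)
        for zr in refs:
            ref_union |= accepted[:, :, zr]
        ref_area = int(ref_union.sum())
        comps = candidates(z)
        grown = False
        adjacent_refs = [zr for zr in refs if abs(zr - z) == 1]
        dilated = None
        for cid in np.unique(comps):
            if cid == 0 or cid in accepted_comp_ids[z]:
                continue
            cmask = comps == cid
            carea = int(cmask.sum())
            overlap = int((cmask & ref_union).sum())
            ok = overlap > 0 and overlap >= params.overlap_fraction * min(carea, ref_area)
            if not ok and overlap == 0 and touch is not None and adjacent_refs:
                if dilated is None:
                    adj = np.zeros(vol.shape[:2], dtype=bool)
                    for zr in adjacent_refs:
                        adj |= accepted[:, :, zr]
                    dilated = ndimage.binary_dilation(adj, structure=touch)
                ok = bool((cmask & dilated).any())
            if ok:
                accepted[:, :, z] |= cmask
                accepted_comp_ids[z].add(int(cid))
                grown = True
        if grown:
            nonempty.add(z)
            for nb in (z - 1, z + 1):
                if 0 <= nb < nz and nb not in queued:
                    queue.append(nb)
                    queued.add(nb)
            # a slice that just became non-empty can also unlock itself as a
            # reference for slices up to `reach` away
            for step in range(2, reach + 1):
                for nb in (z - step, z + step):
                    if 0 <= nb < nz and nb not in queued:
                        queue.append(nb)
                        queued.add(nb)

    lab3, _ = ndimage.label(accepted, structure=_STRUCT_3D[params.connectivity_3d])
    return CompartmentMask(labels=canonical_relabel(lab3), spacing=vol.spacing)


def segment_compartments(vol: CTVolume, roi: ROI, params: SegmentationParams) -> CompartmentMask:
    """Full pipeline: seed-slice segmentation followed by propagation."""
    seed = segment_seed_slice(vol, roi, params)
    if seed.max() == 0:
        return CompartmentMask(
            labels=np.zeros(vol.shape, dtype=np.int32), spacing=vol.spacing
        )
    return propagate(vol, seed, roi.slice_index, params)


# ---------------------------------------------------------------------------
# manual correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskEdit:
    """One radiologist correction: add or remove a set of voxels.

    The voxel set may be given explicitly (``voxels``: iterable of (x, y, z)
    index triples) or as a 2D box plus an inclusive slice range
    (``region=(x0, y0, x1, y1)``, ``slices=(z0, z1)``).
    """

    action: str
    voxels: tuple = ()
    region: tuple[int, int, int, int] | None = None
    slices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError("action must be 'add' or 'remove'")
        if not self.voxels and (self.region is None or self.slices is None):
            raise ValueError("an edit needs either voxels or region + slices")

    def to_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.voxels:
            idx = np.atleast_2d(np.asarray(list(self.voxels), dtype=np.int64))
            if idx.shape[1] != 3:
                raise ValueError("voxels must be (x, y, z) triples")
            if (idx < 0).any() or (idx >= np.asarray(shape)).any():
                raise IndexError("edit voxel outside volume bounds")
            m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if self.region is not None:
            x0, y0, x1, y1 = self.region
            z0, z1 = self.slices
            if not (0 <= x0 <= x1 < shape[0] and 0 <= y0 <= y1 < shape[1] and 0 <= z0 <= z1 < shape[2]):
                raise IndexError("edit region outside volume bounds")
            m[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
        return m


def apply_edits(mask: CompartmentMask, edits: list[MaskEdit]) -> CompartmentMask:
    """Apply add/remove corrections and renumber labels contiguously.

    Added voxels take the label most frequent among their 26-neighbors; an
    added region with no labeled neighbor becomes a new compartment.
    """
    labels = mask.labels.copy()
    struct = _STRUCT_3D[26]
    for edit in edits:
        sel = edit.to_mask(labels.shape)
        if edit.action == "remove":
            labels[sel] = 0
            continue
        todo = sel & (labels == 0)
        # grow labels outward into the added voxels so large additions attach
        # to the adjacent compartment rather than becoming new components
        while todo.any():
            dilated = ndimage.grey_dilation(labels, footprint=struct)
            adoptable = todo & (dilated > 0)
            if not adoptable.any():
                break
            # majority label among 26-neighbors, smallest label on ties
            coords = np.argwhere(adoptable)
            for x, y, z in coords:
                nb = labels[
                    max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
                ]
                vals, counts = np.unique(nb[nb > 0], return_counts=True)
                labels[x, y, z] = int(vals[counts.argmax()])
            todo &= labels == 0
        if todo.any():  # isolated additions: new labels per connected blob
            iso, n = ndimage.label(todo, structure=struct)
            base = int(labels.max())
            labels[todo] = iso[todo] + base
    return CompartmentMask(labels=canonical_relabel(labels), spacing=mask.spacing)
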