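"""Cell/nucleus ROI extraction and post-processing.

The pipeline is mask-agnostic: externally produced masks (e.g. from a
neural-network segmenter) are first-class inputs, and this module supplies
a classical fallback — Otsu thresholding of the smoothed photon-sum image
followed by distance-transform-seeded watershed splitting — plus the
nucleus/cytoplasm bookkeeping every downstream stage relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .core import LabelMask, require_same_grid
from .errors import AmbiguousPairingError

__all__ = [
    "SegmentationParams",
    "PairingResult",
    "segment_cells",
    "segment_nuclei",
    "split_nucleus_cytoplasm",
    "dice_score",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Classical-fallback segmentation knobs.

    ``marker_rel_height`` sets watershed seeds as the connected regions of
    the distance transform above that fraction of each component's
    maximum — one seed per convex cell, two for a touching pair.
    """

    smooth_sigma: float = 2.0
    min_area: int = 50
    marker_rel_height: float = 0.6
    nucleus_intensity_fraction: float = 0.6
    nucleus_min_area: int = 20
    flag_border: bool = True


def _border_labels(labels: np.ndarray) -> tuple:
    edge = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    labs = np.unique(edge)
    return tuple(int(v) for v in labs[labs > 0])


def segment_cells(
    intensity: np.ndarray,
    params: Optional[SegmentationParams] = None,
) -> LabelMask:
    """Segment cells from a photon-sum image.

    Gaussian smoothing, automatic (Otsu) thresholding, hole filling, then
    watershed on the distance transform to split touching objects; objects
    below ``params.min_area`` are discarded. Objects touching the image
    border are flagged in ``border_labels`` but kept.
    """
    params = params or SegmentationParams()
    intensity = np.asarray(intensity, dtype=float)
    if intensity.min() < 0:
        raise ValueError("intensity image must be nonnegative")
    if intensity.max() <= 0:
        return LabelMask(
            np.zeros(intensity.shape, dtype=np.int32),
            kind="cell",
            provenance="classical-fallback",
        )
    smoothed = gaussian(intensity, sigma=params.smooth_sigma, preserve_range=True)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:  # constant image after smoothing
        return LabelMask(
            np.zeros(intensity.shape, dtype=np.int32),
            kind="cell",
            provenance="classical-fallback",
        )
    binary = ndi.binary_fill_holes(smoothed > thr)
    if not binary.any():
        return LabelMask(
            np.zeros(intensity.shape, dtype=np.int32),
            kind="cell",
            provenance="classical-fallback",
        )
    dist = ndi.distance_transform_edt(binary)
    components = cc_label(binary)
    markers = np.zeros_like(components)
    next_marker = 0
    for comp in range(1, components.max() + 1):
        sel = components == comp
        local_max = dist[sel].max()
        seeds = cc_label(sel & (dist > params.marker_rel_height * local_max))
        n_seeds = seeds.max()
        markers[seeds > 0] = seeds[seeds > 0] + next_marker
        next_marker += int(n_seeds)
    labels = watershed(-dist, markers, mask=binary)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < params.min_area)
    labels = np.where(np.isin(labels, small), 0, labels)
    border = _border_labels(labels) if params.flag_border else ()
    return LabelMask(
        labels.astype(np.int32),
        kind="cell",
        provenance="classical-fallback",
        border_labels=border,
    )


def segment_nuclei(
    intensity: np.ndarray,
    cells: LabelMask,
    params: Optional[SegmentationParams] = None,
) -> LabelMask:
    """Dark-interior nucleus detection inside each segmented cell.

    NAD(P)H images show nuclei as dim regions within bright cytoplasm
    (mitochondria dominate the signal), so pixels below
    ``nucleus_intensity_fraction`` of the cell's median intensity are
    candidate nucleus; the largest connected candidate region per cell is
    kept. Nuclei inherit their cell's label.
    """
    params = params or SegmentationParams()
    intensity = np.asarray(intensity, dtype=float)
    require_same_grid(intensity.shape, cells.labels.shape)
    out = np.zeros_like(cells.labels)
    for lab in cells.object_labels:
        sel = cells.labels == lab
        med = np.median(intensity[sel])
        cand = sel & (intensity < params.nucleus_intensity_fraction * med)
        if not cand.any():
            continue
        comps = cc_label(cand)
        sizes = np.bincount(comps.ravel())
        sizes[0] = 0
        best = int(np.argmax(sizes))
        if sizes[best] >= params.nucleus_min_area:
            region = ndi.binary_fill_holes(comps == best) & sel
            out[region] = lab
    return LabelMask(out, kind="nucleus", provenance=cells.provenance)


@dataclass
class PairingResult:
    """Nucleus/cytoplasm split of a cell mask."""

    cytoplasm: LabelMask
    pairing: Dict[int, int]  # cell label -> nucleus label
    unpaired_cells: tuple  # flagged: no nucleus; excluded from nuclear metrics


def split_nucleus_cytoplasm(cells: LabelMask, nuclei: LabelMask) -> PairingResult:
    """Pair nuclei to cells by majority overlap and carve out cytoplasm.

    Cytoplasm of cell k is the pixelwise set difference cell k minus its
    paired nucleus. A nucleus whose area has no majority (>50%) inside a
    single cell raises :class:`AmbiguousPairingError`; cells without a
    paired nucleus keep their whole footprint as cytoplasm and are flagged.
    """
    require_same_grid(cells.labels.shape, nuclei.labels.shape)
    pairing: Dict[int, int] = {}
    claimed: Dict[int, Tuple[int, int]] = {}  # cell -> (nucleus, overlap)
    for nuc in nuclei.object_labels:
        nsel = nuclei.labels == nuc
        under = cells.labels[nsel]
        owners, counts = np.unique(under[under > 0], return_counts=True)
        if owners.size == 0:
            continue  # nucleus entirely over background
        best = int(np.argmax(counts))
        if counts[best] <= 0.5 * nsel.sum():
            raise AmbiguousPairingError(
                f"nucleus {int(nuc)} has no majority cell "
                f"(candidates: {[int(o) for o in owners]})"
            )
        cell = int(owners[best])
        prev = claimed.get(cell)
        if prev is None or counts[best] > prev[1]:
            claimed[cell] = (int(nuc), int(counts[best]))
    pairing = {cell: nuc for cell, (nuc, _) in claimed.items()}

    cyto = cells.labels.copy()
    for cell, nuc in pairing.items():
        cyto[(cells.labels == cell) & (nuclei.labels == nuc)] = 0
    unpaired = tuple(
        int(lab) for lab in cells.object_labels if int(lab) not in pairing
    )
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} cell(s) without a paired nucleus: {unpaired}",
            stacklevel=2,
        )
    return PairingResult(
        cytoplasm=LabelMask(cyto, kind="cytoplasm", provenance=cells.provenance),
        pairing=pairing,
        unpaired_cells=unpaired,
    )


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks (1.0 if both empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    require_same_grid(a.shape, b.shape)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
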