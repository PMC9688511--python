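"""Phantom FLIM scene generator.

Emulates a two-photon TCSPC acquisition of cultured cells: elliptical cells
with dimmer nuclei on a dark background, a per-field photon budget set by
the detector count rate and the frame integration time (default
1.5e5 photons/s for 60 s), Gaussian IRF, Poisson photon noise and a small
uniform dark-count floor. Every scene carries its ground truth — label
masks, per-compartment decay parameters and photon budgets — in a JSON-able
manifest, so downstream segmentation and fitting can be scored by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
from scipy import ndimage as ndi

from .core import AcquisitionConfig, DecayCurve, DecaySpec, FLIMStack, LabelMask
from .errors import InvalidConfigError, PlacementError
from .model import decay_shape, expected_counts, make_irf

__all__ = [
    "PhantomScene",
    "make_irf",
    "simulate_decay_histogram",
    "render_phantom_scene",
]

MANIFEST_VERSION = 1


@dataclass
class PhantomScene:
    """A rendered phantom field of view with its ground truth."""

    stacks: Dict[str, FLIMStack]
    cell_mask: LabelMask
    nucleus_mask: LabelMask
    truth_decays: Dict[str, DecaySpec]  # "channel/compartment" -> spec
    manifest: dict

    @property
    def config(self) -> AcquisitionConfig:
        return next(iter(self.stacks.values())).config

    def truth_pairing(self) -> Dict[int, int]:
        """Cell label -> nucleus label (identical by construction)."""
        return {int(c["label"]): int(c["label"]) for c in self.manifest["cells"]}

    def compartment_budget(self, label: int, compartment: str) -> float:
        """Ground-truth expected signal photons of one ROI compartment."""
        return self.manifest["budgets"][f"{label}/{compartment}"]


def simulate_decay_histogram(
    spec: DecaySpec,
    cfg: AcquisitionConfig,
    photons: float,
    rng: Optional[np.random.Generator] = None,
    sample: bool = True,
    irf: Optional[np.ndarray] = None,
    wrap: bool = False,
):
    """Simulate one ROI-aggregated TCSPC histogram.

    The expected profile is ``photons * (IRF (*) normalized exponential
    mixture)`` plus a uniform dark floor of ``cfg.dark_count_fraction`` of
    the budget; with ``sample=True`` each bin is Poisson-sampled.

    Returns a :class:`~flimcell.core.DecayCurve` (integer counts when
    sampled, expected float counts otherwise).
    """
    lam = expected_counts(spec, cfg, photons, irf=irf, wrap=wrap)
    if sample:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        counts = rng.poisson(lam)
    else:
        counts = lam
    return DecayCurve(counts=counts, config=cfg, roi_id=("", spec.label or "roi"))


def _draw_ellipse(shape, center, axes, angle):
    """Boolean mask of a filled rotated ellipse (pixel-centre inclusion)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = center
    ca, sa = np.cos(angle), np.sin(angle)
    dy, dx = yy - cy, xx - cx
    u = (ca * dx + sa * dy) / axes[1]
    v = (-sa * dx + ca * dy) / axes[0]
    r2 = u * u + v * v
    return r2 <= 1.0, r2


def _place_cells(n_cells, shape, rng, gap=3, max_tries_per_cell=400):
    """Seeded rejection sampling of non-overlapping ellipse footprints."""
    occupied = np.zeros(shape, dtype=bool)
    struct = ndi.generate_binary_structure(2, 2)
    cells = []
    for k in range(n_cells):
        placed = False
        for _ in range(max_tries_per_cell):
            a = rng.uniform(14.0, 20.0)  # semi-major, px
            b = rng.uniform(10.0, 14.0)  # semi-minor, px
            margin = a + gap + 1
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            angle = rng.uniform(0.0, np.pi)
            mask, _ = _draw_ellipse(shape, (cy, cx), (a, b), angle)
            dilated = ndi.binary_dilation(mask, structure=struct, iterations=gap)
            if not np.any(dilated & occupied):
                occupied |= dilated
                cells.append(
                    {
                        "label": k + 1,
                        "center": [float(cy), float(cx)],
                        "axes": [float(a), float(b)],
                        "angle": float(angle),
                    }
                )
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {k + 1} of {n_cells} without overlap"
            )
    return cells


def render_phantom_scene(
    n_cells: int,
    cfg: AcquisitionConfig,
    group_specs: Mapping,
    shape=(256, 256),
    nucleus_budget_fraction: float = 0.4,
    nucleus_scale: float = 0.5,
    sample: bool = True,
    wrap: bool = False,
) -> PhantomScene:
    """Render a phantom field of view with known ground truth.

    Parameters
    ----------
    n_cells
        Number of cells to place (non-overlapping ellipses, seeded
        rejection sampling driven by ``cfg.seed``).
    cfg
        Acquisition configuration; ``photon_budget`` is the total expected
        signal of the field, split across cells in proportion to their
        integrated intensity profile.
    group_specs
        Either ``{compartment: DecaySpec}`` for a single channel or
        ``{channel: {compartment: DecaySpec}}``. Compartments are
        ``"cytoplasm"`` and ``"nucleus"``.
    nucleus_budget_fraction
        Per-pixel photon budget of nuclei relative to cytoplasm (nuclei are
        dimmer in NAD(P)H images where mitochondria dominate).
    nucleus_scale
        Nucleus semi-axes relative to the cell's.
    sample
        Poisson-sample the stack (integer counts); ``False`` returns the
        expected float counts, useful for noise-free oracles.
    """
    if n_cells < 0:
        raise InvalidConfigError("n_cells must be nonnegative")
    # normalize to {channel: {compartment: spec}}
    first = next(iter(group_specs.values()), None)
    if first is None or isinstance(first, DecaySpec):
        channel_specs = {"main": dict(group_specs)}
    else:
        channel_specs = {ch: dict(specs) for ch, specs in group_specs.items()}
    for ch, specs in channel_specs.items():
        for comp in specs:
            if comp not in ("cytoplasm", "nucleus"):
                raise InvalidConfigError(f"unknown compartment {comp!r} in channel {ch!r}")

    rng = np.random.default_rng(cfg.seed)
    cells = _place_cells(n_cells, shape, rng)

    cell_labels = np.zeros(shape, dtype=np.uint16)
    nucleus_labels = np.zeros(shape, dtype=np.uint16)
    weight = np.zeros(shape)  # relative per-pixel photon budget
    for c in cells:
        mask, r2 = _draw_ellipse(shape, c["center"], c["axes"], c["angle"])
        # nucleus concentric with the cell, scaled semi-axes: strictly inside
        nmask, _ = _draw_ellipse(
            shape,
            c["center"],
            (c["axes"][0] * nucleus_scale, c["axes"][1] * nucleus_scale),
            c["angle"],
        )
        nmask &= mask
        cell_labels[mask] = c["label"]
        nucleus_labels[nmask] = c["label"]
        # smooth radial intensity profile: full at centre, half at the rim
        w = np.where(mask, 1.0 - 0.5 * np.clip(r2, 0.0, 1.0), 0.0)
        w[nmask] *= nucleus_budget_fraction
        weight += w

    total_weight = weight.sum()
    budget = cfg.photon_budget
    if total_weight > 0:
        pixel_budget = weight * (budget / total_weight)
    else:
        pixel_budget = weight

    n_bins = cfg.n_bins
    irf = make_irf(cfg)
    dtype = np.float64 if not sample else np.uint16
    stacks: Dict[str, FLIMStack] = {}
    truth_decays: Dict[str, DecaySpec] = {}
    budgets: Dict[str, float] = {}

    cyto_sel = (cell_labels > 0) & (nucleus_labels == 0)
    nuc_sel = nucleus_labels > 0
    for c in cells:
        lab = c["label"]
        budgets[f"{lab}/cytoplasm"] = float(pixel_budget[cyto_sel & (cell_labels == lab)].sum())
        budgets[f"{lab}/nucleus"] = float(pixel_budget[nuc_sel & (nucleus_labels == lab)].sum())
        budgets[f"{lab}/cell"] = budgets[f"{lab}/cytoplasm"] + budgets[f"{lab}/nucleus"]

    for ch, specs in channel_specs.items():
        data = np.zeros(shape + (n_bins,), dtype=np.float64)
        for comp, spec in specs.items():
            sel = cyto_sel if comp == "cytoplasm" else nuc_sel
            if not np.any(sel):
                continue
            shape_vec = decay_shape(spec.lifetimes, spec.amplitudes, irf, cfg, wrap=wrap)
            lam = pixel_budget[sel][:, None] * shape_vec[None, :]
            data[sel] = rng.poisson(lam) if sample else lam
            truth_decays[f"{ch}/{comp}"] = spec
        # dark counts: uniform over pixels and bins
        dark_total = cfg.dark_count_fraction * budget
        if dark_total > 0:
            if sample:
                n_dark = rng.poisson(dark_total)
                if n_dark > 0:
                    flat_idx = rng.integers(0, data.size, size=n_dark)
                    np.add.at(data.reshape(-1), flat_idx, 1)
            else:
                data += dark_total / data.size
        stacks[ch] = FLIMStack(data=data.astype(dtype), config=cfg, channel=ch)

    manifest = {
        "format_version": MANIFEST_VERSION,
        "config": cfg.to_dict(),
        "n_cells": n_cells,
        "shape": list(shape),
        "nucleus_budget_fraction": nucleus_budget_fraction,
        "nucleus_scale": nucleus_scale,
        "sample": sample,
        "wrap": wrap,
        "channels": {
            ch: {comp: spec.to_dict() for comp, spec in specs.items()}
            for ch, specs in channel_specs.items()
        },
        "cells": cells,
        "budgets": budgets,
    }

    return PhantomScene(
        stacks=stacks,
        cell_mask=LabelMask(cell_labels, kind="cell", provenance="ground-truth"),
        nucleus_mask=LabelMask(nucleus_labels, kind="nucleus", provenance="ground-truth"),
        truth_decays=truth_decays,
        manifest=manifest,
    )
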